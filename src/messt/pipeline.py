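"""End-to-end glue: simulate a session to disk, analyze it back.

These functions tie the schedule builder, race simulator, gaze synthesizer
and the two analysis stages together on the documented file formats, and
are what the command-line interface calls.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import gaze_analysis as ga
from .asc import read_asc_subset, write_asc_subset
from .design import SessionConfig, build_schedule
from .gaze_synthesis import Scanpath, synthesize_session_gaze
from .geometry import AOI, aoi_for_side
from .iofmt import (config_to_text, read_aoi_config, write_aoi_config,
                    write_config, write_manifest, write_schedule)
from .race import (ParticipantModel, read_trial_log, simulate_session,
                   write_ground_truth, write_trial_log)
from .ssrt import qc_staircase, session_ssrt_table, write_ssrt_results

__all__ = ["simulate_to_dir", "analyze_dir"]


def simulate_to_dir(
    out_dir: str | Path,
    config: SessionConfig,
    seed: int,
    participant: ParticipantModel | None = None,
    scanpath: Scanpath | None = None,
    noise_sd: float = 2.0,
    loss_fraction: float = 0.02,
) -> dict[str, Path]:
    """Simulate one full session and write every artifact to ``out_dir``.

    Produces: session config, schedule CSV, behavioral trial log CSV,
    ASC-subset gaze file, AOI geometry file, ground-truth sidecars and a
    run manifest.  Behavioral and gaze randomness derive from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participant = participant or ParticipantModel()
    schedule = build_schedule(config, seed)
    trials, _state = simulate_session(schedule, participant, config, seed)
    ssds = {t.index: t.ssd for t in trials if t.is_stop}
    streams, timelines, truths = synthesize_session_gaze(
        schedule, ssds, config, seed + 1, scanpath=scanpath,
        noise_sd=noise_sd, loss_fraction=loss_fraction)
    events = {}
    for ix, tl in timelines.items():
        ev = {"STIM_ONSET": next(e.t for e in tl if e.label == "stimulus-onset"),
              "TRIAL_END": next(e.t for e in tl if e.label == "response-deadline")}
        tone = [e.t for e in tl if e.label == "tone-onset"]
        if tone:
            ev["TONE_ONSET"] = tone[0]
        events[ix] = ev

    paths = {
        "config": out / "session.cfg",
        "schedule": out / "schedule.csv",
        "trials": out / "trials.csv",
        "asc": out / "gaze.asc",
        "aoi": out / "aoi.cfg",
        "gaze_truth": out / "gaze_truth.csv",
        "participant_truth": out / "participant_truth.json",
        "manifest": out / "manifest.json",
    }
    write_config(config, paths["config"])
    write_schedule(schedule, paths["schedule"])
    write_trial_log(trials, paths["trials"])
    write_asc_subset(streams, events, paths["asc"],
                     header={"SAMPLE_RATE": f"{config.sampling_rate:g}",
                             "SEED": str(seed)})
    write_aoi_config({s: aoi_for_side(s, config.stimulus_px,
                                      config.eccentricity_deg)
                      for s in ("left", "right")}, paths["aoi"])
    pd.DataFrame([t.__dict__ for t in truths]).to_csv(
        paths["gaze_truth"], index=False)
    write_ground_truth(participant, seed, paths["participant_truth"])
    write_manifest(paths["manifest"], seed, config_to_text(config),
                   inputs={}, outputs={k: str(v) for k, v in paths.items()
                                       if k != "manifest"})
    return paths


def analyze_dir(
    session_dir: str | Path,
    out_dir: str | Path | None = None,
    config: SessionConfig | None = None,
    dispersion_deg: float = ga.DEFAULT_DISPERSION_DEG,
    min_fix_dur: float = ga.DEFAULT_MIN_DURATION_MS,
    session_wide_ssd: bool = False,
) -> dict[str, object]:
    """Analyze a simulated (or converted) session directory.

    Reads the trial log, gaze ASC and AOI geometry; detects fixations,
    computes per-trial AOI metrics with the exclusion rules, estimates
    per-category SSRT and the staircase QC report; writes metrics/SSRT/QC
    files next to the inputs (or under ``out_dir``).
    """
    src = Path(session_dir)
    out = Path(out_dir) if out_dir else src
    out.mkdir(parents=True, exist_ok=True)
    from .iofmt import read_config
    config = config or read_config(src / "session.cfg")
    trials = read_trial_log(src / "trials.csv")
    aois = read_aoi_config(src / "aoi.cfg")
    streams, events = read_asc_subset(src / "gaze.asc")
    side_by_trial = {t.index: t.side for t in trials}

    metrics = []
    for ix in sorted(streams):
        samples = streams[ix]
        ev = events[ix]
        fix = ga.detect_fixations(samples, dispersion_deg, min_fix_dur)
        metrics.append(ga.compute_aoi_metrics(
            fix, samples, aois[side_by_trial[ix]],
            stimulus_onset=ev["STIM_ONSET"], window_end=ev["TRIAL_END"],
            trial_index=ix))
    included, exclusion_summary = ga.apply_exclusions(metrics)
    metrics_df = ga.metrics_frame(metrics)
    ssrt_df = session_ssrt_table(trials, config.categories,
                                 session_wide_ssd=session_wide_ssd)
    qc = qc_staircase(trials, config)

    metrics_df.to_csv(out / "gaze_metrics.csv", index=False)
    exclusion_summary.to_csv(out / "exclusions.csv", index=False)
    write_ssrt_results(ssrt_df, out / "ssrt.csv", out / "ssrt.json")
    import json
    (out / "qc.json").write_text(json.dumps(qc.__dict__, indent=2))
    return {
        "metrics": metrics_df,
        "included": included,
        "exclusions": exclusion_summary,
        "ssrt": ssrt_df,
        "qc": qc,
    }
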