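"""Synthetic gaze streams time-locked to trial events.

Generates sample-level gaze recordings with known ground truth: the eye
holds central fixation, launches a saccade to the stimulus after a
parameterized latency, dwells inside the AOI (optionally returning to
center and re-fixating), all with Gaussian positional jitter.  Blink-shaped
runs of invalid samples model tracker loss.  Oculomotor realism (main
sequence kinematics, microsaccades, pursuit) is deliberately out of scope —
the streams exist to exercise the fixation detector and the exclusion
rules against a constructed truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SessionConfig, TimelineEvent, TrialSpec, trial_timeline
from .geometry import AOI, ScreenGeometry

__all__ = [
    "GazeSample",
    "Scanpath",
    "GazeGroundTruth",
    "synthesize_trial_gaze",
    "inject_loss",
    "synthesize_session_gaze",
]

PUPIL_BASELINE = 1000.0
BLINK_RAMP_MS = 20.0  # half-cosine pupil ramp into/out of a blink


@dataclass(frozen=True)
class GazeSample:
    """One tracker sample on the common clock; x/y are NaN when invalid."""

    t: float
    x: float
    y: float
    pupil: float
    valid: bool


@dataclass(frozen=True)
class Scanpath:
    """Constructed gaze itinerary for one trial (all durations ms).

    ``saccade_latency`` is measured from stimulus onset; ``travel`` is the
    in-flight saccade duration; ``dwell`` is the *total* time inside the
    AOI, split evenly over ``1 + refix_count`` visits separated by returns
    to center.
    """

    saccade_latency: float = 180.0
    travel: float = 30.0
    dwell: float = 600.0
    refix_count: int = 0
    center_gap: float = 150.0  # center re-fixation time between AOI visits


@dataclass(frozen=True)
class GazeGroundTruth:
    """Constructed per-trial truth against which analysis is validated."""

    trial_index: int
    first_fixation_latency: float | None
    dwell: float
    fixation_count: int
    loss_fraction: float = 0.0


def _segments(timeline: list[TimelineEvent], aoi: AOI, scan: Scanpath,
              screen: ScreenGeometry) -> tuple[list[tuple[float, float, tuple, tuple]], float, float]:
    ev = {e.label: e for e in timeline}
    t_start = ev["fixation-onset"].t
    onset = ev["stimulus-onset"].t
    t_end = ev["response-deadline"].t
    c = screen.center
    a = aoi.center
    visits = scan.refix_count + 1
    visit_dwell = scan.dwell / visits
    # (seg_start, seg_end, from_xy, to_xy); from == to means a hold
    segs: list[tuple[float, float, tuple, tuple]] = []
    t = t_start
    segs.append((t, onset + scan.saccade_latency, c, c))
    t = onset + scan.saccade_latency
    for v in range(visits):
        segs.append((t, t + scan.travel, c, a))          # saccade out
        t += scan.travel
        segs.append((t, t + visit_dwell, a, a))           # AOI hold
        t += visit_dwell
        if v < visits - 1:
            segs.append((t, t + scan.travel, a, c))       # saccade back
            t += scan.travel
            segs.append((t, t + scan.center_gap, c, c))   # center hold
            t += scan.center_gap
    if t + scan.travel > t_end:
        raise ValueError(
            f"scanpath ({t - onset:.0f} ms after onset) exceeds the "
            f"stimulus display window ({t_end - onset:.0f} ms)"
        )
    # leave the AOI after the last visit so total AOI time is exactly `dwell`
    segs.append((t, t + scan.travel, a, c))
    segs.append((t + scan.travel, t_end, c, c))
    return segs, t_start, t_end


def synthesize_trial_gaze(
    timeline: list[TimelineEvent],
    aoi: AOI,
    scanpath: Scanpath,
    noise_sd: float,
    rng: np.random.Generator,
    trial_index: int = 0,
    sampling_rate: float = 2000.0,
    screen: ScreenGeometry = ScreenGeometry(),
) -> tuple[list[GazeSample], GazeGroundTruth]:
    """Generate one trial's gaze samples plus its ground truth.

    Samples cover [fixation-onset, response-deadline) at the tracker
    cadence.  Ground truth is derived from the constructed path under the
    metric definitions: when the AOI excludes screen center the
    first-fixation latency is ``saccade_latency + travel`` (the eye lands
    in the AOI then) and dwell equals the scanpath's total AOI hold time;
    when the AOI overlaps center, central holds count too, exactly as a
    fixation-based analysis counts them.
    """
    aoi.validate_on_screen(screen)
    segs, t_start, t_end = _segments(timeline, aoi, scanpath, screen)
    dt = 1000.0 / sampling_rate
    n = int(round((t_end - t_start) / dt))
    t = t_start + dt * np.arange(n)
    x = np.empty(n)
    y = np.empty(n)
    for s0, s1, p0, p1 in segs:
        m = (t >= s0) & (t < s1)
        if not m.any():
            continue
        if p0 == p1:
            x[m], y[m] = p0
        else:  # linear in-flight interpolation
            frac = (t[m] - s0) / (s1 - s0)
            x[m] = p0[0] + frac * (p1[0] - p0[0])
            y[m] = p0[1] + frac * (p1[1] - p0[1])
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
        y += rng.normal(0.0, noise_sd, n)
    pupil = np.full(n, PUPIL_BASELINE)
    samples = [GazeSample(float(ti), float(xi), float(yi), float(pi), True)
               for ti, xi, yi, pi in zip(t, x, y, pupil)]
    onset = next(e.t for e in timeline if e.label == "stimulus-onset")
    truth = _truth_from_segments(segs, aoi, onset, t_end, trial_index)
    return samples, truth


def _truth_from_segments(segs, aoi: AOI, onset: float, t_end: float,
                         trial_index: int) -> GazeGroundTruth:
    """Ground truth implied by the constructed path under the metric rules.

    Holds (stationary segments) inside the AOI contribute their
    post-onset portion to dwell; the first in-AOI hold *starting* at or
    after onset defines the latency.  When the AOI overlaps screen center
    (the full-size picture at 8 degrees does), central holds count toward
    dwell exactly as a fixation-based analysis would count them.
    """
    holds = [(s0, s1, p0) for s0, s1, p0, p1 in segs if p0 == p1]
    in_aoi = [(s0, s1) for s0, s1, pos in holds
              if aoi.contains(*pos) and s1 > onset and s0 < t_end]
    dwell = sum(min(s1, t_end) - max(s0, onset) for s0, s1 in in_aoi)
    starters = [s0 for s0, s1 in in_aoi if s0 >= onset]
    return GazeGroundTruth(
        trial_index=trial_index,
        first_fixation_latency=(min(starters) - onset) if starters else None,
        dwell=float(dwell),
        fixation_count=len(in_aoi),
        loss_fraction=0.0,
    )


def inject_loss(samples: list[GazeSample], loss_fraction: float,
                blink_len_ms: float, rng: np.random.Generator) -> list[GazeSample]:
    """Mark contiguous blink-shaped runs invalid until the target loss is met.

    Blink starts are drawn uniformly; runs may overlap.  Marking stops as
    soon as the invalid proportion reaches ``loss_fraction``, so the final
    proportion lies in ``[loss_fraction, loss_fraction + one blink)``.
    Pupil traces ramp down/up with a 20 ms half-cosine at run edges; sample
    count and timestamps are unchanged.
    """
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss_fraction must lie in [0, 1]")
    n = len(samples)
    if n == 0 or loss_fraction == 0.0:
        return list(samples)
    dt = samples[1].t - samples[0].t if n > 1 else 0.5
    blink_n = max(1, int(round(blink_len_ms / dt)))
    invalid = np.zeros(n, dtype=bool)
    target = loss_fraction * n
    if loss_fraction >= 1.0:
        invalid[:] = True
    else:
        while invalid.sum() < target:
            start = int(rng.integers(0, n))
            invalid[start:start + blink_n] = True
    pupil = np.array([s.pupil for s in samples])
    ramp_n = max(1, int(round(BLINK_RAMP_MS / dt)))
    edges = np.flatnonzero(np.diff(invalid.astype(int)))
    for e in edges:
        if invalid[e + 1]:  # closing: ramp down before the run
            lo = max(0, e - ramp_n + 1)
            k = e - lo + 1
            pupil[lo:e + 1] *= 0.5 * (1 + np.cos(np.linspace(0, np.pi, k)))
        else:  # opening: ramp up after the run
            hi = min(n, e + 1 + ramp_n)
            k = hi - (e + 1)
            pupil[e + 1:hi] *= 0.5 * (1 - np.cos(np.linspace(0, np.pi, k)))
    out = []
    for i, s in enumerate(samples):
        if invalid[i]:
            out.append(GazeSample(s.t, float("nan"), float("nan"), 0.0, False))
        else:
            out.append(GazeSample(s.t, s.x, s.y, float(pupil[i]), True))
    return out


def synthesize_session_gaze(
    schedule: list[TrialSpec],
    ssds: dict[int, float],
    config: SessionConfig,
    seed: int,
    scanpath: Scanpath | None = None,
    noise_sd: float = 2.0,
    loss_fraction: float = 0.0,
    blink_len_ms: float = 100.0,
    screen: ScreenGeometry = ScreenGeometry(),
) -> tuple[dict[int, list[GazeSample]], dict[int, list[TimelineEvent]], list[GazeGroundTruth]]:
    """Gaze streams for every trial of a session on one common clock.

    ``ssds`` maps stop-trial index -> presented SSD (from the behavioral
    log).  Trials are laid out back to back: each trial starts after the
    previous trial's ITI.  Returns per-trial samples, per-trial timelines
    and the ground-truth list.
    """
    from .geometry import aoi_for_side

    rng = np.random.default_rng(seed)
    base = scanpath or Scanpath()
    t0 = 0.0
    streams: dict[int, list[GazeSample]] = {}
    timelines: dict[int, list[TimelineEvent]] = {}
    truths: list[GazeGroundTruth] = []
    for spec in schedule:
        ssd = ssds.get(spec.index, 0.0) if spec.is_stop else 0.0
        tl = trial_timeline(spec, ssd, config, t0=t0)
        aoi = aoi_for_side(spec.side, config.stimulus_px,
                           config.eccentricity_deg, screen)
        # per-trial latency jitter keeps streams from being carbon copies
        jit = float(rng.normal(0.0, 15.0))
        scan = Scanpath(
            saccade_latency=max(80.0, base.saccade_latency + jit),
            travel=base.travel, dwell=base.dwell,
            refix_count=base.refix_count, center_gap=base.center_gap,
        )
        samples, truth = synthesize_trial_gaze(
            tl, aoi, scan, noise_sd, rng, trial_index=spec.index,
            sampling_rate=config.sampling_rate, screen=screen,
        )
        if loss_fraction > 0:
            samples = inject_loss(samples, loss_fraction, blink_len_ms, rng)
            frac = sum(not s.valid for s in samples) / len(samples)
            truth = GazeGroundTruth(truth.trial_index,
                                    truth.first_fixation_latency,
                                    truth.dwell, truth.fixation_count,
                                    loss_fraction=frac)
        streams[spec.index] = samples
        timelines[spec.index] = tl
        truths.append(truth)
        t0 = tl[-1].t + tl[-1].duration  # next trial after the ITI
    return streams, timelines, truths
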