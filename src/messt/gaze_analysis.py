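"""Fixation detection and AOI metrics for the task's ocular measures.

Fixations are detected with the dispersion-threshold algorithm (I-DT):
maximal runs of valid samples whose spatial dispersion (x-range + y-range,
expressed in degrees of visual angle) stays under a threshold and which
last at least a minimum duration.  From the fixation stream and the
stimulus AOI the module derives the study's three ocular metrics —
latency to first fixation on the picture (attentional vigilance), total
dwell time inside it (attentional maintenance) and fixation count — and
applies the exclusion rules: trials with no stimulus fixation or with more
than 25 % tracker sample loss are dropped from ocular analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_synthesis import GazeSample
from .geometry import AOI, ScreenGeometry

__all__ = [
    "Fixation",
    "OcularTrialMetrics",
    "detect_fixations",
    "compute_aoi_metrics",
    "apply_exclusions",
    "drift_check",
    "metrics_frame",
    "SAMPLE_LOSS_THRESHOLD",
    "DRIFT_THRESHOLD_DEG",
]

#: trials with a loss fraction strictly above this are excluded
SAMPLE_LOSS_THRESHOLD = 0.25
#: drift-correction errors strictly above this trigger recalibration
DRIFT_THRESHOLD_DEG = 1.0

DEFAULT_DISPERSION_DEG = 1.0
DEFAULT_MIN_DURATION_MS = 100.0


@dataclass(frozen=True)
class Fixation:
    start: float  # ms, time of first sample in the fixation
    end: float    # ms, time of last sample + one sample interval
    cx: float
    cy: float
    dispersion_deg: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_fixations(
    samples: list[GazeSample],
    dispersion_deg: float = DEFAULT_DISPERSION_DEG,
    min_dur: float = DEFAULT_MIN_DURATION_MS,
    screen: ScreenGeometry = ScreenGeometry(),
) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    Scans left to right: from each candidate start, the window is extended
    as far as dispersion (max x-range + max y-range, converted to degrees)
    allows; if the maximal window lasts >= ``min_dur`` it becomes a
    fixation and scanning resumes after it, otherwise the start advances
    one sample.  Invalid samples terminate windows.  A fixation's end time
    extends one sample interval past its last sample, so a hold of k
    samples at cadence dt has duration k*dt.
    """
    if dispersion_deg <= 0 or min_dur <= 0:
        raise ValueError("thresholds must be positive")
    t = np.array([s.t for s in samples])
    x = np.array([s.x for s in samples])
    y = np.array([s.y for s in samples])
    valid = np.array([s.valid for s in samples], dtype=bool)
    n = len(samples)
    if valid.sum() < 2:
        return []
    dt = float(np.median(np.diff(t))) if n > 1 else 0.0
    max_disp_px = screen.deg_to_px(dispersion_deg)
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        # extend window [i, j] while all samples valid and dispersion ok
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        j = i
        while j + 1 < n and valid[j + 1]:
            nxmin = min(xmin, x[j + 1]); nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1]); nymax = max(ymax, y[j + 1])
            if (nxmax - nxmin) + (nymax - nymin) > max_disp_px:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        duration = t[j] - t[i] + dt
        if duration >= min_dur:
            fixations.append(Fixation(
                start=float(t[i]), end=float(t[j] + dt),
                cx=float(x[i:j + 1].mean()), cy=float(y[i:j + 1].mean()),
                dispersion_deg=screen.px_to_deg((xmax - xmin) + (ymax - ymin)),
            ))
            i = j + 1
        else:
            i += 1
    return fixations


@dataclass(frozen=True)
class OcularTrialMetrics:
    """Per-trial ocular metrics plus inclusion status."""

    trial_index: int
    first_fixation_latency: float | None
    dwell_time: float
    fixation_count: int
    loss_fraction: float
    included: bool
    exclusion_reason: str  # "none" | "no-stimulus-fixation" | "sample-loss"


def compute_aoi_metrics(
    fixations: list[Fixation],
    samples: list[GazeSample],
    aoi: AOI,
    stimulus_onset: float,
    window_end: float,
    trial_index: int = 0,
) -> OcularTrialMetrics:
    """Derive the trial's AOI metrics over [stimulus_onset, window_end).

    AOI membership is decided by fixation centroid.  Latency is the first
    in-AOI fixation *starting* at or after stimulus onset, relative to
    onset; a fixation already in progress at onset contributes its
    post-onset portion to dwell but cannot be the "first fixation"
    (vigilance must follow onset).  Loss fraction counts invalid samples
    within the window; above the 25 % threshold (strict) the trial is
    excluded, as is a trial with no in-AOI fixation.
    """
    if stimulus_onset >= window_end:
        raise ValueError("stimulus_onset must precede window_end")
    in_window = [s for s in samples if stimulus_onset <= s.t < window_end]
    if not in_window:
        return OcularTrialMetrics(trial_index, None, 0.0, 0, 1.0,
                                  included=False, exclusion_reason="sample-loss")
    loss = sum(not s.valid for s in in_window) / len(in_window)
    aoi_fix = [f for f in fixations
               if aoi.contains(f.cx, f.cy) and f.end > stimulus_onset
               and f.start < window_end]
    dwell = sum(min(f.end, window_end) - max(f.start, stimulus_onset)
                for f in aoi_fix)
    post_onset = [f for f in aoi_fix if f.start >= stimulus_onset]
    latency = post_onset[0].start - stimulus_onset if post_onset else None
    if loss > SAMPLE_LOSS_THRESHOLD:
        inc, reason = False, "sample-loss"
    elif not aoi_fix:
        inc, reason = False, "no-stimulus-fixation"
    else:
        inc, reason = True, "none"
    return OcularTrialMetrics(
        trial_index=trial_index,
        first_fixation_latency=latency,
        dwell_time=float(dwell),
        fixation_count=len(aoi_fix),
        loss_fraction=float(loss),
        included=inc,
        exclusion_reason=reason,
    )


def apply_exclusions(
    metrics: list[OcularTrialMetrics],
) -> tuple[list[OcularTrialMetrics], pd.DataFrame]:
    """Split metrics into the included set and an exclusion summary table."""
    included = [m for m in metrics if m.included]
    counts = {"none": 0, "no-stimulus-fixation": 0, "sample-loss": 0}
    for m in metrics:
        counts[m.exclusion_reason] = counts.get(m.exclusion_reason, 0) + 1
    summary = pd.DataFrame(
        {"reason": list(counts), "n_trials": list(counts.values())}
    )
    return included, summary


def drift_check(reported_error_deg: float) -> str:
    """Return ``"recalibrate"`` when drift error strictly exceeds 1 degree."""
    if reported_error_deg < 0:
        raise ValueError("drift error must be nonnegative")
    return "recalibrate" if reported_error_deg > DRIFT_THRESHOLD_DEG else "pass"


def metrics_frame(metrics: list[OcularTrialMetrics]) -> pd.DataFrame:
    """Per-trial metrics as a tidy table (column order fixed)."""
    return pd.DataFrame([{
        "trial": m.trial_index,
        "first_fixation_latency": m.first_fixation_latency,
        "dwell_time": m.dwell_time,
        "fixation_count": m.fixation_count,
        "loss_fraction": m.loss_fraction,
        "included": m.included,
        "exclusion_reason": m.exclusion_reason,
    } for m in metrics])
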