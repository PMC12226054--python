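"""Integration-method SSRT estimation and staircase quality control.

The stop-signal reaction time (SSRT) is the latent latency of the
inhibitory process.  Under the independent horse-race model it is
estimated per emotional category as

    SSRT = RT_p - mean SSD

where RT_p is the p-th percentile (nearest-rank) of the correct-go RT
distribution, p is that category's stop-failure rate, and mean SSD is the
average stop-signal delay presented on that category's stop trials.  Go
omissions are replaced with the maximum observed go RT before the
percentile is taken; signal-respond RTs (responses on failed stops) never
enter the go distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .design import SessionConfig
from .race import BehavioralTrial

__all__ = [
    "SSRTResult",
    "QCReport",
    "InsufficientDataError",
    "stop_failure_rate",
    "integration_ssrt",
    "per_category_ssrt",
    "session_ssrt_table",
    "qc_staircase",
]

QC_BAND = (0.40, 0.60)


class InsufficientDataError(ValueError):
    """Raised when a category lacks the trials the estimator needs."""


@dataclass(frozen=True)
class SSRTResult:
    category: str
    n_go: int
    n_stop: int
    p_fail: float
    mean_ssd: float
    rt_p: float
    ssrt: float
    n_go_omissions: int


@dataclass(frozen=True)
class QCReport:
    """Staircase health check: stop success should track 40-60 %."""

    stop_success_rate: float
    in_band: bool
    recommended_step: float
    notes: str


def stop_failure_rate(trials: list[BehavioralTrial],
                      category: str | None = None) -> float:
    """Proportion of stop trials on which a response escaped."""
    stops = [t for t in trials
             if t.is_stop and (category is None or t.category == category)]
    if not stops:
        raise InsufficientDataError(
            f"no stop trials{f' for category {category!r}' if category else ''}"
        )
    return sum(t.stop_outcome == "failure" for t in stops) / len(stops)


def nearest_rank_percentile(values: list[float], p: float) -> float:
    """Nearest-rank percentile: element at 1-based index ceil(p*n); p=0 -> min."""
    if not values:
        raise InsufficientDataError("empty value set")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    s = sorted(values)
    k = max(1, math.ceil(p * len(s)))
    return s[k - 1]


def integration_ssrt(go_rts: list[float], n_go_omissions: int, p_fail: float,
                     mean_ssd: float) -> tuple[float, float]:
    """Return (rt_p, ssrt) for one category.

    Omitted go trials are appended as copies of the maximum observed RT —
    the standard correction that keeps the percentile honest when slow
    responses are censored by the deadline.
    """
    if not go_rts:
        raise InsufficientDataError("no correct go RTs")
    rts = list(go_rts) + [max(go_rts)] * n_go_omissions
    rt_p = nearest_rank_percentile(rts, p_fail)
    return rt_p, rt_p - mean_ssd


def per_category_ssrt(trials: list[BehavioralTrial], category: str,
                      session_wide_ssd: bool = False) -> SSRTResult:
    """Integration-method SSRT for one emotional category.

    Go RTs, omissions, stop-failure rate and (by default) mean SSD all come
    from that category's trials; ``session_wide_ssd`` swaps in the mean SSD
    over all stop trials instead.
    """
    cat = [t for t in trials if t.category == category]
    go = [t for t in cat if not t.is_stop]
    stops = [t for t in cat if t.is_stop]
    if not stops:
        raise InsufficientDataError(f"category {category!r} has no stop trials")
    correct_go_rts = [t.rt for t in go if t.responded and t.response_correct]
    if not correct_go_rts:
        raise InsufficientDataError(f"category {category!r} has no correct go trials")
    n_omit = sum(not t.responded for t in go)
    p_fail = stop_failure_rate(trials, category)
    ssd_pool = [t.ssd for t in trials if t.is_stop] if session_wide_ssd \
        else [t.ssd for t in stops]
    mean_ssd = sum(ssd_pool) / len(ssd_pool)
    rt_p, ssrt = integration_ssrt(correct_go_rts, n_omit, p_fail, mean_ssd)
    return SSRTResult(
        category=category, n_go=len(go), n_stop=len(stops), p_fail=p_fail,
        mean_ssd=mean_ssd, rt_p=rt_p, ssrt=ssrt, n_go_omissions=n_omit,
    )


def session_ssrt_table(trials: list[BehavioralTrial],
                       categories: tuple[str, ...],
                       session_wide_ssd: bool = False) -> pd.DataFrame:
    """SSRT results for every category, in config order, as a tidy table."""
    rows = [asdict(per_category_ssrt(trials, c, session_wide_ssd))
            for c in categories]
    return pd.DataFrame(rows, columns=[
        "category", "n_go", "n_stop", "p_fail", "mean_ssd", "rt_p", "ssrt",
        "n_go_omissions",
    ])


def qc_staircase(trials: list[BehavioralTrial],
                 config: SessionConfig) -> QCReport:
    """Check staircase tracking; recommend the larger step when off-band.

    Stop-success rates persistently outside 40-60 % indicate RT
    instability, rectified by enlarging the staircase step (or extending
    practice).  Band bounds are inclusive.
    """
    success = 1.0 - stop_failure_rate(trials)
    in_band = QC_BAND[0] <= success <= QC_BAND[1]
    step = config.ssd_step if in_band else config.ssd_step_escalated
    notes = ("stop-success within 40-60 % band" if in_band else
             f"stop-success {success:.2f} outside 40-60 % band: enlarge "
             f"staircase step to {step:.0f} ms or extend the practice block")
    return QCReport(stop_success_rate=success, in_band=in_band,
                    recommended_step=step, notes=notes)


def write_ssrt_results(table: pd.DataFrame, csv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(table.to_dict(orient="records"), indent=2))
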