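"""Independent horse-race simulation of stop-signal behavior.

Each trial is a race between a go process (ex-Gaussian finishing time) and,
on stop trials, a stop process starting at stimulus onset + SSD with a
known latent latency (the true SSRT).  A response is emitted iff the go
process finishes first — unless the stop process fails to trigger at all,
in which case the response always escapes.  Because the generative SSRT is
known exactly, simulated sessions serve as ground truth for validating the
integration-method estimator.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .design import (
    OCD_CATEGORIES,
    SessionConfig,
    StaircaseState,
    TrialSpec,
    staircase_update,
)

__all__ = [
    "ExGaussian",
    "ParticipantModel",
    "BehavioralTrial",
    "sample_go_rt",
    "race_outcome",
    "simulate_session",
    "write_trial_log",
    "read_trial_log",
    "write_ground_truth",
]


@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian RT distribution: Normal(mu, sigma) + Exponential(tau), ms.

    Mean is ``mu + tau``; variance ``sigma**2 + tau**2``.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.mu < 0 or self.sigma < 0 or self.tau < 0:
            raise ValueError("ex-Gaussian parameters must be nonnegative")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


def sample_go_rt(params: ExGaussian, rng: np.random.Generator,
                 size: int | None = None) -> float | np.ndarray:
    """Draw go-process finishing times, redrawing any non-positive values.

    The truncation bias is negligible for realistic parameters (mu several
    sigma above zero).
    """
    n = 1 if size is None else size
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        draw = rng.normal(params.mu, params.sigma, pending.size) + (
            rng.exponential(params.tau, pending.size) if params.tau > 0 else 0.0
        )
        out[pending] = draw
        pending = pending[draw <= 0]
        # degenerate all-mass-at-zero parameterization cannot terminate
        if pending.size and params.mu == 0 and params.sigma == 0 and params.tau == 0:
            raise ValueError("degenerate ex-Gaussian with all mass at 0")
    return float(out[0]) if size is None else out


def race_outcome(go_rt: float, ssd: float, ssrt_true: float,
                 trigger_failed: bool) -> bool:
    """Independent-race rule: respond iff the go process beats SSD + SSRT.

    A trigger failure (the stop process never launches) always yields a
    response, regardless of the delay.
    """
    if trigger_failed:
        return True
    return go_rt < ssd + ssrt_true


def _default_category_params() -> dict[str, ExGaussian]:
    base = ExGaussian(mu=450.0, sigma=80.0, tau=100.0)
    slowed = ExGaussian(mu=500.0, sigma=80.0, tau=100.0)
    out = {"neutral": base}
    out["generic_aversive"] = slowed
    for cat in OCD_CATEGORIES:
        out[cat] = slowed
    return out


def _default_ssrt_true() -> dict[str, float]:
    out = {"neutral": 180.0}
    out["generic_aversive"] = 245.0
    for cat in OCD_CATEGORIES:
        out[cat] = 245.0
    return out


@dataclass
class ParticipantModel:
    """Latent race-model parameters for one simulated participant.

    Defaults emulate a healthy adult with emotional interference: aversive
    picture categories slow the go process by 50 ms and lengthen the stop
    latency by 65 ms relative to neutral, so category-mean SSRTs sit near
    180 ms (neutral) and 245 ms (aversive).  ``trigger_failure_prob`` is the
    chance a stop trial runs with no stop process at all;
    ``go_omission_prob`` injects go omissions beyond natural deadline
    misses; ``classification_error_prob`` is the chance a given response is
    the wrong valence key (treated as independent of category).
    """

    go_params: dict[str, ExGaussian] = field(default_factory=_default_category_params)
    ssrt_true: dict[str, float] = field(default_factory=_default_ssrt_true)
    trigger_failure_prob: float = 0.02
    go_omission_prob: float = 0.01
    classification_error_prob: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.trigger_failure_prob, self.go_omission_prob,
                  self.classification_error_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for v in self.ssrt_true.values():
            if v < 0:
                raise ValueError("true SSRT must be nonnegative")

    @classmethod
    def stationary(cls, mu: float = 450.0, sigma: float = 80.0,
                   tau: float = 100.0, ssrt: float = 200.0,
                   categories: tuple[str, ...] = None,
                   trigger_failure_prob: float = 0.0,
                   go_omission_prob: float = 0.0,
                   classification_error_prob: float = 0.0) -> "ParticipantModel":
        """A participant with identical parameters in every category."""
        from .design import DEFAULT_CATEGORIES
        cats = tuple(categories) if categories else DEFAULT_CATEGORIES
        eg = ExGaussian(mu, sigma, tau)
        return cls(
            go_params={c: eg for c in cats},
            ssrt_true={c: ssrt for c in cats},
            trigger_failure_prob=trigger_failure_prob,
            go_omission_prob=go_omission_prob,
            classification_error_prob=classification_error_prob,
        )


@dataclass(frozen=True)
class BehavioralTrial:
    """One recorded trial of the behavioral log.

    ``rt`` is present iff ``responded``; on stop-failure trials it is the
    signal-respond RT, which never enters go-RT analyses.  ``stop_outcome``
    is ``"n/a"`` on go trials.
    """

    index: int
    block: int
    category: str
    side: str
    is_stop: bool
    ssd: float | None
    responded: bool
    rt: float | None
    response_correct: bool | None
    stop_outcome: str  # "success" | "failure" | "n/a"


def simulate_session(
    schedule: list[TrialSpec],
    participant: ParticipantModel,
    config: SessionConfig,
    seed: int,
) -> tuple[list[BehavioralTrial], StaircaseState]:
    """Run one session of the task against a simulated participant.

    Stop trials consume the current staircase SSD and feed their outcome
    back, so the delay tracks the ~50 % success point.  Go finishing times
    beyond the response window are omissions; extra omissions and
    classification errors are injected at the participant's rates.
    Fully reproducible under ``seed``.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    missing = {s.category for s in schedule} - set(participant.go_params)
    if missing:
        raise ValueError(f"participant lacks go parameters for categories {sorted(missing)}")
    if len(schedule) != config.n_trials:
        raise ValueError(
            f"schedule length {len(schedule)} != config.n_trials {config.n_trials}"
        )
    rng = np.random.default_rng(seed)
    state = StaircaseState.from_config(config)
    trials: list[BehavioralTrial] = []
    for spec in schedule:
        go_rt = sample_go_rt(participant.go_params[spec.category], rng)
        omitted = rng.random() < participant.go_omission_prob
        misclassified = rng.random() < participant.classification_error_prob
        if spec.is_stop:
            ssd = state.ssd
            trig_fail = rng.random() < participant.trigger_failure_prob
            responds = (
                race_outcome(go_rt, ssd, participant.ssrt_true[spec.category], trig_fail)
                and go_rt <= config.response_window
                and not omitted
            )
            outcome = "failure" if responds else "success"
            trials.append(BehavioralTrial(
                index=spec.index, block=spec.block, category=spec.category,
                side=spec.side, is_stop=True, ssd=ssd,
                responded=responds, rt=go_rt if responds else None,
                response_correct=(not misclassified) if responds else None,
                stop_outcome=outcome,
            ))
            state = staircase_update(state, outcome, trial_index=spec.index)
        else:
            responds = go_rt <= config.response_window and not omitted
            trials.append(BehavioralTrial(
                index=spec.index, block=spec.block, category=spec.category,
                side=spec.side, is_stop=False, ssd=None,
                responded=responds, rt=go_rt if responds else None,
                response_correct=(not misclassified) if responds else None,
                stop_outcome="n/a",
            ))
    return trials, state


# ---------------------------------------------------------------------------
# trial-log persistence

TRIAL_LOG_COLUMNS = ("trial", "block", "category", "side", "is_stop", "ssd",
                     "responded", "rt", "correct", "stop_outcome")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)  # full precision: logs round-trip exactly
    return str(v)


def write_trial_log(trials: list[BehavioralTrial], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_LOG_COLUMNS)
        for t in trials:
            w.writerow([
                t.index, t.block, t.category, t.side, _fmt(t.is_stop),
                _fmt(t.ssd), _fmt(t.responded), _fmt(t.rt),
                _fmt(t.response_correct), t.stop_outcome,
            ])


def read_trial_log(path: str | Path) -> list[BehavioralTrial]:
    trials: list[BehavioralTrial] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trials.append(BehavioralTrial(
                index=int(row["trial"]),
                block=int(row["block"]),
                category=row["category"],
                side=row["side"],
                is_stop=row["is_stop"] == "1",
                ssd=float(row["ssd"]) if row["ssd"] else None,
                responded=row["responded"] == "1",
                rt=float(row["rt"]) if row["rt"] else None,
                response_correct=(row["correct"] == "1") if row["correct"] else None,
                stop_outcome=row["stop_outcome"],
            ))
    return trials


def write_ground_truth(participant: ParticipantModel, seed: int,
                       path: str | Path) -> None:
    """Sidecar JSON with the latent parameters behind a simulated session."""
    payload = {
        "seed": seed,
        "ssrt_true": participant.ssrt_true,
        "go_params": {c: asdict(p) for c, p in participant.go_params.items()},
        "trigger_failure_prob": participant.trigger_failure_prob,
        "go_omission_prob": participant.go_omission_prob,
        "classification_error_prob": participant.classification_error_prob,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
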