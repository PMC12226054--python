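"""Session structure for the modified emotional stop-signal task (MESST).

The task presents emotionally valenced pictures (neutral, generic aversive
and four OCD-relevant themes) left or right of fixation; participants
classify each picture as negative / non-negative, and on a fixed fraction
of trials an auditory stop signal instructs them to withhold the response.
This module builds the block/trial schedule, advances the 1-up/1-down
stop-signal-delay (SSD) staircase, and lays out the within-trial event
timeline on a common millisecond clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_CATEGORIES",
    "OCD_CATEGORIES",
    "SessionConfig",
    "TrialSpec",
    "StaircaseState",
    "TimelineEvent",
    "InvalidConfigError",
    "InvalidTimelineError",
    "build_schedule",
    "staircase_update",
    "trial_timeline",
]

DEFAULT_CATEGORIES = (
    "neutral",
    "generic_aversive",
    "symmetry",
    "checking",
    "hoarding",
    "washing",
)
#: the four symptom-specific picture themes
OCD_CATEGORIES = ("symmetry", "checking", "hoarding", "washing")


class InvalidConfigError(ValueError):
    """Raised when a SessionConfig violates its invariants."""


class InvalidTimelineError(ValueError):
    """Raised when a trial timeline cannot be laid out (e.g. SSD past the deadline)."""


@dataclass(frozen=True)
class SessionConfig:
    """Task-design constants.

    Durations are milliseconds.  Defaults reproduce the published design:
    600 trials in six blocks, 25 % stop trials, staircase starting at
    250 ms with 50 ms steps (escalated to 75 ms when tracking fails),
    a 0–1500 ms response window, 1000 ms inter-trial interval and
    >=200 ms enforced central fixation.  ``ssd_floor``/``ssd_ceiling``
    bound the staircase; the 1200 ms ceiling keeps the tone inside the
    response window with margin.
    """

    n_trials: int = 600
    n_blocks: int = 6
    stop_fraction: float = 0.25
    ssd_init: float = 250.0
    ssd_step: float = 50.0
    ssd_step_escalated: float = 75.0
    ssd_floor: float = 0.0
    ssd_ceiling: float = 1200.0
    response_window: float = 1500.0
    iti: float = 1000.0
    fixation_enforce: float = 200.0
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    stimulus_px: tuple[int, int] = (800, 600)
    eccentricity_deg: float = 8.0
    sampling_rate: float = 2000.0
    practice_trials: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "stimulus_px", tuple(self.stimulus_px))
        if self.n_trials < 0:
            raise InvalidConfigError("n_trials must be >= 0")
        if self.n_blocks <= 0:
            raise InvalidConfigError("n_blocks must be positive")
        if self.n_trials % self.n_blocks != 0:
            raise InvalidConfigError(
                f"n_trials={self.n_trials} not divisible by n_blocks={self.n_blocks}"
            )
        if not 0.0 < self.stop_fraction < 1.0:
            raise InvalidConfigError("stop_fraction must lie strictly in (0, 1)")
        if not self.ssd_floor <= self.ssd_init <= self.ssd_ceiling:
            raise InvalidConfigError("need ssd_floor <= ssd_init <= ssd_ceiling")
        for name in ("ssd_step", "ssd_step_escalated", "response_window", "iti",
                     "fixation_enforce", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not self.categories:
            raise InvalidConfigError("categories must be nonempty")
        if len(set(self.categories)) != len(self.categories):
            raise InvalidConfigError("categories must be unique")

    @property
    def block_size(self) -> int:
        return self.n_trials // self.n_blocks if self.n_blocks else 0

    @property
    def stops_per_block(self) -> int:
        return int(round(self.block_size * self.stop_fraction))


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: 0-based index/block, picture category, side, stop flag."""

    index: int
    block: int
    category: str
    side: str  # "left" | "right"
    is_stop: bool


@dataclass
class StaircaseState:
    """1-up/1-down tracker for the stop-signal delay.

    ``trace`` records one ``(stop_trial_index, ssd_used, outcome)`` tuple per
    stop trial, with the SSD *presented* on that trial (before the update).
    """

    ssd: float
    step: float
    floor: float = 0.0
    ceiling: float = 1200.0
    n_success: int = 0
    n_fail: int = 0
    trace: list[tuple[int, float, str]] = field(default_factory=list)

    @classmethod
    def from_config(cls, config: SessionConfig) -> "StaircaseState":
        return cls(ssd=config.ssd_init, step=config.ssd_step,
                   floor=config.ssd_floor, ceiling=config.ssd_ceiling)


def staircase_update(state: StaircaseState, outcome: str,
                     trial_index: int = -1) -> StaircaseState:
    """Advance the staircase after a stop trial.

    SSD increases by one step after a successful inhibition (making the next
    stop harder) and decreases by one step after a failed stop, clamped to
    ``[floor, ceiling]``.  Returns a new state; the input is not mutated.
    """
    if outcome not in ("success", "failure"):
        raise ValueError(f"outcome must be 'success' or 'failure', got {outcome!r}")
    delta = state.step if outcome == "success" else -state.step
    new_ssd = min(max(state.ssd + delta, state.floor), state.ceiling)
    return replace(
        state,
        ssd=new_ssd,
        n_success=state.n_success + (outcome == "success"),
        n_fail=state.n_fail + (outcome == "failure"),
        trace=state.trace + [(trial_index, state.ssd, outcome)],
    )


def build_schedule(config: SessionConfig, seed: int) -> list[TrialSpec]:
    """Build the full trial schedule for one session.

    Per block: each category appears ``floor(block_size / n_categories)`` or
    one more time (the categories receiving the extra trial are drawn
    uniformly at random per block); exactly
    ``round(block_size * stop_fraction)`` trials carry the stop signal, at
    uniformly random positions; picture side is an independent fair coin.
    The whole construction is deterministic in ``(config, seed)``.
    """
    if config.n_trials == 0:
        return []
    n_cat = len(config.categories)
    bs = config.block_size
    if bs < n_cat:
        raise InvalidConfigError(
            f"block size {bs} smaller than number of categories {n_cat}"
        )
    rng = np.random.default_rng(seed)
    base, extra = divmod(bs, n_cat)
    specs: list[TrialSpec] = []
    for block in range(config.n_blocks):
        counts = np.full(n_cat, base, dtype=int)
        if extra:
            counts[rng.choice(n_cat, size=extra, replace=False)] += 1
        labels = np.repeat(np.arange(n_cat), counts)
        rng.shuffle(labels)
        stop_flags = np.zeros(bs, dtype=bool)
        stop_flags[rng.choice(bs, size=config.stops_per_block, replace=False)] = True
        sides = rng.integers(0, 2, size=bs)
        for i in range(bs):
            specs.append(TrialSpec(
                index=block * bs + i,
                block=block,
                category=config.categories[labels[i]],
                side="left" if sides[i] == 0 else "right",
                is_stop=bool(stop_flags[i]),
            ))
    return specs


@dataclass(frozen=True)
class TimelineEvent:
    """One named event on the common session clock (ms)."""

    label: str
    t: float
    duration: float = 0.0


def trial_timeline(spec: TrialSpec, ssd: float, config: SessionConfig,
                   t0: float = 0.0) -> list[TimelineEvent]:
    """Lay out the event sequence of one trial.

    fixation-onset at ``t0``; stimulus-onset after the enforced fixation
    period; on stop trials the tone at stimulus-onset + SSD; the response
    deadline at stimulus-onset + response window; the inter-trial interval
    starting at the deadline.  The SSD must leave the tone strictly inside
    the response window.
    """
    if ssd < config.ssd_floor or ssd > config.ssd_ceiling:
        raise InvalidTimelineError(f"ssd {ssd} outside clamp range")
    if spec.is_stop and ssd >= config.response_window:
        raise InvalidTimelineError(
            f"ssd {ssd} >= response window {config.response_window}"
        )
    onset = t0 + config.fixation_enforce
    events = [
        TimelineEvent("fixation-onset", t0, config.fixation_enforce),
        TimelineEvent("stimulus-onset", onset),
    ]
    if spec.is_stop:
        events.append(TimelineEvent("tone-onset", onset + ssd))
    deadline = onset + config.response_window
    events.append(TimelineEvent("response-deadline", deadline))
    events.append(TimelineEvent("iti-onset", deadline, config.iti))
    return events
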