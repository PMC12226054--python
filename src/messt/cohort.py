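"""Simulated study cohorts: subject-level SSRT/gaze tables and trait scores.

Generates the tables the statistical workflow consumes — a long
(subject, group, condition, value) table of per-category SSRTs, wide
per-category SSRT and gaze-metric tables, questionnaire totals (STAI-Y2,
BIS-11, OCI-R) and OCI-R subscale scores — with controllable ground-truth
structure: a condition (emotional-interference) effect, a group effect, a
group x condition interaction, and an optional coupling between each OCI-R
symptom dimension and the SSRT of its matching stimulus category.  This is
a subject-level parametric generator; it does not re-run the trial-level
race simulator for every subject, so it is cheap enough for Monte-Carlo
checks of the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_CATEGORIES
from .stats import SYMPTOM_DIMENSIONS

__all__ = ["CohortSpec", "CohortData", "simulate_cohort"]


def _default_condition_effects() -> dict[str, float]:
    # aversive categories ~65 ms above neutral, echoing the pilot SSRT gap
    eff = {c: 65.0 for c in DEFAULT_CATEGORIES}
    eff["neutral"] = 0.0
    return eff


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth structure of a simulated cohort (values in ms).

    ``ssrt_base`` is the control-group neutral-category mean;
    ``interaction`` adds to the clinical group's non-neutral categories on
    top of the main effects.  ``symptom_coupling`` is the slope (ms per SD
    of subscale score) tying each OCD category's SSRT to the matching
    OCI-R dimension.
    """

    n_per_group: int = 14
    groups: tuple[str, ...] = ("control", "ocd")
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    ssrt_base: float = 180.0
    condition_effects: dict[str, float] = field(
        default_factory=_default_condition_effects)
    group_effect: float = 30.0
    interaction: float = 0.0
    subject_sd: float = 40.0
    noise_sd: float = 30.0
    symptom_coupling: float = 0.0
    dwell_base: float = 640.0
    dwell_aversive_effect: float = 60.0
    latency_base: float = 181.0


@dataclass
class CohortData:
    long: pd.DataFrame           # subject, group, condition, value (SSRT ms)
    ssrt_wide: pd.DataFrame      # subject-indexed, one column per category
    metrics: pd.DataFrame        # subject-indexed mean SSRT / dwell / latency
    traits: pd.DataFrame         # subject-indexed stai_y2, bis11, ocir_total
    ocir_subscales: pd.DataFrame  # subject-indexed symptom-dimension scores


def simulate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0) -> CohortData:
    rng = np.random.default_rng(seed)
    subjects, groups = [], []
    for g in spec.groups:
        for i in range(spec.n_per_group):
            subjects.append(f"{g}_{i:02d}")
            groups.append(g)
    n = len(subjects)
    subj_int = rng.normal(0.0, spec.subject_sd, n)

    # OCI-R subscales: clinical group scores higher; totals built from them
    clinical = np.array([g != spec.groups[0] for g in groups], dtype=float)
    sub = {dim: np.clip(rng.normal(4.0 + 5.0 * clinical, 2.5), 0, 12)
           for dim in SYMPTOM_DIMENSIONS}
    ocir_subscales = pd.DataFrame(sub, index=subjects)
    traits = pd.DataFrame({
        "stai_y2": np.clip(rng.normal(38 + 10 * clinical, 8), 20, 80),
        "bis11": np.clip(rng.normal(60 + 6 * clinical, 9), 30, 120),
        "ocir_total": ocir_subscales.sum(axis=1)
        + np.clip(rng.normal(4 + 4 * clinical, 3), 0, 24),
    }, index=subjects)

    rows = []
    for s_ix, (s, g) in enumerate(zip(subjects, groups)):
        for cat in spec.categories:
            mu = (spec.ssrt_base + subj_int[s_ix]
                  + spec.condition_effects.get(cat, 0.0)
                  + (spec.group_effect if g != spec.groups[0] else 0.0))
            if g != spec.groups[0] and cat != "neutral":
                mu += spec.interaction
            if spec.symptom_coupling and cat in SYMPTOM_DIMENSIONS:
                z = (ocir_subscales[cat].iloc[s_ix]
                     - ocir_subscales[cat].mean()) / ocir_subscales[cat].std()
                mu += spec.symptom_coupling * z
            rows.append({"subject": s, "group": g, "condition": cat,
                         "value": mu + rng.normal(0.0, spec.noise_sd)})
    long = pd.DataFrame(rows)
    ssrt_wide = long.pivot_table(index="subject", columns="condition",
                                 values="value").loc[subjects, list(spec.categories)]
    ssrt_wide.columns.name = None

    aversive = [c for c in spec.categories if c != "neutral"]
    metrics = pd.DataFrame({
        "ssrt_mean": ssrt_wide.mean(axis=1),
        "dwell_time": spec.dwell_base
        + spec.dwell_aversive_effect * np.clip(
            (ssrt_wide[aversive].mean(axis=1) - ssrt_wide["neutral"]) / 65.0,
            -2, 3)
        + rng.normal(0.0, 80.0, n),
        "first_fixation_latency": spec.latency_base + rng.normal(0.0, 12.0, n),
    }, index=subjects)
    return CohortData(long=long, ssrt_wide=ssrt_wide, metrics=metrics,
                      traits=traits, ocir_subscales=ocir_subscales)
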