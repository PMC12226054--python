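"""Statistical workflow for the task: paired tests, mixed-design ANOVA,
planned contrasts, Bonferroni-corrected trait correlations, the
symptom-targeted mapping and the a-priori sample-size calculation.

The central analysis is a split-plot (mixed) ANOVA with stimulus Condition
(six categories) as the within-subject factor and Group (e.g. OCD vs
control) between subjects.  Sphericity is assessed with Mauchly's test and
the Greenhouse-Geisser epsilon; when epsilon falls below 0.75 the
within-subject degrees of freedom are deflated by epsilon.  Effect sizes
are partial eta squared for ANOVA effects and Cohen's d (mean difference
over SD of differences) for planned paired comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "RMAnovaResult",
    "PowerSpec",
    "DegenerateInputError",
    "IncompleteDesignError",
    "paired_test",
    "rm_anova",
    "rm_anova_table",
    "planned_contrasts",
    "trait_correlations",
    "symptom_mapping",
    "achieved_power",
    "required_sample_size",
    "GG_EPSILON_RULE",
]

#: Greenhouse-Geisser correction is applied when epsilon drops below this
GG_EPSILON_RULE = 0.75

SYMPTOM_DIMENSIONS = ("symmetry", "checking", "hoarding", "washing")


class DegenerateInputError(ValueError):
    """Raised for inputs on which a test statistic is undefined."""


class IncompleteDesignError(ValueError):
    """Raised when a subject is missing one or more conditions."""


# ---------------------------------------------------------------------------
# paired comparison

@dataclass(frozen=True)
class PairedComparison:
    label: str
    t: float
    df: int
    p: float
    d: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n: int
    shapiro_p: float


def paired_test(a, b, label: str = "") -> PairedComparison:
    """Paired-samples t-test on ``a - b`` with Cohen's d for paired data.

    d = mean(diff) / sd(diff).  Shapiro-Wilk on the differences is reported
    as a normality flag but never blocks the test.  All-zero differences
    (a identical to b) return t = 0, d = 0; a nonzero constant difference
    has no defined t and raises ``DegenerateInputError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DegenerateInputError(
            f"paired samples must be equal-length 1-d vectors, got {a.shape} vs {b.shape}"
        )
    n = a.size
    if n < 2:
        raise DegenerateInputError("need at least 2 pairs")
    diff = a - b
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if md != 0.0:
            raise DegenerateInputError("constant nonzero differences: t undefined")
        t, p, d = 0.0, 1.0, 0.0
    else:
        t = md / (sd / math.sqrt(n))
        p = 2.0 * sps.t.sf(abs(t), n - 1)
        d = md / sd
    shapiro_p = float("nan")
    if n >= 3 and np.ptp(diff) > 0:
        shapiro_p = float(sps.shapiro(diff).pvalue)
    return PairedComparison(
        label=label, t=float(t), df=n - 1, p=float(p), d=float(d),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n=n, shapiro_p=shapiro_p,
    )


# ---------------------------------------------------------------------------
# mixed-design (split-plot) ANOVA

@dataclass(frozen=True)
class RMAnovaResult:
    effect: str  # "Condition" | "Group" | "Condition x Group"
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    mauchly_p: float
    eta_p_sq: float
    gg_applied: bool


def _orthonormal_contrasts(m: int) -> np.ndarray:
    """(m-1) x m orthonormal contrast matrix (rows orthogonal to the mean)."""
    h = np.zeros((m - 1, m))
    for i in range(m - 1):
        h[i, :i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def _sphericity(pooled_cov: np.ndarray, df_error: int) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon and Mauchly p from a pooled covariance."""
    m = pooled_cov.shape[0]
    if m <= 2:
        return 1.0, 1.0
    c = _orthonormal_contrasts(m)
    s = c @ pooled_cov @ c.T
    lam = np.linalg.eigvalsh(s)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    if tr <= 0:
        return 1.0, 1.0
    eps = tr ** 2 / ((m - 1) * (lam ** 2).sum())
    eps = float(min(1.0, max(1.0 / (m - 1), eps)))
    # Mauchly's W with Box's chi-square approximation (second-order term
    # included, as in R's mauchly.test)
    p_dim = m - 1
    det = float(np.prod(lam))
    w = det / (tr / p_dim) ** p_dim
    if w <= 0 or df_error <= 0:
        return eps, float("nan")
    f = 1.0 - (2.0 * p_dim ** 2 + p_dim + 2.0) / (6.0 * p_dim * df_error)
    chi2 = -df_error * f * math.log(w)
    dof = p_dim * (p_dim + 1) // 2 - 1
    w2 = ((p_dim + 2) * (p_dim - 1) * (p_dim - 2)
          * (2 * p_dim ** 3 + 6 * p_dim ** 2 + 3 * p_dim + 2)
          / (288.0 * (df_error * p_dim * f) ** 2))
    p1 = sps.chi2.sf(chi2, dof)
    p2 = sps.chi2.sf(chi2, dof + 4)
    return eps, float(p1 + w2 * (p2 - p1))


def rm_anova(long: pd.DataFrame, dv: str = "value", subject: str = "subject",
             within: str = "condition", between: str = "group") -> list[RMAnovaResult]:
    """Split-plot ANOVA: within-subject Condition, between-subject Group.

    Expects a long table with one row per (subject, condition); every
    subject must have every condition exactly once.  Returns results for
    Condition, Group and the Condition x Group interaction.  Mauchly's test
    and the Greenhouse-Geisser epsilon come from the pooled group-centered
    within-subject covariance; when epsilon < 0.75 the within-effect df are
    multiplied by epsilon (the reported df1/df2 are then the adjusted ones).
    """
    d = long[[subject, between, within, dv]].copy()
    conditions = list(pd.unique(d[within]))
    m = len(conditions)
    counts = d.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise IncompleteDesignError(
            f"subject {bad[0]!r} has {counts[bad]} rows for condition {bad[1]!r}"
        )
    wide = d.pivot(index=subject, columns=within, values=dv)[conditions]
    if wide.isna().any().any():
        s_idx, c_idx = np.argwhere(wide.isna().to_numpy())[0]
        raise IncompleteDesignError(
            f"subject {wide.index[s_idx]!r} missing condition "
            f"{wide.columns[c_idx]!r}"
        )
    y = wide.to_numpy(dtype=float)            # subjects x conditions
    group_of = d.drop_duplicates(subject).set_index(subject)[between]
    groups = group_of.loc[wide.index].to_numpy()
    glabels = pd.unique(groups)
    k = len(glabels)
    n_total = y.shape[0]
    if n_total <= k:
        raise DegenerateInputError("need more subjects than groups")

    gm = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n_total * ((cond_means - gm) ** 2).sum()
    ss_between_subj = m * ((subj_means - gm) ** 2).sum()
    ss_group = 0.0
    ss_inter = 0.0
    ss_err_within = 0.0
    pooled = np.zeros((m, m))
    for g in glabels:
        sel = groups == g
        n_g = int(sel.sum())
        yg = y[sel]
        ss_group += m * n_g * (yg.mean() - gm) ** 2
        cell = yg.mean(axis=0)                # group x condition means
        ss_inter += n_g * ((cell - yg.mean() - cond_means + gm) ** 2).sum()
        resid = yg - cell - subj_means[sel, None] + yg.mean()
        ss_err_within += (resid ** 2).sum()
        if n_g > 1:
            pooled += (n_g - 1) * np.cov(yg, rowvar=False)
    ss_err_between = ss_between_subj - ss_group
    pooled /= max(1, n_total - k)

    df_cond = m - 1.0
    df_group = k - 1.0
    df_inter = (k - 1.0) * (m - 1.0)
    df_errw = (n_total - k) * (m - 1.0)
    df_errb = float(n_total - k)
    eps, mauchly_p = _sphericity(pooled, n_total - k)
    gg = eps < GG_EPSILON_RULE

    def _within(effect: str, ss: float, df1: float) -> RMAnovaResult:
        f = (ss / df1) / (ss_err_within / df_errw)
        a1, a2 = (df1 * eps, df_errw * eps) if gg else (df1, df_errw)
        return RMAnovaResult(
            effect=effect, F=float(f), df1=float(a1), df2=float(a2),
            p=float(sps.f.sf(f, a1, a2)), gg_epsilon=eps, mauchly_p=mauchly_p,
            eta_p_sq=float(ss / (ss + ss_err_within)), gg_applied=gg,
        )

    f_group = (ss_group / df_group) / (ss_err_between / df_errb) \
        if k > 1 else float("nan")
    results = [_within("Condition", ss_cond, df_cond)]
    if k > 1:
        results.append(RMAnovaResult(
            effect="Group", F=float(f_group), df1=df_group, df2=df_errb,
            p=float(sps.f.sf(f_group, df_group, df_errb)), gg_epsilon=eps,
            mauchly_p=mauchly_p,
            eta_p_sq=float(ss_group / (ss_group + ss_err_between)),
            gg_applied=False,
        ))
        results.append(_within("Condition x Group", ss_inter, df_inter))
    return results


def rm_anova_table(results: list[RMAnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def planned_contrasts(long: pd.DataFrame, target: str,
                      references: tuple[str, ...] = ("neutral", "generic_aversive"),
                      dv: str = "value", subject: str = "subject",
                      within: str = "condition") -> list[PairedComparison]:
    """Symptom-relevant category vs each reference, as paired comparisons.

    Each participant contributes one value per condition; the target
    category (the participant group's symptom-relevant one) is compared
    against neutral and against generic aversive.
    """
    wide = long.pivot_table(index=subject, columns=within, values=dv)
    for cat in (target, *references):
        if cat not in wide.columns:
            raise KeyError(f"condition {cat!r} absent from table")
    out = []
    for ref in references:
        cols = list(dict.fromkeys((target, ref)))  # dedupe target == ref
        pair = wide[cols].dropna()
        out.append(paired_test(pair[target], pair[ref],
                               label=f"{target} vs {ref}"))
    return out


# ---------------------------------------------------------------------------
# correlations

def _pearson_family(pairs: list[tuple[str, str, np.ndarray, np.ndarray]]
                    ) -> pd.DataFrame:
    rows = []
    for xl, yl, xv, yv in pairs:
        ok = ~(np.isnan(xv) | np.isnan(yv))
        xs, ys = xv[ok], yv[ok]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            rows.append({"trait": xl, "metric": yl, "r": float("nan"),
                         "p_raw": float("nan"), "n": int(xs.size),
                         "defined": False})
            continue
        r, p = sps.pearsonr(xs, ys)
        rows.append({"trait": xl, "metric": yl, "r": float(r),
                     "p_raw": float(p), "n": int(xs.size), "defined": True})
    df = pd.DataFrame(rows)
    family = int(df["defined"].sum())
    df["n_family"] = family
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * family)
    return df


def trait_correlations(traits: pd.DataFrame,
                       metrics: pd.DataFrame) -> pd.DataFrame:
    """All trait x task-metric Pearson correlations, Bonferroni-adjusted.

    ``traits`` (e.g. STAI-Y2, BIS-11, OCI-R totals) and ``metrics`` (e.g.
    SSRT, dwell time, first-fixation latency) are subject-indexed tables;
    rows are aligned on the index.  The Bonferroni family is the number of
    defined correlations computed in this call; constant columns are
    flagged undefined and excluded from the family count.
    """
    traits, metrics = traits.align(metrics, join="inner", axis=0)
    if len(traits) < 3:
        raise DegenerateInputError("need at least 3 aligned subjects")
    pairs = [(tc, mc, traits[tc].to_numpy(float), metrics[mc].to_numpy(float))
             for tc in traits.columns for mc in metrics.columns]
    return _pearson_family(pairs)


def symptom_mapping(ocir_subscales: pd.DataFrame,
                    ssrt_by_category: pd.DataFrame) -> pd.DataFrame:
    """Symptom-targeted correlations: each OCI-R subscale against the SSRT
    of its matching stimulus category (symmetry score with symmetry images,
    and so on).
    """
    bad = [c for c in ocir_subscales.columns if c not in SYMPTOM_DIMENSIONS]
    if bad:
        raise KeyError(
            f"unmapped OCI-R subscales {bad}; valid labels: "
            f"{list(SYMPTOM_DIMENSIONS)}"
        )
    missing = [c for c in ocir_subscales.columns
               if c not in ssrt_by_category.columns]
    if missing:
        raise KeyError(f"SSRT table lacks categories {missing}")
    ocir_subscales, ssrt_by_category = ocir_subscales.align(
        ssrt_by_category, join="inner", axis=0)
    pairs = [(dim, dim,
              ocir_subscales[dim].to_numpy(float),
              ssrt_by_category[dim].to_numpy(float))
             for dim in ocir_subscales.columns]
    return _pearson_family(pairs)


# ---------------------------------------------------------------------------
# a-priori power for the within-between interaction

@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the noncentral-F power computation, G*Power convention.

    f is Cohen's f for the effect; rho the assumed correlation among
    repeated measures; eps the assumed nonsphericity correction.  Defaults
    are the task's published design values.
    """

    f: float = 0.25
    alpha: float = 0.05
    power: float = 0.95
    k: int = 2          # groups
    m: int = 6          # repeated measures
    rho: float = 0.50
    eps: float = 1.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.k < 2 or self.m < 2:
            raise ValueError("need k >= 2 groups and m >= 2 measures")
        if not -1.0 / (self.m - 1) < self.rho < 1.0:
            raise ValueError("rho outside the valid range")
        if not 1.0 / (self.m - 1) <= self.eps <= 1.0:
            raise ValueError("eps outside [1/(m-1), 1]")


def achieved_power(n_total: int, spec: PowerSpec) -> float:
    """Power of the within-between interaction test at total sample N.

    Noncentrality lambda = f^2 * N * m * eps / (1 - rho); numerator df
    (k-1)(m-1)eps, denominator df (N-k)(m-1)eps — the G*Power
    parameterization for repeated-measures interaction effects.
    """
    if n_total <= spec.k:
        return 0.0
    lam = spec.f ** 2 * n_total * spec.m * spec.eps / (1.0 - spec.rho)
    df1 = (spec.k - 1) * (spec.m - 1) * spec.eps
    df2 = (n_total - spec.k) * (spec.m - 1) * spec.eps
    fcrit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec,
                         max_n: int = 10 ** 6) -> tuple[int, int, float]:
    """Smallest total N (a multiple of k) reaching the target power.

    Returns ``(N_total, n_per_group, achieved_power)``.
    """
    n = 2 * spec.k
    while n <= max_n:
        pw = achieved_power(n, spec)
        if pw >= spec.power:
            return n, n // spec.k, pw
        n += spec.k
    raise RuntimeError(f"target power {spec.power} not attainable with N <= {max_n}")
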