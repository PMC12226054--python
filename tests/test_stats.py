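"""Statistical workflow: paired tests, mixed ANOVA, correlations, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy import stats as sps

from messt.cohort import CohortSpec, simulate_cohort
from messt.stats import (DegenerateInputError, IncompleteDesignError,
                         PowerSpec, achieved_power, paired_test,
                         planned_contrasts, required_sample_size, rm_anova,
                         symptom_mapping, trait_correlations)


def long_table(y, groups=None, prefix="s"):
    """subjects x conditions matrix -> long-format frame."""
    n, m = y.shape
    groups = groups if groups is not None else ["g"] * n
    return pd.DataFrame([
        {"subject": f"{prefix}{i}", "group": groups[i],
         "condition": f"c{j}", "value": y[i, j]}
        for i in range(n) for j in range(m)])


class TestPairedTest:
    def test_closed_form_example(self):
        res = paired_test([2, 3, 4], [1, 1, 1])
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        assert res.df == 2 and res.d == pytest.approx(2.0)

    def test_identical_vectors(self):
        res = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.d == 0.0 and res.p == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_test([1, 2, 3], [1, 2, 3, 4])

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_test([2, 3, 4], [1, 2, 3])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40),
           st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_closed_form(self, a, seed):
        b = list(np.random.default_rng(seed).normal(0, 10, len(a)))
        diff = np.asarray(a) - np.asarray(b)
        if diff.std(ddof=1) == 0:
            return
        res = paired_test(a, b)
        n = len(a)
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(n))
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), n - 1), rel=1e-9)
        assert res.d == pytest.approx(diff.mean() / diff.std(ddof=1))


class TestMixedAnova:
    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        c = simulate_cohort(CohortSpec(interaction=25.0), seed=7)
        mine = {r.effect: r for r in rm_anova(c.long)}
        ref = pg.mixed_anova(data=c.long, dv="value", within="condition",
                             subject="subject", between="group")
        by_src = {row["Source"]: row for _, row in ref.iterrows()}
        for eff, src in [("Condition", "condition"), ("Group", "group"),
                         ("Condition x Group", "Interaction")]:
            assert mine[eff].F == pytest.approx(by_src[src]["F"], rel=1e-9)
            assert mine[eff].eta_p_sq == pytest.approx(by_src[src]["np2"],
                                                       rel=1e-9)

    def test_single_group_sphericity_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (20, 6)) @ np.diag([1, 1.5, 2, 0.7, 1, 3])
        res = rm_anova(long_table(y))[0]
        wide = pd.DataFrame(y)
        assert res.gg_epsilon == pytest.approx(
            float(pg.epsilon(wide, correction="gg")), rel=1e-9)
        sp = pg.sphericity(long_table(y), dv="value", within="condition",
                           subject="subject")
        # Box's second-order term differs by one coefficient between
        # pingouin and R's mauchly.test (followed here): sub-0.1 % gap
        assert res.mauchly_p == pytest.approx(sp.pval, rel=1e-2)

    def test_two_conditions_epsilon_is_one(self, rng):
        y = rng.normal(0, 1, (12, 2))
        res = rm_anova(long_table(y))[0]
        assert res.gg_epsilon == 1.0 and not res.gg_applied

    def test_gg_applied_only_below_rule(self, rng):
        # strongly nonspherical: one dominant component
        base = rng.normal(0, 1, (20, 1))
        y = base @ np.array([[3.0, 0.1, 0.1, 0.1, 0.1, 0.1]]) \
            + rng.normal(0, 0.1, (20, 6))
        res = rm_anova(long_table(y))[0]
        assert res.gg_epsilon < 0.75 and res.gg_applied
        assert res.df1 == pytest.approx(5 * res.gg_epsilon)

    def test_missing_cell_named(self, rng):
        y = rng.normal(0, 1, (8, 3))
        long = long_table(y)
        long = long[~((long.subject == "s3") & (long.condition == "c1"))]
        with pytest.raises(IncompleteDesignError, match="s3"):
            rm_anova(long)

    def test_epsilon_bounds_on_random_covariances(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = int(rng.integers(3, 7))
            y = rng.normal(0, 1, (m + 6, m)) @ rng.normal(0, 1, (m, m))
            res = rm_anova(long_table(y))[0]
            assert 1.0 / (m - 1) - 1e-12 <= res.gg_epsilon <= 1.0 + 1e-12
            assert 0.0 <= res.eta_p_sq <= 1.0

    def test_injected_effect_raises_partial_eta(self, rng):
        noise = rng.normal(0, 1, (16, 6))
        null = rm_anova(long_table(noise))[0]
        effect = noise + np.linspace(0, 1.5, 6)
        alt = rm_anova(long_table(effect))[0]
        assert alt.eta_p_sq > null.eta_p_sq

    def test_partial_eta_equals_ss_ratio(self, rng):
        """eta_p^2 recomputed from an independent decomposition of the
        same matrix (direct sums of squares)."""
        y = rng.normal(0, 1, (10, 4)) + np.array([0, 0.5, 1.0, 0.2])
        res = rm_anova(long_table(y))[0]
        gm = y.mean()
        ss_cond = y.shape[0] * ((y.mean(0) - gm) ** 2).sum()
        resid = y - y.mean(0)[None, :] - y.mean(1)[:, None] + gm
        ss_err = (resid ** 2).sum()
        assert res.eta_p_sq == pytest.approx(ss_cond / (ss_cond + ss_err))


class TestContrasts:
    def test_symptom_effect_sign_recovered(self):
        """+40 ms symmetry-specific effect: positive contrast mean in
        >= 18 of 20 seeded cohorts."""
        effects = {c: 0.0 for c in
                   ("neutral", "generic_aversive", "symmetry", "checking",
                    "hoarding", "washing")}
        effects["symmetry"] = 40.0
        hits = 0
        for seed in range(20):
            c = simulate_cohort(CohortSpec(condition_effects=effects,
                                           group_effect=0.0), seed=seed)
            res = planned_contrasts(c.long, "symmetry",
                                    references=("neutral",))[0]
            hits += res.mean_a > res.mean_b
        assert hits >= 18

    def test_target_equals_reference_gives_zero_t(self):
        c = simulate_cohort(seed=3)
        res = planned_contrasts(c.long, "neutral", references=("neutral",))[0]
        assert res.t == 0.0 and res.d == 0.0

    def test_absent_category_rejected(self):
        c = simulate_cohort(seed=3)
        with pytest.raises(KeyError):
            planned_contrasts(c.long, "nonexistent")

    def test_two_references_by_default(self):
        c = simulate_cohort(seed=3)
        out = planned_contrasts(c.long, "washing")
        assert [r.label for r in out] == ["washing vs neutral",
                                         "washing vs generic_aversive"]


class TestCorrelations:
    def test_copy_has_unit_correlation(self):
        c = simulate_cohort(seed=1)
        traits = c.traits[["stai_y2"]]
        metrics = pd.DataFrame({"copy": c.traits["stai_y2"]})
        out = trait_correlations(traits, metrics)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_is_family_times_raw(self):
        c = simulate_cohort(seed=2)
        out = trait_correlations(c.traits, c.metrics)  # 3 x 3 = 9 tests
        assert (out["n_family"] == 9).all()
        expect = np.minimum(1.0, out["p_raw"] * 9)
        np.testing.assert_allclose(out["p_bonferroni"], expect)

    def test_constant_column_flagged_and_out_of_family(self):
        c = simulate_cohort(seed=2)
        metrics = c.metrics.copy()
        metrics["flat"] = 1.0
        out = trait_correlations(c.traits, metrics)
        flat = out[out.metric == "flat"]
        assert not flat["defined"].any()
        assert (out["n_family"] == 9).all()  # 12 pairs, 3 undefined

    def test_null_rejection_rate_near_alpha(self):
        """Permutation-destroyed associations: raw p < .05 in ~5 % of tests."""
        rng = np.random.default_rng(42)
        hits, total = 0, 0
        for _ in range(150):
            x = pd.DataFrame({"t": rng.normal(0, 1, 30)})
            y = pd.DataFrame({"m": rng.normal(0, 1, 30)})
            out = trait_correlations(x, y)
            hits += int(out["p_raw"].iloc[0] < 0.05)
            total += 1
        assert abs(hits / total - 0.05) < 0.05


class TestSymptomMapping:
    def test_four_dimensions_out(self):
        c = simulate_cohort(seed=4)
        out = symptom_mapping(c.ocir_subscales, c.ssrt_wide)
        assert len(out) == 4
        assert set(out["trait"]) == {"symmetry", "checking", "hoarding",
                                     "washing"}

    def test_unmapped_subscale_lists_valid_labels(self):
        c = simulate_cohort(seed=4)
        bad = c.ocir_subscales.rename(columns={"washing": "cleaning"})
        with pytest.raises(KeyError, match="washing"):
            symptom_mapping(bad, c.ssrt_wide)

    def test_coupling_recovered_in_sign(self):
        """Washing SSRT coupled to washing score (positive slope): positive
        r in >= 18 of 20 seeded cohorts of 30 subjects."""
        hits = 0
        for seed in range(20):
            c = simulate_cohort(CohortSpec(n_per_group=15,
                                           symptom_coupling=30.0), seed=seed)
            out = symptom_mapping(c.ocir_subscales, c.ssrt_wide)
            hits += out.loc[out.trait == "washing", "r"].iloc[0] > 0
        assert hits >= 18

    def test_shuffled_alignment_kills_correlation(self):
        """Destroying subject alignment: 95 % CI covers 0 in ~95 % of seeds."""
        cover = 0
        n_seeds = 40
        for seed in range(n_seeds):
            c = simulate_cohort(CohortSpec(n_per_group=15,
                                           symptom_coupling=30.0), seed=seed)
            rng = np.random.default_rng(seed + 1000)
            shuffled = c.ocir_subscales.sample(frac=1.0, random_state=seed)
            shuffled.index = c.ocir_subscales.index
            out = symptom_mapping(shuffled, c.ssrt_wide)
            r = out.loc[out.trait == "washing", "r"].iloc[0]
            n = out.loc[out.trait == "washing", "n"].iloc[0]
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n - 3)
            cover += (z - 1.96 * se) < 0 < (z + 1.96 * se)
        assert cover >= int(0.85 * n_seeds)


class TestPower:
    def test_published_design_needs_28(self):
        n_total, per_group, pw = required_sample_size(PowerSpec())
        assert (n_total, per_group) == (28, 14)
        assert pw >= 0.95

    def test_lower_power_target_needs_fewer(self):
        n80, _, _ = required_sample_size(PowerSpec(power=0.80))
        assert n80 < 28

    def test_monotone_in_n_f_alpha_rho(self):
        spec = PowerSpec()
        powers = [achieved_power(n, spec) for n in range(6, 80, 4)]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
        assert achieved_power(28, PowerSpec(f=0.30)) > achieved_power(28, spec)
        assert achieved_power(28, PowerSpec(alpha=0.10)) > achieved_power(28, spec)
        assert achieved_power(28, PowerSpec(rho=0.70)) > achieved_power(28, spec)

    def test_required_n_weakly_decreasing_in_f(self):
        ns = [required_sample_size(PowerSpec(f=f))[0]
              for f in (0.15, 0.25, 0.40)]
        assert ns == sorted(ns, reverse=True)

    def test_against_numerical_integration_oracle(self):
        """m=2, rho=0: power recomputed by integrating the noncentral-F
        density directly."""
        spec = PowerSpec(m=2, rho=0.0)
        n = 40
        lam = spec.f ** 2 * n * spec.m
        df1 = (spec.k - 1) * (spec.m - 1)
        df2 = (n - spec.k) * (spec.m - 1)
        crit = sps.f.ppf(0.95, df1, df2)
        oracle, _ = integrate.quad(
            lambda u: sps.ncf.pdf(u, df1, df2, lam), crit, np.inf)
        assert achieved_power(n, spec) == pytest.approx(oracle, abs=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(f=-0.1)
        with pytest.raises(ValueError):
            PowerSpec(eps=0.1)  # below 1/(m-1) for m=6
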