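"""Differential methylation tests, q-value correction and extraction."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bsmethkit as bk
from bsmethkit import ModelSpec, ValidationError

from conftest import make_methylome


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Integer arithmetic throughout: sums the exact probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    w_obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = sum(
        comb(r1, x) * comb(n - r1, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(n - r1, c1 - x) <= w_obs
    )
    return float(Fraction(total, comb(n, c1)))


class TestLogisticTest:
    def test_strong_effect_2x2_matches_deviance_oracle(self):
        """80/100 vs 20/100: p equals the independent G-test on the table."""
        p, diff, beta1 = bk.logistic_test([80, 20], [20, 80], [1, 0])
        assert diff == pytest.approx(60.0)
        assert p < 1e-10
        g, p_oracle, *_ = stats.chi2_contingency(
            [[80, 20], [20, 80]], correction=False, lambda_="log-likelihood"
        )
        assert p == pytest.approx(p_oracle, rel=1e-10)
        assert beta1 == pytest.approx(np.log(4.0) - np.log(0.25))

    def test_identical_proportions_give_null_result(self):
        p, diff, beta1 = bk.logistic_test([30, 30], [70, 70], [1, 0])
        assert p == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)
        assert beta1 == pytest.approx(0.0)

    def test_confounder_adjustment_removes_spurious_difference(self):
        """Simpson's-paradox design: marginal diff is large, within-stratum nil.

        Treatment has 3 samples in stratum A (80% methylated) and 1 in B
        (20%); control the reverse.  Pooled diff is +30 points and the
        unadjusted test calls it, but within each stratum the groups are
        identical, so adjusting for the stratum must give p ~ 1.
        """
        n_meth = [80, 80, 80, 20, 80, 20, 20, 20]
        n_unmeth = [20, 20, 20, 80, 20, 80, 80, 80]
        treatment = [1, 1, 1, 1, 0, 0, 0, 0]
        stratum = ("A", "A", "A", "B", "A", "B", "B", "B")

        p_raw, diff, _ = bk.logistic_test(n_meth, n_unmeth, treatment)
        assert diff == pytest.approx(30.0)
        assert p_raw < 1e-6

        spec = ModelSpec(covariates={"stratum": stratum})
        p_adj, _, beta1 = bk.logistic_test(n_meth, n_unmeth, treatment, spec)
        assert p_adj > 0.9
        assert abs(beta1) < 1e-6

    def test_closed_form_agrees_with_glm_route(self):
        """The vectorized deviance equals statsmodels' GLM LRT per unit."""
        rng = np.random.default_rng(15)
        treatment = np.array([0, 0, 1, 1, 1])
        for _ in range(10):
            cov = rng.integers(10, 60, 5)
            meth = rng.binomial(cov, rng.uniform(0.1, 0.9))
            p_closed, _, _ = bk.logistic_test(meth, cov - meth, treatment)
            import statsmodels.api as sm

            endog = np.column_stack([meth, cov - meth])
            exog = np.column_stack([np.ones(5), treatment])
            full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, exog[:, :1], family=sm.families.Binomial()).fit()
            p_glm = stats.chi2.sf(null.deviance - full.deviance, 1)
            assert p_closed == pytest.approx(p_glm, rel=1e-6)

    def test_wald_variant_runs_and_agrees_in_order(self):
        p_lrt, _, _ = bk.logistic_test([40, 10], [10, 40], [1, 0])
        p_wald, _, _ = bk.logistic_test([40, 10], [10, 40], [1, 0], ModelSpec(test="wald"))
        assert 0 < p_wald < 0.01 and 0 < p_lrt < 0.01

    def test_complete_separation_stays_finite(self):
        p, diff, beta1 = bk.logistic_test([10, 0], [0, 10], [1, 0])
        assert 0 <= p < 1e-4
        assert diff == pytest.approx(100.0)
        assert np.isinf(beta1)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            bk.logistic_test([5, 5], [5, 5], [1, 1])


class TestFisherTest:
    def test_balanced_table_gives_p_one(self):
        p, diff = bk.fisher_test(5, 5, 5, 5)
        assert p == pytest.approx(1.0) and diff == 0.0

    @pytest.mark.parametrize("table", [(10, 0, 0, 10), (3, 9, 9, 3), (1, 11, 7, 5)])
    def test_matches_enumeration_oracle(self, table):
        p, _ = bk.fisher_test(*table)
        assert p == pytest.approx(fisher_enumeration_oracle(*table), abs=1e-12)

    def test_direction_of_difference(self):
        _, diff = bk.fisher_test(3, 9, 9, 3)
        assert diff == pytest.approx(-50.0)

    def test_exhaustive_small_margins(self):
        """All 2x2 tables with row margins <= 8 against exact enumeration."""
        worst = 0.0
        for r1 in range(1, 9):
            for r2 in range(1, 9):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        p, _ = bk.fisher_test(a, r1 - a, c, r2 - c)
                        worst = max(worst, abs(p - fisher_enumeration_oracle(a, r1 - a, c, r2 - c)))
        assert worst < 1e-10

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            bk.fisher_test(0, 0, 5, 5)


class TestAdjustPvalues:
    def test_bh_matches_step_up_formula(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bk.adjust_pvalues(p, "bh"), [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_bh_matches_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for n in (1, 7, 100, 1003):
            p = rng.uniform(0, 1, n)
            order = np.argsort(p)
            q_manual = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                running = min(running, p[order[rank - 1]] * n / rank)
                q_manual[order[rank - 1]] = running
            assert np.abs(bk.adjust_pvalues(p, "bh") - q_manual).max() < 1e-12

    def test_single_pvalue_unchanged_under_bh(self):
        assert bk.adjust_pvalues([0.37], "bh")[0] == pytest.approx(0.37)

    def test_bh_qvalues_monotone_in_ranked_pvalues(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0, 1, 500)
        q = bk.adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_slim_on_uniform_pvalues(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(0, 1, 10_000)
        pi0 = bk.estimate_pi0_slim(p)
        assert 0.9 <= pi0 <= 1.0
        q_slim = bk.adjust_pvalues(p, "slim")
        q_bh = bk.adjust_pvalues(p, "bh")
        assert (q_slim <= q_bh + 1e-12).all()
        assert np.allclose(q_slim, pi0 * q_bh)

    def test_slim_less_conservative_with_true_effects(self):
        rng = np.random.default_rng(31)
        p = np.concatenate([rng.uniform(0, 1e-4, 3000), rng.uniform(0, 1, 7000)])
        pi0 = bk.estimate_pi0_slim(p)
        assert 0.0 < pi0 < 1.0
        assert pi0 == pytest.approx(0.7, abs=0.1)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            bk.adjust_pvalues([0.5, 1.2])


class TestCalculateDiffMeth:
    def _united(self, samples_per_group, n_sites=120, seed=37, **kw):
        spec = bk.SimSpec(n_sites=n_sites, samples_per_group=samples_per_group,
                          seed=seed, **kw)
        samples, _ = bk.simulate_methylomes(spec)
        return bk.unite(samples)

    def test_one_vs_one_uses_fisher(self):
        u = self._united((1, 1))
        d = bk.calculate_diff_meth(u, ModelSpec(correction="bh"))
        for i in range(0, len(u), 17):
            a, b = u.counts(u.samples[0]), u.counts(u.samples[1])
            t_idx = u.treatments.index(1)
            t, c = u.counts(u.samples[t_idx]), u.counts(u.samples[1 - t_idx])
            p_expected, _ = bk.fisher_test(int(t[0][i]), int(t[1][i]), int(c[0][i]), int(c[1][i]))
            assert d["pvalue"].iloc[i] == pytest.approx(p_expected, abs=1e-12)

    def test_replicated_design_uses_logistic(self):
        u = self._united((3, 4))
        d = bk.calculate_diff_meth(u, ModelSpec(correction="bh"))
        treatment = np.asarray(u.treatments)
        for i in range(0, len(u), 23):
            meth = np.array([u.counts(s)[0][i] for s in u.samples])
            unmeth = np.array([u.counts(s)[1][i] for s in u.samples])
            p_expected, _, _ = bk.logistic_test(meth, unmeth, treatment)
            assert d["pvalue"].iloc[i] == pytest.approx(p_expected, abs=1e-12)

    def test_result_invariant_to_worker_count(self):
        u = self._united((2, 2), n_sites=400)
        d1 = bk.calculate_diff_meth(u, ModelSpec(correction="slim"), workers=1)
        d4 = bk.calculate_diff_meth(u, ModelSpec(correction="slim"), workers=4)
        pd.testing.assert_frame_equal(d1, d4)

    def test_missing_control_group_rejected(self):
        spec = bk.SimSpec(n_sites=20, samples_per_group=(1, 1), seed=3)
        samples, _ = bk.simulate_methylomes(spec)
        for s in samples:
            s.treatment = s.treatment + 1
        u = bk.unite(samples)
        with pytest.raises(ValidationError, match="control"):
            bk.calculate_diff_meth(u)

    def test_three_group_design_tested_with_extra_df(self):
        u = self._united((2, 2, 2))
        d = bk.calculate_diff_meth(u, ModelSpec(correction="bh"))
        assert len(d) == len(u)
        assert ((d["pvalue"] >= 0) & (d["pvalue"] <= 1)).all()


class TestExtraction:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "pvalue", "qvalue", "meth_diff"]
        )

    def test_default_cutoffs_retain_and_classify(self):
        d = self._table([("chr1", 100, 100, "+", 1e-4, 0.005, 30.0)])
        out = bk.get_methyl_diff(d)
        assert len(out) == 1 and out["class"].iloc[0] == "hyper"

    def test_boundary_values_excluded_by_strict_inequality(self):
        d = self._table(
            [("chr1", 100, 100, "+", 1e-4, 0.005, 25.0),
             ("chr1", 200, 200, "+", 1e-4, 0.01, 30.0)]
        )
        assert len(bk.get_methyl_diff(d)) == 0

    def test_type_filters_sign(self):
        d = self._table(
            [("chr1", 100, 100, "+", 1e-4, 0.001, 30.0),
             ("chr1", 200, 200, "+", 1e-4, 0.001, -30.0)]
        )
        assert list(bk.get_methyl_diff(d, type="hyper")["start"]) == [100]
        assert list(bk.get_methyl_diff(d, type="hypo")["start"]) == [200]
        assert len(bk.get_methyl_diff(d, type="all")) == 2

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(41)
        rows = [
            ("chr1", i, i, "+", rng.uniform(), rng.uniform(), rng.uniform(-60, 60))
            for i in range(1, 101)
        ]
        d = self._table(rows)
        out = bk.get_methyl_diff(d, 0.2, 20, "all")
        expected = {r[1] for r in rows if r[5] < 0.2 and abs(r[6]) > 20}
        assert set(out["start"]) == expected


class TestPerChromosome:
    def _setup(self):
        a = make_methylome([("chr1", p, 5, 5) for p in range(100, 1100, 100)], "a")
        b = make_methylome([("chr1", p, 5, 5) for p in range(100, 1100, 100)], "b", treatment=1)
        return bk.unite([a, b])

    def test_no_dmcs_gives_all_zero_percentages(self):
        u = self._setup()
        d = bk.calculate_diff_meth(u, ModelSpec(correction="bh"))
        table = bk.diff_per_chromosome(d, u)
        assert (table["hyper_pct"] == 0).all() and (table["hypo_pct"] == 0).all()

    def test_counting_oracle_two_hyper_of_ten(self):
        u = self._setup()
        d = u.df[["chrom", "start", "end", "strand"]].copy()
        d["pvalue"] = 1.0
        d["qvalue"] = 1.0
        d["meth_diff"] = 0.0
        d.loc[:1, ["qvalue", "meth_diff"]] = [[0.001, 40.0], [0.001, 50.0]]
        table = bk.diff_per_chromosome(d, u)
        chr1 = table[table["chrom"] == "chr1"].iloc[0]
        assert chr1["hyper_pct"] == pytest.approx(20.0)
        assert chr1["hypo_pct"] == 0.0

    def test_hyper_plus_hypo_bounded_by_100(self):
        spec = bk.SimSpec(n_sites=300, samples_per_group=(2, 2), effect_fraction=0.3,
                          effect_delta=60, frac_low=1.0, frac_high=0.0, seed=43)
        samples, _ = bk.simulate_methylomes(spec)
        u = bk.unite(samples)
        d = bk.calculate_diff_meth(u)
        table = bk.diff_per_chromosome(d, u)
        assert ((table["hyper_pct"] + table["hypo_pct"]) <= 100.0 + 1e-9).all()
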