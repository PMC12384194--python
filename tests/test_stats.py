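"""Cohort-level inference: correlations, Fisher machinery, FDR, moderation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from boldcomplexity import (
    CohortTable,
    correlation_matrix,
    fdr_bh,
    fisher_compare,
    independent_ttest,
    interaction_model,
    pearson_with_ci,
    read_cohort_csv,
    write_cohort_csv,
)
from boldcomplexity.stats import ANALYSIS_VARS, GROUP_CODES

from ._reference import naive_fdr_bh


def _toy_cohort(rng, n_asd=14, n_ctl=15):
    rows = []
    for g, n in (("ASD", n_asd), ("Control", n_ctl)):
        for i in range(n):
            rows.append({
                "id": f"{g}{i}", "group": g,
                "age": rng.uniform(18, 30), "fiq": rng.normal(110, 12),
                "viq": rng.normal(112, 11), "piq": rng.normal(108, 18),
                "hurst": rng.normal(0.45, 0.03),
                "fapen": rng.normal(0.87, 0.03),
                "fsampen": rng.normal(1.08, 0.07),
            })
    return CohortTable(pd.DataFrame(rows))


class TestPearsonWithCI:
    def test_closed_form_on_small_fixture(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 9.0])
        res = pearson_with_ci(x, y)
        r_hand = (np.cov(x, y, ddof=1)[0, 1]
                  / (np.std(x, ddof=1) * np.std(y, ddof=1)))
        assert res.r == pytest.approx(r_hand)
        zr = math.atanh(res.r)
        half = 1.959963984540054 / math.sqrt(5 - 3)
        assert res.ci_low == pytest.approx(math.tanh(zr - half))
        assert res.ci_high == pytest.approx(math.tanh(zr + half))

    def test_p_matches_t_survival_function(self, rng):
        """p must equal the regularized-incomplete-beta tail of the t map."""
        x = rng.standard_normal(20)
        y = 0.4 * x + rng.standard_normal(20)
        res = pearson_with_ci(x, y)
        df = res.n - 2
        t = res.r * math.sqrt(df / (1 - res.r**2))
        p_beta = special.betainc(df / 2.0, 0.5, df / (df + t * t))
        assert res.p == pytest.approx(p_beta, abs=1e-12)

    def test_perfect_anticorrelation_degenerate_ci(self):
        x = np.arange(6.0)
        res = pearson_with_ci(x, -3.0 * x + 1.0)
        assert res.r == -1.0
        assert res.ci_low == res.ci_high == -1.0

    def test_invariants_bracket(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        res = pearson_with_ci(x, y)
        assert -1 <= res.ci_low <= res.r <= res.ci_high <= 1
        assert 0 <= res.p <= 1

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [1, 2, 4])  # n < 4
        with pytest.raises(ValueError):
            pearson_with_ci(np.ones(10), rng.standard_normal(10))

    @given(r=st.floats(-0.999, 0.999))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_fisher_round_trip(self, r):
        assert math.tanh(math.atanh(r)) == pytest.approx(r, abs=1e-12)


class TestFisherCompare:
    def test_identical_correlations_null(self):
        res = fisher_compare(0.42, 20, 0.42, 33)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_hand_evaluated_closed_form(self):
        res = fisher_compare(0.9, 30, 0.0, 30)
        assert res.z == pytest.approx(math.atanh(0.9) / math.sqrt(2 / 27))

    def test_antisymmetry(self, rng):
        for _ in range(10):
            r1, r2 = rng.uniform(-0.95, 0.95, 2)
            n1, n2 = rng.integers(5, 50, 2)
            a = fisher_compare(r1, n1, r2, n2)
            b = fisher_compare(r2, n2, r1, n1)
            assert a.z == pytest.approx(-b.z)
            assert a.p == pytest.approx(b.p)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(1.0, 10, 0.5, 10)


class TestCorrelationMatrix:
    def test_twenty_one_pairs(self, rng):
        cohort = _toy_cohort(rng)
        results = correlation_matrix(cohort, "ASD")
        assert len(results) == 21
        pairs = {frozenset((c.var_x, c.var_y)) for c in results}
        assert len(pairs) == 21

    def test_duplicated_variable_unit_correlation(self, rng):
        cohort = _toy_cohort(rng)
        df = cohort.frame.copy()
        df["viq"] = df["fiq"]
        res = correlation_matrix(CohortTable(df), "Control")
        row = next(c for c in res if {c.var_x, c.var_y} == {"fiq", "viq"})
        assert row.r == pytest.approx(1.0)

    def test_matches_bruteforce_recomputation(self, rng):
        cohort = _toy_cohort(rng)
        sub = cohort.group("ASD")
        for c in correlation_matrix(cohort, "ASD"):
            r_naive = np.corrcoef(sub[c.var_x], sub[c.var_y])[0, 1]
            assert c.r == pytest.approx(r_naive, abs=1e-12)


class TestFdrBH:
    def test_all_tiny_rejected(self):
        reject, adj = fdr_bh([0.001] * 21, 0.05)
        assert reject.all()

    def test_all_ones_kept(self):
        reject, adj = fdr_bh([1.0] * 10, 0.05)
        assert not reject.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_stepup_example(self):
        reject, _ = fdr_bh([0.001, 0.011, 0.02, 0.9], 0.05)
        naive_reject, _ = naive_fdr_bh([0.001, 0.011, 0.02, 0.9], 0.05)
        np.testing.assert_array_equal(reject, naive_reject)

    def test_agrees_with_exhaustive_stepup(self):
        """Package FDR equals the hand-rolled step-up on random vectors."""
        rng = np.random.default_rng(321)
        for _ in range(1000):
            n = rng.integers(1, 26)
            p = rng.uniform(0, 1, n) ** rng.uniform(0.5, 3)
            reject, adj = fdr_bh(p, 0.05)
            nr, na = naive_fdr_bh(p, 0.05)
            np.testing.assert_array_equal(reject, nr)
            np.testing.assert_allclose(adj, na, atol=1e-12)

    def test_empty_input(self):
        reject, adj = fdr_bh([], 0.05)
        assert reject.size == 0 and adj.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestIndependentTTest:
    def test_identical_groups_null(self):
        res = independent_ttest([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups(self):
        a = np.array([1.0, 2, 3]) + np.random.default_rng(0).normal(0, 1e-3, 3)
        res = independent_ttest(a, a + 10.0)
        assert res.p < 1e-3

    def test_pooled_formula_on_four_plus_four(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 4.0, 6.0])
        res = independent_ttest(a, b)
        sp2 = (np.var(a, ddof=1) * 3 + np.var(b, ddof=1) * 3) / 6
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (0.25 + 0.25))
        assert res.t == pytest.approx(t_hand)
        assert res.df == 6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            independent_ttest([2.0, 2.0], [2.0, 2.0])


class TestInteractionModel:
    def _exact_cohort(self, noise_sd=0.0, n=20, seed=0):
        """PIQ built from an exact linear rule in group code and entropy."""
        rng = np.random.default_rng(seed)
        rows = []
        for g, ng in (("ASD", n), ("Control", n)):
            code = GROUP_CODES[g]
            for i in range(ng):
                ent = rng.normal(0.9, 0.05)
                rows.append({
                    "id": f"{g}{i}", "group": g, "age": 25.0 + i,
                    "fiq": 110.0 + i, "viq": 112.0 - i,
                    "piq": 100.0 + 2.0 * code + 50.0 * ent + 30.0 * code * ent
                    + rng.normal(0, noise_sd),
                    "hurst": rng.normal(0.45, 0.02), "fapen": ent,
                    "fsampen": rng.normal(1.08, 0.05),
                })
        return CohortTable(pd.DataFrame(rows))

    def test_zero_noise_exact_recovery(self):
        cohort = self._exact_cohort()
        m = interaction_model(cohort, "fapen")
        # centring shifts B_group and the intercept but not the interaction
        assert m.terms["interaction"]["B"] == pytest.approx(30.0, abs=1e-8)
        ent_mean = cohort.frame["fapen"].mean()
        assert m.terms["entropy_c"]["B"] == pytest.approx(50.0, abs=1e-8)
        assert m.terms["group"]["B"] == pytest.approx(
            2.0 + 30.0 * ent_mean, abs=1e-8
        )
        assert m.r_squared == pytest.approx(1.0)

    def test_group_slopes_follow_coding(self):
        m = interaction_model(self._exact_cohort(), "fapen")
        b_ent = m.terms["entropy_c"]["B"]
        b_int = m.terms["interaction"]["B"]
        assert m.group_slopes["ASD"] == pytest.approx(b_ent + 1 * b_int)
        assert m.group_slopes["Control"] == pytest.approx(b_ent + 2 * b_int)

    def test_subject_order_irrelevant(self, rng):
        cohort = self._exact_cohort(noise_sd=5.0, seed=3)
        m1 = interaction_model(cohort, "fapen")
        shuffled = CohortTable(
            cohort.frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
        )
        m2 = interaction_model(shuffled, "fapen")
        for term in m1.terms:
            assert m1.terms[term]["B"] == pytest.approx(m2.terms[term]["B"])

    def test_ci_brackets_b_and_df(self):
        m = interaction_model(self._exact_cohort(noise_sd=4.0, seed=5), "fapen")
        for t in m.terms.values():
            assert t["ci_low"] <= t["B"] <= t["ci_high"]
        assert m.df_resid == m.n - 4

    def test_one_group_rejected(self, rng):
        df = _toy_cohort(rng).frame
        df = df[df["group"] == "ASD"].reset_index(drop=True)
        with pytest.raises(ValueError):
            interaction_model(CohortTable(df), "fapen")


class TestCohortTable:
    def test_csv_round_trip(self, tmp_path, rng):
        cohort = _toy_cohort(rng)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        pd.testing.assert_frame_equal(
            back.frame, cohort.frame[list(back.frame.columns)],
            check_exact=False,
        )

    def test_missing_column_named(self, rng):
        df = _toy_cohort(rng).frame.drop(columns=["piq"])
        with pytest.raises(ValueError, match="piq"):
            CohortTable(df)

    def test_missing_values_fail_loudly(self, rng):
        df = _toy_cohort(rng).frame.copy()
        df.loc[0, "fapen"] = np.nan
        with pytest.raises(ValueError, match="fapen"):
            CohortTable(df)

    def test_unknown_group_rejected(self, rng):
        df = _toy_cohort(rng).frame.copy()
        df.loc[0, "group"] = "Patient"
        with pytest.raises(ValueError, match="Patient"):
            CohortTable(df)

    def test_small_group_blocks_inference(self, rng):
        small = _toy_cohort(rng, n_asd=3, n_ctl=15)
        with pytest.raises(ValueError, match="4 subjects"):
            small.require_inferential()

    def test_analysis_variable_set(self):
        assert ANALYSIS_VARS == (
            "age", "fiq", "viq", "piq", "hurst", "fapen", "fsampen",
        )
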