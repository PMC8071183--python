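"""Exact-permutation correlation, summary-statistics ANOVA, Sidak, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from girkfit.dose_response import SigmoidFit
from girkfit.kinetics import KineticEstimate
from girkfit.reference import ARROW_GRID, REFERENCE_CONDITIONS
from girkfit.stats import (SummaryCell, anova_two_way_summary,
                           build_shift_table, build_summary_table,
                           read_summary_table_tsv, sidak_adjust,
                           spearman_exact, summary_table_to_tsv)


class TestSpearmanExact:
    def test_matches_scipy_permutation_oracle(self):
        """Exact p agrees with scipy's exhaustive pairing permutation test."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        y = 0.5 * x + rng.normal(size=6)
        res = spearman_exact(x, y)
        assert res.method == "exact_permutation"

        def statistic(perm_y):
            return sps.spearmanr(x, perm_y).statistic

        oracle = sps.permutation_test(
            (y,), statistic, permutation_type="pairings",
            alternative="two-sided", n_resamples=np.inf)
        assert res.rho == pytest.approx(float(sps.spearmanr(x, y).statistic),
                                        abs=1e-12)
        assert res.p_two_sided == pytest.approx(float(oracle.pvalue), abs=1e-9)

    def test_perfect_monotone_association(self):
        x = np.arange(6, dtype=float)
        res = spearman_exact(x, x ** 3 + 1)
        assert res.rho == 1.0
        # only the identity and the full reversal reach |rho| = 1
        import math
        assert res.p_two_sided == pytest.approx(2 / math.factorial(6))

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        base = spearman_exact(x, y)
        warped = spearman_exact(np.exp(x), 3 * y ** 3)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)

    def test_rho_equals_pearson_of_ranks(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        res = spearman_exact(x, y)
        pearson = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert res.rho == pytest.approx(pearson, abs=1e-12)

    def test_ties_fall_back_to_t_approximation_with_warning(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 0.5, 0.3, 0.8, 0.9])
        with pytest.warns(UserWarning, match="ties"):
            res = spearman_exact(x, y)
        assert res.method == "t_approximation"

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = spearman_exact(x, y)
        assert res.method == "t_approximation"
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(float(ref_rho))
        assert res.p_two_sided == pytest.approx(float(ref_p))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_exact([1, 2, 3], [1, 2, 3])


class TestSidak:
    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(sidak_adjust([0.03]), [0.03])

    def test_closed_form_example(self):
        out = sidak_adjust([0.01, 0.2, 0.5, 0.9])
        assert out[0] == pytest.approx(1 - 0.99 ** 4, abs=1e-12)

    def test_zero_stays_zero(self):
        assert sidak_adjust([0.0, 0.5])[0] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_monotone_and_bounded_by_bonferroni(self, ps):
        out = sidak_adjust(ps)
        m = len(ps)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        assert np.all(out <= np.minimum(1.0, m * np.asarray(ps)) + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust([1.5])


def _cells_with_exact_moments(rng, a, b, n):
    """Random cell summaries plus raw data realizing them exactly."""
    cells, raw = [], []
    for i in range(a):
        row = []
        for j in range(b):
            mean = rng.normal(scale=2.0)
            sd = rng.uniform(0.5, 2.0)
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            values = mean + sd * z
            row.append(SummaryCell(mean=float(values.mean()),
                                   sem=float(values.std(ddof=1) / np.sqrt(n)),
                                   n=n))
            raw += [{"y": v, "A": f"a{i}", "B": f"b{j}"} for v in values]
        cells.append(row)
    return cells, pd.DataFrame(raw)


class TestAnovaSummary:
    def test_equal_cell_means_give_zero_f(self):
        cells = [[SummaryCell(1.0, 0.2, 5)] * 2 for _ in range(2)]
        out = anova_two_way_summary(cells)
        assert out["F_rows"] == pytest.approx(0.0, abs=1e-12)
        assert out["F_cols"] == pytest.approx(0.0, abs=1e-12)
        assert out["F_interaction"] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_one_factor_equals_pooled_t_squared(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=7)
        b = rng.normal(loc=1.0, size=5)
        cells = [[SummaryCell(a.mean(), a.std(ddof=1) / np.sqrt(7), 7)],
                 [SummaryCell(b.mean(), b.std(ddof=1) / np.sqrt(5), 5)]]
        out = anova_two_way_summary(cells)
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert out["F_rows"] == pytest.approx(t ** 2, rel=1e-10)
        assert out["df_error"] == 10

    def test_balanced_grid_matches_statsmodels_on_reconstructed_data(self):
        """Summary-statistics ANOVA equals the raw-data ANOVA when the raw
        data realize exactly the summarized moments (balanced design)."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(2)
        cells, frame = _cells_with_exact_moments(rng, a=4, b=2, n=6)
        out = anova_two_way_summary(cells)
        fit = smf.ols("y ~ C(A) * C(B)", data=frame).fit()
        table = anova_lm(fit, typ=2)
        assert out["F_rows"] == pytest.approx(table.loc["C(A)", "F"], rel=1e-6)
        assert out["F_cols"] == pytest.approx(table.loc["C(B)", "F"], rel=1e-6)
        assert out["F_interaction"] == pytest.approx(
            table.loc["C(A):C(B)", "F"], rel=1e-6)
        assert out["df_error"] == int(table.loc["Residual", "df"])

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            anova_two_way_summary([[SummaryCell(1, 0.1, 4), None],
                                   [SummaryCell(1, 0.1, 4),
                                    SummaryCell(2, 0.1, 4)]])


def reference_estimates_and_fits():
    estimates, fits, tops = [], {}, {}
    for cond in REFERENCE_CONDITIONS:
        estimates.append(KineticEstimate(
            ligand=cond.ligand, receptor=cond.receptor,
            k_on=cond.k_on, k_on_sem=cond.k_on_sem,
            k_off=cond.k_off, k_off_sem=cond.k_off_sem))
        fits[(cond.ligand, cond.receptor)] = SigmoidFit(
            pec50=cond.pec50, top=cond.top, pec50_sem=cond.pec50_sem,
            top_sem=cond.top_sem, n_points=0, converged=True)
        tops[(cond.ligand, cond.receptor)] = cond.top
    return estimates, fits, tops


class TestTables:
    def test_summary_tsv_round_trip_is_stable(self):
        estimates, fits, _ = reference_estimates_and_fits()
        table = build_summary_table(estimates, fits)
        tsv = summary_table_to_tsv(table)
        parsed = read_summary_table_tsv(tsv)
        rebuilt_estimates = [
            KineticEstimate(r.ligand, r.receptor, k_on=r.k_on,
                            k_on_sem=r.k_on_sem, k_off=r.k_off,
                            k_off_sem=r.k_off_sem)
            for r in parsed.itertuples()]
        rebuilt_fits = {
            (r.ligand, r.receptor): SigmoidFit(
                pec50=r.pEC50, top=1.0, pec50_sem=r.pEC50_sem, top_sem=0.0,
                n_points=0, converged=True)
            for r in parsed.itertuples()}
        tsv2 = summary_table_to_tsv(build_summary_table(rebuilt_estimates,
                                                        rebuilt_fits))
        assert tsv2 == tsv

    def test_shift_table_reproduces_reference_arrows(self):
        estimates, fits, tops = reference_estimates_and_fits()
        summary = build_summary_table(estimates, fits)
        shift = build_shift_table(summary, tops)
        for _, row in shift.iterrows():
            expected = ARROW_GRID[row["ligand"]]
            assert (row["potency"], row["efficacy"],
                    row["k_off"], row["k_on"]) == expected

    def test_empty_input_gives_header_only_table(self):
        table = build_summary_table([], {})
        assert len(table) == 0
        assert list(table.columns) == [
            "ligand", "receptor", "pEC50", "pEC50_sem", "EC50_nM",
            "k_off", "k_off_sem", "k_on", "k_on_sem", "pKd", "pKd_sem"]

    def test_key_mismatch_rejected(self):
        estimates, fits, _ = reference_estimates_and_fits()
        with pytest.raises(KeyError):
            build_summary_table(estimates, {})
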