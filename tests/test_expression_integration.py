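import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microcna.expression_integration import (
    ContingencyTable2x2,
    anova_by_status,
    dichotomize_expression,
    fisher_exact_2x2,
    gene_concordance,
    pooled_contingency,
)
from microcna.io_formats import ExpressionMatrix


def expr_matrix(rows: dict, samples=None):
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    else:
        df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(values=df)


class TestDichotomize:
    def test_odd_row(self):
        out = dichotomize_expression(expr_matrix({"g": [1, 2, 3]}))
        assert list(out.loc["g"]) == [-1, 0, 1]

    def test_all_equal_row_contributes_nothing(self):
        out = dichotomize_expression(expr_matrix({"g": [2, 2, 2, 2]}))
        assert (out.loc["g"] == 0).all()

    def test_even_row_midpoint_median(self):
        out = dichotomize_expression(expr_matrix({"g": [1, 2, 3, 4]}))
        assert list(out.loc["g"]) == [-1, -1, 1, 1]

    def test_thin_genes_dropped(self):
        out = dichotomize_expression(expr_matrix({"g": [1.0, np.nan, np.nan, 2.0], "h": [1, 2, 3, 4]}))
        assert list(out.index) == ["h"]


def status_df(data, genes, samples):
    return pd.DataFrame(data, index=genes, columns=samples)


class TestGeneConcordance:
    def test_fully_concordant_gene(self):
        statuses = status_df([["micro-amp", "micro-amp", "none", "none", "none"]], ["g"], list("ABCDE"))
        dicho = pd.DataFrame([[1, 1, -1, -1, 0]], index=["g"], columns=list("ABCDE"))
        summary = gene_concordance(statuses, dicho).table
        assert summary.loc["micro-amp", "n_genes_with_class"] == 1
        assert summary.loc["micro-amp", "n_100pct"] == 1
        assert summary.loc["micro-amp", "n_ge50pct"] == 1

    def test_half_concordant_counts_only_ge50(self):
        statuses = status_df([["micro-amp", "micro-amp", "none", "none"]], ["g"], list("ABCD"))
        dicho = pd.DataFrame([[1, -1, 1, -1]], index=["g"], columns=list("ABCD"))
        summary = gene_concordance(statuses, dicho).table
        assert summary.loc["micro-amp", "n_100pct"] == 0
        assert summary.loc["micro-amp", "n_ge50pct"] == 1

    def test_counts_ordering_invariant(self, default_cohort, default_calls):
        from microcna.aberration_calling import status_matrix

        cohort = default_cohort
        statuses = status_matrix(
            default_calls["segments"], [w.gene_symbol for w in cohort.windows], cohort.samples
        )
        dicho = dichotomize_expression(cohort.expression_matrix)
        summary = gene_concordance(statuses, dicho).table
        assert (summary["n_100pct"] <= summary["n_ge50pct"]).all()
        assert (summary["n_ge50pct"] <= summary["n_genes_with_class"]).all()


class TestPooledContingency:
    def test_empty_universe(self):
        t = pooled_contingency(pd.DataFrame(), pd.DataFrame(), "micro-amp")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_coupled_cohort_direction(self):
        """Full expression coupling puts micro-amp pairs mostly above the median."""
        statuses = status_df(
            [["micro-amp"] * 3 + ["none"] * 5], ["g"], [f"S{i}" for i in range(8)]
        )
        dicho = pd.DataFrame([[1, 1, 1, -1, -1, -1, -1, 1]], index=["g"], columns=[f"S{i}" for i in range(8)])
        t = pooled_contingency(statuses, dicho, "micro-amp")
        assert (t.a, t.b, t.c, t.d) == (3, 1, 0, 4)
        # odds ratio in the amplification direction
        assert t.a * t.d > t.b * t.c


def brute_force_fisher(a, b, c, d):
    """Exact two-sided Fisher by integer enumeration of hypergeometric weights."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= w_obs) / total


class TestFisherExact:
    def test_enumerated_small_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_row_column_swap_invariance(self):
        t = ContingencyTable2x2(7, 2, 3, 11)
        swapped = ContingencyTable2x2(11, 3, 2, 7)
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(swapped), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_cross_check(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 50, size=4))
        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        _, ref = stats.fisher_exact([[a, b], [c, d]])
        assert ours == pytest.approx(min(ref, 1.0), rel=1e-6)

    def test_matches_brute_force_small_totals(self):
        for total in (8, 12):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c in range(total + 1 - a - b):
                        d = total - a - b - c
                        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
                        ref = brute_force_fisher(a, b, c, d)
                        assert ours == pytest.approx(ref, rel=1e-9), (a, b, c, d)


class TestAnova:
    def test_worked_example(self):
        f, p = anova_by_status([1, 2, 3, 4, 5, 6], ["aberrant"] * 3 + ["other"] * 3)
        assert f == pytest.approx(13.5)
        assert p == pytest.approx(0.021312, rel=1e-3)

    def test_identical_means_f_zero(self):
        f, p = anova_by_status([1.0, 1.0, 1.0, 1.0], ["aberrant", "aberrant", "other", "other"])
        assert f == 0.0
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        labels = ["aberrant"] * 30 + ["other"] * 30
        _, p = anova_by_status(vals, labels)
        assert p < 1e-3

    def test_thin_group_is_na_with_warning(self):
        with pytest.warns(UserWarning):
            f, p = anova_by_status([1, 2, 3], ["aberrant", "other", "other"])
        assert math.isnan(f) and math.isnan(p)
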