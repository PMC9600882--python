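"""TPM, differential filtering, enrichment, ddCT, and concordance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caproflux.expression import (
    cog_enrichment,
    ddct_relative_expression,
    deg_filter,
    fold_change_concordance,
    tpm_from_counts,
    transcript_fraction,
)


class TestTpm:
    def test_rate_formula_by_hand(self):
        tpm = tpm_from_counts([10, 10], [100, 200])
        assert tpm == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_equal_rates_split_evenly(self):
        tpm = tpm_from_counts([5] * 8, [250] * 8)
        assert np.allclose(tpm, 1e6 / 8)

    def test_single_gene_takes_the_whole_million(self):
        assert tpm_from_counts([42], [1000])[0] == pytest.approx(1e6)

    def test_always_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        tpm = tpm_from_counts(rng.integers(0, 500, 200), rng.integers(100, 3000, 200))
        assert tpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_all_zero_counts_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert tpm_from_counts([0, 0], [100, 100]).sum() == 0

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            tpm_from_counts([1, 1], [100, 0])


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])


class TestDegFilter:
    def test_boundary_values_are_excluded_by_strict_inequalities(self):
        t = _table([("a", 1.0, 0.01), ("b", 1.01, 0.05), ("c", 1.01, 0.049)])
        sets = deg_filter(t)
        assert sets.up == {"c"}  # a fails |lfc| > 1, b fails padj < 0.05

    def test_planted_fixture_recovers_exact_count(self):
        rows = [(f"g{i}", 2.0, 0.001) for i in range(4)]  # 4 up
        rows += [(f"h{i}", -3.0, 0.001) for i in range(3)]  # 3 down
        rows += [(f"n{i}", 0.2, 0.001) for i in range(8)]
        rows += [(f"p{i}", 4.0, 0.5) for i in range(5)]
        sets = deg_filter(_table(rows))
        assert (len(sets.up), len(sets.down)) == (4, 3)
        assert len(sets) == 7

    def test_up_and_down_never_overlap(self):
        t = _table([("a", 2.0, 0.01), ("b", -2.0, 0.01)])
        sets = deg_filter(t)
        assert not (sets.up & sets.down)

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(KeyError):
            deg_filter(pd.DataFrame({"gene_id": ["a"]}))

    def test_nan_padj_never_passes(self):
        sets = deg_filter(_table([("a", 3.0, float("nan"))]))
        assert len(sets) == 0

    @given(
        lfc=st.floats(0.5, 3.0),
        padj=st.floats(0.001, 0.2),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_deg_count_monotone_nonincreasing_in_thresholds(self, lfc, padj):
        rng = np.random.default_rng(7)
        t = _table(
            [(f"g{i}", x, p) for i, (x, p) in enumerate(
                zip(rng.normal(0, 2, 80), rng.uniform(0, 0.3, 80))
            )]
        )
        base = len(deg_filter(t, lfc, padj))
        assert len(deg_filter(t, lfc + 0.5, padj)) <= base
        assert len(deg_filter(t, lfc, padj / 2)) <= base


def _enumeration_pvalue(N, K, n, k):
    """P(X >= k) by exhaustive enumeration over all n-subsets of N genes."""
    if N > 12:  # weighted enumeration via binomial coefficients
        total = math.comb(N, n)
        return sum(
            math.comb(K, i) * math.comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)
        ) / total
    members = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(range(N), n)
        if len(members & set(draw)) >= k
    )
    return hits / math.comb(N, n)


class TestCogEnrichment:
    def _genome(self, N, K, cat="C"):
        cogs = [cat] * K + ["J"] * (N - K)
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(N)], "cog": cogs})

    def test_small_case_matches_exhaustive_enumeration(self):
        genome = self._genome(N=20, K=7, cat="C")
        deg = {f"g{i}" for i in range(4)} | {"g10", "g11", "g12", "g13", "g14", "g15"}
        res = next(r for r in cog_enrichment(deg, genome, min_genes=5) if r.cog == "C")
        k = len({f"g{i}" for i in range(7)} & deg)
        assert res.deg_in_category == k
        assert res.pvalue == pytest.approx(_enumeration_pvalue(20, 7, 10, k), abs=1e-12)

    def test_true_subset_enumeration_agrees_on_tiny_universe(self):
        genome = self._genome(N=10, K=6, cat="C")
        deg = {f"g{i}" for i in (0, 1, 2, 7, 8)}
        res = next(r for r in cog_enrichment(deg, genome, min_genes=5) if r.cog == "C")
        assert res.pvalue == pytest.approx(_enumeration_pvalue(10, 6, 5, 3), abs=1e-12)

    def test_all_genes_differential_gives_p_one(self):
        genome = self._genome(N=15, K=8)
        res = cog_enrichment(set(genome.gene_id), genome, min_genes=5)
        assert all(r.pvalue == pytest.approx(1.0) for r in res)

    def test_zero_hits_gives_p_one(self):
        genome = self._genome(N=15, K=8, cat="C")
        deg = {f"g{i}" for i in range(8, 12)}  # all in J
        res = next(r for r in cog_enrichment(deg, genome, min_genes=5) if r.cog == "C")
        assert res.pvalue == pytest.approx(1.0)

    def test_small_categories_are_not_reported(self):
        genome = self._genome(N=20, K=5, cat="C")  # exactly 5: "more than five" fails
        res = cog_enrichment({"g0"}, genome, min_genes=5)
        assert all(r.cog != "C" for r in res)

    def test_empty_genome_is_an_error(self):
        with pytest.raises(ValueError):
            cog_enrichment(set(), pd.DataFrame(columns=["gene_id", "cog"]))

    def test_significance_flags_at_both_levels(self):
        genome = self._genome(N=200, K=20, cat="C")
        deg = {f"g{i}" for i in range(15)}  # 15/15 hits in C: extreme enrichment
        res = next(r for r in cog_enrichment(deg, genome, min_genes=5) if r.cog == "C")
        assert res.flag == "**"


class TestTranscriptFraction:
    def _table(self):
        return pd.DataFrame(
            {
                "gene_id": ["lldP", "larA", "ldh", "other"],
                "tpm_lactate": [11321.0, 16133.0, 35189.0, 937357.0],
            }
        )

    def test_lactate_utilization_genes_account_for_6_percent(self):
        pct = transcript_fraction(self._table(), ["lldP", "larA", "ldh"], "lactate")
        assert pct == pytest.approx(6.26, abs=0.005)

    def test_all_genes_sum_to_100(self):
        t = self._table()
        assert transcript_fraction(t, list(t.gene_id), "lactate") == pytest.approx(100.0)

    def test_empty_selection_is_zero(self):
        assert transcript_fraction(self._table(), [], "lactate") == 0.0

    def test_unknown_gene_listed_in_error(self):
        with pytest.raises(KeyError, match="nope"):
            transcript_fraction(self._table(), ["nope"], "lactate")


class TestDdct:
    def test_control_sample_is_exactly_one(self):
        assert ddct_relative_expression(21.0, 15.0, 21.0, 15.0) == 1.0

    def test_one_cycle_advantage_doubles(self):
        # ddCT = -1
        assert ddct_relative_expression(20.0, 15.0, 21.0, 15.0) == pytest.approx(2.0)

    def test_two_cycle_lag_quarters(self):
        assert ddct_relative_expression(23.0, 15.0, 21.0, 15.0) == pytest.approx(0.25)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_relative_expression(float("nan"), 15.0, 21.0, 15.0)

    @given(
        ct_t=st.floats(5, 35),
        ct_r=st.floats(5, 35),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_control_is_one_for_any_reference_values(self, ct_t, ct_r):
        assert ddct_relative_expression(ct_t, ct_r, ct_t, ct_r) == 1.0


class TestConcordance:
    def test_identical_vectors_correlate_perfectly(self):
        r, n = fold_change_concordance([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0) and n == 4

    def test_anticorrelated_vectors(self):
        r, _ = fold_change_concordance([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_noisy_qpcr_still_concordant(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-3, 5, 16)
        y = x + rng.normal(0, 0.2, 16)
        r, n = fold_change_concordance(x, y)
        assert r > 0.9 and n == 16

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fold_change_concordance([1, 2], [1, 2])

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            fold_change_concordance([1, 1, 1], [1, 2, 3])
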