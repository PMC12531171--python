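import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycosig.crispr import (
    ScreenZTable,
    aggregate_rank,
    enrichment_test,
    gene_level_lfc,
    top_fraction,
    zscore_normalize,
)
from glycosig.io import GeneSet


def table(rows):
    return pd.DataFrame(rows, columns=["gene", "sgrna", "lfc"])


def ztable(dataset_id, mapping):
    s = pd.Series(mapping, dtype=float)
    return zscore_normalize(s, dataset_id)


class TestGeneLevelLfc:
    def test_mean_of_sgrnas(self):
        t = table([("A", "a1", -1.0), ("A", "a2", -3.0), ("B", "b1", 2.0)])
        out = gene_level_lfc(t)
        assert out["A"] == -2.0 and out["B"] == 2.0

    def test_four_guides(self):
        t = table([("A", f"a{i}", float(v)) for i, v in enumerate([1, 2, 3, 4])])
        assert gene_level_lfc(t)["A"] == 2.5

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lfc"):
            gene_level_lfc(pd.DataFrame({"gene": ["A"]}))


class TestZscoreNormalize:
    def test_sample_sd_denominator(self):
        out = zscore_normalize(pd.Series({"A": -2.0, "B": 0.0, "C": 2.0}), "d1")
        np.testing.assert_allclose(out.z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized(self):
        z1 = zscore_normalize(pd.Series({"A": -2.0, "B": 0.0, "C": 2.0}), "d")
        z2 = zscore_normalize(z1.z, "d")
        np.testing.assert_allclose(z1.z.to_numpy(), z2.z.to_numpy(), atol=1e-15)

    def test_two_point_standardization(self):
        out = zscore_normalize(pd.Series({"A": 1.0, "B": 5.0}), "d")
        np.testing.assert_allclose(
            out.z.to_numpy(), [-math.sqrt(0.5), math.sqrt(0.5)], rtol=1e-12
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_normalize(pd.Series({"A": 1.0, "B": 1.0}), "d")

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError, match="standardized"):
            ScreenZTable("d", pd.Series({"A": 5.0, "B": 9.0}))


class TestAggregateRank:
    def test_missing_aware_mean(self):
        t1 = ztable("d1", {"A": -5.0, "B": 0.0, "C": 5.0})
        t2 = ztable("d2", {"B": -4.0, "C": 0.0, "D": 4.0})
        ranked = aggregate_rank([t1, t2])
        by_gene = {r.gene: r for r in ranked}
        assert by_gene["A"].n_datasets_present == 1
        assert by_gene["B"].mean_z == pytest.approx(
            (t1.z["B"] + t2.z["B"]) / 2
        )

    def test_rank_permutation_and_monotone_mean(self):
        rng = np.random.default_rng(0)
        tables = [
            ztable(f"d{i}", {f"G{j}": float(v) for j, v in enumerate(rng.normal(size=30))})
            for i in range(4)
        ]
        ranked = aggregate_rank(tables)
        assert sorted(r.rank for r in ranked) == list(range(1, 31))
        means = [r.mean_z for r in sorted(ranked, key=lambda r: r.rank)]
        assert all(a <= b + 1e-15 for a, b in zip(means, means[1:]))

    def test_tie_broken_lexicographically(self):
        t1 = ztable("d1", {"B": -1.0, "A": -1.0, "C": 1.0, "D": 1.0})
        ranked = aggregate_rank([t1])
        assert [r.gene for r in ranked[:2]] == ["A", "B"]

    def test_dataset_order_invariance(self):
        rng = np.random.default_rng(1)
        tables = [
            ztable(f"d{i}", {f"G{j}": float(v) for j, v in enumerate(rng.normal(size=12))})
            for i in range(3)
        ]
        ref = aggregate_rank(tables)
        for perm in itertools.permutations(tables):
            assert aggregate_rank(list(perm)) == ref

    def test_disjoint_dataset_only_changes_presence(self):
        t1 = ztable("d1", {"A": -1.0, "B": 0.0, "C": 1.0})
        t2 = ztable("d2", {"X": -1.0, "Y": 1.0})
        ranked = aggregate_rank([t1, t2])
        sub = [r for r in ranked if r.gene in "ABC"]
        assert [r.gene for r in sorted(sub, key=lambda r: r.rank)] == ["A", "B", "C"]

    def test_min_presence_filter(self):
        t1 = ztable("d1", {"A": -1.0, "B": 1.0})
        t2 = ztable("d2", {"B": -1.0, "C": 1.0})
        ranked = aggregate_rank([t1, t2], min_presence=2)
        assert [r.gene for r in ranked] == ["B"]


class TestTopFraction:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [
            (22505, 0.05, 1125),
            (22505, 0.10, 2250),
            (22505, 0.20, 4501),
            (10, 0.25, 2),
            (101, 0.10, 10),
        ],
    )
    def test_floor_rule_counts(self, n, frac, expected):
        ranked = aggregate_rank(
            [
                ztable(
                    "d",
                    {f"G{i:06d}": float(i) for i in range(n)},
                )
            ]
        )
        assert len(top_fraction(ranked, frac)) == expected

    def test_takes_lowest_mean_z(self):
        ranked = aggregate_rank([ztable("d", {"A": -2.0, "B": 0.0, "C": 1.0, "D": 3.0})])
        assert top_fraction(ranked, 0.5).genes == ("A", "B")

    def test_empty_fraction_rejected(self):
        ranked = aggregate_rank([ztable("d", {"A": -1.0, "B": 1.0})])
        with pytest.raises(ValueError, match="empty"):
            top_fraction(ranked, 0.1)


def hypergeom_tail_oracle(k, N, K, n):
    """Exhaustive hypergeometric sum: P[overlap >= k]."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        for i in range(k, min(K, n) + 1)
    )


class TestEnrichment:
    def universe(self, n):
        return GeneSet("U", tuple(f"G{i:03d}" for i in range(n)))

    def test_signature_subset_of_top(self):
        uni = self.universe(40)
        top = GeneSet("T", uni.genes[:10])
        sig = GeneSet("S", uni.genes[:5])
        k, prop, p = enrichment_test(sig, top, uni)
        assert k == 5 and prop == 1.0
        assert p == pytest.approx(hypergeom_tail_oracle(5, 40, 5, 10), rel=1e-12)

    def test_matches_exhaustive_sum(self):
        # N=100 case reduced per the documented formula; also scan small universes
        uni = self.universe(60)
        for n_top, n_sig, k in [(20, 10, 5), (12, 6, 2), (30, 8, 8)]:
            top = GeneSet("T", uni.genes[:n_top])
            sig = GeneSet("S", uni.genes[n_top - k : n_top - k + n_sig])
            got_k, _, p = enrichment_test(sig, top, uni)
            assert got_k == k
            assert p == pytest.approx(hypergeom_tail_oracle(k, 60, n_sig, n_top), rel=1e-12)

    def test_expected_overlap_near_half_p(self):
        uni = self.universe(50)
        top = GeneSet("T", uni.genes[:25])  # half the universe
        sig = GeneSet("S", (uni.genes[0], uni.genes[1], uni.genes[30], uni.genes[40]))
        _, _, p = enrichment_test(sig, top, uni)  # k = 2 = expectation
        assert 0.2 < p < 0.8

    def test_restriction_to_universe(self):
        uni = self.universe(30)
        top = GeneSet("T", uni.genes[:6])
        sig = GeneSet("S", uni.genes[:3] + ("NOT_IN_UNIVERSE",))
        k, prop, _ = enrichment_test(sig, top, uni)
        assert k == 3 and prop == 1.0

    def test_top_outside_universe_rejected(self):
        uni = self.universe(10)
        with pytest.raises(ValueError, match="universe"):
            enrichment_test(
                GeneSet("S", uni.genes[:2]), GeneSet("T", ("ZZZ",)), uni
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(10, 60), st.data())
    def test_agrees_with_enumeration_everywhere(self, n, data):
        n_top = data.draw(st.integers(1, n - 1))
        n_sig = data.draw(st.integers(1, n - 1))
        uni = self.universe(n)
        rng = np.random.default_rng(n * 1000 + n_top * 10 + n_sig)
        top = GeneSet("T", tuple(np.random.default_rng(1).permutation(uni.genes)[:n_top]))
        sig = GeneSet("S", tuple(rng.permutation(uni.genes)[:n_sig]))
        k, _, p = enrichment_test(sig, top, uni)
        assert p == pytest.approx(hypergeom_tail_oracle(k, n, n_sig, n_top), abs=1e-12)
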