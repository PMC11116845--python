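"""Allele frequencies, fixed differences with tolerance, delta-p, Nei's D.

The fixed-difference and Nei's-D implementations are checked against
independent brute-force oracles (plain per-locus loops written here from the
published formulas) on randomly generated frequency tables.
"""

import math

import numpy as np
import pytest

from crypticlade.diagnosability import (
    AlleleFrequencyTable,
    allele_frequencies,
    count_fixed_differences,
    delta_p,
    nei_unbiased_D,
    pairwise_matrices,
)
from crypticlade.genotypes import ValidationError
from crypticlade.simulate import LineageSpec, ScenarioConfig, simulate_genotypes
from tests.conftest import make_dataset


def table_from_freqs(freqs, copies):
    """freqs: {(group, locus): {allele: x}}; copies: {(group, locus): 2n}."""
    groups = sorted({g for g, _ in freqs})
    loci = sorted({l for _, l in freqs})
    return AlleleFrequencyTable(groups, loci, dict(freqs), dict(copies))


def random_table(rng, n_groups=2, n_loci=8):
    """Random frequency table from multinomial gene-copy counts."""
    groups = [f"G{i}" for i in range(n_groups)]
    loci = [f"L{j}" for j in range(n_loci)]
    freqs, copies = {}, {}
    for g in groups:
        for l in loci:
            n2 = int(rng.integers(2, 40)) * 2
            k = int(rng.integers(1, 4))
            alleles = [chr(ord("a") + i) for i in range(k)]
            counts = rng.multinomial(n2, np.ones(k) / k)
            freqs[(g, l)] = {
                a: c / n2 for a, c in zip(alleles, counts) if c > 0
            }
            copies[(g, l)] = n2
    return table_from_freqs(freqs, copies)


class TestAlleleFrequencies:
    def test_counting_two_individuals(self):
        ds = make_dataset(
            [("i1", "s", {"L": "a/a"}), ("i2", "s", {"L": "a/b"})], ["L"]
        )
        t = allele_frequencies(ds, {"i1": "g", "i2": "g"})
        assert t.frequencies("g", "L") == {"a": 0.75, "b": 0.25}
        assert t.gene_copies("g", "L") == 4

    def test_missing_genotype_excluded_from_denominator(self):
        ds = make_dataset(
            [("i1", "s", {"L": "a/a"}), ("i2", "s", {"L": None})], ["L"]
        )
        t = allele_frequencies(ds, {"i1": "g", "i2": "g"})
        assert t.gene_copies("g", "L") == 2
        assert t.frequencies("g", "L") == {"a": 1.0}

    def test_binomial_sampling_bound_at_large_n(self):
        spec = LineageSpec("P", {"L": {"a": 0.7, "b": 0.3}}, n=500)
        ds, _ = simulate_genotypes(ScenarioConfig([spec], seed=11))
        t = allele_frequencies(ds, {i: "P" for i in ds.individual_ids})
        assert abs(t.frequencies("P", "L")["a"] - 0.7) < 0.05

    def test_grouping_by_site_default(self, two_group_dataset):
        t = allele_frequencies(two_group_dataset)
        assert t.groups == ["north", "south"]


class TestFixedDifferences:
    def test_disjoint_sets_diagnostic_at_any_tolerance(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {"b": 1.0}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        for tau in (0.0, 0.05, 0.10):
            assert count_fixed_differences(t, "A", "B", tau).count == 1

    def test_high_frequency_shared_allele_blocks_diagnosis(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 0.95, "b": 0.05}, ("B", "L"): {"b": 1.0}},
            {("A", "L"): 40, ("B", "L"): 40},
        )
        res = count_fixed_differences(t, "A", "B", 0.10)
        rec = res.loci[0]
        assert rec.shared_alleles == ("b",)
        assert rec.shared_sum_a == pytest.approx(0.05)
        assert rec.shared_sum_b == pytest.approx(1.0)
        assert res.count == 0

    def test_low_frequency_sharing_within_tolerance_is_diagnostic(self):
        t = table_from_freqs(
            {
                ("A", "L"): {"a": 0.92, "b": 0.08},
                ("B", "L"): {"b": 0.06, "c": 0.94},
            },
            {("A", "L"): 50, ("B", "L"): 50},
        )
        res = count_fixed_differences(t, "A", "B", 0.10)
        assert res.loci[0].shared_sum_a == pytest.approx(0.08)
        assert res.loci[0].shared_sum_b == pytest.approx(0.06)
        assert res.count == 1
        # under sum-mode the same locus fails: 0.08 + 0.06 > 0.10
        assert count_fixed_differences(t, "A", "B", 0.10, mode="sum").count == 0

    def test_count_monotone_nondecreasing_in_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = random_table(rng)
            counts = [
                count_fixed_differences(t, "G0", "G1", tau).count
                for tau in (0.0, 0.05, 0.10, 0.20)
            ]
            assert counts == sorted(counts)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            t = random_table(rng)
            res = count_fixed_differences(t, "G0", "G1", 0.10)
            expected = 0
            for locus in t.loci:
                fa = t.frequencies("G0", locus)
                fb = t.frequencies("G1", locus)
                s_a = s_b = 0.0
                for al in fa:
                    if al in fb:
                        s_a += fa[al]
                        s_b += fb[al]
                if max(s_a, s_b) <= 0.10:
                    expected += 1
            assert res.count == expected

    def test_rare_allele_merging_never_reduces_count(self):
        """Allele-label hygiene guard: folding each group's rare alleles
        (pooled frequency < 0.05) into its own commonest allele — as one
        would when rare variants are suspected mis-scores — can only
        remove sharing, so the diagnostic count at tau = 0.10 must not
        decrease."""
        rng = np.random.default_rng(37)
        for _ in range(50):
            t = random_table(rng)
            merged_freqs, merged_copies = {}, {}
            for key, f in t.freqs.items():
                merged_copies[key] = t.copies[key]
                if not f:
                    merged_freqs[key] = {}
                    continue
                top = max(f, key=lambda a: (f[a], a))
                out: dict[str, float] = {}
                for a, x in f.items():
                    target = top if (x < 0.05 and a != top) else a
                    out[target] = out.get(target, 0.0) + x
                merged_freqs[key] = out
            merged = AlleleFrequencyTable(
                t.groups, t.loci, merged_freqs, merged_copies
            )
            before = count_fixed_differences(t, "G0", "G1", 0.10).count
            after = count_fixed_differences(merged, "G0", "G1", 0.10).count
            assert before <= after

    def test_undefined_locus_never_diagnostic(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {}},
            {("A", "L"): 10, ("B", "L"): 0},
        )
        res = count_fixed_differences(t, "A", "B", 0.0)
        assert res.count == 0 and not res.loci[0].defined


class TestDeltaP:
    def test_identical_frequencies_give_zero(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 0.6, "b": 0.4}, ("B", "L"): {"a": 0.6, "b": 0.4}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        per_locus, exceeding = delta_p(t, "A", "B")
        assert per_locus["L"] == 0.0 and exceeding == []

    def test_partial_overlap_differential(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {"a": 0.55, "b": 0.45}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        per_locus, exceeding = delta_p(t, "A", "B", threshold=0.40)
        assert per_locus["L"] == pytest.approx(0.45)
        assert exceeding == ["L"]


class TestNeiD:
    def test_identity_monomorphic_self_comparison(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {"a": 1.0}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        res = nei_unbiased_D(t, "A", "B")
        assert res.identity == 1.0 and res.distance == 0.0

    def test_disjoint_fixation_gives_infinite_distance(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {"b": 1.0}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        assert nei_unbiased_D(t, "A", "B").distance == math.inf

    def test_unbiased_overshoot_clamped_to_zero_distance(self):
        # both groups 0.5/0.5 with n = 10: Jx_hat = (20*0.5 - 1)/19 = 9/19,
        # Jxy = 0.5, so raw I = 0.5/(9/19) = 19/18 > 1 -> clamp to D = 0
        t = table_from_freqs(
            {("A", "L"): {"a": 0.5, "b": 0.5}, ("B", "L"): {"a": 0.5, "b": 0.5}},
            {("A", "L"): 20, ("B", "L"): 20},
        )
        res = nei_unbiased_D(t, "A", "B")
        assert res.jx[0] == pytest.approx(9 / 19)
        assert res.jxy[0] == pytest.approx(0.5)
        assert res.clamped and res.distance == 0.0

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            t = random_table(rng)
            d1 = nei_unbiased_D(t, "G0", "G1").distance
            d2 = nei_unbiased_D(t, "G1", "G0").distance
            assert d1 == pytest.approx(d2, abs=1e-15)

    def test_self_distance_uncorrected_is_exactly_zero(self):
        rng = np.random.default_rng(29)
        t = random_table(rng)
        res = nei_unbiased_D(t, "G0", "G0", corrected=False)
        assert res.distance == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            t = random_table(rng, n_loci=6)
            res = nei_unbiased_D(t, "G0", "G1")
            jx, jy, jxy = [], [], []
            for locus in t.loci:
                fa = t.frequencies("G0", locus)
                fb = t.frequencies("G1", locus)
                na2 = t.gene_copies("G0", locus)
                nb2 = t.gene_copies("G1", locus)
                jx.append(
                    min(1.0, max(0.0, (na2 * sum(x * x for x in fa.values()) - 1)
                                 / (na2 - 1)))
                )
                jy.append(
                    min(1.0, max(0.0, (nb2 * sum(y * y for y in fb.values()) - 1)
                                 / (nb2 - 1)))
                )
                jxy.append(sum(x * fb.get(a, 0.0) for a, x in fa.items()))
            i_raw = (sum(jxy) / len(jxy)) / math.sqrt(
                (sum(jx) / len(jx)) * (sum(jy) / len(jy))
            )
            expected = -math.log(min(i_raw, 1.0)) if i_raw > 0 else math.inf
            assert res.distance == pytest.approx(expected, abs=1e-12)

    def test_group_without_scoreable_loci_rejected(self):
        t = table_from_freqs(
            {("A", "L"): {"a": 1.0}, ("B", "L"): {}},
            {("A", "L"): 10, ("B", "L"): 0},
        )
        with pytest.raises(ValidationError):
            nei_unbiased_D(t, "A", "B")


class TestPairwiseMatrices:
    def test_identical_groups_give_zero_everything(self):
        ds = make_dataset(
            [(f"i{k}", "s1" if k < 5 else "s2", {"L": "a/b"}) for k in range(10)],
            ["L"],
        )
        t = allele_frequencies(ds)
        fixed, nei = pairwise_matrices(t)
        assert fixed.loc["s1", "s2"] == 0
        assert nei.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_counts_recovered(self):
        # three lineages with planted 2/5/7 strictly diagnostic loci
        planted = {("A", "B"): 2, ("A", "C"): 5, ("B", "C"): 7}
        freqs = {g: {} for g in "ABC"}
        idx = 0
        for (g1, g2), count in planted.items():
            g3 = next(g for g in "ABC" if g not in (g1, g2))
            for _ in range(count):
                locus = f"D{idx}"
                idx += 1
                freqs[g1][locus] = {"a": 1.0}
                freqs[g2][locus] = {"b": 1.0}
                # the third group segregates both alleles, so the locus is
                # diagnostic for exactly the planted pair
                freqs[g3][locus] = {"a": 0.5, "b": 0.5}
        specs = [LineageSpec(g, freqs[g], n=12) for g in "ABC"]
        ds, truth = simulate_genotypes(ScenarioConfig(specs, seed=3))
        t = allele_frequencies(ds, truth.mapping)
        fixed, _ = pairwise_matrices(t, tolerance=0.0)
        for (g1, g2), count in planted.items():
            assert fixed.loc[g1, g2] == count
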