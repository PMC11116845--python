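"""Dosage encoding, classical scaling, split detection, stepwise delineation.

The PCoA implementation is checked against a brute-force classical-scaling
oracle written here from first principles (explicit double-centring loops and
numpy eigendecomposition on small random inputs).
"""

import numpy as np
import pandas as pd
import pytest

from crypticlade.genotypes import ValidationError
from crypticlade.ordination import (
    detect_split,
    encode_genotypes,
    flag_admixture,
    pcoa,
    stepwise_delineate,
)
from crypticlade.simulate import (
    LineageSpec,
    ScenarioConfig,
    default_scenario,
    simulate_genotypes,
)
from tests.conftest import make_dataset


def brute_force_classical_scaling(x):
    """Independent oracle: explicit loops for B = -1/2 J D^2 J, then eigh."""
    n = x.shape[0]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = np.sum((x[i] - x[j]) ** 2)
    b = np.zeros((n, n))
    row = d2.mean(axis=1)
    grand = d2.mean()
    for i in range(n):
        for j in range(n):
            b[i, j] = -0.5 * (d2[i, j] - row[i] - row[j] + grand)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-9 * max(1.0, abs(vals).max())
    return vals[keep], vecs[:, keep] * np.sqrt(vals[keep])


class TestEncoding:
    def test_homozygote_and_heterozygote_dosages(self):
        ds = make_dataset(
            [("i1", "s", {"L": "a/a"}), ("i2", "s", {"L": "a/b"})], ["L"]
        )
        fm = encode_genotypes(ds)
        assert fm.values.loc["i1", ("L", "a")] == 1.0
        assert fm.values.loc["i1", ("L", "b")] == 0.0
        assert fm.values.loc["i2", ("L", "a")] == 0.5
        assert fm.values.loc["i2", ("L", "b")] == 0.5

    def test_missing_imputed_with_observed_column_mean(self):
        # observed dosages for allele b: 0.5, 0, 0.25 -> mean 0.25
        ds = make_dataset(
            [
                ("i1", "s", {"L": "a/b", "M": "a/a"}),
                ("i2", "s", {"L": "a/a", "M": "a/a"}),
                ("i3", "s", {"L": "a/b", "M": "a/a"}),
                ("i4", "s", {"L": "a/a", "M": "a/a"}),
                ("i5", "s", {"L": None, "M": "a/a"}),
            ],
            ["L", "M"],
        )
        fm = encode_genotypes(ds)
        assert fm.values.loc["i5", ("L", "b")] == pytest.approx(0.25)
        assert fm.imputed.loc["i5", ("L", "b")]
        assert not fm.imputed.loc["i1", ("L", "b")]

    def test_individual_missing_everywhere_rejected(self):
        ds = make_dataset(
            [("i1", "s", {"L": "a/a"}), ("i2", "s", {"L": None})], ["L"]
        )
        with pytest.raises(ValidationError, match="i2"):
            encode_genotypes(ds)


class TestPCoA:
    def test_three_equidistant_points_split_variance_evenly(self):
        # unit simplex in the plane: pairwise distance 1
        x = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        res = pcoa(x)
        assert res.eigenvalues.shape == (2,)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.percent_contribution[0] == pytest.approx(50.0)

    def test_distances_reproduced_for_planar_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=(7, 2))
            res = pcoa(x)
            coords = res.coordinates.to_numpy()
            for i in range(7):
                for j in range(7):
                    orig = np.linalg.norm(x[i] - x[j])
                    rec = np.linalg.norm(coords[i] - coords[j])
                    assert rec == pytest.approx(orig, abs=1e-9)

    def test_matches_brute_force_oracle_on_small_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 11))
            x = rng.normal(size=(n, int(rng.integers(2, 6))))
            res = pcoa(x)
            vals, coords = brute_force_classical_scaling(x)
            assert res.eigenvalues == pytest.approx(vals, abs=1e-9)
            # compare axis by axis up to sign (equal-eigenvalue rotations
            # do not arise for generic random input)
            got = res.coordinates.to_numpy()
            for k in range(len(vals)):
                diff = min(
                    np.abs(got[:, k] - coords[:, k]).max(),
                    np.abs(got[:, k] + coords[:, k]).max(),
                )
                assert diff < 1e-8

    def test_variance_conservation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(9, 5))
        res = pcoa(x)
        centred = x - x.mean(axis=0)
        assert res.eigenvalues.sum() == pytest.approx(
            (centred**2).sum(), abs=1e-9
        )

    def test_degenerate_identical_points_give_no_axes(self):
        res = pcoa(np.ones((4, 3)))
        assert res.n_axes == 0
        assert res.eigenvalues.size == 0

    def test_deterministic_with_canonical_signs(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 3))
        r1, r2 = pcoa(x.copy()), pcoa(x.copy())
        assert (r1.coordinates.to_numpy() == r2.coordinates.to_numpy()).all()
        # largest-magnitude loading on each axis is positive
        for k in range(r1.n_axes):
            col = r1.coordinates.to_numpy()[:, k]
            assert col[np.argmax(np.abs(col))] > 0


def gaussian_clusters(rng, centers, n_each, spread):
    pts, ids = [], []
    for c, (cx, cy) in enumerate(centers):
        pts.append(rng.normal([cx, cy], spread, size=(n_each, 2)))
        ids.extend(f"c{c}_{i:02d}" for i in range(n_each))
    x = np.vstack(pts)
    return pd.DataFrame(x, index=ids, columns=["axis1", "axis2"])


def as_pcoa_result(coords_df):
    from crypticlade.ordination import PCoAResult

    var = coords_df.to_numpy().var(axis=0) * len(coords_df)
    return PCoAResult(coords_df, var, 100 * var / var.sum())


class TestDetectSplit:
    def test_two_lineages_at_ten_times_spread_accepted(self):
        rng = np.random.default_rng(7)
        coords = gaussian_clusters(rng, [(0, 0), (10, 0)], 12, 1.0)
        dec = detect_split(as_pcoa_result(coords))
        assert dec.accepted and dec.n_children == 2
        # membership matches construction exactly
        assert {frozenset(c) for c in dec.children} == {
            frozenset(i for i in coords.index if i.startswith("c0")),
            frozenset(i for i in coords.index if i.startswith("c1")),
        }

    def test_panmictic_cloud_rejected(self):
        rng = np.random.default_rng(8)
        coords = gaussian_clusters(rng, [(0, 0)], 30, 1.0)
        assert not detect_split(as_pcoa_result(coords)).accepted

    def test_three_clusters_found_in_one_decision(self):
        rng = np.random.default_rng(9)
        coords = gaussian_clusters(rng, [(0, 0), (12, 0), (6, 10)], 10, 0.8)
        dec = detect_split(as_pcoa_result(coords))
        assert dec.accepted and dec.n_children == 3

    def test_small_groups_never_split(self):
        rng = np.random.default_rng(10)
        coords = gaussian_clusters(rng, [(0, 0), (10, 0)], 3, 0.5)
        assert not detect_split(as_pcoa_result(coords), min_cluster=4).accepted


class TestStepwiseDelineation:
    def test_two_lineages_with_diagnostic_loci_fully_recovered(self):
        freqs = {g: {} for g in "AB"}
        for k in range(5):
            freqs["A"][f"D{k}"] = {"a": 1.0}
            freqs["B"][f"D{k}"] = {"b": 1.0}
        for k in range(10):
            for g in "AB":
                freqs[g][f"S{k}"] = {"a": 0.7, "b": 0.3}
        ds, truth = simulate_genotypes(
            ScenarioConfig([LineageSpec(g, freqs[g], 15) for g in "AB"], seed=21)
        )
        assign = stepwise_delineate(ds)
        assert len(assign.labels) == 2
        for label in assign.labels:
            assert len({truth.mapping[i] for i in assign.members(label)}) == 1

    def test_single_lineage_stays_single(self):
        freqs = {f"S{k}": {"a": 0.7, "b": 0.3} for k in range(20)}
        ds, _ = simulate_genotypes(
            ScenarioConfig([LineageSpec("P", freqs, 30)], seed=22)
        )
        assign = stepwise_delineate(ds)
        assert assign.labels == ["L"]
        assert not assign.admixed

    def test_nested_structure_gives_three_leaves(self):
        # deep split (C vs A+B at 10 loci) plus shallow split (A vs B at 4);
        # C carries the ancestral allele at the shallow loci
        freqs = {g: {} for g in "ABC"}
        for k in range(10):
            loc = f"D{k:02d}"
            freqs["A"][loc] = {"a": 1.0}
            freqs["B"][loc] = {"a": 1.0}
            freqs["C"][loc] = {"b": 1.0}
        for k in range(4):
            loc = f"E{k:02d}"
            freqs["A"][loc] = {"a": 1.0}
            freqs["B"][loc] = {"b": 1.0}
            freqs["C"][loc] = {"a": 1.0}
        for k in range(16):
            loc = f"S{k:02d}"
            for g in "ABC":
                freqs[g][loc] = {"a": 0.8, "b": 0.2}
        ds, truth = simulate_genotypes(
            ScenarioConfig(
                [LineageSpec(g, freqs[g], 20, 0.05) for g in "ABC"], seed=23
            )
        )
        assign = stepwise_delineate(ds)
        assert len(assign.labels) == 3
        for label in assign.labels:
            assert len({truth.mapping[i] for i in assign.members(label)}) == 1

    def test_provenance_logs_every_step(self):
        ds, _ = simulate_genotypes(default_scenario(seed=24))
        assign = stepwise_delineate(ds)
        actions = [s["action"] for s in assign.provenance]
        assert actions.count("split") >= 1
        assert sum(a.startswith("leaf") for a in actions) == len(assign.labels)

    def test_pins_override_and_unflag(self):
        ds, truth = simulate_genotypes(
            default_scenario(seed=25, admixed_per_pair=1)
        )
        f1 = sorted(truth.admixed)[0]
        assign = stepwise_delineate(ds, pins={f1: "manual"})
        assert assign.mapping[f1] == "manual"
        assert f1 not in assign.admixed


class TestAdmixtureFlagging:
    def test_f1_individuals_flagged_and_pure_ones_not(self):
        ds, truth = simulate_genotypes(
            default_scenario(seed=26, admixed_per_pair=2)
        )
        assign = stepwise_delineate(ds)
        assert assign.admixed == truth.admixed

    def test_f1_with_all_diagnostic_loci_missing_not_flagged(self, caplog):
        # strip every diagnostic-locus genotype from one F1 individual
        cfg = default_scenario(seed=27, admixed_per_pair=1)
        ds, truth = simulate_genotypes(cfg)
        f1 = "F1_L1xL2_01"
        diag = [l for pair, loci in cfg.planted.items()
                for l in loci if pair == ("L1", "L2")]
        for locus in diag:
            ds._genotypes.pop((f1, locus), None)
        import logging

        logging.getLogger("crypticlade").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="crypticlade.ordination"):
            assign = stepwise_delineate(ds)
        assert f1 not in assign.admixed
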