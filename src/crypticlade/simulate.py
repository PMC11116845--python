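"""Synthetic genotype and sequence generators with known lineage truth.

Every pipeline stage is testable without downloads: genotypes are drawn per
individual per locus as two independent allele draws from lineage-specific
frequencies (Hardy-Weinberg sampling) and masked to missing at a configured
rate; admixed (F1-like) individuals draw one allele from each parental
lineage at every locus; sequences evolve down a user-supplied tree under
Jukes-Cantor substitution with exact per-branch transition probabilities.

The default scenario plants three lineages (n = 25 each, 40 loci, 5%
missing) with strict diagnostic loci in counts 4, 6 and 8 for the three
lineage pairs: at a locus diagnostic for pair (A, B), A is fixed for one
allele, B for another, and the third lineage segregates both at 0.5/0.5 so
that the locus is diagnostic for exactly that one pair.  The remaining loci
share the same two-allele frequencies across lineages (major allele cycling
through 0.9/0.8/0.7/0.6 — typical allozyme polymorphism levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from crypticlade.genotypes import (
    AllozymeDataset,
    Genotype,
    Individual,
    LineageAssignment,
    ValidationError,
)
from crypticlade.seqdiv import Alignment, CladePartition
from crypticlade.trees import read_newick

__all__ = [
    "LineageSpec",
    "ScenarioConfig",
    "default_scenario",
    "simulate_genotypes",
    "simulate_sequences",
]


@dataclass
class LineageSpec:
    """One lineage's sampling design: per-locus allele frequencies, sample
    size, missing-data rate, and an optional subdivision into sites."""

    label: str
    freqs: dict[str, dict[str, float]]  # locus -> allele -> frequency
    n: int
    missing_rate: float = 0.0
    sites: list[tuple[str, int]] | None = None  # (site label, count)

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing rate must be in [0, 1)")
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.label}/{locus}: frequencies sum to {total}, not 1"
                )
            if any(x < 0 for x in f.values()):
                raise ValidationError(f"{self.label}/{locus}: negative frequency")
        if self.sites is not None and sum(c for _, c in self.sites) != self.n:
            raise ValidationError(
                f"{self.label}: site counts do not sum to n = {self.n}"
            )

    def site_of(self, index: int) -> str:
        if self.sites is None:
            return self.label
        for site, count in self.sites:
            if index < count:
                return site
            index -= count
        raise IndexError(index)


@dataclass
class ScenarioConfig:
    """A full genotype-simulation scenario.

    ``planted`` records, per unordered lineage pair, the loci planted as
    strict diagnostics (disjoint allele sets between that pair); it is
    validated against the frequency vectors.  ``admixed`` gives F1 counts
    per pair.  The seed is mandatory: outputs are bit-identical per seed.
    """

    lineages: list[LineageSpec]
    seed: int
    planted: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    admixed: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        labels = [s.label for s in self.lineages]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate lineage labels")
        by_label = {s.label: s for s in self.lineages}
        loci = None
        for spec in self.lineages:
            if loci is None:
                loci = set(spec.freqs)
            elif set(spec.freqs) != loci:
                raise ValidationError("lineages disagree on the locus set")
        for (a, b), planted_loci in self.planted.items():
            for locus in planted_loci:
                fa = {al for al, x in by_label[a].freqs[locus].items() if x > 0}
                fb = {al for al, x in by_label[b].freqs[locus].items() if x > 0}
                if fa & fb:
                    raise ValidationError(
                        f"planted diagnostic locus {locus!r} for ({a}, {b}) "
                        f"shares allele(s) {sorted(fa & fb)}"
                    )
        for pair in self.admixed:
            for label in pair:
                if label not in by_label:
                    raise ValidationError(f"admixed pair names unknown {label!r}")

    @property
    def loci(self) -> list[str]:
        return sorted(self.lineages[0].freqs)

    def spec(self, label: str) -> LineageSpec:
        for s in self.lineages:
            if s.label == label:
                return s
        raise KeyError(label)


def default_scenario(
    seed: int,
    n_per_lineage: int = 25,
    n_loci: int = 40,
    planted_counts: Sequence[int] = (4, 6, 8),
    missing_rate: float = 0.05,
    admixed_per_pair: int = 0,
) -> ScenarioConfig:
    """The reference three-lineage scenario used throughout the tests.

    Diagnostic loci are assigned to the pairs (L1, L2), (L1, L3), (L2, L3)
    in ``planted_counts`` order; remaining loci are shared two-allele
    polymorphisms identical across lineages.
    """
    labels = ["L1", "L2", "L3"]
    pairs = [("L1", "L2"), ("L1", "L3"), ("L2", "L3")]
    if len(planted_counts) != 3:
        raise ValidationError("planted_counts must have one entry per pair")
    total_diag = sum(planted_counts)
    if total_diag > n_loci:
        raise ValidationError("more planted loci than loci")
    freqs: dict[str, dict[str, dict[str, float]]] = {l: {} for l in labels}
    planted: dict[tuple[str, str], list[str]] = {p: [] for p in pairs}
    locus_no = 0
    for pair, count in zip(pairs, planted_counts):
        third = next(l for l in labels if l not in pair)
        for _ in range(count):
            locus_no += 1
            locus = f"D{locus_no:02d}"
            planted[pair].append(locus)
            freqs[pair[0]][locus] = {"a": 1.0}
            freqs[pair[1]][locus] = {"b": 1.0}
            freqs[third][locus] = {"a": 0.5, "b": 0.5}
    majors = [0.9, 0.8, 0.7, 0.6]
    for k in range(n_loci - total_diag):
        locus = f"S{k + 1:02d}"
        p = majors[k % len(majors)]
        for l in labels:
            freqs[l][locus] = {"a": p, "b": round(1 - p, 12)}
    lineages = [
        LineageSpec(l, freqs[l], n_per_lineage, missing_rate) for l in labels
    ]
    admixed = {p: admixed_per_pair for p in pairs} if admixed_per_pair else {}
    return ScenarioConfig(lineages, seed=seed, planted=planted, admixed=admixed)


def _draw_genotype(rng, freqs: dict[str, float]) -> tuple[str, str]:
    alleles = sorted(freqs)
    probs = np.array([freqs[a] for a in alleles])
    probs = probs / probs.sum()
    picks = rng.choice(len(alleles), size=2, p=probs)
    return alleles[picks[0]], alleles[picks[1]]


def simulate_genotypes(
    config: ScenarioConfig,
) -> tuple[AllozymeDataset, LineageAssignment]:
    """Draw a genotype dataset and its ground-truth lineage assignment.

    Pure-lineage individuals: two independent allele draws per locus from
    the lineage frequencies, masked to missing at the lineage's rate.
    Admixed individuals: one allele from each parental lineage at every
    locus (F1 model), missing rate averaged over the parents.  Ground-truth
    labels (and admixed flags) are returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    loci = config.loci
    individuals: list[Individual] = []
    genotypes: dict[tuple[str, str], object] = {}
    mapping: dict[str, str] = {}
    admixed_ids: set[str] = set()
    for spec in config.lineages:
        for i in range(spec.n):
            ind_id = f"{spec.label}_{i + 1:03d}"
            individuals.append(Individual(ind_id, spec.site_of(i)))
            mapping[ind_id] = spec.label
            for locus in loci:
                if spec.missing_rate and rng.random() < spec.missing_rate:
                    continue
                genotypes[(ind_id, locus)] = Genotype(
                    locus, _draw_genotype(rng, spec.freqs[locus])
                )
    for (a, b), count in sorted(config.admixed.items()):
        spec_a, spec_b = config.spec(a), config.spec(b)
        rate = 0.5 * (spec_a.missing_rate + spec_b.missing_rate)
        for i in range(count):
            ind_id = f"F1_{a}x{b}_{i + 1:02d}"
            individuals.append(Individual(ind_id, f"{a}x{b}"))
            admixed_ids.add(ind_id)
            for locus in loci:
                if rate and rng.random() < rate:
                    continue
                allele_a = _draw_genotype(rng, spec_a.freqs[locus])[0]
                allele_b = _draw_genotype(rng, spec_b.freqs[locus])[0]
                genotypes[(ind_id, locus)] = Genotype(locus, (allele_a, allele_b))
    dataset = AllozymeDataset(individuals, loci, genotypes)
    truth = LineageAssignment(mapping=mapping, admixed=admixed_ids)
    return dataset, truth


# -- sequence simulation ---------------------------------------------------

_BASES = np.arange(4, dtype=np.uint8)


def _jc_transition(seq: np.ndarray, t: float, rng) -> np.ndarray:
    """Evolve a sequence for branch length t (expected substitutions/site)
    under Jukes-Cantor, using the exact transition probabilities."""
    if t <= 0:
        return seq.copy()
    p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    changed = rng.random(seq.shape[0]) >= p_same
    out = seq.copy()
    if changed.any():
        # conditional on change: uniform over the three other bases
        shifts = rng.integers(1, 4, size=int(changed.sum()), dtype=np.uint8)
        out[changed] = (out[changed] + shifts) % 4
    return out


def simulate_sequences(
    tree,
    length: int,
    seed: int,
    mask: dict[str, tuple[int, int]] | None = None,
) -> tuple[Alignment, CladePartition]:
    """Evolve sequences down a tree under Jukes-Cantor.

    ``tree`` is a newick string/path or a dendropy tree whose branch lengths
    are expected substitutions per site; the root sequence is uniform over
    {A, C, G, T}.  Leaf clade labels are taken from labelled internal nodes
    (every leaf below a labelled node belongs to that clade; nested labels —
    the nearest labelled ancestor wins; unlabelled leaves form their own
    clade).  ``mask`` optionally maps sequence ids to (n_leading,
    n_trailing) site counts replaced by N, emulating partial amplicons of
    varying length.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if isinstance(tree, (str,)) or hasattr(tree, "__fspath__"):
        tree = read_newick(tree)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    clade_of: dict[str, str] = {}

    def walk(node, seq: np.ndarray, clade: str | None) -> None:
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.label:
            clade = node.label
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            walk(child, _jc_transition(seq, t, rng), clade)
        if label is not None:
            ids.append(label)
            rows.append(seq)
            clade_of[label] = clade if clade is not None else label

    walk(tree.seed_node, root_seq, None)
    matrix = np.vstack(rows)
    if mask:
        for seq_id, (lead, trail) in mask.items():
            if seq_id not in ids:
                raise ValueError(f"mask names unknown sequence {seq_id!r}")
            i = ids.index(seq_id)
            if lead + trail >= length:
                raise ValueError(f"mask for {seq_id!r} covers the whole sequence")
            if lead:
                matrix[i, :lead] = 255
            if trail:
                matrix[i, length - trail :] = 255
    order = sorted(range(len(ids)), key=lambda k: ids[k])
    aln = Alignment([ids[k] for k in order], matrix[order])
    partition = CladePartition({i: clade_of[i] for i in aln.ids})
    return aln, partition
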