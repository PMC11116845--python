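"""p-distance over aligned sequences and clade divergence summaries.

The p-distance is the proportion of compared sites at which two aligned
sequences differ.  Sites where either sequence is missing (``N``) or gapped
(``-``) are excluded pairwise ("pairwise deletion"), mirroring the default
treatment in mainstream distance software; complete deletion (drop a column
if *any* sequence is unscored there) is available for sensitivity analysis.
IUPAC ambiguity codes are conservatively mapped to N on read.

Divergence between clades of a partition is summarised as the min-max range
of pairwise p-distances among (cross-clade) and within (diagonal) clades,
the conventional presentation for mtDNA barcoding-style comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from crypticlade.trees import DistanceMatrix

__all__ = [
    "Alignment",
    "CladePartition",
    "DivergenceSummary",
    "read_alignment",
    "write_alignment",
    "p_distance",
    "pairwise_p_matrix",
    "clade_divergence_summary",
    "prune_alignment",
]

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255, "-": 255}
_VALID = set("ACGTN-")


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A, C, G, T, N, -}.

    Internally sequences are a uint8 matrix (A=0, C=1, G=2, T=3,
    unscored=255) for vectorised site comparisons.
    """

    ids: list[str]
    matrix: np.ndarray  # (n_seqs, n_sites) uint8

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")

    @classmethod
    def from_strings(cls, records: Mapping[str, str] | Sequence[tuple[str, str]]
                     ) -> "Alignment":
        items = list(records.items()) if isinstance(records, Mapping) else list(records)
        ids = [i for i, _ in items]
        lengths = {len(s) for _, s in items}
        if len(lengths) > 1:
            for i, s in items:
                if len(s) != len(items[0][1]):
                    raise ValueError(
                        f"ragged alignment: record {i!r} has length {len(s)}, "
                        f"expected {len(items[0][1])}"
                    )
        n_mapped = 0
        rows = []
        for _, seq in items:
            row = np.empty(len(seq), dtype=np.uint8)
            for k, ch in enumerate(seq.upper()):
                if ch not in _VALID:
                    n_mapped += 1
                    ch = "N"
                row[k] = _CODE[ch]
            rows.append(row)
        if n_mapped:
            logger.warning(
                "%d unknown residue character(s) mapped to N", n_mapped
            )
        return cls(ids, np.vstack(rows) if rows else np.zeros((0, 0), np.uint8))

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, seq_id: str) -> str:
        row = self.matrix[self.ids.index(seq_id)]
        lookup = np.array(list("ACGT" + "N" * 252), dtype="U1")
        return "".join(lookup[row])


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; unknown residues are mapped to N with a
    warning; ragged records raise ``ValueError`` naming the offender."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ref_id, ref_seq = records[0]
    for rid, seq in records:
        if len(seq) != len(ref_seq):
            raise ValueError(
                f"ragged alignment: record {rid!r} has length {len(seq)}, "
                f"expected {len(ref_seq)} (as {ref_id!r})"
            )
    return Alignment.from_strings(records)


def write_alignment(aln: Alignment, path, width: int = 70) -> None:
    lines = []
    for seq_id in aln.ids:
        lines.append(f">{seq_id}")
        s = aln.sequence(seq_id)
        lines.extend(s[i : i + width] for i in range(0, len(s), width))
    Path(path).write_text("\n".join(lines) + "\n")


def _p_dist_rows(a: np.ndarray, b: np.ndarray) -> float:
    valid = (a != 255) & (b != 255)
    compared = int(valid.sum())
    if compared == 0:
        return float("nan")
    return float((a[valid] != b[valid]).sum() / compared)


def p_distance(s1: str | np.ndarray, s2: str | np.ndarray) -> float:
    """Proportion of differing sites under pairwise deletion.

    Sites with N or '-' in either sequence are excluded; comparison is
    case-insensitive.  Raises ``ValueError`` when no site is comparable.
    """
    if isinstance(s1, str) or isinstance(s2, str):
        aln = Alignment.from_strings([("s1", str(s1)), ("s2", str(s2))])
        a, b = aln.matrix
    else:
        a, b = np.asarray(s1, np.uint8), np.asarray(s2, np.uint8)
        if a.shape != b.shape:
            raise ValueError("sequences differ in length")
    p = _p_dist_rows(a, b)
    if np.isnan(p):
        raise ValueError("no comparable sites between the two sequences")
    return p


def pairwise_p_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs p-distance matrix.

    ``deletion="pairwise"`` (default) excludes unscored sites per pair;
    ``"complete"`` drops every column unscored in any sequence first.
    Pairs with no comparable sites get NaN (flagged, not raised).
    """
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    if deletion not in {"pairwise", "complete"}:
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    m = aln.matrix
    if deletion == "complete":
        keep = (m != 255).all(axis=0)
        m = m[:, keep]
    n = len(aln)
    values = np.zeros((n, n))
    undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            p = _p_dist_rows(m[i], m[j])
            if np.isnan(p):
                undefined += 1
            values[i, j] = values[j, i] = p
    if undefined:
        logger.warning("%d sequence pair(s) have no comparable sites", undefined)
    return DistanceMatrix(aln.ids, values, source="p-distance")


@dataclass
class CladePartition:
    """Mapping of sequence ids to clade labels, with optional exclusions."""

    mapping: dict[str, str]
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = set(self.mapping) & self.excluded
        if overlap:
            raise ValueError(f"ids both labelled and excluded: {sorted(overlap)}")

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, clade: str) -> list[str]:
        return sorted(i for i, c in self.mapping.items() if c == clade)

    @classmethod
    def from_csv(cls, path) -> "CladePartition":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(df.columns[:2]) != ["id", "clade"]:
            raise ValueError("clade file must have columns 'id,clade'")
        mapping, excluded = {}, set()
        for _, row in df.iterrows():
            if row["clade"]:
                mapping[row["id"]] = row["clade"]
            else:
                excluded.add(row["id"])
        return cls(mapping, excluded)


@dataclass
class DivergenceSummary:
    """Min-max p-distance per clade pair (among) and per clade (within).

    ``among[(a, b)]`` with a < b is (min, max, n_pairs); ``within[c]`` is
    (min, max, n_pairs) or None when the clade has fewer than two members.
    """

    clades: list[str]
    among: dict[tuple[str, str], tuple[float, float, int]]
    within: dict[str, tuple[float, float, int] | None]

    def to_frame(self, decimals: int = 3, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0

        def fmt(cell):
            if cell is None:
                return "n/a"
            lo, hi, _ = cell
            return f"{lo * scale:.{decimals}f}-{hi * scale:.{decimals}f}"

        k = len(self.clades)
        out = pd.DataFrame("", index=self.clades, columns=self.clades)
        for i, ci in enumerate(self.clades):
            out.iloc[i, i] = fmt(self.within[ci])
            for j in range(i):
                cj = self.clades[j]
                key = (min(ci, cj), max(ci, cj))
                out.iloc[i, j] = fmt(self.among[key])
        return out


def clade_divergence_summary(
    dm: DistanceMatrix, partition: CladePartition
) -> DivergenceSummary:
    """Summarise a p-distance matrix by clade: among-clade and within-clade
    min-max ranges.  Excluded ids are ignored; NaN (undefined) pairs are
    dropped from ranges."""
    labels = set(dm.labels)
    for seq_id in partition.mapping:
        if seq_id not in labels:
            raise ValueError(f"clade member {seq_id!r} absent from matrix")
    clades = partition.clades
    idx = {l: k for k, l in enumerate(dm.labels)}

    def collect(ids_a, ids_b, cross: bool):
        vals = []
        if cross:
            pairs = [(a, b) for a in ids_a for b in ids_b]
        else:
            pairs = [
                (ids_a[i], ids_a[j])
                for i in range(len(ids_a))
                for j in range(i + 1, len(ids_a))
            ]
        for a, b in pairs:
            v = dm.values[idx[a], idx[b]]
            if not np.isnan(v):
                vals.append(v)
        if not vals:
            return None
        return (float(min(vals)), float(max(vals)), len(vals))

    among = {}
    within = {}
    for i, ci in enumerate(clades):
        mi = partition.members(ci)
        within[ci] = collect(mi, mi, cross=False) if len(mi) >= 2 else None
        for cj in clades[i + 1 :]:
            among[(ci, cj)] = collect(mi, partition.members(cj), cross=True)
    return DivergenceSummary(clades, among, within)


def prune_alignment(aln: Alignment, start: int, end: int) -> Alignment:
    """Column slice by 1-based inclusive coordinates (e.g. a 400-bp
    window for comparison with short partial amplicons)."""
    if not (1 <= start <= end <= aln.length):
        raise ValueError(
            f"window {start}-{end} out of bounds for length {aln.length}"
        )
    return Alignment(list(aln.ids), aln.matrix[:, start - 1 : end].copy())
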