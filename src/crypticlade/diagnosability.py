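"""Diagnosability and divergence statistics over grouped allele frequencies.

Three statistics quantify how distinguishable two groups (sites or lineages)
are from codominant genotype data:

* **Fixed differences with tolerance** — a locus is diagnostic between groups
  A and B when the alleles they share account for at most a tolerance
  ``tau`` of each group's allele pool (``tau = 0`` is a strict fixed
  difference: disjoint allele sets).  The default tolerance of 10% follows
  standard allozyme diagnosability practice, absorbing rare shared alleles
  that would otherwise veto an otherwise fully diagnostic locus.
* **Delta-p** — the largest per-allele frequency differential at a locus;
  loci with large differentials (default > 0.40) are reported as near-
  diagnostic even when alleles are shared.
* **Nei's unbiased genetic distance** — ``D = -ln(I)`` where ``I`` is the
  normalised gene identity with the small-sample (unbiased) correction of
  within-group homozygosity: per locus ``Jx_hat = (2n * sum(x_i^2) - 1) /
  (2n - 1)``, ``Jxy = sum(x_i * y_i)``, and ``I`` is the ratio of arithmetic
  means over shared scoreable loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from crypticlade.genotypes import MISSING, AllozymeDataset, ValidationError

__all__ = [
    "AlleleFrequencyTable",
    "FixedDiffLocus",
    "FixedDiffResult",
    "NeiDResult",
    "allele_frequencies",
    "count_fixed_differences",
    "delta_p",
    "nei_unbiased_D",
    "pairwise_matrices",
    "render_combined_table",
]

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTable:
    """Per-group, per-locus allele frequencies with gene-copy counts.

    ``freqs[(group, locus)]`` maps allele -> frequency; ``copies[(group,
    locus)]`` is the number of gene copies scored (2n).  A (group, locus)
    cell with zero copies has an empty frequency dict and is *undefined*.
    """

    groups: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[str, float]]
    copies: dict[tuple[str, str], int]

    def __post_init__(self):
        for key, f in self.freqs.items():
            n2 = self.copies.get(key, 0)
            if n2 > 0:
                total = sum(f.values())
                if abs(total - 1.0) > 1e-12:
                    raise ValidationError(
                        f"frequencies at {key} sum to {total}, not 1"
                    )
            elif f:
                raise ValidationError(f"frequencies given at {key} with 2n=0")

    def defined(self, group: str, locus: str) -> bool:
        return self.copies.get((group, locus), 0) > 0

    def frequencies(self, group: str, locus: str) -> dict[str, float]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return self.freqs.get((group, locus), {})

    def gene_copies(self, group: str, locus: str) -> int:
        return self.copies.get((group, locus), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            for locus in self.loci:
                f = self.freqs.get((group, locus), {})
                for allele, x in sorted(f.items()):
                    rows.append(
                        {
                            "group": group,
                            "locus": locus,
                            "allele": allele,
                            "frequency": x,
                            "gene_copies": self.copies[(group, locus)],
                        }
                    )
        return pd.DataFrame(
            rows, columns=["group", "locus", "allele", "frequency", "gene_copies"]
        )


def allele_frequencies(
    dataset: AllozymeDataset,
    grouping: Mapping[str, str] | str = "site",
) -> AlleleFrequencyTable:
    """Tabulate allele frequencies per group per locus.

    ``grouping`` is either the string ``"site"`` (group by the site column)
    or a mapping individual id -> group label covering a subset of the
    dataset; individuals absent from the mapping are ignored.  Missing
    genotypes are excluded from the denominator, so 2n can differ between
    loci within a group.
    """
    if grouping == "site":
        grouping = {ind.id: ind.site for ind in dataset.individuals}
    members: dict[str, list[str]] = {}
    known = set(dataset.individual_ids)
    for ind_id, group in grouping.items():
        if ind_id not in known:
            raise ValidationError(f"grouping names unknown individual {ind_id!r}")
        members.setdefault(group, []).append(ind_id)
    if not members:
        raise ValidationError("empty grouping")
    for group, ids in members.items():
        if not ids:
            raise ValidationError(f"group {group!r} has no individuals")
    groups = sorted(members)
    freqs: dict[tuple[str, str], dict[str, float]] = {}
    copies: dict[tuple[str, str], int] = {}
    for group in groups:
        for locus in dataset.loci:
            counts: dict[str, int] = {}
            n2 = 0
            for ind_id in members[group]:
                g = dataset.genotype(ind_id, locus)
                if g is MISSING:
                    continue
                for a in g.alleles:
                    counts[a] = counts.get(a, 0) + 1
                n2 += 2
            copies[(group, locus)] = n2
            freqs[(group, locus)] = (
                {a: c / n2 for a, c in counts.items()} if n2 else {}
            )
    return AlleleFrequencyTable(groups, list(dataset.loci), freqs, copies)


# -- fixed differences -----------------------------------------------------


@dataclass(frozen=True)
class FixedDiffLocus:
    locus: str
    shared_alleles: tuple[str, ...]
    shared_sum_a: float
    shared_sum_b: float
    diagnostic: bool
    defined: bool


@dataclass
class FixedDiffResult:
    """Per-locus diagnosability detail between one pair of groups."""

    group_a: str
    group_b: str
    tolerance: float
    mode: str
    loci: list[FixedDiffLocus]

    @property
    def count(self) -> int:
        return sum(1 for rec in self.loci if rec.diagnostic)

    @property
    def diagnostic_loci(self) -> list[str]:
        return [rec.locus for rec in self.loci if rec.diagnostic]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": rec.locus,
                    "shared_alleles": ",".join(rec.shared_alleles),
                    "shared_sum_a": rec.shared_sum_a,
                    "shared_sum_b": rec.shared_sum_b,
                    "diagnostic": rec.diagnostic,
                    "defined": rec.defined,
                }
                for rec in self.loci
            ]
        )


def count_fixed_differences(
    table: AlleleFrequencyTable,
    group_a: str,
    group_b: str,
    tolerance: float = 0.10,
    mode: str = "max",
) -> FixedDiffResult:
    """Count diagnostic loci between two groups under a shared-allele
    tolerance.

    Per locus, shared alleles are those with positive frequency in both
    groups; ``S_A`` and ``S_B`` sum the shared-allele frequencies within each
    group.  Under ``mode="max"`` (default) the locus is diagnostic iff
    ``max(S_A, S_B) <= tolerance`` — each group's shared-allele budget must
    be within tolerance.  ``mode="sum"`` uses ``S_A + S_B <= tolerance``.
    A locus undefined (no scored copies) in either group is never diagnostic.
    """
    for g in (group_a, group_b):
        if g not in table.groups:
            raise KeyError(f"unknown group {g!r}")
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    if mode not in {"max", "sum"}:
        raise ValueError("mode must be 'max' or 'sum'")
    records = []
    for locus in table.loci:
        if not (table.defined(group_a, locus) and table.defined(group_b, locus)):
            records.append(FixedDiffLocus(locus, (), 0.0, 0.0, False, False))
            continue
        fa = table.frequencies(group_a, locus)
        fb = table.frequencies(group_b, locus)
        shared = tuple(sorted(set(fa) & set(fb)))
        s_a = sum(fa[a] for a in shared)
        s_b = sum(fb[a] for a in shared)
        stat = max(s_a, s_b) if mode == "max" else s_a + s_b
        records.append(
            FixedDiffLocus(locus, shared, s_a, s_b, stat <= tolerance, True)
        )
    return FixedDiffResult(group_a, group_b, tolerance, mode, records)


def delta_p(
    table: AlleleFrequencyTable,
    group_a: str,
    group_b: str,
    threshold: float = 0.40,
) -> tuple[dict[str, float], list[str]]:
    """Per-locus maximum allele-frequency differential.

    Returns ``(per_locus, exceeding)`` where ``per_locus`` maps each locus
    defined in both groups to ``max_i |x_A,i - x_B,i|`` (absent alleles count
    as frequency 0) and ``exceeding`` lists loci with differential strictly
    above ``threshold``.  Loci undefined in either group are skipped with a
    warning.
    """
    for g in (group_a, group_b):
        if g not in table.groups:
            raise KeyError(f"unknown group {g!r}")
    per_locus: dict[str, float] = {}
    for locus in table.loci:
        if not (table.defined(group_a, locus) and table.defined(group_b, locus)):
            logger.warning(
                "delta_p: locus %s undefined in %s or %s; skipped",
                locus,
                group_a,
                group_b,
            )
            continue
        fa = table.frequencies(group_a, locus)
        fb = table.frequencies(group_b, locus)
        alleles = set(fa) | set(fb)
        per_locus[locus] = max(
            abs(fa.get(a, 0.0) - fb.get(a, 0.0)) for a in alleles
        )
    exceeding = [l for l, d in per_locus.items() if d > threshold]
    return per_locus, exceeding


# -- Nei's unbiased D ------------------------------------------------------


@dataclass
class NeiDResult:
    """Nei's unbiased genetic distance between two groups with per-locus
    identity terms."""

    group_a: str
    group_b: str
    loci: list[str]
    jx: list[float]
    jy: list[float]
    jxy: list[float]
    identity: float
    distance: float
    clamped: bool
    dropped_loci: list[str] = field(default_factory=list)


def nei_unbiased_D(
    table: AlleleFrequencyTable,
    group_a: str,
    group_b: str,
    corrected: bool = True,
) -> NeiDResult:
    """Nei's (1978) unbiased genetic distance between two groups.

    Over the loci scoreable (2n >= 2) in both groups: ``Jx_hat = (2n_A *
    sum(x_i^2) - 1) / (2n_A - 1)`` (clamped to [0, 1]), analogously
    ``Jy_hat``, and ``Jxy = sum(x_i * y_i)``.  The identity is ``I =
    mean(Jxy) / sqrt(mean(Jx_hat) * mean(Jy_hat))`` with arithmetic means
    over the shared loci, and ``D = -ln(I)``.  ``I > 1`` — possible under
    the unbiased correction at small n — is clamped to 1 (D = 0) with
    ``clamped=True``; ``I <= 0`` yields ``D = +inf``.

    With ``corrected=False`` the uncorrected ``Jx = sum(x_i^2)`` is used
    (the infinite-sample identity, under which D(A, A) is exactly 0).
    """
    for g in (group_a, group_b):
        if g not in table.groups:
            raise KeyError(f"unknown group {g!r}")
    for g in (group_a, group_b):
        if all(table.gene_copies(g, locus) <= 1 for locus in table.loci):
            raise ValidationError(
                f"group {g!r} has 2n <= 1 at every locus; Nei's D undefined"
            )
    loci, jx, jy, jxy, dropped = [], [], [], [], []
    for locus in table.loci:
        na2 = table.gene_copies(group_a, locus)
        nb2 = table.gene_copies(group_b, locus)
        if na2 < 2 or nb2 < 2:
            dropped.append(locus)
            continue
        fa = table.frequencies(group_a, locus)
        fb = table.frequencies(group_b, locus)
        sum_xa2 = sum(x * x for x in fa.values())
        sum_xb2 = sum(x * x for x in fb.values())
        if corrected:
            jx_l = (na2 * sum_xa2 - 1) / (na2 - 1)
            jy_l = (nb2 * sum_xb2 - 1) / (nb2 - 1)
        else:
            jx_l, jy_l = sum_xa2, sum_xb2
        jx_l = min(1.0, max(0.0, jx_l))
        jy_l = min(1.0, max(0.0, jy_l))
        jxy_l = sum(x * fb.get(a, 0.0) for a, x in fa.items())
        loci.append(locus)
        jx.append(jx_l)
        jy.append(jy_l)
        jxy.append(jxy_l)
    if not loci:
        raise ValidationError(
            f"no locus scoreable in both {group_a!r} and {group_b!r}"
        )
    if dropped:
        logger.info(
            "Nei's D %s vs %s: %d locus/loci dropped pairwise (2n < 2)",
            group_a,
            group_b,
            len(dropped),
        )
    mean_jx = float(np.mean(jx))
    mean_jy = float(np.mean(jy))
    mean_jxy = float(np.mean(jxy))
    clamped = False
    if mean_jxy == 0.0 or mean_jx == 0.0 or mean_jy == 0.0:
        identity, distance = 0.0, math.inf
    else:
        identity = mean_jxy / math.sqrt(mean_jx * mean_jy)
        if identity > 1.0:
            logger.info(
                "Nei's D %s vs %s: I = %.6f > 1 under unbiased correction; "
                "clamped to 1 (D = 0)",
                group_a,
                group_b,
                identity,
            )
            identity, clamped = 1.0, True
        distance = -math.log(identity) if identity > 0 else math.inf
    return NeiDResult(
        group_a, group_b, loci, jx, jy, jxy, identity, distance, clamped, dropped
    )


# -- pairwise matrices -----------------------------------------------------


def pairwise_matrices(
    table: AlleleFrequencyTable,
    groups: Sequence[str] | None = None,
    tolerance: float = 0.10,
    mode: str = "max",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric fixed-difference and Nei's-D matrices over groups.

    Returns ``(fixed_diff, nei_d)`` as labelled DataFrames (ints and floats
    respectively, zero diagonal).
    """
    groups = list(groups) if groups is not None else list(table.groups)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    k = len(groups)
    fd = np.zeros((k, k), dtype=int)
    nd = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            fd[i, j] = fd[j, i] = count_fixed_differences(
                table, groups[i], groups[j], tolerance, mode
            ).count
            nd[i, j] = nd[j, i] = nei_unbiased_D(table, groups[i], groups[j]).distance
    return (
        pd.DataFrame(fd, index=groups, columns=groups),
        pd.DataFrame(nd, index=groups, columns=groups),
    )


def render_combined_table(
    fixed: pd.DataFrame, nei: pd.DataFrame, decimals: int = 2
) -> str:
    """Render a combined matrix — fixed differences in the lower-left
    triangle, Nei's D (rounded) in the upper-right — as plain text."""
    groups = list(fixed.index)
    width = max(6, max(len(g) for g in groups) + 1, decimals + 4)
    header = "".rjust(width) + "".join(g.rjust(width) for g in groups)
    lines = [header]
    for i, gi in enumerate(groups):
        cells = []
        for j in range(len(groups)):
            if i == j:
                cells.append("-".rjust(width))
            elif i > j:
                cells.append(str(int(fixed.iloc[i, j])).rjust(width))
            else:
                val = nei.iloc[i, j]
                cells.append(
                    ("inf" if math.isinf(val) else f"{val:.{decimals}f}").rjust(width)
                )
        lines.append(gi.rjust(width) + "".join(cells))
    return "\n".join(lines)
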