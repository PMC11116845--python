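"""Data model and I/O for codominant multi-locus genotype tables.

Each individual carries, at each locus, an unordered pair of allele labels
(codominant scoring: heterozygotes are distinguishable from homozygotes) or a
MISSING observation.  Allele labels are opaque tokens compared by exact,
case-normalised string identity; their electrophoretic meaning plays no role
in any downstream statistic.

The on-disk dialect is a delimited table with header
``individual,site[,region],locus1,...,locusL``.  Genotype tokens are accepted
in two-character form (``ab``, ``aa``) or slash form (``a/b``); missing
genotypes are empty fields.  On write, the slash form is always used and
homozygotes are written explicitly (``a/a``) so that the format round-trips
without ambiguity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "Genotype",
    "Individual",
    "AllozymeDataset",
    "LineageAssignment",
    "GenotypeParseError",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "write_genepop",
]


class GenotypeParseError(ValueError):
    """A malformed token or table structure, located by row/column."""


class ValidationError(ValueError):
    """A structurally valid table that violates dataset invariants."""


_TWO_CHAR = re.compile(r"^[A-Za-z]{2}$")
_SLASH = re.compile(r"^([A-Za-z0-9]+)/([A-Za-z0-9]+)$")


class _Missing:
    """Singleton sentinel for an unscored genotype."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele labels at one locus.

    ``Genotype("Est1", ("b", "a"))`` and ``Genotype("Est1", ("a", "b"))``
    compare equal: the pair is stored sorted.  Use :data:`MISSING` (not a
    Genotype) for unscored observations.
    """

    locus: str
    alleles: tuple[str, str]

    def __post_init__(self):
        a, b = self.alleles
        a, b = a.lower(), b.lower()
        if b < a:
            a, b = b, a
        object.__setattr__(self, "alleles", (a, b))

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    def token(self) -> str:
        return f"{self.alleles[0]}/{self.alleles[1]}"


@dataclass(frozen=True)
class Individual:
    id: str
    site: str
    region: str | None = None


def _parse_token(token: str, locus: str, row: int, column: str):
    token = token.strip()
    if token == "":
        return MISSING
    m = _SLASH.match(token)
    if m:
        return Genotype(locus, (m.group(1), m.group(2)))
    if _TWO_CHAR.match(token):
        return Genotype(locus, (token[0], token[1]))
    raise GenotypeParseError(
        f"malformed genotype token {token!r} at row {row}, column {column!r}"
    )


class AllozymeDataset:
    """Individuals x loci table of codominant genotypes with site metadata.

    Parameters
    ----------
    individuals:
        Ordered individual records; ids must be unique.
    loci:
        Ordered locus names.
    genotypes:
        Mapping ``(individual_id, locus) -> Genotype | MISSING``.  Absent
        keys are treated as MISSING.
    """

    def __init__(
        self,
        individuals: Sequence[Individual],
        loci: Sequence[str],
        genotypes: Mapping[tuple[str, str], object],
    ):
        ids = [ind.id for ind in individuals]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate individual id(s): {sorted(dupes)}")
        self.individuals: list[Individual] = list(individuals)
        self.loci: list[str] = list(loci)
        locus_set = set(self.loci)
        self._genotypes: dict[tuple[str, str], object] = {}
        id_set = set(ids)
        for (ind_id, locus), g in genotypes.items():
            if locus not in locus_set:
                raise ValidationError(f"genotype at unknown locus {locus!r}")
            if ind_id not in id_set:
                raise ValidationError(f"genotype for unknown individual {ind_id!r}")
            if g is not MISSING:
                if not isinstance(g, Genotype):
                    raise ValidationError(f"not a Genotype: {g!r}")
                if g.locus != locus:
                    raise ValidationError(
                        f"genotype locus {g.locus!r} filed under {locus!r}"
                    )
                self._genotypes[(ind_id, locus)] = g

    # -- basic access ------------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.site, None)
        return list(seen)

    def genotype(self, individual_id: str, locus: str):
        return self._genotypes.get((individual_id, locus), MISSING)

    def site_of(self, individual_id: str) -> str:
        for ind in self.individuals:
            if ind.id == individual_id:
                return ind.site
        raise KeyError(individual_id)

    def alleles_at(self, locus: str) -> list[str]:
        """Sorted allele universe at a locus, recomputed from the data."""
        if locus not in self.loci:
            raise KeyError(locus)
        seen: set[str] = set()
        for ind in self.individuals:
            g = self._genotypes.get((ind.id, locus))
            if g is not None:
                seen.update(g.alleles)
        return sorted(seen)

    def __len__(self) -> int:
        return len(self.individuals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AllozymeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self._genotypes == other._genotypes
        )

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        individuals: Iterable[str] | None = None,
        sites: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "AllozymeDataset":
        """Restrict to selected individuals and/or sites and/or loci.

        Selectors combine by intersection; allele universes are implicitly
        recomputed because they are always derived from the retained rows.
        """
        keep_inds = self.individuals
        if sites is not None:
            sites = set(sites)
            unknown = sites - set(self.sites)
            if unknown:
                raise ValidationError(f"unknown site(s): {sorted(unknown)}")
            keep_inds = [ind for ind in keep_inds if ind.site in sites]
        if individuals is not None:
            wanted = set(individuals)
            unknown = wanted - set(self.individual_ids)
            if unknown:
                raise ValidationError(f"unknown individual(s): {sorted(unknown)}")
            keep_inds = [ind for ind in keep_inds if ind.id in wanted]
        keep_loci = self.loci
        if loci is not None:
            wanted_loci = list(dict.fromkeys(loci))
            unknown = set(wanted_loci) - set(self.loci)
            if unknown:
                raise ValidationError(f"unknown locus/loci: {sorted(unknown)}")
            keep_loci = [l for l in self.loci if l in set(wanted_loci)]
        if not keep_inds:
            raise ValidationError("subset selects no individuals")
        if not keep_loci:
            raise ValidationError("subset selects no loci")
        keep_ids = {ind.id for ind in keep_inds}
        keep_locus_set = set(keep_loci)
        g = {
            k: v
            for k, v in self._genotypes.items()
            if k[0] in keep_ids and k[1] in keep_locus_set
        }
        return AllozymeDataset(keep_inds, keep_loci, g)


@dataclass
class LineageAssignment:
    """A partition of individuals into lineages, plus admixed flags.

    Every individual carries exactly one lineage label or is flagged admixed
    (admixture is a flag, not a lineage).  ``provenance`` is an ordered log of
    the analysis steps (one record per ordination and split decision) that
    produced each label.
    """

    mapping: dict[str, str]
    admixed: set[str] = field(default_factory=set)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.mapping) & self.admixed
        if overlap:
            raise ValidationError(
                f"individuals both assigned and admixed: {sorted(overlap)}"
            )

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def members(self, label: str) -> list[str]:
        return sorted(i for i, l in self.mapping.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"individual": i, "lineage": l, "admixed": False}
            for i, l in sorted(self.mapping.items())
        ]
        rows += [
            {"individual": i, "lineage": "", "admixed": True}
            for i in sorted(self.admixed)
        ]
        return pd.DataFrame(rows, columns=["individual", "lineage", "admixed"])


# -- I/O -------------------------------------------------------------------


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_genotypes(path, sep: str | None = None) -> AllozymeDataset:
    """Read a delimited genotype table.

    The header must begin ``individual,site`` with an optional ``region``
    column, followed by one column per locus.  Tokens: ``ab``, ``a/b``,
    ``a/a``; empty field = missing.  Unknown tokens raise
    :class:`GenotypeParseError` naming the row and column.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "individual" or cols[1] != "site":
        raise GenotypeParseError(
            "header must start 'individual,site[,region]' followed by loci; "
            f"got {cols[:3]}"
        )
    has_region = len(cols) > 2 and cols[2] == "region"
    loci = cols[3:] if has_region else cols[2:]
    if not loci:
        raise GenotypeParseError("no locus columns found")
    individuals = []
    genotypes: dict[tuple[str, str], object] = {}
    for row_idx, row in df.iterrows():
        ind_id = row["individual"].strip()
        if not ind_id:
            raise GenotypeParseError(f"empty individual id at row {row_idx + 2}")
        region = row["region"].strip() or None if has_region else None
        individuals.append(Individual(ind_id, row["site"].strip(), region))
        for locus in loci:
            g = _parse_token(row[locus], locus, row_idx + 2, locus)
            if g is not MISSING:
                genotypes[(ind_id, locus)] = g
    return AllozymeDataset(individuals, loci, genotypes)


def write_genotypes(dataset: AllozymeDataset, path, sep: str | None = None) -> None:
    """Write the canonical dialect: slash tokens, explicit homozygotes,
    empty field for missing."""
    path = Path(path)
    sep = _sep_for(path, sep)
    has_region = any(ind.region is not None for ind in dataset.individuals)
    header = ["individual", "site"] + (["region"] if has_region else []) + dataset.loci
    lines = [sep.join(header)]
    for ind in dataset.individuals:
        row = [ind.id, ind.site]
        if has_region:
            row.append(ind.region or "")
        for locus in dataset.loci:
            g = dataset.genotype(ind.id, locus)
            row.append("" if g is MISSING else g.token())
        lines.append(sep.join(row))
    path.write_text("\n".join(lines) + "\n")


def write_genepop(dataset: AllozymeDataset, path, title: str = "crypticlade export") -> None:
    """Export in Genepop format, one POP block per site.

    Alleles get 2-digit codes assigned per locus in sorted label order
    (01, 02, ...); missing genotypes are 0000.
    """
    path = Path(path)
    codes: dict[str, dict[str, str]] = {}
    for locus in dataset.loci:
        alleles = dataset.alleles_at(locus)
        if len(alleles) > 99:
            raise ValidationError(f"locus {locus!r} has >99 alleles")
        codes[locus] = {a: f"{i + 1:02d}" for i, a in enumerate(alleles)}
    lines = [title]
    lines.extend(dataset.loci)
    for site in dataset.sites:
        lines.append("POP")
        for ind in dataset.individuals:
            if ind.site != site:
                continue
            toks = []
            for locus in dataset.loci:
                g = dataset.genotype(ind.id, locus)
                if g is MISSING:
                    toks.append("0000")
                else:
                    toks.append(codes[locus][g.alleles[0]] + codes[locus][g.alleles[1]])
            lines.append(f"{ind.id} ,  " + " ".join(toks))
    path.write_text("\n".join(lines) + "\n")
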