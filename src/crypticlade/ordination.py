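"""Individual-level principal coordinates analysis and stepwise lineage
delineation.

The delineation protocol treats individuals, not populations, as the unit of
analysis and uses no locality information: genotypes are encoded as allele
dosages, ordinated by classical scaling (PCoA) on Euclidean distances, and a
cluster-splitting rule is applied recursively to each discovered group until
no further split is supported.  Putative admixed individuals (F1-like) are
recognised by intermediacy in ordination space combined with mixed ancestry
at diagnostic loci, and are flagged rather than assigned to a lineage.

Dosage encoding: per (locus, allele) column, a homozygote for the allele
scores 1, a heterozygote carrying it 0.5, otherwise 0, so the non-missing
dosages at a locus sum to 1.  Missing genotypes are mean-imputed per column
*within the current analysis subset*, so imputation never leaks
between-group signal into a nested analysis.  PCoA on Euclidean distances
over this encoding is equivalent to a PCA of the dosage matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from crypticlade.diagnosability import (
    FixedDiffResult,
    allele_frequencies,
    count_fixed_differences,
)
from crypticlade.genotypes import (
    MISSING,
    AllozymeDataset,
    LineageAssignment,
    ValidationError,
)

__all__ = [
    "FeatureMatrix",
    "PCoAResult",
    "SplitDecision",
    "encode_genotypes",
    "pcoa",
    "detect_split",
    "flag_admixture",
    "stepwise_delineate",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Allele-dosage encoding of a genotype dataset.

    ``values`` has individual ids as the index and (locus, allele)
    MultiIndex columns; ``imputed`` is a same-shaped boolean mask of cells
    filled with the subset column mean.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)


def encode_genotypes(dataset: AllozymeDataset) -> FeatureMatrix:
    """Encode genotypes as allele dosages with subset-mean imputation.

    Columns cover exactly the alleles observed within ``dataset`` (so a
    nested analysis recomputes its own allele universe).  Monomorphic
    columns are retained.  An individual missing at every locus cannot be
    placed and raises :class:`ValidationError`.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    ids = dataset.individual_ids
    columns: list[tuple[str, str]] = []
    for locus in dataset.loci:
        for allele in dataset.alleles_at(locus):
            columns.append((locus, allele))
    if not columns:
        raise ValidationError("no scored genotypes in dataset")
    col_index = pd.MultiIndex.from_tuples(columns, names=["locus", "allele"])
    values = np.zeros((len(ids), len(columns)))
    missing = np.zeros((len(ids), len(columns)), dtype=bool)
    col_pos = {c: k for k, c in enumerate(columns)}
    locus_cols: dict[str, list[int]] = {}
    for (locus, _), k in col_pos.items():
        locus_cols.setdefault(locus, []).append(k)
    for i, ind_id in enumerate(ids):
        any_scored = False
        for locus in dataset.loci:
            g = dataset.genotype(ind_id, locus)
            cols = locus_cols.get(locus, [])
            if g is MISSING:
                for k in cols:
                    missing[i, k] = True
                continue
            any_scored = True
            for a in g.alleles:
                values[i, col_pos[(locus, a)]] += 0.5
        if not any_scored:
            raise ValidationError(
                f"individual {ind_id!r} is missing at every locus"
            )
    # column-mean imputation over observed cells only
    for k in range(len(columns)):
        obs = ~missing[:, k]
        if missing[:, k].any():
            mean = values[obs, k].mean() if obs.any() else 0.0
            values[~obs, k] = mean
    return FeatureMatrix(
        pd.DataFrame(values, index=ids, columns=col_index),
        pd.DataFrame(missing, index=ids, columns=col_index),
    )


@dataclass
class PCoAResult:
    """Classical-scaling ordination: coordinates on axes with positive
    eigenvalues, eigenvalues sorted descending, and percent contribution of
    each retained axis relative to the positive-eigenvalue total."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_contribution: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(features: FeatureMatrix | pd.DataFrame | np.ndarray,
         ids: Sequence[str] | None = None) -> PCoAResult:
    """Principal coordinates analysis on Euclidean distances.

    Accepts a :class:`FeatureMatrix`, a DataFrame (index = ids), or a plain
    array with explicit ``ids``.  The squared-distance matrix is double-
    centred and eigendecomposed; axes with eigenvalues <= a relative
    tolerance are discarded.  Axis signs are canonicalised (the largest-
    magnitude coordinate on each axis is made positive), so the result is
    deterministic.  A degenerate input (all individuals identical) yields
    zero retained axes, not an exception.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values.to_numpy(dtype=float)
        ids = features.individual_ids
    elif isinstance(features, pd.DataFrame):
        x = features.to_numpy(dtype=float)
        ids = list(features.index)
    else:
        x = np.asarray(features, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(x.shape[0])]
        ids = list(ids)
    n = x.shape[0]
    if n < 2:
        raise ValidationError("PCoA requires at least two individuals")
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    b = d2 - d2.mean(axis=0, keepdims=True) - d2.mean(axis=1, keepdims=True) + d2.mean()
    b *= -0.5
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-12 if n else 0.0
    keep = eigvals > tol
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    # sign canonicalisation: largest-|coordinate| entry positive per axis
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    total = eigvals.sum()
    percent = 100.0 * eigvals / total if total > 0 else np.zeros(0)
    return PCoAResult(
        pd.DataFrame(
            coords, index=ids, columns=[f"axis{k + 1}" for k in range(coords.shape[1])]
        ),
        eigvals,
        percent,
    )


@dataclass
class SplitDecision:
    """Outcome of the cluster-splitting rule on one ordination.

    ``children`` are disjoint member-id lists (empty when the split is
    rejected); ``gap`` is the smallest between-cluster single-link distance
    on the first two axes and ``within`` the median within-cluster nearest-
    neighbour distance.  ``absorbed`` lists individuals that did not belong
    to any size-floor cluster (isolated or intermediate points folded into
    the nearest child) — the candidate pool for admixture flagging.
    """

    parent: str
    children: list[list[str]] = field(default_factory=list)
    gap: float = float("nan")
    within: float = float("nan")
    accepted: bool = False
    absorbed: list[str] = field(default_factory=list)
    admixed: list[str] = field(default_factory=list)

    @property
    def n_children(self) -> int:
        return len(self.children)


def detect_split(
    result: PCoAResult,
    gap_factor: float = 3.0,
    min_cluster: int = 4,
    jump_factor: float = 1.7,
    parent: str = "root",
) -> SplitDecision:
    """Apply the gap rule to the first two ordination axes.

    Single-linkage clustering is run on the (at most) first two axes.  For
    each candidate number of clusters ``k`` the dendrogram is cut with the
    maxclust criterion; clusters below the ``min_cluster`` size floor are
    set aside, and the candidate is accepted iff

    * at least two clusters reach the size floor,
    * the smallest between-cluster single-link distance among them (the
      gap) exceeds ``gap_factor`` times the median within-cluster
      nearest-neighbour distance, and
    * every retained cluster is internally coherent: the gap also exceeds
      ``jump_factor`` times the largest single-link merge height *inside*
      any retained cluster.  This is the automated analogue of the by-eye
      judgement that a scatterplot shows discrete clusters rather than one
      continuous cloud, and it is what keeps a single panmictic sample
      from being shaved into spurious edge clumps.

    Among accepted candidates the one with the largest gap-to-coherence
    ratio wins.  Members of sub-threshold clusters (isolated or
    intermediate individuals — e.g. F1 hybrids that single linkage chains
    off on their own) are absorbed into the nearest qualifying cluster and
    recorded as ``absorbed``; the admixture gate downstream decides
    whether they are flagged.  Never raises on structureless data —
    returns ``accepted=False``.
    """
    if result.n_axes < 1:
        return SplitDecision(parent=parent)
    ids = list(result.coordinates.index)
    order = np.argsort(np.asarray(ids, dtype=object))
    ids = [ids[i] for i in order]
    x = result.coordinates.to_numpy()[order, : min(2, result.n_axes)]
    n = len(ids)
    if n < 2 * min_cluster:
        return SplitDecision(parent=parent)
    dvec = pdist(x)
    dmat = squareform(dvec)
    z = linkage(dvec, method="single")
    best = None
    best_score = -np.inf
    for k in range(2, n // min_cluster + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        uniq = np.unique(labels)
        if len(uniq) != k:
            continue
        big = [u for u in uniq if (labels == u).sum() >= min_cluster]
        if len(big) < 2:
            continue
        members = {u: np.where(labels == u)[0] for u in big}
        gap = np.inf
        for a in range(len(big)):
            for b in range(a + 1, len(big)):
                cross = dmat[np.ix_(members[big[a]], members[big[b]])]
                gap = min(gap, float(cross.min()))
        nn = []
        max_link = 0.0
        for u in big:
            idx = members[u]
            sub = dmat[np.ix_(idx, idx)].copy()
            if len(idx) > 1:
                max_link = max(
                    max_link,
                    float(linkage(squareform(sub), method="single")[:, 2].max()),
                )
            np.fill_diagonal(sub, np.inf)
            nn.extend(sub.min(axis=1))
        nn = np.asarray(nn)
        within = float(np.median(nn))
        if within == 0.0:
            positive = nn[np.isfinite(nn) & (nn > 0)]
            within = float(np.median(positive)) if positive.size else 0.0
        if within > 0.0 and gap <= gap_factor * within:
            continue
        if within == 0.0 and gap <= 0.0:
            continue
        if max_link > 0.0:
            score = gap / max_link
            if score <= jump_factor:
                continue
        else:
            score = np.inf if gap > 0 else 0.0
            if score == 0.0:
                continue
        if score <= best_score:
            continue
        # absorb sub-threshold clusters into the nearest qualifying one
        assigned = {u: list(members[u]) for u in big}
        absorbed: list[str] = []
        for u in uniq:
            if u in big:
                continue
            for i in np.where(labels == u)[0]:
                nearest = min(
                    big, key=lambda v: float(dmat[i, members[v]].min())
                )
                assigned[nearest].append(i)
                absorbed.append(ids[i])
        children = [sorted(ids[i] for i in idx) for idx in assigned.values()]
        children.sort(key=lambda m: (-len(m), m[0]))
        best = SplitDecision(
            parent=parent, children=children, gap=gap, within=within,
            accepted=True, absorbed=sorted(absorbed),
        )
        best_score = score
    if best is not None:
        return best
    return SplitDecision(parent=parent)


def _separating_axis(
    result: PCoAResult, members_a: Sequence[str], members_b: Sequence[str]
) -> pd.Series:
    """Of the first two axes, the one with the larger standardised
    separation between the two member sets."""
    coords = result.coordinates
    best_axis, best_sep = 0, -np.inf
    for k in range(min(2, result.n_axes)):
        va = coords.loc[list(members_a)].iloc[:, k].to_numpy()
        vb = coords.loc[list(members_b)].iloc[:, k].to_numpy()
        spread = va.std() + vb.std() + 1e-12
        sep = abs(va.mean() - vb.mean()) / spread
        if sep > best_sep:
            best_axis, best_sep = k, sep
    return coords.iloc[:, best_axis]


def _strictly_between(
    axis: pd.Series,
    pos: float,
    core_a: Sequence[str],
    core_b: Sequence[str],
) -> bool:
    """Whether ``pos`` lies strictly between the convex ranges of the two
    core member sets on ``axis``."""
    ra = axis.loc[list(core_a)]
    rb = axis.loc[list(core_b)]
    if float(ra.max()) <= float(rb.max()):
        return float(ra.max()) < pos < float(rb.min())
    return float(rb.max()) < pos < float(ra.min())


def flag_admixture(
    dataset: AllozymeDataset,
    result: PCoAResult,
    split: SplitDecision,
    diagnostics: FixedDiffResult | None = None,
    pair: tuple[int, int] = (0, 1),
    min_fraction: float = 0.5,
    tolerance: float = 0.10,
    tolerance_mode: str = "max",
) -> list[str]:
    """Flag putative admixed (F1-like) individuals after an accepted split.

    Candidates are the individuals the split decision *absorbed* — members
    of sub-threshold single-linkage components, i.e. the points that did
    not cohere with any cluster core.  For the two child clusters named by
    ``pair`` (default: the two largest), a candidate is flagged iff (a) its
    position on the axis separating the pair lies strictly between the
    convex ranges of the two cluster cores (members minus absorbed), and
    (b) it carries private alleles of *both* clusters at >=
    ``min_fraction`` of its scoreable diagnostic loci.  ``diagnostics``
    supplies the diagnostic-locus set; when omitted it is computed here
    between the two cores, so that intermediates cannot mask the very loci
    that betray them.  Individuals with every diagnostic locus missing are
    never flagged (logged as unscoreable).
    """
    if not split.accepted or len(split.children) < 2 or not split.absorbed:
        return []
    i, j = pair
    big_a, big_b = split.children[i], split.children[j]
    absorbed = set(split.absorbed)
    core_a = [m for m in big_a if m not in absorbed]
    core_b = [m for m in big_b if m not in absorbed]
    if not core_a or not core_b:
        return []
    axis = _separating_axis(result, core_a, core_b)
    # only absorbed members folded into one of *this* pair's children are
    # candidates: a straggler of a third cluster can project between the
    # pair's cores without being intermediate between them
    candidates = {
        c
        for c in absorbed
        if (c in set(big_a) or c in set(big_b))
        and _strictly_between(axis, float(axis.loc[c]), core_a, core_b)
    }
    if not candidates:
        return []
    table = allele_frequencies(
        dataset,
        {**{m: "A" for m in core_a}, **{m: "B" for m in core_b}},
    )
    if diagnostics is None:
        diagnostics = count_fixed_differences(
            table, "A", "B", tolerance=tolerance, mode=tolerance_mode
        )
    priv: dict[str, tuple[set[str], set[str]]] = {}
    for locus in diagnostics.diagnostic_loci:
        fa = set(table.frequencies("A", locus))
        fb = set(table.frequencies("B", locus))
        priv[locus] = (fa - fb, fb - fa)
    if not priv:
        logger.debug(
            "no diagnostic loci between child cores %d/%d of %s; "
            "admixture criterion unscoreable",
            i,
            j,
            split.parent,
        )
        return []
    flagged = []
    for ind_id in sorted(candidates):
        scoreable = 0
        both = 0
        for locus, (pa, pb) in priv.items():
            g = dataset.genotype(ind_id, locus)
            if g is MISSING:
                continue
            scoreable += 1
            alleles = set(g.alleles)
            if alleles & pa and alleles & pb:
                both += 1
        if scoreable == 0:
            logger.warning(
                "admixture criterion unscoreable for %s: all %d diagnostic "
                "loci missing",
                ind_id,
                len(priv),
            )
            continue
        if both / scoreable >= min_fraction:
            flagged.append(ind_id)
    return flagged


def _corroborate_children(
    group: AllozymeDataset,
    split: SplitDecision,
    tolerance: float,
    tolerance_mode: str,
    min_diagnostic_loci: int,
) -> list[list[str]]:
    """Merge child clusters whose cores are not diagnosably different.

    Returns the (possibly merged) child member lists, largest first.
    Merging is transitive: if A-B and B-C are each uncorroborated, all
    three become one child.
    """
    absorbed = set(split.absorbed)
    cores = [[m for m in c if m not in absorbed] for c in split.children]
    k = len(cores)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(k):
        for b in range(a + 1, k):
            if not cores[a] or not cores[b]:
                count = 0
            else:
                table = allele_frequencies(
                    group,
                    {**{m: "A" for m in cores[a]}, **{m: "B" for m in cores[b]}},
                )
                count = count_fixed_differences(
                    table, "A", "B", tolerance=tolerance, mode=tolerance_mode
                ).count
            if count < min_diagnostic_loci:
                parent[find(a)] = find(b)
    merged: dict[int, list[str]] = {}
    for a in range(k):
        merged.setdefault(find(a), []).extend(split.children[a])
    children = [sorted(c) for c in merged.values()]
    children.sort(key=lambda m: (-len(m), m[0]))
    return children


def stepwise_delineate(
    dataset: AllozymeDataset,
    gap_factor: float = 3.0,
    min_cluster: int = 4,
    tolerance: float = 0.10,
    tolerance_mode: str = "max",
    min_diagnostic_loci: int = 1,
    pins: Mapping[str, str] | None = None,
) -> LineageAssignment:
    """Recursive lineage delineation: encode, ordinate, split, repeat.

    Starting from the full dataset, each current group is re-encoded (its
    own allele universe and imputation), ordinated by PCoA, and tested with
    the gap rule.  An accepted geometric split is then *corroborated* by
    the genotypes: any pair of child clusters whose cores share fewer than
    ``min_diagnostic_loci`` diagnostic loci (at the given tolerance) is
    merged back together — ordination clusters are only recognised as
    lineages when the markers diagnose them, which protects against the
    apparent gaps that discrete multi-locus genotypes can produce by
    chance.  Admixed individuals are flagged per child pair, excluded from
    child membership, and the recursion continues on each child.  Groups
    for which no split survives become the final lineages, labelled
    hierarchically ("L", "L1", "L1.2", ...).

    ``pins`` maps individual ids to fixed lineage labels applied after
    delineation (manual overrides); a pinned individual is never reported
    admixed.
    """
    if len(dataset) == 0:
        raise ValidationError("empty dataset")
    provenance: list[dict] = []
    mapping: dict[str, str] = {}
    admixed: set[str] = set()

    def recurse(ids: list[str], label: str) -> None:
        group = dataset.subset(individuals=ids)
        step: dict = {"group": label, "n": len(ids)}
        if len(ids) < 2:
            step["action"] = "leaf (too small to ordinate)"
            provenance.append(step)
            for i in ids:
                mapping[i] = label
            return
        features = encode_genotypes(group)
        result = pcoa(features)
        step["n_axes"] = int(result.n_axes)
        step["percent_contribution"] = [
            round(float(p), 4) for p in result.percent_contribution[:2]
        ]
        split = detect_split(
            result, gap_factor=gap_factor, min_cluster=min_cluster, parent=label
        )
        if split.accepted and min_diagnostic_loci > 0:
            merged = _corroborate_children(
                group, split, tolerance, tolerance_mode, min_diagnostic_loci
            )
            if len(merged) < 2:
                split.accepted = False
                step["action"] = "leaf (split not corroborated by markers)"
            elif len(merged) < len(split.children):
                step["merged_uncorroborated"] = (
                    f"{len(split.children)} -> {len(merged)} children"
                )
                split.children = merged
        if not split.accepted:
            step.setdefault("action", "leaf (no split accepted)")
            provenance.append(step)
            for i in ids:
                mapping[i] = label
            return
        found_admixed: list[str] = []
        for a in range(len(split.children)):
            for b in range(a + 1, len(split.children)):
                found_admixed.extend(
                    flag_admixture(
                        group,
                        result,
                        split,
                        pair=(a, b),
                        tolerance=tolerance,
                        tolerance_mode=tolerance_mode,
                    )
                )
        found_admixed = sorted(set(found_admixed))
        split.admixed = found_admixed
        admixed.update(found_admixed)
        step["action"] = "split"
        step["gap"] = float(split.gap)
        step["within"] = float(split.within)
        step["children"] = [len(c) for c in split.children]
        step["admixed"] = found_admixed
        provenance.append(step)
        for k, child in enumerate(split.children, start=1):
            child_ids = [i for i in child if i not in found_admixed]
            child_label = f"{label}{k}" if label == "L" else f"{label}.{k}"
            if child_ids:
                recurse(child_ids, child_label)

    recurse(list(dataset.individual_ids), "L")
    if pins:
        for ind_id, label in pins.items():
            if ind_id not in set(dataset.individual_ids):
                raise ValidationError(f"pinned unknown individual {ind_id!r}")
            admixed.discard(ind_id)
            mapping[ind_id] = label
            provenance.append(
                {"group": label, "action": "pinned", "individual": ind_id}
            )
    return LineageAssignment(mapping=mapping, admixed=admixed, provenance=provenance)
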