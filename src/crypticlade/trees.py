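"""Neighbour-joining tree construction and newick serialisation.

The NJ implementation follows the Saitou-Nei agglomeration with the standard
Q-criterion.  Two conventions are fixed for determinism and hygiene:

* ties in Q are broken by the lexicographically smallest label pair (an
  internal node is identified by the smallest leaf label beneath it);
* a negative branch length arising at a join is clamped to zero and the
  deficit transferred to its sibling so the joined pair's distance is
  preserved; the raw (unclamped) lengths are kept as node annotations.

Trees are returned as unrooted :class:`dendropy.Tree` objects (trifurcating
seed node).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]

_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}/\\,;:=*'\"`<>]+$")


class DistanceMatrix:
    """A labelled, symmetric, zero-diagonal distance matrix.

    ``values`` may contain NaN for undefined pairs (e.g. sequence pairs with
    no comparable sites); consumers decide whether to reject them.  ``+inf``
    entries are allowed here (Nei's D between fully fixed groups) but are
    rejected by :func:`neighbor_joining`.
    """

    def __init__(self, labels: Sequence[str], values, source: str = ""):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(values - values.T)) if len(labels) else 0.0
        if asym > 1e-12:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
        if np.any(np.diagonal(values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        finite = values[np.isfinite(values)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative distances not allowed")
        self.labels = labels
        self.values = values
        self.source = source

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    # -- I/O: labelled TSV and PHYLIP square ------------------------------

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy(), source)

    def to_phylip(self, path) -> None:
        lines = [f"    {len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{v:.6f}" for v in self.values[i])
            lines.append(f"{label:<10s} {row}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_phylip(cls, path, source: str = "") -> "DistanceMatrix":
        lines = Path(path).read_text().strip().splitlines()
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1 : n + 1]])
        return cls(labels, np.array(rows), source)


class _Node:
    __slots__ = ("node", "key")

    def __init__(self, node: dendropy.Node, key: str):
        self.node = node  # dendropy node being grown
        self.key = key  # smallest leaf label beneath, for tie-breaking


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a finite distance matrix.

    Raises ``ValueError`` on fewer than three labels or any non-finite
    entry (the offending pair is named).
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbour-joining requires at least 3 labels")
    bad = np.argwhere(~np.isfinite(dm.values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite distance between {dm.labels[i]!r} and {dm.labels[j]!r}"
        )
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    active: list[_Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        active.append(_Node(node, label))
    d = {frozenset((a.key, b.key)): dm[(a.key, b.key)]
         for i, a in enumerate(active) for b in active[i + 1:]}

    def dist(a: _Node, b: _Node) -> float:
        return d[frozenset((a.key, b.key))]

    def set_len(nd: _Node, length: float, raw: float) -> None:
        nd.node.edge.length = length
        nd.node.annotations.add_new("raw_length", f"{raw:.12g}")

    while len(active) > 3:
        r = len(active)
        rowsum = {a.key: sum(dist(a, b) for b in active if b is not a)
                  for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * dist(a, b) - rowsum[a.key] - rowsum[b.key]
                pair_key = tuple(sorted((a.key, b.key)))
                cand = (q, pair_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, a, b = best
        dab = dist(a, b)
        raw_a = 0.5 * dab + (rowsum[a.key] - rowsum[b.key]) / (2 * (r - 2))
        raw_b = dab - raw_a
        la, lb = raw_a, raw_b
        if la < 0:
            lb += la
            la = 0.0
        elif lb < 0:
            la += lb
            lb = 0.0
        lb = max(lb, 0.0)
        parent = dendropy.Node()
        parent.add_child(a.node)
        parent.add_child(b.node)
        set_len(a, la, raw_a)
        set_len(b, lb, raw_b)
        merged = _Node(parent, min(a.key, b.key))
        new_d = {}
        for c in active:
            if c is a or c is b:
                continue
            new_d[c.key] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c is not a and c is not b]
        for c in active:
            d[frozenset((merged.key, c.key))] = new_d[c.key]
        active.append(merged)

    a, b, c = sorted(active, key=lambda nd: nd.key)
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    raw = {
        a.key: 0.5 * (dab + dac - dbc),
        b.key: 0.5 * (dab + dbc - dac),
        c.key: 0.5 * (dac + dbc - dab),
    }
    center = tree.seed_node
    for nd in (a, b, c):
        center.add_child(nd.node)
        set_len(nd, max(raw[nd.key], 0.0), raw[nd.key])
    tree.is_rooted = False
    return tree


def _fmt_length(value: float, precision: int) -> str:
    s = f"{value:.{precision}f}".rstrip("0").rstrip(".")
    return s if s and s != "-0" else "0"


def _fmt_label(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: dendropy.Tree, precision: int = 6, path=None) -> str:
    """Serialise a tree to newick with branch lengths.

    Labels containing whitespace or newick metacharacters are single-quoted
    (internal quotes doubled).  If ``path`` is given the string is also
    written there.
    """

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            body = _fmt_label(node.taxon.label if node.taxon else node.label or "")
        else:
            body = "(" + ",".join(render(ch) for ch in node.child_nodes()) + ")"
        if node.edge.length is not None:
            body += ":" + _fmt_length(node.edge.length, precision)
        return body

    text = render(tree.seed_node) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick string or file into an (unrooted) dendropy tree."""
    src = str(source)
    if "(" in src and ";" in src:
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    tree.is_rooted = False
    return tree
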