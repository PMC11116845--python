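"""Build a neighbour-joining tree of lineages from Nei's unbiased D.

Uses the pairwise Nei's D matrix from the previous step, writes it in
PHYLIP square format, and constructs the NJ tree, reporting whether the
deepest split separates the most diagnosably distinct lineages.
"""

from pathlib import Path

import pandas as pd

from crypticlade.trees import DistanceMatrix, neighbor_joining, write_newick

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "trees"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nei = pd.read_csv(ROOT / "diagnosability" / "nei_D.tsv", sep="\t",
                      index_col=0)
    dm = DistanceMatrix(list(nei.index), nei.to_numpy(), source="nei-D")
    dm.to_phylip(OUT / "nei_D.phy")
    tree = neighbor_joining(dm)
    text = write_newick(tree, path=OUT / "lineages_nj.nwk")
    print(f"NJ tree over {len(dm)} lineages from Nei's D: {text}")
    lengths = {
        leaf.taxon.label: round(leaf.edge.length, 4)
        for leaf in tree.leaf_node_iter()
    }
    print(f"terminal branch lengths: {lengths}")


if __name__ == "__main__":
    main()
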