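"""Classify indicators by the similarity of their mutual-prediction matrices.

Euclidean distances between the flattened matrices feed Ward clustering;
SIMPROF (alpha = 0.01, 999 permutations) decides which splits are
significant.  Indicators landing in one cluster respond to environmental
change with the same dynamics — they track the same dimension of
biodiversity.
"""

import argparse
from pathlib import Path

import pandas as pd
from scipy.spatial.distance import squareform

from divdyn import io
from divdyn.cluster import classify_indicators, to_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrices", type=Path, default=Path("results/matrices"))
    ap.add_argument("--alpha", type=float, default=0.01)
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    mats = {
        p.stem: io.read_matrix(p).to_numpy() for p in sorted(args.matrices.glob("*.csv"))
    }
    result = classify_indicators(mats, alpha=args.alpha, n_perm=args.n_perm, seed=args.seed)

    args.out.mkdir(parents=True, exist_ok=True)
    dist = pd.DataFrame(
        squareform(result.distances), index=result.names, columns=result.names
    )
    dist.to_csv(args.out / "distances.csv", index_label="indicator")
    (args.out / "dendrogram.nwk").write_text(to_newick(result.linkage, result.names))
    result.labels.rename("cluster").to_csv(args.out / "clusters.csv", index_label="indicator")
    result.node_pvalues.to_csv(args.out / "simprof_nodes.csv", index_label="node")

    print(f"{result.n_clusters} significant clusters (alpha={args.alpha}):")
    for cid in sorted(result.labels.unique()):
        members = ", ".join(result.labels.index[result.labels == cid])
        print(f"  cluster {cid}: {members}")


if __name__ == "__main__":
    main()
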