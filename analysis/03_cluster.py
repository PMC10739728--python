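"""Cluster and embed the reference-tissue cells; compare with ground truth.

Runs PCA (15 PCs) + SNN-Leiden (resolution 0.8) + UMAP on the reference
tissue and reports the adjusted Rand index against the simulated
subpopulations plus each cluster's majority subpopulation.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import OUTDIR, get_config

from inktmap.cli import run_pipeline


def main() -> None:
    report = run_pipeline(get_config(), OUTDIR, stages=["cluster"])
    print("clustering:", report["stages"]["cluster"])
    emb = pd.read_csv(OUTDIR / "cluster" / "embedding.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(OUTDIR / "data" / "truth_cells.tsv", sep="\t", index_col=0)
    sub = truth.loc[emb.index, "subpop"]
    ari = adjusted_rand_score(sub, emb["cluster"])
    print(f"ARI vs simulated subpopulations: {ari:.3f}")
    comp = pd.crosstab(emb["cluster"], sub)
    print("\ncluster x true-subpopulation composition:")
    print(comp.to_string())
    comp.to_csv(OUTDIR / "cluster" / "cluster_vs_truth.tsv", sep="\t")


if __name__ == "__main__":
    main()
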