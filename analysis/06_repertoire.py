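"""Paired-chain TCR repertoire analytics per reference cluster.

Reports normalized Shannon diversity and richness per cluster, the pairwise
clonotype-overlap matrices (the engineered sharing between the U-like and
S-like clusters should surface here), and the CDR3beta spectratype.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import OUTDIR, get_config

from inktmap.cli import run_pipeline


def main() -> None:
    report = run_pipeline(get_config(), OUTDIR, stages=["repertoire"])
    print("repertoire:", report["stages"]["repertoire"])
    rdir = OUTDIR / "repertoire"
    print("\nper-cluster diversity:")
    print(pd.read_csv(rdir / "diversity.tsv", sep="\t", index_col=0).round(3))
    print("\nshared clonotype counts:")
    print(pd.read_csv(rdir / "overlap_shared.tsv", sep="\t", index_col=0))
    print("\nJaccard overlap:")
    print(pd.read_csv(rdir / "overlap_jaccard.tsv", sep="\t", index_col=0).round(3))
    hist = pd.read_csv(rdir / "cdr3_length_hist.tsv", sep="\t", index_col=0)
    print("\nCDR3beta length histogram (cluster 0):")
    print(hist.T.to_string())


if __name__ == "__main__":
    main()
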