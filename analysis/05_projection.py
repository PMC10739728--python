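"""Project query-tissue cells onto the reference atlas; mapping ratios.

Query (T1) cells lack the reference-specific subpopulation S, so their
mapping ratio onto the S-like cluster should be near zero while the shared
subpopulations absorb nearly all of them.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import OUTDIR, get_config

from inktmap.cli import run_pipeline


def main() -> None:
    report = run_pipeline(get_config(), OUTDIR, stages=["project"])
    print("projection:", report["stages"]["project"])
    ratios = pd.read_csv(OUTDIR / "project" / "mapping_ratio.tsv", sep="\t",
                         index_col=0)
    comp = pd.read_csv(OUTDIR / "cluster" / "cluster_vs_truth.tsv", sep="\t",
                       index_col=0)
    majority = comp.idxmax(axis=1)
    ratios.columns = [
        f"{c} ({majority[int(c.replace('cluster', ''))]})" for c in ratios.columns
    ]
    print("\nmapping ratio of query cells onto reference clusters "
          "(majority subpopulation in parentheses):")
    print(ratios.round(3).to_string())


if __name__ == "__main__":
    main()
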