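"""Infer the MST cluster lineage and per-cell pseudotime; write the report.

The lineage starts at cluster 0 (the largest, shared-subpopulation cluster,
playing the role of the universal iNKT1 pool); pseudotime orders cells along
the centroid path in the UMAP embedding.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import OUTDIR, get_config

from inktmap.cli import run_pipeline


def main() -> None:
    report = run_pipeline(get_config(), OUTDIR, stages=["lineage", "report"])
    print("lineage:", report["stages"]["lineage"])
    graph = json.loads((OUTDIR / "lineage" / "lineage.json").read_text())
    print("start cluster:", graph["start"], "| edges:",
          [(a, b, round(d, 2)) for a, b, d in graph["edges"]])
    print("lineages:", graph["lineages"])
    pt = pd.read_csv(OUTDIR / "lineage" / "pseudotime.tsv", sep="\t")
    emb = pd.read_csv(OUTDIR / "cluster" / "embedding.tsv", sep="\t", index_col=0)
    pt = pt.set_index("barcode").join(emb["cluster"])
    print("\nmean pseudotime per cluster:")
    print(pt.groupby("cluster")["pseudotime"].mean().round(2).to_string())
    print(f"\nrun report written: {OUTDIR / 'run_report.json'} "
          f"({len(report['manifest'])} files in manifest)")


if __name__ == "__main__":
    main()
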