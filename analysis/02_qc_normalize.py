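"""QC-filter the cohort, compute size factors, and select HVGs.

Reports how many cells each filter removed and how many genes pass the
FDR < 0.05 biological-variability cut on the reference tissue.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import OUTDIR, get_config

from inktmap.cli import run_pipeline


def main() -> None:
    report = run_pipeline(get_config(), OUTDIR, stages=["qc", "normalize", "hvg"])
    qc = pd.read_csv(OUTDIR / "qc" / "qc_report.tsv", sep="\t", index_col=0)
    print("QC:", report["stages"]["qc"])
    print("exclusion reasons:")
    print(qc.loc[~qc["kept"], "reason"].value_counts().to_string())
    sf = pd.read_csv(OUTDIR / "normalize" / "size_factors.tsv", sep="\t")
    print(f"\nsize factors: mean={sf['size_factor'].mean():.4f} "
          f"(range {sf['size_factor'].min():.2f}-{sf['size_factor'].max():.2f})")
    hvg = pd.read_csv(OUTDIR / "hvg" / "hvg_table.tsv", sep="\t", index_col=0)
    print(f"HVGs selected (reference tissue): {int(hvg['selected'].sum())} "
          f"of {len(hvg)} genes")


if __name__ == "__main__":
    main()
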