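"""Shared configuration of the synthetic demonstration study.

Two tissues: T0 (the adipose-like reference, carrying a tissue-specific
subpopulation S alongside shared U and P17) and T1 (query, carrying U, P17
and its own specific subpopulation X). Three clonotypes are engineered to be
shared between U and S, mimicking lineage-related subpopulations.
"""

from pathlib import Path

from inktmap.io_formats import PipelineConfig
from inktmap.synthdata import SimParams

RESULTS = Path(__file__).resolve().parent.parent / "results"
OUTDIR = RESULTS / "pipeline"

SEED = 17


def get_config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, ref_tissue="T0")


def get_sim_params() -> SimParams:
    return SimParams(
        seed=SEED,
        n_cells_per_tissue=400,
        n_genes=1200,
        marker_log2fc=3.0,
        shared_clone_spec=[("U", "S", 3)],
    )
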