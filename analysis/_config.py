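"""Shared study conditions for the numbered analysis scripts.

Every script regenerates the deterministic cohort from this seed, so the
scripts can be run independently or in order; file-based intermediates
(probe panel, SNP records, array table) are exchanged through results/.
"""

from pathlib import Path

from tetrasnp.simcore import SimConfig
from tetrasnp.workflow import WorkflowConfig

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def workflow_config(seed: int = SEED) -> WorkflowConfig:
    return WorkflowConfig(sim=SimConfig(seed=seed))


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
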