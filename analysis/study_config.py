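"""Shared study configuration for the numbered analysis drivers.

One seeded synthetic world at the study conditions: a 42x81 grid of 0.33°
cells split into two realms, 36 virtual amphibian-like species, a
high-warming control (RCP85) plus the four freshwater-hosing scenarios
(A-D: 0.11/0.22/0.34/0.68 Sv over 2020-2070), horizons 2030 and 2070,
three learners with ten subsampling runs each.
"""

from pathlib import Path

from amocrange import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "study"


def study_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        seed=seed,
        n_species=36,
        scenarios=("RCP85", "A", "B", "C", "D"),
        horizons=(2030, 2070),
        n_boot=1000,
        outdir=str(STUDY_DIR),
    )
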