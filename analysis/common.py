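"""Shared configuration for the numbered analysis drivers.

All steps read/write under results/ with a single seed, so the whole
analysis reruns deterministically end to end:

    python analysis/01_simulate_study.py
    python analysis/02_culture_kinetics.py
    python analysis/03_fit_response_models.py
    python analysis/04_optimise_process.py
    python analysis/05_compare_conditions.py
"""

from pathlib import Path

from cartdoe.io import RunConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"


def config() -> RunConfig:
    return RunConfig(
        data_dir=RESULTS / "data",
        out_dir=RESULTS,
        responses=("cpd", "fold", "pd1lag3_pct", "cd69_pct", "q_gluc",
                   "p_lac", "dlac_dgluc"),
        goals={"cpd": "maximize", "pd1lag3_pct": "minimize"},
        seed=42,
    )
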