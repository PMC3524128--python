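"""Shared run configuration for the numbered analysis drivers.

All drivers operate on one file-based run directory under results/run so
each step can be re-executed independently from the previous step's tables.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"

CONFIG = {
    "seed": 20,
    # study-like defaults: 128 gene windows, 200 bp tiling, 96 samples
    "simulate": {},
    "segmentation": {},
    "calling": {},
}


def run_stage(stage: str) -> None:
    from microcna.pipeline import run_pipeline

    cfg = {**CONFIG, "stages": [stage]}
    clinical = RUN_DIR / "clinical.tsv"
    if stage != "simulate" and clinical.exists():
        cfg["inputs"] = {"clinical": str(clinical)}
    run_pipeline(cfg, RUN_DIR)
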