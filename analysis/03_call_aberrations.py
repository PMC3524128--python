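#!/usr/bin/env python
"""Classify aberrant segments as micro (< 64 probes) vs. macro, assign each
(gene, sample) a copy-number status, and summarise micro burden by intrinsic
subtype."""

import pandas as pd

from _common import RUN_DIR, run_stage

run_stage("call")

micros = pd.read_csv(RUN_DIR / "micro_aberrations.tsv", sep="\t")
print(f"{len(micros)} micro-aberration instances "
      f"({(micros.Kind == 'micro-amp').sum()} amplifications, "
      f"{(micros.Kind == 'micro-del').sum()} deletions)")
print("\nburden by subtype (mean / median micro per sample, % with any):")
print(pd.read_csv(RUN_DIR / "subtype_summary.tsv", sep="\t").to_string(index=False))
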