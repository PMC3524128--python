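#!/usr/bin/env python
"""Test whether copy-number status shows in expression: per-gene concordance
rates, pooled 2x2 Fisher exact tests, and per-gene ANOVA of aberrant vs.
non-aberrant samples."""

import pandas as pd

from _common import RUN_DIR, run_stage

run_stage("integrate")

conc = pd.read_csv(RUN_DIR / "concordance.tsv", sep="\t")
print("per-gene concordance by aberration class:")
print(conc.to_string(index=False))

cont = pd.read_csv(RUN_DIR / "contingency.tsv", sep="\t")
print("\npooled expression-by-aberration tables (Fisher exact):")
print(cont.to_string(index=False))

anova = pd.read_csv(RUN_DIR / "anova.tsv", sep="\t")
sig = anova[(anova["p"] < 0.05) & anova["p"].notna()]
print(f"\n{len(sig)} of {anova['p'].notna().sum()} testable genes show differential "
      f"expression between aberrant and non-aberrant samples (ANOVA p < 0.05)")
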