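#!/usr/bin/env python
"""Compare observed per-gene micro-aberration counts to the scan-statistic
chance expectation built from the pooled log-ratio distribution (with gene-
size correction); Poisson-exact p-values per gene."""

import pandas as pd

from _common import RUN_DIR, run_stage

run_stage("chance")

tab = pd.read_csv(RUN_DIR / "chance_table.tsv", sep="\t")
print("top 10 most micro-aberrant genes vs. chance expectation:")
cols = ["gene", "observed_all", "observed_amp", "observed_del", "expected", "p_display"]
print(tab[cols].head(10).to_string(index=False))
print(f"\npooled exceedance probability P(|log2| > 0.30) = {tab['p_exceed'].iloc[0]:.4f}")
print(f"all expected-by-chance counts < {tab['expected'].max():.2g} — observed recurrence "
      f"is far beyond the independent-probe null")
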