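#!/usr/bin/env python
"""Stratify samples into the top 67% vs. bottom 33% by micro-aberration
burden and compare Kaplan-Meier curves (overall and relapse-free survival)
with a log-rank test."""

import pandas as pd

from _common import RUN_DIR, run_stage

run_stage("survive")

res = pd.read_csv(RUN_DIR / "survival.tsv", sep="\t")
print(res.to_string(index=False))
for _, row in res.iterrows():
    verdict = "separates" if row["logrank_p"] < 0.05 else "does not separate"
    print(f"{row['endpoint']}: high-burden group (n={row['n_high']:.0f}) {verdict} "
      f"from low-burden (n={row['n_low']:.0f}); log-rank p = {row['logrank_p']:.3g}")
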