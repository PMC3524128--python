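#!/usr/bin/env python
"""Segment every (gene, sample) probe profile into constant-mean segments
and write the SEG table. Aberrant segments are those with |mean log2| > 0.30."""

import pandas as pd

from _common import RUN_DIR, run_stage

run_stage("segment")

segs = pd.read_csv(RUN_DIR / "segments.seg", sep="\t")
aberrant = segs[segs["Segment_Mean"].abs() > 0.30]
print(f"{len(segs)} segments across {segs['Sample'].nunique()} samples")
print(f"{len(aberrant)} aberrant segments (|mean log2| > 0.30); "
      f"median size {int(aberrant['Num_Probes'].median())} probes")
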