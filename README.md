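# microcna

Micro-aberration analysis for high-density tiling array CGH (aCGH) data.

Gene-centric tiling arrays (one probe every ~200 bp across each gene ± flanks)
resolve somatic copy-number changes far below the scale that genome-wide SNP
platforms can call. At that resolution, tumors carry **micro-aberrations**:
amplifications and deletions spanning fewer than 64 contiguous probes
(~≤15 kb), often confined to a single gene region. This package implements the
full analysis chain for such data, aimed at cancer-genomics analysts working
with probe-level log2 tumor/reference ratios:

1. **Segmentation** — each per-gene, per-sample ordered probe profile is
   partitioned into constant-mean segments by recursive binary splitting on a
   Welch-style change-point statistic, plus a CBS-style interval scan that
   isolates short events strictly interior to a long run. Segments with
   |mean log2| > 0.30 are called aberrant.
2. **Micro/macro calling** — aberrant segments with fewer than 64 probes
   (strict; equivalently the smallest-25% cohort quantile, which is also
   available as a mode) are micro-amplifications/micro-deletions; the rest are
   gross gains/losses. Each (gene, sample) receives a single copy-number
   status.
3. **Positional analysis** — each gene window is split into four equal
   quadrants (5′End, 5′Mid, 3′Mid, 3′End, oriented by strand) and every micro
   instance is tallied against the quadrants, the promoter (upstream of the
   TSS) and the 5′UTR.
4. **Expression integration** — per-gene concordance (amplification with
   above-median expression, deletion with below-median), pooled 2×2 tables
   tested with a two-sided Fisher exact test, and per-gene ANOVA of aberrant
   vs. non-aberrant samples.
5. **Chance model** — the expected number of micro-aberrations per gene under
   an independent-probe null built from the pooled empirical log-ratio
   distribution, with gene-size correction:
   E[micro] = N · Σ_{r=m}^{M−1} [(n−r−1) p^r (1−p)² + 2 p^r (1−p)],
   where p = P(|log2| > 0.30), n = probes in the gene, r ranges over callable
   micro lengths and N is the cohort size; observed counts get exact Poisson
   tail p-values (a chi-square mode is provided for display parity with the
   classical test).
6. **Survival** — samples ranked by micro burden are split top 67% vs. bottom
   33% and compared with Kaplan–Meier curves and a log-rank test.

A first-class synthetic-cohort generator (`microcna.synthetic_cohort`)
emulates the array design and cohort structure — implanted macro and micro
events with recorded ground truth, expression statistically coupled to copy
number, subtype labels, censored survival — so every stage is testable
against known truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (128 gene windows, 96 samples, seed 20), writing tables under
`results/run/`:

```sh
cd analysis
python 01_simulate_cohort.py   # cohort + ground truth
python 02_segment_profiles.py  # SEG table
python 03_call_aberrations.py  # micro/macro calls, status matrix
python 04_positional_bias.py   # quadrant occupancy
python 05_expression_integration.py
python 06_chance_model.py
python 07_survival_by_burden.py
```

Step 03 prints, for that seed:

```
336 micro-aberration instances (156 amplifications, 180 deletions)

burden by subtype (mean / median micro per sample, % with any):
      subtype  n_samples  mean_micro  median_micro  pct_with_micro
   Basal-like         29      3.5172           3.0        100.0000
HER2-enriched          6      4.3333           4.5        100.0000
    Luminal A         25      3.0800           3.0         96.0000
    Luminal B         30      3.6333           4.0         96.6667
  Normal-like          6      3.6667           3.0        100.0000
```

i.e. of 521 implanted events, 336 called micro instances (~3.5 per sample)
with burden broken down by intrinsic subtype. Step 06 then shows every
gene's expected-by-chance count is < 0.05 events while the most recurrent
gene carries 7 observed micro-aberrations (Poisson p < .001): observed
recurrence is far beyond the independent-probe null. Step 07 reports the
high-burden group separating in relapse-free survival (log-rank p ≈ 0.001).

The same pipeline is scriptable as a CLI over file-based stages:

```sh
microcna run --config config.yaml --seed 20 --outdir run/
microcna report --outdir run/
```

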