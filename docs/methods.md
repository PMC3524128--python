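# Methods

## Data model and coordinates

The unit of analysis is the **gene window**: a gene's genomic span padded by
5 kb on each side (`pad_bp`, configurable). Probes (midpoint coordinates)
belong to exactly one window; analysis never crosses window boundaries, so no
cross-gene segments can arise. Internally all intervals are 0-based half-open;
every on-disk table (gene windows, probe matrices, SEG, clinical) is 1-based
inclusive, matching the convention of the gene-annotation tables such data
ship with. The conversion happens exactly once at I/O time, and round-trips
are the identity.

On the − strand the TSS is the right edge of the gene span (the coordinate
one past the last transcribed base, consistent with half-open spans), and all
5′/3′ labels follow the biological orientation.

Expression matrices pass a presence filter before integration: a gene row
survives only if at least 70% of samples have present values (and, when
two-channel intensities are supplied, both channels ≥ 10). The filter is
idempotent and preserves row order.

## Segmentation

Each (gene, sample) ordered probe run is segmented by recursive splitting.
At every recursion level two candidate moves are scored:

* **single split** — the index maximising the Welch-style two-sample
  statistic |x̄_L − x̄_R| / √(s²_L/n_L + s²_R/n_R) over all admissible split
  points (≥ `min_probes` = 5 probes per side), accepted when the statistic
  reaches `split_stat_threshold` = 4.0;
* **interval scan** — the best interior interval of length `min_probes` …
  `interval_scan_max` (96) against the rest of the run, scored with a
  pooled-variance two-sample t statistic and accepted at
  `interval_stat_threshold` = 6.0.

The better accepted move is applied and recursion continues (depth cap 20).
Adjacent segments whose means differ by less than half the aberration
threshold are then merged, and each segment is called gain/loss/neutral by a
strict |mean log2| > 0.30 rule (boundary equality is neutral, applied
post-merge).

Two numerical points deserve explanation. The interval scan exists because a
single split cannot isolate a short event strictly interior to a long run:
the event barely moves either side's mean, so the split statistic stays at
noise level no matter how strong the event is. Scanning intervals directly
(the move circular binary segmentation makes) fixes this. Second, the
interval scan uses a **pooled** variance (n − 2 df, estimated from the whole
run) rather than per-side variances: with 5-probe intervals a per-side
estimate has heavy t-like small-sample tails, and maximising it over the
~n × 90 candidate intervals of every profile shatters long uniform shifts
into spurious fragments. With the pooled estimate the null maximum behaves
like a Gaussian extreme, about √(2 ln(n·L)) ≈ 4.7 for a 500-probe window, so
the acceptance threshold 6.0 sits above the null maximum while the weakest
real event under the cohort's conditions (a 5-probe event at ±0.6 against
noise SD 0.15) scores ≈ 9. Ties break toward the leftmost split and the
shortest-then-leftmost interval, making segmentation fully deterministic.

The engine sits behind `segment_gene_profile`'s contract (segments tile the
probe run; each carries a mean log2 and a call), so an alternative engine can
be plugged in without touching downstream stages. Probes missing in a sample
are removed from that sample's run before segmentation; no imputation.

## Micro-aberration definition and status

An aberrant segment is **micro** when it spans fewer than `max_probes` = 64
contiguous probes (strict; ~≤15 kb at 200 bp tiling), else macro. The
`cohort_percentile` mode instead recomputes the cutoff as the smallest
integer k for which the fraction of aberrant segments with fewer than k
probes reaches 25% — the empirical rule the fixed default descends from.
"Contiguous" counts probes inside the called segment after missing-value
removal.

Per (gene, sample), macro events take precedence for the single status
(gross-gain/gross-loss by the dominant |mean × n_probes| macro segment);
otherwise the micro event with the largest |mean| decides. Micro instances
are still counted individually for burden, positional, and per-gene tallies
regardless of the gene-level status.

## Positional analysis

Quadrants divide the analysis window (gene ± 5 kb — called segments can
extend into the pad, so the window rather than the bare gene span is the
natural support) into four equal intervals at floor offsets, the last
absorbing any remainder; labels run 5′→3′ in gene orientation. An instance
affects a quadrant when it overlaps it by ≥ 1 bp (configurable minimum). The
occupancy proportion per quadrant is affected instances over all instances.
The promoter is the window's upstream pad up to the TSS (a `cds` switch is
accepted for the alternative anchoring but resolves to the TSS when only
gene spans are annotated); the 5′UTR uses explicit coordinates when present.
The 5′-only breakdown restricts to instances overlapping the 5′End quadrant
and no other, reporting promoter/5′UTR rates among them (undefined on an
empty restriction).

## Expression integration

Expression is dichotomized per gene at the cohort median (midpoint convention
for even counts, computed over present values; genes with < 3 present values
are dropped). Exact-median ties are excluded from counts rather than
assigned — the strict above/below wording of the dichotomy implies exclusion.
Concordance pairs amplification-type status with above-median and
deletion-type with below-median expression; a gene is 100% (≥50%) concordant
for a class when all (at least half) of its class-bearing samples are
concordant. Pooled 2×2 tables count (gene, sample) pairs across all genes
without per-gene stratification. The two-sided Fisher exact test uses the
minimum-likelihood convention: the sum of hypergeometric point probabilities
≤ the observed one, with a 1e-7 relative tolerance so floating-point ties
count; any zero margin yields p = 1. Per-gene ANOVA is one-way, two-group
(equivalent to the squared pooled-variance t test); groups with fewer than
two samples return NA. No multiple-testing correction is applied across
genes — the per-gene ANOVAs are reported raw.

## Chance model

The null treats every probe as an independent draw from the pooled empirical
log-ratio distribution, with p = empirical P(|log2| > 0.30). A chance
micro-aberration is a maximal run of consecutive exceedances with length in
[`min_probes`, `max_probes`). For a Bernoulli(p) string of n probes the
expected number of maximal runs of length exactly r is
(n − r − 1)·p^r·(1 − p)² + 2·p^r·(1 − p) for r < n (boundary placements need
only one non-exceeding flank) and p^n for r = n; summing over callable r and
multiplying by the cohort size gives the per-gene expectation, the
(n − r ± 1) factors being the gene-size correction. This is exact for the
stated null (verified against direct string simulation), but the null itself
deliberately ignores spatial autocorrelation in array noise (GC waves,
segmental artifacts), so real-data expectations are, if anything,
understated.

Observed vs. expected uses an exact Poisson upper tail
P(X ≥ observed | λ = max(expected, 1e−12)) by default. A `chisq` mode
computes the classical one-cell chi-square with the same ε floor; with
expectations this close to zero that statistic is degenerate (the floor alone
decides it), which is why the exact tail is the default, and p-values below
0.001 display as "<.001".

## Survival

Samples are ranked ascending by micro burden; the lowest ⌊n × 0.33⌋ (at
least 1) form the low-burden group and the rest the high-burden group.
Samples tied at the boundary value stay together in the low group — with
small-integer burden counts this can move the realised split noticeably away
from 67/33, which is reported rather than broken arbitrarily. Kaplan–Meier
estimation and the two-group log-rank test are delegated to lifelines behind
this module's interface; hand-computed product-limit values serve as the
test oracle. Other split fractions are configurable; 67/33 is the default.

## Synthetic cohorts

The generator's defaults are the study conditions the pipeline targets:
128 gene windows (gene lengths uniform 10–100 kb, ±5 kb pads) tiled at
200 bp; 96 samples; probe noise N(0, 0.15) — giving a pooled exceedance
fraction of 2Φ(−2) ≈ 0.0455 at the 0.30 cutoff; Poisson(2.0) whole-window
macro implants and Poisson(3.5) micro implants per sample (spans uniform
1–12.6 kb, i.e. 5–63 probes) at ±0.6 log2; subtype labels drawn with the
31/27/21/10/5 frequencies of a 94-tumor cohort; expression N(0, 1) per gene
with a concordant ±3.0 shift applied with probability `expr_coupling` = 0.6;
exponential survival with hazard multiplied by 1.8 per true-burden tercile
and ~30% independent censoring. Implants within one (gene, sample) are kept
disjoint by rejection; every implant is recorded with its affected quadrants
and whether its expression was shifted. The 150 kb flanks are array real
estate the analysis windows exclude; the generator accounts for them in the
genomic layout but emits no probes there, since no stage ever reads them.
A `5prime_bias` placement mode centres micro implants in the biological 5′
quarter of the window, for exercising the positional analysis.

What the generator does **not** emulate: spatially correlated noise, dye
bias and GC waves, allele-specific or integer copy number, implant size/sign
distributions estimated from real tumors, or subtype-dependent aberration
rates. Passing recovery tests therefore demonstrates correctness of the
calling machinery under idealised noise, not expected performance on real
arrays.

All generator randomness flows through one seeded NumPy generator: identical
parameters and seed reproduce the cohort bit-identically, and the file-based
pipeline is byte-reproducible end to end (timings go to the log, never into
outputs; the manifest records digests and the seed).

## Problem sizes

Default test and driver runs use the full 128-gene × 96-sample cohort for
end-to-end recovery (a single segmentation pass of ~12,000 profiles),
50 replicates for noisy-breakpoint recovery, 10⁴ Bernoulli strings per
configuration for the chance-model oracle, and 10⁶ draws for the Gaussian
exceedance check; smaller cohorts (8–16 genes, 12–24 samples) back the
byte-determinism and I/O tests. These sizes were chosen so the whole suite
exercises every stage at study scale while remaining convenient to run
locally.

## Known limitations

* The segmentation engine is a deterministic stand-in with the downstream
  contract (segments + mean log2 + 0.30 filter); it is not a reimplementation
  of any published segmenter's internals, and its thresholds are calibrated
  to the generator's noise model.
* The chance model's independence assumption understates clustering of
  aberrant probes under correlated noise.
* The promoter is bounded by the 5 kb pad; regulatory space further upstream
  is invisible to the positional analysis.
* Quadrants cover the padded window, not the bare gene body; with the
  default 5 kb pads the 5′End quadrant therefore contains the promoter and
  typically the 5′UTR.
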