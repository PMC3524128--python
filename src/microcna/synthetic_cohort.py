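"""Synthetic tiling-aCGH cohorts with recorded ground truth.

The generator emulates the structure the analysis assumes: a gene-centric
tiling array (by default 128 gene windows at 200 bp probe spacing, gene span
padded by 5 kb), a cohort of 96 samples whose probe log2 ratios are Gaussian
noise plus implanted macro aberrations (whole-window) and micro-aberrations
(sub-15 kb spans), gene expression statistically coupled to copy-number
status, intrinsic-subtype labels, and censored exponential survival whose
hazard grows with a sample's true micro-aberration burden. Every implant is
recorded as a :class:`TruthRecord`, so recovery can be scored exactly.

All randomness flows through one ``numpy`` Generator seeded from the params,
so identical parameters reproduce a bit-identical cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    SUBTYPES,
    ClinicalRecord,
    ExpressionMatrix,
    GeneWindow,
    LogRatioMatrix,
    ProbeSet,
)

logger = logging.getLogger(__name__)

# subtype frequencies of the 94-tumor cohort the generator emulates
SUBTYPE_WEIGHTS = np.array([31, 27, 21, 10, 5], dtype=float) / 94.0


@dataclass(frozen=True)
class ArrayDesignParams:
    n_genes: int = 128
    probe_spacing_bp: int = 200
    gene_length_range: tuple[int, int] = (10_000, 100_000)
    pad_bp: int = 5000
    flank_bp: int = 150_000  # array content either side of each window; carries no probes here

    def __post_init__(self):
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be a positive interval")


@dataclass(frozen=True)
class CohortSimParams:
    n_samples: int = 96
    noise_sd: float = 0.15
    macro_rate: float = 2.0           # expected whole-window implants per sample
    micro_rate: float = 3.5           # expected micro implants per sample
    micro_span_range: tuple[int, int] = (1000, 12_600)
    amp_effect: float = 0.6
    del_effect: float = -0.6
    expr_coupling: float = 0.6        # P(an implant shifts expression concordantly)
    expr_shift_log2: float = 3.0      # magnitude of the concordant expression shift
    survival_hazard_ratio: float = 1.8  # hazard multiplier per micro-burden tercile
    censor_rate: float = 0.3
    placement: str = "uniform"        # or "5prime_bias"
    seed: int = 0

    def __post_init__(self):
        if self.macro_rate < 0 or self.micro_rate < 0:
            raise ValueError("implant rates must be >= 0")
        if not 0 <= self.expr_coupling <= 1 or not 0 <= self.censor_rate < 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.amp_effect <= 0 or self.del_effect >= 0:
            raise ValueError("amp_effect must be > 0 and del_effect < 0")
        if self.placement not in ("uniform", "5prime_bias"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    gene_symbol: str
    kind: str  # macro-gain | macro-loss | micro-amp | micro-del
    start: int
    end: int
    affected_quadrants: tuple[str, ...]
    expression_shifted: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("truth interval must be nonempty")


@dataclass
class SyntheticCohort:
    windows: list[GeneWindow]
    probes: ProbeSet
    log_ratio_matrix: LogRatioMatrix
    expression_matrix: ExpressionMatrix
    clinical: list[ClinicalRecord]
    truth: list[TruthRecord]

    @property
    def samples(self) -> list[str]:
        return self.log_ratio_matrix.samples


def design_array(params: ArrayDesignParams = ArrayDesignParams(), seed: int = 0) -> tuple[list[GeneWindow], ProbeSet]:
    """Lay out gene windows and tile each with probes at fixed spacing.

    Genes are placed across synthetic chromosomes with ``flank_bp`` of
    separation on each side (the flanks are array real estate but carry no
    analysis probes). Probe positions are window_start + k * spacing; even a
    window narrower than the spacing gets one probe.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=params.n_genes)
    strands = rng.choice(["+", "-"], size=params.n_genes)
    utr5_lens = rng.integers(100, 501, size=params.n_genes)

    windows: list[GeneWindow] = []
    probe_rows = []
    genes_per_chrom = 6
    offset = 0
    chrom_idx = 1
    placed_on_chrom = 0
    for i in range(params.n_genes):
        if placed_on_chrom == genes_per_chrom:
            chrom_idx += 1
            placed_on_chrom = 0
            offset = 0
        chrom = f"chr{chrom_idx}"
        gene_start = offset + params.flank_bp + params.pad_bp
        gene_end = gene_start + int(lengths[i])
        strand = str(strands[i])
        if strand == "+":
            utr5 = (gene_start, gene_start + int(utr5_lens[i]))
        else:
            utr5 = (gene_end - int(utr5_lens[i]), gene_end)
        w = GeneWindow.from_span(
            gene_symbol=f"GENE{i + 1:03d}",
            chrom=chrom,
            strand=strand,
            gene_start=gene_start,
            gene_end=gene_end,
            pad_bp=params.pad_bp,
            utr5_start=utr5[0],
            utr5_end=utr5[1],
        )
        windows.append(w)
        positions = np.arange(w.window_start, w.window_end, params.probe_spacing_bp, dtype=np.int64)
        if positions.size == 0:
            positions = np.array([w.window_start], dtype=np.int64)
        for k, pos in enumerate(positions):
            probe_rows.append((f"{w.gene_symbol}_p{k + 1:05d}", chrom, int(pos), w.gene_symbol))
        offset = w.window_end + params.flank_bp
        placed_on_chrom += 1

    table = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "position", "gene_symbol"])
    return windows, ProbeSet(table)


def _quadrants_hit(window: GeneWindow, start: int, end: int) -> tuple[str, ...]:
    from .positional_analysis import quadrant_bounds  # deferred: avoids import cycle

    hit = []
    for label, lo, hi in quadrant_bounds(window):
        if min(end, hi) - max(start, lo) >= 1:
            hit.append(label)
    return tuple(hit)


def _place_micro(rng, window: GeneWindow, span: int, placement: str) -> tuple[int, int]:
    ws, we = window.window_start, window.window_end
    span = min(span, we - ws)
    if placement == "5prime_bias":
        # centre the implant in the biological 5' quarter of the window
        q = (we - ws) // 4
        if window.strand == "+":
            c_lo, c_hi = ws, ws + q
        else:
            c_lo, c_hi = we - q, we
        centre = int(rng.integers(c_lo, c_hi))
        start = int(np.clip(centre - span // 2, ws, we - span))
    else:
        start = int(rng.integers(ws, we - span + 1))
    return start, start + span


def simulate_cohort(
    windows: Sequence[GeneWindow],
    probes: ProbeSet,
    params: CohortSimParams = CohortSimParams(),
) -> SyntheticCohort:
    """Simulate probe log2 ratios, expression, clinical data, and ground truth.

    Baseline probe values are N(0, noise_sd). Per sample, Poisson numbers of
    macro implants (whole analysis window) and micro implants (span drawn
    from ``micro_span_range``, placed per ``placement``) add
    ``amp_effect``/``del_effect`` to the covered probes; overlapping
    placements within one (gene, sample) are rejected and retried (logged).
    Each implant shifts the gene's expression in that sample concordantly
    with probability ``expr_coupling``. Survival is exponential with hazard
    scaled by ``survival_hazard_ratio`` per true-micro-burden tercile.
    """
    rng = np.random.default_rng(params.seed)
    windows = list(windows)
    n_genes = len(windows)
    samples = [f"S{j + 1:03d}" for j in range(params.n_samples)]
    gene_names = [w.gene_symbol for w in windows]

    probe_tab = probes.table
    gene_rows = {g: np.flatnonzero(probe_tab["gene_symbol"].to_numpy() == g) for g in gene_names}
    positions = probe_tab["position"].to_numpy()

    values = rng.normal(0.0, params.noise_sd, size=(len(probe_tab), params.n_samples))
    truth: list[TruthRecord] = []
    n_rejected = 0

    # (gene, sample) -> list of occupied intervals, to keep implants disjoint
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}

    for sj, sample in enumerate(samples):
        n_macro = rng.poisson(params.macro_rate)
        n_micro = rng.poisson(params.micro_rate)
        macro_genes = rng.choice(n_genes, size=min(n_macro, n_genes), replace=False)
        for gi in macro_genes:
            w = windows[gi]
            sign = rng.random() < 0.5
            effect = params.amp_effect if sign else params.del_effect
            kind = "macro-gain" if sign else "macro-loss"
            rows = gene_rows[w.gene_symbol]
            values[rows, sj] += effect
            occupied[(w.gene_symbol, sample)] = [(w.window_start, w.window_end)]
            truth.append(
                TruthRecord(
                    sample_id=sample,
                    gene_symbol=w.gene_symbol,
                    kind=kind,
                    start=w.window_start,
                    end=w.window_end,
                    affected_quadrants=_quadrants_hit(w, w.window_start, w.window_end),
                    expression_shifted=False,  # filled below
                )
            )
        for _ in range(n_micro):
            placed = False
            for _attempt in range(20):
                gi = int(rng.integers(n_genes))
                w = windows[gi]
                lo, hi = params.micro_span_range
                span = int(rng.integers(lo, hi + 1))
                start, end = _place_micro(rng, w, span, params.placement)
                key = (w.gene_symbol, sample)
                if any(min(end, e) - max(start, s) > 0 for s, e in occupied.get(key, [])):
                    n_rejected += 1
                    continue
                sign = rng.random() < 0.5
                effect = params.amp_effect if sign else params.del_effect
                kind = "micro-amp" if sign else "micro-del"
                rows = gene_rows[w.gene_symbol]
                in_span = (positions[rows] >= start) & (positions[rows] < end)
                values[rows[in_span], sj] += effect
                occupied.setdefault(key, []).append((start, end))
                truth.append(
                    TruthRecord(
                        sample_id=sample,
                        gene_symbol=w.gene_symbol,
                        kind=kind,
                        start=start,
                        end=end,
                        affected_quadrants=_quadrants_hit(w, start, end),
                        expression_shifted=False,
                    )
                )
                placed = True
                break
            if not placed:
                n_rejected += 1
    if n_rejected:
        logger.info("rejected %d overlapping micro placements", n_rejected)

    # expression: baseline noise plus concordant shifts for coupled implants
    expr = rng.normal(0.0, 1.0, size=(n_genes, params.n_samples))
    gene_index = {g: i for i, g in enumerate(gene_names)}
    sample_index = {s: j for j, s in enumerate(samples)}
    coupled_truth: list[TruthRecord] = []
    for rec in truth:
        coupled = bool(rng.random() < params.expr_coupling)
        if coupled:
            direction = 1.0 if rec.kind in ("macro-gain", "micro-amp") else -1.0
            expr[gene_index[rec.gene_symbol], sample_index[rec.sample_id]] += (
                direction * params.expr_shift_log2
            )
        coupled_truth.append(replace(rec, expression_shifted=coupled))
    truth = coupled_truth

    # clinical: subtype labels and burden-linked censored exponential survival
    subtype_idx = rng.choice(len(SUBTYPES), size=params.n_samples, p=SUBTYPE_WEIGHTS)
    micro_burden = np.zeros(params.n_samples, dtype=int)
    for rec in truth:
        if rec.kind.startswith("micro"):
            micro_burden[sample_index[rec.sample_id]] += 1
    terciles = np.searchsorted(
        np.quantile(micro_burden, [1 / 3, 2 / 3], method="lower"), micro_burden, side="right"
    )
    base_hazard = np.log(2) / 5.0  # median survival 5 time units at lowest burden
    clinical = []
    for j, sample in enumerate(samples):
        haz = base_hazard * params.survival_hazard_ratio ** int(terciles[j])
        rec = {}
        for endpoint, scale in (("os", 1.0), ("rfs", 1.3)):
            h = haz * scale
            t_event = rng.exponential(1.0 / h)
            if params.censor_rate > 0:
                h_cens = h * params.censor_rate / (1.0 - params.censor_rate)
                t_cens = rng.exponential(1.0 / h_cens)
            else:
                t_cens = np.inf
            rec[f"{endpoint}_time"] = float(min(t_event, t_cens))
            rec[f"{endpoint}_event"] = int(t_event <= t_cens)
        clinical.append(
            ClinicalRecord(sample_id=sample, subtype=SUBTYPES[subtype_idx[j]], **rec)
        )

    lrm_values = pd.DataFrame(values, index=pd.Index(probe_tab["probe_id"], name="probe_id"), columns=samples)
    expr_values = pd.DataFrame(expr, index=pd.Index(gene_names, name="gene"), columns=samples)
    return SyntheticCohort(
        windows=windows,
        probes=probes,
        log_ratio_matrix=LogRatioMatrix(probes=probes, values=lrm_values),
        expression_matrix=ExpressionMatrix(values=expr_values),
        clinical=clinical,
        truth=truth,
    )


def _same_sign(kind_a: str, kind_b: str) -> bool:
    pos = ("micro-amp", "macro-gain", "gain", "gross-gain")
    return (kind_a in pos) == (kind_b in pos)


def score_recovery(cohort: SyntheticCohort, micros) -> dict[str, float]:
    """Recall/precision of called micro-aberrations against implanted truth.

    A truth micro counts as recovered when some called micro in the same
    (gene, sample) overlaps it by >= 1 bp with matching sign; a called micro
    is a true positive under the symmetric rule.
    """
    truth_micro = [t for t in cohort.truth if t.kind.startswith("micro")]
    called: dict[tuple[str, str], list] = {}
    for m in micros:
        called.setdefault((m.segment.gene_symbol, m.segment.sample_id), []).append(m)
    truth_by: dict[tuple[str, str], list[TruthRecord]] = {}
    for t in truth_micro:
        truth_by.setdefault((t.gene_symbol, t.sample_id), []).append(t)

    def _hit(t, m):
        seg = m.segment
        return (
            min(t.end, seg.genomic_end) - max(t.start, seg.genomic_start) >= 1
            and _same_sign(t.kind, m.kind)
        )

    n_rec = sum(
        1
        for t in truth_micro
        if any(_hit(t, m) for m in called.get((t.gene_symbol, t.sample_id), []))
    )
    n_tp = sum(
        1
        for m in micros
        if any(_hit(t, m) for t in truth_by.get((m.segment.gene_symbol, m.segment.sample_id), []))
    )
    return {
        "n_truth": len(truth_micro),
        "n_called": len(micros),
        "recall": n_rec / len(truth_micro) if truth_micro else float("nan"),
        "precision": n_tp / len(micros) if micros else float("nan"),
    }


def truth_summary(cohort: SyntheticCohort) -> dict[str, pd.DataFrame]:
    """Per-sample and per-gene implant counts by kind; totals equal len(truth)."""
    kinds = ["macro-gain", "macro-loss", "micro-amp", "micro-del"]
    samples = cohort.samples
    genes = [w.gene_symbol for w in cohort.windows]
    per_sample = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=kinds)
    per_gene = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=kinds)
    for rec in cohort.truth:
        per_sample.loc[rec.sample_id, rec.kind] += 1
        per_gene.loc[rec.gene_symbol, rec.kind] += 1
    return {"per_sample": per_sample, "per_gene": per_gene}
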