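"""Where micro-aberrations fall within genes: quadrant occupancy and
promoter / 5'UTR overlap rates.

Each gene's analysis window is split into four equal intervals, labelled by
biological orientation (5'End, 5'Mid, 3'Mid, 3'End — on the − strand the
5'End quadrant is the rightmost genomic interval). An instance "affects" a
quadrant when it overlaps it by at least ``min_overlap_bp`` (1 bp default),
and the occupancy proportion for a quadrant is affected instances over all
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .aberration_calling import MicroAberration
from .io_formats import GeneWindow

QUADRANT_LABELS = ("5'End", "5'Mid", "3'Mid", "3'End")


@dataclass
class QuadrantSummary:
    affected_counts: dict  # label -> count of instances overlapping that quadrant
    possible_count: int    # number of micro instances
    proportions: dict      # label -> affected / possible
    promoter_rate: Optional[float]
    utr5_rate: Optional[float]
    five_prime_only_promoter_rate: Optional[float]
    five_prime_only_utr5_rate: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": label,
                "affected": self.affected_counts[label],
                "possible": self.possible_count,
                "proportion": self.proportions[label],
            }
            for label in QUADRANT_LABELS
        ]
        return pd.DataFrame(rows)


def quadrant_bounds(window: GeneWindow) -> list[tuple[str, int, int]]:
    """Four equal, exhaustive, non-overlapping intervals over the window.

    Boundaries fall at floor offsets; the last genomic interval absorbs any
    remainder. Labels run 5'->3' in the gene's orientation.
    """
    ws, we = window.window_start, window.window_end
    q = (we - ws) // 4
    edges = [ws, ws + q, ws + 2 * q, ws + 3 * q, we]
    intervals = list(zip(edges[:-1], edges[1:]))
    labels = QUADRANT_LABELS if window.strand == "+" else QUADRANT_LABELS[::-1]
    return [(label, lo, hi) for label, (lo, hi) in zip(labels, intervals)]


def promoter_interval(window: GeneWindow, definition: str = "tss") -> tuple[int, int]:
    """Upstream-of-TSS interval within the analysis window, oriented by strand.

    ``definition="cds"`` would anchor at the coding start instead; with
    gene-span annotations only, the TSS anchor is the operative one and "cds"
    falls back to it.
    """
    if definition not in ("tss", "cds"):
        raise ValueError(f"unknown promoter definition {definition!r}")
    if window.strand == "+":
        return (window.window_start, window.tss)
    return (window.tss, window.window_end)


def _overlap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    return max(0, min(a_hi, b_hi) - max(a_lo, b_lo))


def annotate_positions(
    micros: Sequence[MicroAberration],
    windows: Sequence[GeneWindow],
    min_overlap_bp: int = 1,
    promoter_definition: str = "tss",
) -> list[MicroAberration]:
    """Fill each instance's quadrant/promoter/5'UTR flags in place (and return them)."""
    by_gene = {w.gene_symbol: w for w in windows}
    for m in micros:
        seg = m.segment
        w = by_gene.get(seg.gene_symbol)
        if w is None:
            raise KeyError(f"micro-aberration references unknown gene {seg.gene_symbol!r}")
        flags = []
        for _, lo, hi in quadrant_bounds(w):
            flags.append(_overlap(seg.genomic_start, seg.genomic_end, lo, hi) >= min_overlap_bp)
        # store flags in label order 5'End..3'End regardless of strand
        labelled = dict(zip(quadrant_labels_for(w), flags))
        m.quadrant_flags = tuple(labelled[l] for l in QUADRANT_LABELS)
        plo, phi = promoter_interval(w, promoter_definition)
        m.promoter_flag = _overlap(seg.genomic_start, seg.genomic_end, plo, phi) >= min_overlap_bp
        if w.utr5_start is not None and w.utr5_end is not None:
            m.utr5_flag = (
                _overlap(seg.genomic_start, seg.genomic_end, w.utr5_start, w.utr5_end)
                >= min_overlap_bp
            )
        else:
            m.utr5_flag = False
    return list(micros)


def quadrant_labels_for(window: GeneWindow) -> tuple[str, ...]:
    return tuple(label for label, _, _ in quadrant_bounds(window))


def tally_quadrants(
    micros: Sequence[MicroAberration],
    windows: Sequence[GeneWindow],
    min_overlap_bp: int = 1,
    promoter_definition: str = "tss",
) -> QuadrantSummary:
    """Occupancy proportions per quadrant plus promoter/5'UTR overlap rates.

    Every instance contributes one "possible" slot per quadrant; a quadrant's
    proportion is the fraction of instances overlapping it. Rates over an
    empty instance set are reported as None.
    """
    micros = annotate_positions(micros, windows, min_overlap_bp, promoter_definition)
    n = len(micros)
    affected = {label: 0 for label in QUADRANT_LABELS}
    n_promoter = n_utr5 = n_utr5_known = 0
    by_gene = {w.gene_symbol: w for w in windows}
    for m in micros:
        for label, flag in zip(QUADRANT_LABELS, m.quadrant_flags):
            affected[label] += bool(flag)
        n_promoter += m.promoter_flag
        w = by_gene[m.segment.gene_symbol]
        if w.utr5_start is not None:
            n_utr5_known += 1
            n_utr5 += m.utr5_flag
    fp_prom, fp_utr5 = five_prime_only_breakdown(micros, windows, min_overlap_bp, promoter_definition,
                                                 _already_annotated=True)
    return QuadrantSummary(
        affected_counts=affected,
        possible_count=n,
        proportions={l: (affected[l] / n if n else 0.0) for l in QUADRANT_LABELS},
        promoter_rate=(n_promoter / n) if n else None,
        utr5_rate=(n_utr5 / n_utr5_known) if n_utr5_known else None,
        five_prime_only_promoter_rate=fp_prom,
        five_prime_only_utr5_rate=fp_utr5,
    )


def five_prime_only_breakdown(
    micros: Sequence[MicroAberration],
    windows: Sequence[GeneWindow],
    min_overlap_bp: int = 1,
    promoter_definition: str = "tss",
    _already_annotated: bool = False,
) -> tuple[Optional[float], Optional[float]]:
    """Promoter and 5'UTR overlap rates among instances confined to the 5'End quadrant.

    Returns ``(None, None)`` when no instance is 5'End-only; the 5'UTR rate is
    None when no restricted instance has 5'UTR coordinates.
    """
    if not _already_annotated:
        micros = annotate_positions(micros, windows, min_overlap_bp, promoter_definition)
    by_gene = {w.gene_symbol: w for w in windows}
    restricted = [m for m in micros if m.quadrant_flags == (True, False, False, False)]
    if not restricted:
        return None, None
    prom = sum(m.promoter_flag for m in restricted) / len(restricted)
    with_utr5 = [m for m in restricted if by_gene[m.segment.gene_symbol].utr5_start is not None]
    utr5 = (sum(m.utr5_flag for m in with_utr5) / len(with_utr5)) if with_utr5 else None
    return prom, utr5


def per_instance_table(micros: Sequence[MicroAberration]) -> pd.DataFrame:
    rows = []
    for m in micros:
        row = {
            "Sample": m.segment.sample_id,
            "Gene": m.segment.gene_symbol,
            "Start": m.segment.genomic_start + 1,
            "Stop": m.segment.genomic_end,
            "Kind": m.kind,
            "Promoter": m.promoter_flag,
            "UTR5": m.utr5_flag,
        }
        row.update({label: flag for label, flag in zip(QUADRANT_LABELS, m.quadrant_flags)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["Sample", "Gene", "Start", "Stop", "Kind", *QUADRANT_LABELS, "Promoter", "UTR5"])
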