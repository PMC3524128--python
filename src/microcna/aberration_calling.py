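"""Micro vs. macro classification of aberrant segments and per-(gene, sample) status.

A micro-aberration is an aberrant segment spanning fewer than ``max_probes``
contiguous probes (default 64, strict; ~15 kb at 200 bp tiling). The cutoff
can instead be recomputed from the cohort's aberrant-segment size distribution
as the smallest-25% empirical quantile, which is how the fixed default was
originally derived.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import Segment

logger = logging.getLogger(__name__)

MICRO_KINDS = ("micro-amp", "micro-del")
MACRO_KINDS = ("macro-gain", "macro-loss")
STATUSES = ("gross-gain", "gross-loss", "micro-amp", "micro-del", "none")


@dataclass(frozen=True)
class MicroDefinition:
    max_probes: int = 64          # exclusive: micro iff n_probes < max_probes
    approx_span_bp: int = 15000   # informational only
    percentile: float = 0.25
    mode: str = "fixed_probes"    # or "cohort_percentile"

    def __post_init__(self):
        if self.max_probes < 2:
            raise ValueError("max_probes must be >= 2")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.mode not in ("fixed_probes", "cohort_percentile"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class MicroAberration:
    """One micro-aberration instance with positional annotations."""

    segment: Segment
    kind: str  # micro-amp | micro-del
    quadrant_flags: tuple[bool, bool, bool, bool] = (False, False, False, False)
    promoter_flag: bool = False
    utr5_flag: bool = False


@dataclass(frozen=True)
class GeneSampleStatus:
    gene_symbol: str
    sample_id: str
    status: str  # one of STATUSES


def size_threshold_from_cohort(segment_probe_counts: Iterable[int], percentile: float = 0.25) -> int:
    """Smallest integer k with fraction(counts < k) >= percentile.

    This is the empirical lower-exclusive quantile: segments with fewer than
    k probes make up at least the requested fraction of all aberrant
    segments. A degenerate all-equal distribution yields k = c + 1 (everything
    micro) with a warning.
    """
    counts = np.asarray(sorted(segment_probe_counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty aberrant-segment size distribution")
    uniq, cum = np.unique(counts, return_counts=True)
    frac_le = np.cumsum(cum) / counts.size  # fraction with n <= uniq[i] == fraction < uniq[i]+1
    k = int(uniq[np.argmax(frac_le >= percentile)]) + 1
    if uniq.size == 1:
        logger.warning(
            "degenerate segment-size distribution (all %d probes); every aberration is micro", uniq[0]
        )
    return k


def resolve_max_probes(micro_def: MicroDefinition, aberrant: Sequence[Segment]) -> int:
    if micro_def.mode == "fixed_probes":
        return micro_def.max_probes
    return size_threshold_from_cohort((s.n_probes for s in aberrant), micro_def.percentile)


def classify_segment(segment: Segment, micro_def: MicroDefinition = MicroDefinition(),
                     max_probes: Optional[int] = None) -> str:
    """Classify an aberrant segment: micro iff n_probes < max_probes (strict)."""
    if segment.call == "neutral":
        raise ValueError("classify_segment requires a non-neutral segment")
    cutoff = max_probes if max_probes is not None else micro_def.max_probes
    small = segment.n_probes < cutoff
    if segment.mean_log2 > 0:
        return "micro-amp" if small else "macro-gain"
    return "micro-del" if small else "macro-loss"


def call_aberrations(
    segments: Sequence[Segment],
    micro_def: MicroDefinition = MicroDefinition(),
    log2_threshold: float = 0.30,
) -> tuple[list[MicroAberration], list[Segment]]:
    """Split a cohort's segments into micro instances and macro segments.

    Returns ``(micros, macros)``; neutral segments are discarded. Under
    ``cohort_percentile`` mode the probe cutoff is first recomputed from this
    cohort's aberrant-segment sizes.
    """
    aberrant = [s for s in segments if abs(s.mean_log2) > log2_threshold and s.call != "neutral"]
    cutoff = resolve_max_probes(micro_def, aberrant)
    micros, macros = [], []
    for s in aberrant:
        kind = classify_segment(s, micro_def, max_probes=cutoff)
        if kind in MICRO_KINDS:
            micros.append(MicroAberration(segment=s, kind=kind))
        else:
            macros.append(s)
    return micros, macros


def assign_gene_sample_status(
    segments: Sequence[Segment],
    micro_def: MicroDefinition = MicroDefinition(),
    max_probes: Optional[int] = None,
    log2_threshold: float = 0.30,
) -> str:
    """Single copy-number status for one (gene, sample)'s segments.

    Macro events take precedence (the dominant one by |mean x n_probes|);
    otherwise the micro event with the largest |mean| decides; no aberrant
    segment means status "none".
    """
    aberrant = [s for s in segments if abs(s.mean_log2) > log2_threshold and s.call != "neutral"]
    if not aberrant:
        return "none"
    cutoff = max_probes if max_probes is not None else resolve_max_probes(micro_def, aberrant)
    macros = [s for s in aberrant if s.n_probes >= cutoff]
    if macros:
        top = max(macros, key=lambda s: abs(s.mean_log2 * s.n_probes))
        return "gross-gain" if top.mean_log2 > 0 else "gross-loss"
    top = max(aberrant, key=lambda s: abs(s.mean_log2))
    return "micro-amp" if top.mean_log2 > 0 else "micro-del"


def status_matrix(
    segments: Sequence[Segment],
    genes: Sequence[str],
    samples: Sequence[str],
    micro_def: MicroDefinition = MicroDefinition(),
    log2_threshold: float = 0.30,
) -> pd.DataFrame:
    """Gene x sample status DataFrame over the full cohort universe."""
    aberrant = [s for s in segments if abs(s.mean_log2) > log2_threshold and s.call != "neutral"]
    cutoff = resolve_max_probes(micro_def, aberrant) if aberrant else micro_def.max_probes
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in aberrant:
        by_key.setdefault((s.gene_symbol, s.sample_id), []).append(s)
    out = pd.DataFrame("none", index=pd.Index(genes, name="gene"), columns=list(samples))
    for (gene, sample), segs in by_key.items():
        if gene in out.index and sample in out.columns:
            out.loc[gene, sample] = assign_gene_sample_status(
                segs, micro_def, max_probes=cutoff, log2_threshold=log2_threshold
            )
    return out


def micro_counts_per_sample(micros: Sequence[MicroAberration], samples: Sequence[str]) -> pd.Series:
    counts = Counter(m.segment.sample_id for m in micros)
    return pd.Series([counts.get(s, 0) for s in samples], index=list(samples), name="micro_count")


def per_subtype_summary(micros: Sequence[MicroAberration], clinical) -> pd.DataFrame:
    """Per-subtype micro-aberration burden: mean, median, % samples with >= 1.

    Samples without a recognised subtype label are grouped under "unknown".
    """
    if not clinical:
        return pd.DataFrame(
            columns=["n_samples", "mean_micro", "median_micro", "pct_with_micro"]
        ).rename_axis("subtype")
    samples = [c.sample_id for c in clinical]
    subtype = {c.sample_id: (c.subtype if c.subtype and c.subtype != "nan" else "unknown") for c in clinical}
    counts = micro_counts_per_sample(micros, samples)
    df = pd.DataFrame({"subtype": [subtype[s] for s in samples], "count": counts.to_numpy()})
    grouped = df.groupby("subtype", sort=True)["count"]
    out = pd.DataFrame(
        {
            "n_samples": grouped.size(),
            "mean_micro": grouped.mean(),
            "median_micro": grouped.median(),
            "pct_with_micro": grouped.apply(lambda c: 100.0 * (c > 0).mean()),
        }
    )
    return out


def micros_to_table(micros: Sequence[MicroAberration], clinical=None) -> pd.DataFrame:
    """Micro-aberration instance table (Sample, Subtype, Gene, Start, Stop, mean log2)."""
    subtype = {c.sample_id: c.subtype for c in clinical} if clinical else {}
    rows = []
    for m in micros:
        s = m.segment
        rows.append(
            {
                "Sample": s.sample_id,
                "Subtype": subtype.get(s.sample_id, "unknown"),
                "Gene": s.gene_symbol,
                "Start": s.genomic_start + 1,
                "Stop": s.genomic_end,
                "Num_Probes": s.n_probes,
                "Avg_Log_Ratio": s.mean_log2,
                "Kind": m.kind,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["Sample", "Subtype", "Gene", "Start", "Stop", "Num_Probes", "Avg_Log_Ratio", "Kind"],
    )


def micros_from_table(df: pd.DataFrame, chrom_by_gene: Optional[dict] = None) -> list[MicroAberration]:
    """Rebuild micro instances from an instance table written by micros_to_table."""
    out = []
    for r in df.itertuples(index=False):
        n_probes = int(getattr(r, "Num_Probes", 1))
        mean = float(r.Avg_Log_Ratio)
        seg = Segment(
            sample_id=str(r.Sample),
            gene_symbol=str(r.Gene),
            chrom=(chrom_by_gene or {}).get(str(r.Gene), ""),
            probe_index_start=0,
            probe_index_end=n_probes,
            genomic_start=int(r.Start) - 1,
            genomic_end=int(r.Stop),
            n_probes=n_probes,
            mean_log2=mean,
            call="gain" if mean > 0 else "loss",
        )
        kind = getattr(r, "Kind", None) or ("micro-amp" if mean > 0 else "micro-del")
        out.append(MicroAberration(segment=seg, kind=str(kind)))
    return out
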