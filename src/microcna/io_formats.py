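"""Tabular I/O and coordinate conventions shared by every analysis stage.

Internal coordinates are 0-based half-open; every on-disk table is 1-based
inclusive (the convention of the gene-annotation tables the pipeline mirrors).
The conversion happens exactly once, at read/write time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PAD_BP = 5000

MISSING_TOKENS = {"", "NA", "NaN", "nan", "null", "None"}


class FormatError(ValueError):
    """A file does not match the documented schema."""


class RecordError(ValueError):
    """A single record violates its invariants."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneWindow:
    """A gene's genomic span and its padded analysis window.

    Coordinates are internal (0-based half-open). ``tss`` is the biological
    transcription start: ``gene_start`` on the + strand, ``gene_end`` on the
    − strand (one past the last transcribed base, matching half-open spans).
    """

    gene_symbol: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    window_start: int
    window_end: int
    utr5_start: Optional[int] = None
    utr5_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise RecordError(f"{self.gene_symbol}: strand must be '+' or '-'")
        if self.gene_start >= self.gene_end:
            raise RecordError(
                f"{self.gene_symbol}: gene_start {self.gene_start} >= gene_end {self.gene_end}"
            )
        if not (self.window_start <= self.gene_start and self.gene_end <= self.window_end):
            raise RecordError(f"{self.gene_symbol}: window does not contain gene span")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end

    @property
    def length(self) -> int:
        return self.window_end - self.window_start

    @classmethod
    def from_span(
        cls,
        gene_symbol: str,
        chrom: str,
        strand: str,
        gene_start: int,
        gene_end: int,
        pad_bp: int = DEFAULT_PAD_BP,
        utr5_start: Optional[int] = None,
        utr5_end: Optional[int] = None,
    ) -> "GeneWindow":
        """Build a window from an internal gene span padded by ``pad_bp`` on each side."""
        return cls(
            gene_symbol=gene_symbol,
            chrom=chrom,
            strand=strand,
            gene_start=gene_start,
            gene_end=gene_end,
            window_start=max(0, gene_start - pad_bp),
            window_end=gene_end + pad_bp,
            utr5_start=utr5_start,
            utr5_end=utr5_end,
        )


@dataclass
class ProbeSet:
    """Ordered probe annotations: one row per probe, grouped by owning window.

    ``table`` columns: probe_id, chrom, position (probe midpoint, internal bp),
    gene_symbol. Probes within a window are sorted by strictly increasing
    position; each probe belongs to exactly one window.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"probe_id", "chrom", "position", "gene_symbol"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"probe table missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dupes = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise FormatError(f"duplicate probe id: {dupes.iloc[0]!r}")
        for gene, grp in self.table.groupby("gene_symbol", sort=False):
            pos = grp["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise RecordError(f"probes for {gene} not strictly increasing")

    def for_gene(self, gene_symbol: str) -> pd.DataFrame:
        return self.table[self.table["gene_symbol"] == gene_symbol]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LogRatioMatrix:
    """Probe x sample log2 tumor/reference ratios (NaN marks missing)."""

    probes: ProbeSet
    values: pd.DataFrame  # index = probe_id, columns = samples

    def __post_init__(self):
        if len(self.values) != len(self.probes):
            raise FormatError("value matrix and probe table disagree on probe count")
        if not self.values.index.equals(pd.Index(self.probes.table["probe_id"])):
            raise FormatError("value matrix index must equal the probe_id column, in order")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression log2 R/G ratios with a presence mask."""

    values: pd.DataFrame  # index = gene, columns = samples
    present_mask: pd.DataFrame = None

    def __post_init__(self):
        if self.present_mask is None:
            self.present_mask = self.values.notna()
        if self.present_mask.shape != self.values.shape:
            raise FormatError("present_mask shape differs from values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    subtype: str
    os_time: float
    os_event: int
    rfs_time: float
    rfs_event: int

    def __post_init__(self):
        if self.os_time < 0 or self.rfs_time < 0:
            raise RecordError(f"{self.sample_id}: negative survival time")
        if self.os_event not in (0, 1) or self.rfs_event not in (0, 1):
            raise RecordError(f"{self.sample_id}: events must be 0/1")


SUBTYPES = ("Basal-like", "Luminal A", "Luminal B", "HER2-enriched", "Normal-like")


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_windows(path, pad_bp: int = DEFAULT_PAD_BP) -> list[GeneWindow]:
    """Read a gene-window table (TSV, 1-based inclusive spans on disk).

    Required columns: gene, chrom, strand, gene_start, gene_end. Optional
    columns utr5_start/utr5_end. Windows pad the gene span by ``pad_bp`` on
    both sides. Overlapping windows on one chromosome are tolerated with a
    warning (array content may legitimately abut).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("gene", "chrom", "strand", "gene_start", "gene_end"):
        if col not in df.columns:
            raise FormatError(f"gene window table missing column {col!r}")
    windows = []
    for row in df.itertuples(index=False):
        start1, end1 = int(row.gene_start), int(row.gene_end)
        if start1 >= end1:
            raise RecordError(f"{row.gene}: gene_start {start1} >= gene_end {end1}")
        utr5_start = utr5_end = None
        if "utr5_start" in df.columns and not pd.isna(getattr(row, "utr5_start")):
            utr5_start = int(getattr(row, "utr5_start")) - 1
            utr5_end = int(getattr(row, "utr5_end"))
        windows.append(
            GeneWindow.from_span(
                gene_symbol=str(row.gene),
                chrom=str(row.chrom),
                strand=str(row.strand),
                gene_start=start1 - 1,
                gene_end=end1,
                pad_bp=pad_bp,
                utr5_start=utr5_start,
                utr5_end=utr5_end,
            )
        )
    _warn_on_overlaps(windows)
    return windows


def _warn_on_overlaps(windows: Sequence[GeneWindow]) -> None:
    by_chrom: dict[str, list[GeneWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.window_start)
        for a, b in zip(ws, ws[1:]):
            if b.window_start < a.window_end:
                logger.warning(
                    "analysis windows overlap on %s: %s and %s", chrom, a.gene_symbol, b.gene_symbol
                )


def write_gene_windows(windows: Sequence[GeneWindow], path) -> None:
    rows = []
    for w in windows:
        rows.append(
            {
                "gene": w.gene_symbol,
                "chrom": w.chrom,
                "strand": w.strand,
                "gene_start": w.gene_start + 1,
                "gene_end": w.gene_end,
                "utr5_start": w.utr5_start + 1 if w.utr5_start is not None else np.nan,
                "utr5_end": w.utr5_end if w.utr5_end is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_log_ratio_matrix(path, windows: Sequence[GeneWindow]) -> LogRatioMatrix:
    """Read a probe x sample log2-ratio TSV and assign probes to windows.

    The first three columns are probe_id, chrom, position (1-based probe
    midpoint); the rest are samples. Probes outside every analysis window are
    dropped (count logged). Probe order within a window is sorted by position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=sorted(MISSING_TOKENS))
    for col in ("probe_id", "chrom", "position"):
        if col not in df.columns:
            raise FormatError(f"probe matrix missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"]
        raise FormatError(f"duplicate probe id: {dupes.iloc[0]!r}")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "position")]
    for c in sample_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.loc[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna(), c]
            raise FormatError(f"non-numeric log2 value in sample column {c!r}: {bad.iloc[0]!r}")

    pos0 = df["position"].to_numpy(dtype=np.int64) - 1  # midpoint, to 0-based
    gene = np.full(len(df), None, dtype=object)
    for w in windows:
        in_w = (df["chrom"].to_numpy() == w.chrom) & (pos0 >= w.window_start) & (pos0 < w.window_end)
        clash = in_w & (gene != None)  # noqa: E711
        if clash.any():
            # first assignment wins so no probe lands in two windows
            in_w &= gene == None  # noqa: E711
        gene[in_w] = w.gene_symbol
    keep = gene != None  # noqa: E711
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d probes outside every analysis window", n_dropped)
    df = df.loc[keep].copy()
    df["gene_symbol"] = gene[keep]
    df["position"] = pos0[keep]

    order = {w.gene_symbol: i for i, w in enumerate(windows)}
    df["_gene_order"] = df["gene_symbol"].map(order)
    df = df.sort_values(["_gene_order", "position"], kind="stable").drop(columns="_gene_order")
    probes = ProbeSet(df[["probe_id", "chrom", "position", "gene_symbol"]].reset_index(drop=True))
    values = df[sample_cols].astype(float)
    values.index = pd.Index(df["probe_id"], name="probe_id")
    return LogRatioMatrix(probes=probes, values=values)


def write_log_ratio_matrix(matrix: LogRatioMatrix, path) -> None:
    df = matrix.probes.table[["probe_id", "chrom", "position"]].copy()
    df["position"] = df["position"] + 1
    out = pd.concat([df.reset_index(drop=True), matrix.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def apply_presence_filter(
    expr: ExpressionMatrix, min_intensity: float = 10.0, min_present: float = 0.70,
    intensities: Optional[tuple[pd.DataFrame, pd.DataFrame]] = None,
) -> ExpressionMatrix:
    """Drop gene rows present in fewer than ``min_present`` of samples.

    Presence is the matrix's ``present_mask``; when per-channel ``intensities``
    (R, G) are supplied the mask is first tightened to entries where both
    channels reach ``min_intensity``. Row order of survivors is preserved, and
    the operation is idempotent.
    """
    if not 0.0 <= min_present <= 1.0:
        raise ValueError(f"min_present must be in [0, 1], got {min_present}")
    mask = expr.present_mask
    if intensities is not None:
        red, green = intensities
        mask = mask & (red >= min_intensity) & (green >= min_intensity)
    frac = mask.mean(axis=1)
    keep = frac >= min_present
    return ExpressionMatrix(values=expr.values.loc[keep].copy(), present_mask=mask.loc[keep].copy())


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=sorted(MISSING_TOKENS))
    return ExpressionMatrix(values=df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6f", index_label="gene")


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "subtype", "os_time", "os_event", "rfs_time", "rfs_event"):
        if col not in df.columns:
            raise FormatError(f"clinical table missing column {col!r}")
    return [
        ClinicalRecord(
            sample_id=str(r.sample_id),
            subtype=str(r.subtype),
            os_time=float(r.os_time),
            os_event=int(r.os_event),
            rfs_time=float(r.rfs_time),
            rfs_event=int(r.rfs_event),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical(records: Iterable[ClinicalRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def write_segments_seg(segments, path) -> None:
    """Write segments to a standard SEG file (1-based inclusive on disk)."""
    rows = []
    for s in segments:
        rows.append(
            {
                "Sample": s.sample_id,
                "Chromosome": s.chrom,
                "Start": s.genomic_start + 1,
                "End": s.genomic_end,
                "Num_Probes": s.n_probes,
                "Segment_Mean": s.mean_log2,
                # extra columns keep the file self-contained for downstream stages
                "Gene": s.gene_symbol,
                "Probe_Index_Start": s.probe_index_start,
                "Probe_Index_End": s.probe_index_end,
                "Call": s.call,
            }
        )
    df = pd.DataFrame(rows, columns=SEG_COLUMNS + ["Gene", "Probe_Index_Start", "Probe_Index_End", "Call"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segments_seg(path):
    from .segmentation import Segment  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"SEG file missing columns: {sorted(missing)}")
    segs = []
    for r in df.itertuples(index=False):
        segs.append(
            Segment(
                sample_id=str(r.Sample),
                gene_symbol=str(getattr(r, "Gene", "")),
                chrom=str(r.Chromosome),
                probe_index_start=int(getattr(r, "Probe_Index_Start", 0)),
                probe_index_end=int(getattr(r, "Probe_Index_End", r.Num_Probes)),
                genomic_start=int(r.Start) - 1,
                genomic_end=int(r.End),
                n_probes=int(r.Num_Probes),
                mean_log2=float(r.Segment_Mean),
                call=str(getattr(r, "Call", "neutral")),
            )
        )
    return segs
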