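"""File-based pipeline: simulate -> segment -> call -> position -> integrate
-> chance -> survive, with a manifest and report tables.

Every stage consumes and produces TSV/SEG files, so any stage can be rerun
from disk, and a full run under a fixed seed is byte-reproducible (the
manifest records digests, not wall-clock times; timings go to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .aberration_calling import (
    MicroDefinition,
    call_aberrations,
    micro_counts_per_sample,
    micros_from_table,
    micros_to_table,
    per_subtype_summary,
    status_matrix,
)
from .chance_model import chance_table
from .expression_integration import (
    dichotomize_expression,
    fisher_exact_2x2,
    gene_concordance,
    per_gene_anova,
    pooled_contingency,
)
from .io_formats import (
    apply_presence_filter,
    read_clinical,
    read_expression_matrix,
    read_gene_windows,
    read_log_ratio_matrix,
    read_segments_seg,
    write_clinical,
    write_expression_matrix,
    write_gene_windows,
    write_log_ratio_matrix,
    write_segments_seg,
)
from .outcome_analysis import SurvivalSplit, km_table, survival_by_burden
from .positional_analysis import per_instance_table, tally_quadrants
from .segmentation import SegmentationParams, segment_cohort
from .synthetic_cohort import (
    ArrayDesignParams,
    CohortSimParams,
    design_array,
    simulate_cohort,
    truth_summary,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "call", "position", "integrate", "chance", "survive")


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Validate every stage's parameters before any stage runs."""
    if "seed" not in cfg:
        raise PipelineError("config must set a top-level seed")
    _sim_params(cfg)
    _seg_params(cfg)
    _micro_def(cfg)
    _split(cfg)
    stages = cfg.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    if "survive" in stages and "simulate" not in stages:
        if "clinical" not in cfg.get("inputs", {}):
            raise PipelineError("survive stage needs a clinical table (inputs.clinical) or the simulate stage")


def _sim_params(cfg) -> tuple[ArrayDesignParams, CohortSimParams]:
    block = dict(cfg.get("simulate", {}))
    design_keys = {"n_genes", "probe_spacing_bp", "gene_length_range", "pad_bp", "flank_bp"}
    design = {k: v for k, v in block.items() if k in design_keys}
    sim = {k: v for k, v in block.items() if k not in design_keys}
    if "gene_length_range" in design:
        design["gene_length_range"] = tuple(design["gene_length_range"])
    if "micro_span_range" in sim:
        sim["micro_span_range"] = tuple(sim["micro_span_range"])
    sim.setdefault("seed", cfg.get("seed", 0))
    return ArrayDesignParams(**design), CohortSimParams(**sim)


def _seg_params(cfg) -> SegmentationParams:
    return SegmentationParams(**cfg.get("segmentation", {}))


def _micro_def(cfg) -> MicroDefinition:
    return MicroDefinition(**cfg.get("calling", {}))


def _split(cfg) -> SurvivalSplit:
    return SurvivalSplit(**cfg.get("survive", {}))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir, seed: Optional[int] = None) -> dict:
    """Run all configured stages in dependency order into ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) with the
    seed, package version, parameters, and a sha256 digest per output. A
    stage failure writes a FAILED marker naming the stage and re-raises.
    """
    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = {**config, "seed": seed}
    seed = int(config["seed"])
    stages = config.get("stages", list(STAGES))
    paths = {
        "windows": outdir / "gene_windows.tsv",
        "matrix": outdir / "log_ratio_matrix.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
        "segments": outdir / "segments.seg",
        "micros": outdir / "micro_aberrations.tsv",
        "status": outdir / "status_matrix.tsv",
        "subtype_summary": outdir / "subtype_summary.tsv",
        "quadrants": outdir / "quadrant_summary.tsv",
        "instance_flags": outdir / "instance_flags.tsv",
        "concordance": outdir / "concordance.tsv",
        "contingency": outdir / "contingency.tsv",
        "anova": outdir / "anova.tsv",
        "chance": outdir / "chance_table.tsv",
        "survival": outdir / "survival.tsv",
        "km_curves": outdir / "km_curves.tsv",
    }
    for key, src in config.get("inputs", {}).items():
        paths[key] = Path(src)

    current = "?"
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            current = stage
            logger.info("stage %s starting", stage)
            _run_stage(stage, config, paths, seed)
            logger.info("stage %s done", stage)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise PipelineError(f"stage {current} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config": _jsonable(config),
        "outputs": {
            k: _digest(p) for k, p in sorted(paths.items()) if p.exists() and p.is_relative_to(outdir)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _run_stage(stage: str, config: dict, paths: dict, seed: int) -> None:
    seg_params = _seg_params(config)
    micro_def = _micro_def(config)
    if stage == "simulate":
        design, sim = _sim_params(config)
        sim = CohortSimParams(**{**asdict_params(sim), "seed": seed})
        windows, probes = design_array(design, seed=seed)
        cohort = simulate_cohort(windows, probes, sim)
        write_gene_windows(cohort.windows, paths["windows"])
        write_log_ratio_matrix(cohort.log_ratio_matrix, paths["matrix"])
        write_expression_matrix(cohort.expression_matrix, paths["expression"])
        write_clinical(cohort.clinical, paths["clinical"])
        truth_df = pd.DataFrame(
            [
                {
                    "sample_id": t.sample_id,
                    "gene": t.gene_symbol,
                    "kind": t.kind,
                    "start": t.start + 1,
                    "end": t.end,
                    "quadrants": ",".join(t.affected_quadrants),
                    "expression_shifted": t.expression_shifted,
                }
                for t in cohort.truth
            ]
        )
        truth_df.to_csv(paths["truth"], sep="\t", index=False)
    elif stage == "segment":
        windows = read_gene_windows(paths["windows"])
        matrix = read_log_ratio_matrix(paths["matrix"], windows)
        segments = segment_cohort(matrix, windows, seg_params)
        write_segments_seg(segments, paths["segments"])
    elif stage == "call":
        segments = read_segments_seg(paths["segments"])
        windows = read_gene_windows(paths["windows"])
        clinical = read_clinical(paths["clinical"]) if paths["clinical"].exists() else []
        micros, _macros = call_aberrations(segments, micro_def, seg_params.log2_threshold)
        micros_to_table(micros, clinical).to_csv(paths["micros"], sep="\t", index=False, float_format="%.6f")
        genes = [w.gene_symbol for w in windows]
        samples = sorted({s.sample_id for s in segments}) if not clinical else [c.sample_id for c in clinical]
        status_matrix(segments, genes, samples, micro_def, seg_params.log2_threshold).to_csv(
            paths["status"], sep="\t"
        )
        if clinical:
            per_subtype_summary(micros, clinical).to_csv(
                paths["subtype_summary"], sep="\t", float_format="%.4f"
            )
    elif stage == "position":
        windows = read_gene_windows(paths["windows"])
        micros = micros_from_table(pd.read_csv(paths["micros"], sep="\t"))
        pos_cfg = config.get("position", {})
        summary = tally_quadrants(
            micros,
            windows,
            min_overlap_bp=pos_cfg.get("min_overlap_bp", 1),
            promoter_definition=pos_cfg.get("promoter_definition", "tss"),
        )
        df = summary.to_frame()
        extra = pd.DataFrame(
            [
                {"region": "promoter", "affected": None, "possible": summary.possible_count,
                 "proportion": summary.promoter_rate},
                {"region": "5'UTR", "affected": None, "possible": summary.possible_count,
                 "proportion": summary.utr5_rate},
                {"region": "5'End-only:promoter", "affected": None, "possible": None,
                 "proportion": summary.five_prime_only_promoter_rate},
                {"region": "5'End-only:5'UTR", "affected": None, "possible": None,
                 "proportion": summary.five_prime_only_utr5_rate},
            ]
        )
        pd.concat([df, extra], ignore_index=True).to_csv(
            paths["quadrants"], sep="\t", index=False, float_format="%.6f"
        )
        per_instance_table(micros).to_csv(paths["instance_flags"], sep="\t", index=False)
    elif stage == "integrate":
        statuses = pd.read_csv(paths["status"], sep="\t", index_col=0)
        expr = apply_presence_filter(read_expression_matrix(paths["expression"]))
        dicho = dichotomize_expression(expr)
        gene_concordance(statuses, dicho).table.to_csv(paths["concordance"], sep="\t", float_format="%.4f")
        rows = []
        for cls in ("micro-amp", "micro-del", "any-micro"):
            tab = pooled_contingency(statuses, dicho, cls)
            rows.append(
                {"class": cls, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                 "fisher_p": fisher_exact_2x2(tab)}
            )
        pd.DataFrame(rows).to_csv(paths["contingency"], sep="\t", index=False, float_format="%.6g")
        per_gene_anova(statuses, expr).to_csv(paths["anova"], sep="\t", float_format="%.6g")
    elif stage == "chance":
        windows = read_gene_windows(paths["windows"])
        matrix = read_log_ratio_matrix(paths["matrix"], windows)
        micros = micros_from_table(pd.read_csv(paths["micros"], sep="\t"))
        chance_cfg = config.get("chance", {})
        chance_table(
            matrix,
            micros,
            threshold=seg_params.log2_threshold,
            min_probes=seg_params.min_probes,
            max_probes=micro_def.max_probes,
            mode=chance_cfg.get("mode", "exact"),
        ).to_csv(paths["chance"], sep="\t", float_format="%.6g")
    elif stage == "survive":
        clinical = read_clinical(paths["clinical"])
        micros = micros_from_table(pd.read_csv(paths["micros"], sep="\t"))
        counts = micro_counts_per_sample(micros, [c.sample_id for c in clinical])
        split = _split(config)
        rows = []
        curves = []
        for endpoint in ("os", "rfs"):
            res = survival_by_burden(clinical, counts, split, endpoint)
            rows.append(
                {
                    "endpoint": endpoint,
                    "n_low": res["n"]["low"],
                    "n_high": res["n"]["high"],
                    "logrank_stat": res["logrank_stat"],
                    "logrank_p": res["logrank_p"],
                }
            )
            for g, curve in res["curves"].items():
                tab = km_table(curve)
                tab.insert(0, "group", g)
                tab.insert(0, "endpoint", endpoint)
                curves.append(tab)
        pd.DataFrame(rows).to_csv(paths["survival"], sep="\t", index=False, float_format="%.6g")
        (pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()).to_csv(
            paths["km_curves"], sep="\t", index=False, float_format="%.6g"
        )
    else:  # pragma: no cover
        raise PipelineError(f"unknown stage {stage}")


def asdict_params(p) -> dict:
    from dataclasses import asdict

    return asdict(p)


def make_report(run_dir) -> dict[str, Path]:
    """Summary tables mirroring the published table layouts.

    Writes report_burden_by_subtype, report_concordance, report_expression_
    contingency, and report_gene_frequency TSVs from the stage outputs in
    ``run_dir``; sections with missing inputs are skipped (noted in the
    returned mapping as absent keys).
    """
    run_dir = Path(run_dir)
    out: dict[str, Path] = {}

    src = run_dir / "subtype_summary.tsv"
    if src.exists():
        dst = run_dir / "report_burden_by_subtype.tsv"
        df = pd.read_csv(src, sep="\t")
        df.to_csv(dst, sep="\t", index=False)
        out["burden_by_subtype"] = dst

    src = run_dir / "concordance.tsv"
    if src.exists():
        dst = run_dir / "report_concordance.tsv"
        df = pd.read_csv(src, sep="\t")
        df["display"] = df.apply(
            lambda r: f"{int(r.n_100pct)}/{int(r.n_genes_with_class)}"
            + (f" ({100 * r.rate_100pct:.1f}%)" if r.n_genes_with_class else ""),
            axis=1,
        )
        df.to_csv(dst, sep="\t", index=False)
        out["concordance"] = dst

    src = run_dir / "contingency.tsv"
    if src.exists():
        dst = run_dir / "report_expression_contingency.tsv"
        pd.read_csv(src, sep="\t").to_csv(dst, sep="\t", index=False)
        out["expression_contingency"] = dst

    src = run_dir / "chance_table.tsv"
    if src.exists():
        dst = run_dir / "report_gene_frequency.tsv"
        df = pd.read_csv(src, sep="\t")
        df["All/Amp/Del"] = (
            df["observed_all"].astype(str)
            + "/" + df["observed_amp"].astype(str)
            + "/" + df["observed_del"].astype(str)
        )
        df[["gene", "All/Amp/Del", "expected", "p_display"]].to_csv(dst, sep="\t", index=False)
        out["gene_frequency"] = dst
    return out
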