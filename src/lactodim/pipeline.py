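"""End-to-end orchestration: simulate/load → normalize → DE → enrichment →
CNA segmentation → integration → correlations → cohort summary.

A single YAML/JSON config drives the run; every intermediate artifact is
written as TSV under the output directory, and a machine-readable JSON
report records versions, the seed, every threshold, and the headline counts
so that each reported number is recomputable from the emitted files.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, datasets
from .cna import (
    DEFAULT_GAIN_CUTOFF,
    DEFAULT_LOSS_CUTOFF,
    DEFAULT_MIN_SEGMENT_PROBES,
    arm_intervals_from_annotation,
    assign_arms,
    call_segments,
    recurrence_by_group,
    recurrence_frame,
    segment_all,
)
from .de import (
    DEFAULT_ALPHA,
    DEFAULT_FC_MIN,
    deregulated_counts,
    results_frame,
    select_deregulated,
)
from .enrichment import delta_statistic, enrichment_frame, rank_by_median_distance
from .integrate import candidates_frame, category_crosstab, gained_region_candidates, pearson_panel
from .io import (
    read_annotation,
    read_copy_number,
    read_expression,
    read_sample_sheet,
    write_annotation,
    write_copy_number,
    write_expression,
    write_probe_map,
    write_sample_sheet,
    write_seg,
    write_segment_calls,
)
from .model import PipelineError
from .preprocess import DEFAULT_K_SD, detection_call, log2_transform, median_normalize
from .simulate import SimulationConfig, simulate_dataset
from .summary import cohort_table, era_esr1_correlation, summary_frame

log = logging.getLogger("lactodim.pipeline")

DEFAULT_THRESHOLDS = {
    "alpha": DEFAULT_ALPHA,
    "fc_min": DEFAULT_FC_MIN,
    "k_sd": DEFAULT_K_SD,
    "gain_cutoff": DEFAULT_GAIN_CUTOFF,
    "loss_cutoff": DEFAULT_LOSS_CUTOFF,
    "penalty": None,
    "min_segment_probes": DEFAULT_MIN_SEGMENT_PROBES,
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    return cfg


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            report["stages"][name] = {}
            return report["stages"][name]

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report["stages"][name]["seconds"] = round(dt, 3)
            if exc is not None:
                report["stages"][name]["error"] = str(exc)
                log.error("stage %s failed after %.2fs: %s", name, dt, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: str | Path | Mapping[str, Any], out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "lactodim_results"))
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {
        "package": "lactodim",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "thresholds": thresholds,
        "stages": {},
    }

    with _stage(report, "simulate") as blk:
        if "inputs" in config:
            inputs = config["inputs"]
            cohort = read_sample_sheet(inputs["sample_sheet"])
            annotation = read_annotation(inputs["annotation"])
            expr = read_expression(
                inputs["expression"],
                control_prefix=inputs.get("control_prefix", "NEG_"),
                probe_map=inputs.get("probe_map"),
            )
            cn = read_copy_number(inputs["copy_number"]) if "copy_number" in inputs else None
            blk["source"] = "files"
        else:
            sim_cfg = SimulationConfig(seed=seed, **(config.get("simulate") or {}))
            cohort, annotation, expr, cn = simulate_dataset(sim_cfg)
            write_sample_sheet(cohort, out / "sample_sheet.tsv")
            write_annotation(annotation, out / "annotation.tsv")
            write_expression(expr, out / "expression_raw.tsv")
            write_probe_map(expr, out / "probe_map.tsv")
            if cn is not None:
                write_copy_number(cn, out / "copy_number.tsv")
            blk["source"] = "simulation"
        blk["n_samples"] = len(cohort)
        blk["n_probes"] = len(expr.probe_ids)
        blk["n_genes"] = len(annotation)

    sex_of = {s.sample_id: s.sex for s in cohort}

    with _stage(report, "normalize") as blk:
        normalized = median_normalize(expr)
        detection = detection_call(normalized, k_sd=thresholds["k_sd"])
        log2m = log2_transform(normalized)
        write_expression(normalized, out / "expression_normalized.tsv")
        detection.present.to_csv(out / "detection_present.tsv", sep="\t")
        blk["present_fraction"] = round(detection.present_fraction(), 4)

    with _stage(report, "de") as blk:
        de_results = select_deregulated(
            log2m, cohort, alpha=thresholds["alpha"], fc_min=thresholds["fc_min"],
            detection=detection,
        )
        df = results_frame(de_results)
        chrom_of = {a.symbol: a.chromosome for a in annotation}
        df.insert(1, "chromosome", df["symbol"].map(chrom_of))
        df.to_csv(out / "de_results.tsv", sep="\t", index=False)
        total, up, down = deregulated_counts(de_results)
        blk.update({"tested_genes": len(de_results), "deregulated": total,
                    "up": up, "down": down})

    with _stage(report, "chrom_enrich") as blk:
        dereg_symbols = [r.symbol for r in de_results if r.deregulated]
        if not dereg_symbols:
            blk["skipped"] = "no deregulated genes"
            ranked, median = [], float("nan")
        else:
            rows = delta_statistic(dereg_symbols, annotation, chromosomes="autosomes")
            ranked, median = rank_by_median_distance(rows)
            enrichment_frame(ranked, median).to_csv(
                out / "chromosome_enrichment.tsv", sep="\t", index=False
            )
            blk["median_delta_percent"] = round(median, 2)
            blk["top_chromosome"] = ranked[0].chromosome

    segments_called: list = []
    with _stage(report, "cna_segment") as blk:
        if cn is None:
            blk["skipped"] = "no copy-number input"
        else:
            segments = segment_all(cn, penalty=thresholds["penalty"],
                                   min_probes=thresholds["min_segment_probes"])
            segments = assign_arms(segments, arm_intervals_from_annotation(annotation))
            segments_called = call_segments(
                segments, sex_of,
                gain_cutoff=thresholds["gain_cutoff"],
                loss_cutoff=thresholds["loss_cutoff"],
            )
            write_seg(segments_called, out / "segments.seg", sample_sex=sex_of)
            write_segment_calls(segments_called, out / "segment_calls.tsv")
            rec = recurrence_by_group(
                segments_called, cohort,
                groups={"aggressive_male": "aggressive_male", "aggressive": "aggressive"},
                targets=["19p", "11"],
            )
            recurrence_frame(rec).to_csv(out / "recurrence.tsv", sep="\t", index=False)
            blk["n_segments"] = len(segments_called)
            blk["gains"] = sum(1 for s in segments_called if s.call == "gain")
            blk["losses"] = sum(1 for s in segments_called if s.call == "loss")

    with _stage(report, "integrate") as blk:
        if not segments_called:
            blk["skipped"] = "no called segments"
            candidates = []
        else:
            candidates = gained_region_candidates(
                de_results, segments_called, annotation, cohort,
                subgroup=config.get("integration_subgroup", "male"),
                min_samples=int(config.get("integration_min_samples", 1)),
                alpha=thresholds["alpha"], fc_min=thresholds["fc_min"],
            )
            candidates_frame(candidates).to_csv(out / "candidates.tsv", sep="\t", index=False)
            blk["n_candidates"] = len(candidates)
            blk["candidates"] = [c.symbol for c in candidates]
        dereg_df = pd.DataFrame(
            [(r.symbol, r.fold_change, r.p_value) for r in de_results if r.deregulated],
            columns=["symbol", "fold_change", "p_value"],
        )
        onc, pit = datasets.category_maps()
        cross = category_crosstab(dereg_df, onc, pit)
        cross.to_csv(out / "category_crosstab.tsv", sep="\t", index=False)
        blk["cross_subset"] = int(cross["in_cross_subset"].sum())

    with _stage(report, "correlate") as blk:
        corr_cfg = config.get("correlate") or {}
        anchor = corr_cfg.get("anchor", "CTAG2")
        panel = corr_cfg.get("panel", ["ADAMTS6", "AURKB", "CCNB1", "CENPE", "PTTG1"])
        gene_symbols = set(expr.probe_to_gene.values())
        if anchor in gene_symbols and set(panel) <= gene_symbols:
            rows = []
            for grp in ("female", "male"):
                for cr in pearson_panel(log2m, cohort, anchor, panel, group=grp):
                    rows.append((cr.gene_a, cr.gene_b, cr.group,
                                 round(cr.pearson_r, 4), cr.p_value, cr.n))
            pd.DataFrame(rows, columns=["gene_a", "gene_b", "group", "pearson_r",
                                        "p_value", "n"]).to_csv(
                out / "correlations.tsv", sep="\t", index=False)
            blk["anchor"] = anchor
            blk["n_pairs"] = len(rows)
        else:
            blk["skipped"] = "anchor/panel genes not in matrix"

    with _stage(report, "summarize") as blk:
        summary = cohort_table(cohort)
        summary_frame(summary).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        blk["n_by_sex"] = summary.n
        ir = [s.era_ir_score for s in cohort]
        if "ESR1" in set(expr.probe_to_gene.values()) and all(v is not None for v in ir):
            from .de import _collapse_genes

            esr1 = _collapse_genes(log2m).loc["ESR1", [s.sample_id for s in cohort]]
            cr = era_esr1_correlation(ir, esr1.to_numpy())
            blk["era_esr1_pearson_r"] = round(cr.pearson_r, 4)
            blk["era_esr1_p_value"] = cr.p_value

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
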