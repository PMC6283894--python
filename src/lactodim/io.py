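"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV.  Expression matrices are probes × samples
with a header row of sample ids; the sample sheet, gene annotation and
probe-level copy-number tables are column-named TSVs described in the README.
Segments are written in the IGV SEG dialect (Segment_Mean is the log2 ratio
of mean copies over the germline baseline).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CohortError,
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    ParseError,
    PipelineError,
    SampleRecord,
    Segment,
    check_annotation,
    check_cohort,
    normalize_chromosome,
    sex_baseline_copies,
)

log = logging.getLogger(__name__)

DEFAULT_CONTROL_PREFIX = "NEG_"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc


def read_expression(
    path: str | Path,
    control_prefix: str = DEFAULT_CONTROL_PREFIX,
    probe_map: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a raw probe × sample intensity TSV.

    Probes whose id starts with ``control_prefix`` become the negative-control
    set.  ``probe_map``, if given, is a two-column TSV (probe_id, symbol)
    attaching probes to gene symbols.
    """
    df = _read_tsv(path, index_col=0)
    if df.shape[1] < 2:
        raise CohortError(f"{path}: need at least 2 samples, found {df.shape[1]}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate probe ids {dups[:5]}")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        if bad:
            raise ParseError(f"{path}: non-numeric value at probe {bad[0]!r}, sample {col!r}")
    df = df.astype(float)
    df.index = df.index.astype(str)

    controls = frozenset(p for p in df.index if p.startswith(control_prefix))
    if not controls:
        log.warning("%s: no probes with control prefix %r", path, control_prefix)

    mapping: dict[str, str] = {}
    if probe_map is not None:
        pm = _read_tsv(probe_map, dtype=str)
        if not {"probe_id", "symbol"} <= set(pm.columns):
            raise ParseError(f"{probe_map}: probe map needs columns probe_id, symbol")
        mapping = dict(zip(pm["probe_id"], pm["symbol"]))
        mapping = {p: g for p, g in mapping.items() if p in set(df.index)}

    return ExpressionMatrix(
        values=df,
        probe_to_gene=mapping,
        negative_control_probes=controls,
        scale="raw",
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")


def write_probe_map(matrix: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(matrix.probe_to_gene), "symbol": list(matrix.probe_to_gene.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED-like gene annotation TSV: symbol, chromosome, arm, start, end."""
    df = _read_tsv(path, dtype=str)
    required = ["symbol", "chromosome", "arm", "start", "end"]
    if not set(required) <= set(df.columns):
        raise ParseError(f"{path}: annotation needs columns {required}")
    out: list[GeneAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                GeneAnnotation(
                    symbol=str(row.symbol),
                    chromosome=normalize_chromosome(str(row.chromosome)),
                    arm=str(row.arm),
                    start=int(row.start),
                    end=int(row.end),
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    check_annotation(out)
    return out


def write_annotation(annotation: Sequence[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.symbol, a.chromosome, a.arm, a.start, a.end) for a in annotation],
        columns=["symbol", "chromosome", "arm", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


_SHEET_COLUMNS = {
    "sample_id": str,
    "sex": str,
    "grade": str,
    "invasive": str,
    "era_ir_score": float,
    "tumor_size_mm": float,
    "clinical_behavior": str,
    "age_years": float,
    "mitotic_count": float,
    "ki67_percent": float,
    "p53_percent": float,
}


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return cast(value)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read the clinical sample sheet; missing optional fields stay missing."""
    df = _read_tsv(path, dtype=str).fillna("")
    required = ["sample_id", "sex", "grade", "invasive"]
    if not set(required) <= set(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {required}")
    out: list[SampleRecord] = []
    for i, row in df.iterrows():
        line = i + 2
        inv = row["invasive"].strip().lower()
        if inv not in ("true", "false", "1", "0", "yes", "no"):
            raise ParseError(f"{path}:{line}: invasive must be boolean-like, got {inv!r}")
        tags = tuple(t for t in row.get("clinical_behavior", "").split(",") if t)
        try:
            out.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    sex=row["sex"],
                    grade=row["grade"],
                    invasive=inv in ("true", "1", "yes"),
                    era_ir_score=_opt(row.get("era_ir_score", ""), lambda v: int(float(v))),
                    tumor_size_mm=_opt(row.get("tumor_size_mm", ""), float),
                    clinical_behavior=tags,
                    age_years=_opt(row.get("age_years", ""), float),
                    mitotic_count=_opt(row.get("mitotic_count", ""), float),
                    ki67_percent=_opt(row.get("ki67_percent", ""), float),
                    p53_percent=_opt(row.get("p53_percent", ""), float),
                )
            )
        except PipelineError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
    check_cohort(out)
    return out


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "sex": s.sex,
                "grade": s.grade,
                "invasive": str(s.invasive).lower(),
                "era_ir_score": "" if s.era_ir_score is None else s.era_ir_score,
                "tumor_size_mm": "" if s.tumor_size_mm is None else round(s.tumor_size_mm, 1),
                "clinical_behavior": ",".join(s.clinical_behavior),
                "age_years": "" if s.age_years is None else round(s.age_years, 1),
                "mitotic_count": "" if s.mitotic_count is None else round(s.mitotic_count, 1),
                "ki67_percent": "" if s.ki67_percent is None else round(s.ki67_percent, 2),
                "p53_percent": "" if s.p53_percent is None else round(s.p53_percent, 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_copy_number(path: str | Path) -> CopyNumberMatrix:
    """Read a probe-level copy-number TSV: probe_id, chromosome, position, samples..."""
    df = _read_tsv(path)
    required = ["probe_id", "chromosome", "position"]
    if not set(required) <= set(df.columns):
        raise ParseError(f"{path}: copy-number table needs columns {required}")
    df["chromosome"] = df["chromosome"].astype(str).map(normalize_chromosome)
    sample_cols = [c for c in df.columns if c not in required]
    probes = df[required].reset_index(drop=True)
    copies = df[sample_cols].astype(float).reset_index(drop=True)
    return CopyNumberMatrix(probes=probes, copies=copies)


def write_copy_number(cn: CopyNumberMatrix, path: str | Path) -> None:
    pd.concat([cn.probes.reset_index(drop=True), cn.copies.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def _check_non_overlapping(segments: Sequence[Segment]) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chromosome), []).append(seg)
    for (sid, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise PipelineError(
                    f"overlapping segments for sample {sid} chr{chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_seg(
    segments: Sequence[Segment],
    path: str | Path,
    sample_sex: dict[str, str] | None = None,
) -> None:
    """Write segments as an IGV-style SEG file.

    Segment_Mean is log2(mean_copies / baseline) where baseline is the
    germline copy number for the segment's chromosome and the sample's sex
    (autosomes: 2).  ``sample_sex`` is only needed when sex chromosomes are
    present.
    """
    _check_non_overlapping(segments)
    rows = []
    for seg in segments:
        sex = (sample_sex or {}).get(seg.sample_id, "F")
        baseline = sex_baseline_copies(seg.chromosome, sex)
        if not math.isfinite(baseline) or baseline <= 0:
            raise PipelineError(
                f"no baseline copy number for chr{seg.chromosome} in sample {seg.sample_id}"
            )
        ratio = seg.mean_copies / baseline
        mean = math.log2(ratio) if ratio > 0 else float("-inf")
        rows.append(
            (seg.sample_id, seg.chromosome, seg.start, seg.end, seg.n_probes, f"{mean:.6f}")
        )
    pd.DataFrame(
        rows, columns=["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
    ).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path, sample_sex: dict[str, str] | None = None) -> list[Segment]:
    """Read a SEG file back into (uncalled) segments, inverting the log2 ratio."""
    df = _read_tsv(path, dtype={"Chromosome": str})
    out: list[Segment] = []
    for row in df.itertuples(index=False):
        chrom = normalize_chromosome(str(row.Chromosome))
        sex = (sample_sex or {}).get(str(row.Sample), "F")
        baseline = sex_baseline_copies(chrom, sex)
        out.append(
            Segment(
                sample_id=str(row.Sample),
                chromosome=chrom,
                start=int(row.Start),
                end=int(row.End),
                n_probes=int(row.Num_Probes),
                mean_copies=baseline * 2.0 ** float(row.Segment_Mean),
            )
        )
    return out


def write_segment_calls(segments: Sequence[Segment], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.chromosome, s.arm_label, s.start, s.end, s.n_probes,
             round(s.mean_copies, 6), s.call)
            for s in segments
        ],
        columns=["sample_id", "chromosome", "arm", "start", "end", "n_probes",
                 "mean_copies", "call"],
    ).to_csv(path, sep="\t", index=False)
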