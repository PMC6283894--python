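"""Cohort description tables and the ERα/ESR1 correlation.

The cohort table mirrors the conventional clinical summary: per sex, the
number of samples, mean ± standard error (and median) for continuous
variables, and count (percentage of the sex group) for categorical ones.
Missing values are excluded from their own variable's denominator only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .integrate import pearson_with_p
from .model import CohortError, CorrelationResult, PipelineError, SampleRecord

_CONTINUOUS = (
    ("age_years", "Age (years)"),
    ("tumor_size_mm", "Tumor size (mm)"),
    ("era_ir_score", "ERα expression (IR score)"),
    ("mitotic_count", "Mitotic count"),
    ("ki67_percent", "Ki-67 (%)"),
    ("p53_percent", "p53 (%)"),
)

_SIZE_BINS = (("<10 mm", 0.0, 10.0), ("10-40 mm", 10.0, 40.0), (">40 mm", 40.0, math.inf))
_GRADE_ROWS = ("1a", "1b", "2a", "2b")  # 2b->3 tallied with 2b, as reclassified 2b


@dataclass
class CohortSummary:
    """Per-sex summary rows; raw precision kept, rounding at serialization."""

    n: dict[str, int]
    continuous: dict[str, dict[str, tuple[float | None, float | None, float | None, int]]]
    categorical: dict[str, dict[str, tuple[int, float]]]


def _mean_se_median(values: list[float]) -> tuple[float | None, float | None, float | None, int]:
    if not values:
        return None, None, None, 0
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    med = float(np.median(arr))
    se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
    return mean, se, med, len(arr)


def cohort_table(samples: Sequence[SampleRecord]) -> CohortSummary:
    """Sex-stratified clinical summary of the cohort."""
    if not samples:
        raise CohortError("empty cohort")
    sexes = sorted({s.sex for s in samples}, reverse=True)  # F then M? keep M/F order
    sexes = [sx for sx in ("F", "M") if any(s.sex == sx for s in samples)]
    n = {sx: sum(1 for s in samples if s.sex == sx) for sx in sexes}

    continuous: dict[str, dict] = {}
    for attr, label in _CONTINUOUS:
        continuous[label] = {
            sx: _mean_se_median(
                [getattr(s, attr) for s in samples
                 if s.sex == sx and getattr(s, attr) is not None]
            )
            for sx in sexes
        }

    categorical: dict[str, dict] = {}

    def add_cat(label: str, predicate) -> None:
        categorical[label] = {}
        for sx in sexes:
            grp = [s for s in samples if s.sex == sx]
            count = sum(1 for s in grp if predicate(s))
            categorical[label][sx] = (count, 100.0 * count / len(grp))

    add_cat("Invasive tumors", lambda s: s.invasive)
    for label, lo, hi in _SIZE_BINS:
        add_cat(
            f"Tumor size {label}",
            lambda s, lo=lo, hi=hi: s.tumor_size_mm is not None and lo <= s.tumor_size_mm < hi,
        )
    for grade in _GRADE_ROWS:
        add_cat(
            f"Grade {grade}",
            lambda s, g=grade: s.grade == g or (g == "2b" and s.grade == "2b->3"),
        )
    add_cat("Metastasis", lambda s: "metastasis" in s.clinical_behavior)
    return CohortSummary(n=n, continuous=continuous, categorical=categorical)


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Display table: mean ± SE (median) strings, integer percentages."""
    rows = []
    for label, per_sex in summary.continuous.items():
        row = {"variable": label}
        for sx, (mean, se, med, k) in per_sex.items():
            if mean is None:
                cell = ""
            elif se is None:
                cell = f"{mean:.1f} (n={k}, SE n/a)"
            else:
                cell = f"{mean:.1f} ± {se:.1f} ({med:.1f})"
            row[sx] = cell
        rows.append(row)
    for label, per_sex in summary.categorical.items():
        row = {"variable": f"{label}, n (%)"}
        for sx, (count, pct) in per_sex.items():
            row[sx] = f"{count} ({round(pct)})"
        rows.append(row)
    header = {"variable": "n"}
    for sx, k in summary.n.items():
        header[sx] = str(k)
    return pd.DataFrame([header, *rows])


def era_esr1_correlation(
    ir_scores: Sequence[float], esr1_log2: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of ERα immunoreactivity with ESR1 log2 expression."""
    if len(ir_scores) != len(esr1_log2):
        raise PipelineError("IR scores and ESR1 values differ in length")
    pairs = [
        (float(a), float(b))
        for a, b in zip(ir_scores, esr1_log2)
        if a is not None and b is not None and math.isfinite(float(a)) and math.isfinite(float(b))
    ]
    if len(pairs) < 3:
        raise CohortError("need at least 3 paired observations")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult("ERa_IR", "ESR1", "all", float("nan"), float("nan"),
                                 len(pairs), degenerate=True)
    r, p = pearson_with_p(x, y)
    return CorrelationResult("ERa_IR", "ESR1", "all", r, p, len(pairs))
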