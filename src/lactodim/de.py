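"""Two-group differential expression with a signed fold-change convention.

The contrast is male vs female (group A = M, group B = F).  Per gene, probes
are collapsed by averaging log2 intensities, a two-sided equal-variance
Student's t-test gives the p-value, and the fold change is sign-folded:
with r = 2^(mean_A − mean_B), the reported value is r when r ≥ 1 and −1/r
otherwise, so magnitudes are symmetric about ±1 and a value in (−1, 1) can
never occur.  A gene is deregulated when p ≤ α and |fold change| ≥ fc_min
(defaults 0.05 and 2); no multiple-testing correction enters that call,
though a Benjamini–Hochberg column is available for reporting.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CohortError,
    DEResult,
    ExpressionMatrix,
    PipelineError,
    SampleRecord,
)
from .preprocess import DetectionResult

DEFAULT_ALPHA = 0.05
DEFAULT_FC_MIN = 2.0


def signed_fold_change(mean_a_log2: float, mean_b_log2: float) -> float:
    """Sign-folded linear ratio of two log2 group means (never in (−1, 1))."""
    if not (math.isfinite(mean_a_log2) and math.isfinite(mean_b_log2)):
        raise PipelineError("fold change requires finite group means")
    r = 2.0 ** (mean_a_log2 - mean_b_log2)
    return r if r >= 1.0 else -1.0 / r


def student_t(group_a: Sequence[float], group_b: Sequence[float],
              welch: bool = False) -> tuple[float, bool]:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    Returns ``(p, degenerate)``; ``degenerate`` is True when both groups are
    constant and equal, in which case p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs at least 2 values for the t-test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0, True
        return 0.0, True
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue), False


def _collapse_genes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean log2 intensity per gene per sample, over that gene's probes."""
    mapped = [p for p in matrix.values.index if p in matrix.probe_to_gene]
    if not mapped:
        raise PipelineError("matrix has no probes mapped to genes")
    sub = matrix.values.loc[mapped]
    genes = pd.Index([matrix.probe_to_gene[p] for p in mapped], name="symbol")
    return sub.groupby(genes).mean()


def _gene_presence(matrix: ExpressionMatrix, detection: DetectionResult) -> pd.DataFrame:
    """A gene is present in a sample iff any of its probes is present there."""
    mapped = [p for p in matrix.values.index if p in matrix.probe_to_gene]
    genes = pd.Index([matrix.probe_to_gene[p] for p in mapped], name="symbol")
    return detection.present.loc[mapped].groupby(genes).any()


def _split_sexes(
    samples: Sequence[SampleRecord], sample_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    by_id = {s.sample_id: s for s in samples}
    males = [sid for sid in sample_ids if sid in by_id and by_id[sid].sex == "M"]
    females = [sid for sid in sample_ids if sid in by_id and by_id[sid].sex == "F"]
    if len(males) < 2 or len(females) < 2:
        raise CohortError(
            f"sex contrast needs >= 2 samples per group, got {len(males)} M / {len(females)} F"
        )
    return males, females


def select_deregulated(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleRecord],
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
    detection: DetectionResult | None = None,
    welch: bool = False,
) -> list[DEResult]:
    """Per-gene male-vs-female differential expression over the whole cohort.

    Genes absent (below the detection threshold) in every sample are dropped
    before testing; genes detected in at least one sample are all tested.
    """
    if matrix.scale != "log2":
        raise PipelineError(f"select_deregulated expects a log2 matrix, got {matrix.scale}")
    genes = _collapse_genes(matrix)
    if detection is not None:
        presence = _gene_presence(matrix, detection)
        keep = presence.any(axis=1)
        genes = genes.loc[keep.index[keep].intersection(genes.index)]
    males, females = _split_sexes(samples, matrix.sample_ids)

    a = genes[males].to_numpy()
    b = genes[females].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0)
    equal = degenerate & (mean_a == mean_b)
    pvals = np.where(equal, 1.0, np.where(degenerate & ~equal, 0.0, pvals))

    out: list[DEResult] = []
    for i, symbol in enumerate(genes.index):
        fc = signed_fold_change(mean_a[i], mean_b[i])
        dereg = bool(pvals[i] <= alpha and abs(fc) >= fc_min)
        direction = "none"
        if dereg:
            direction = "up" if fc >= fc_min else "down"
        out.append(
            DEResult(
                symbol=str(symbol),
                mean_log2_a=float(mean_a[i]),
                mean_log2_b=float(mean_b[i]),
                fold_change=float(fc),
                p_value=float(pvals[i]),
                deregulated=dereg,
                direction=direction,
                degenerate=bool(degenerate[i]),
            )
        )
    return out


def deregulated_counts(results: Sequence[DEResult]) -> tuple[int, int, int]:
    """(total deregulated, up, down) over a result list."""
    up = sum(1 for r in results if r.direction == "up")
    down = sum(1 for r in results if r.direction == "down")
    return up + down, up, down


def subgroup_contrast(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleRecord],
    gene: str,
    include: Callable[[SampleRecord], bool] = lambda s: True,
    welch: bool = False,
) -> tuple[float, float]:
    """Signed fold change and p-value for one gene on a filtered cohort."""
    if matrix.scale != "log2":
        raise PipelineError(f"subgroup_contrast expects a log2 matrix, got {matrix.scale}")
    genes = _collapse_genes(matrix)
    if gene not in genes.index:
        raise PipelineError(f"gene {gene!r} not present in the matrix")
    kept = [s for s in samples if include(s) and s.sample_id in matrix.sample_ids]
    males = [s.sample_id for s in kept if s.sex == "M"]
    females = [s.sample_id for s in kept if s.sex == "F"]
    if len(males) < 2 or len(females) < 2:
        raise CohortError("subgroup predicate leaves fewer than 2 samples in a group")
    a = genes.loc[gene, males].to_numpy(dtype=float)
    b = genes.loc[gene, females].to_numpy(dtype=float)
    p, _ = student_t(a, b, welch=welch)
    return signed_fold_change(float(a.mean()), float(b.mean())), p


def results_frame(results: Sequence[DEResult], with_fdr: bool = True) -> pd.DataFrame:
    """Tabular view of DE results, optionally with a BH-FDR column."""
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "deregulated": [r.deregulated for r in results],
            "direction": [r.direction for r in results],
        }
    )
    if with_fdr and len(df):
        df["fdr_bh"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df
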