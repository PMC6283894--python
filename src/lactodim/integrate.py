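"""Transcriptome × copy-number integration and correlation panels.

Three operations: intersecting a subgroup's recurrently gained regions with
its upregulated genes (candidate genes sitting on gained DNA), Pearson
correlation of an anchor gene against a marker panel within a sample group,
and cross-tabulation of a gene list against two user-supplied category maps
(e.g. oncology processes vs pituitary functions), keeping the genes marked
in at least one category of each map.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEFAULT_ALPHA, DEFAULT_FC_MIN, _collapse_genes
from .model import (
    CohortError,
    DEResult,
    ExpressionMatrix,
    GeneAnnotation,
    IntegrationCandidate,
    PipelineError,
    Predicate,
    SampleRecord,
    Segment,
    resolve_predicate,
)

log = logging.getLogger(__name__)


def gained_region_candidates(
    de_results: Sequence[DEResult],
    segments: Sequence[Segment],
    annotation: Sequence[GeneAnnotation],
    samples: Sequence[SampleRecord],
    subgroup: str | Predicate = "male",
    min_samples: int = 1,
    alpha: float = DEFAULT_ALPHA,
    fc_min: float = DEFAULT_FC_MIN,
) -> list[IntegrationCandidate]:
    """Genes upregulated in the subgroup whose interval overlaps a called gain.

    A gene qualifies when fold_change ≥ fc_min, p ≤ α, and its annotated
    interval overlaps (1-based inclusive, ≥ 1 bp) at least one called gain
    segment in at least ``min_samples`` distinct samples of the subgroup.
    Results are sorted by decreasing fold change.
    """
    pred = resolve_predicate(subgroup)
    members = {s.sample_id for s in samples if pred(s)}
    ann = {a.symbol: a for a in annotation}
    gains_by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        if seg.call == "gain" and seg.sample_id in members:
            gains_by_chrom.setdefault(seg.chromosome, []).append(seg)

    out: list[IntegrationCandidate] = []
    for r in de_results:
        if not (r.fold_change >= fc_min and r.p_value <= alpha):
            continue
        rec = ann.get(r.symbol)
        if rec is None:
            log.warning("gene %s has no annotation; skipped in integration", r.symbol)
            continue
        support = sorted(
            {
                seg.sample_id
                for seg in gains_by_chrom.get(rec.chromosome, ())
                if seg.start <= rec.end and seg.end >= rec.start
            }
        )
        if len(support) >= min_samples:
            out.append(
                IntegrationCandidate(
                    symbol=r.symbol,
                    chromosome=rec.chromosome,
                    arm=rec.arm,
                    fold_change=r.fold_change,
                    p_value=r.p_value,
                    supporting_samples=tuple(support),
                )
            )
    out.sort(key=lambda c: (-c.fold_change, c.symbol))
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value via the exact t transform (n−2 df)."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pearson_panel(
    matrix: ExpressionMatrix,
    samples: Sequence[SampleRecord],
    anchor: str,
    panel: Sequence[str],
    group: str | Predicate = "all",
    permutation: int = 0,
    seed: int = 0,
) -> list["CorrelationResult"]:
    """Pearson r (and p) of the anchor gene against each panel gene in a group.

    With ``permutation`` > 0 the p-value is replaced by a label-permutation
    estimate, useful at very small n.  Zero-variance genes are reported with
    NaN r and the degenerate flag set.
    """
    from .model import CorrelationResult

    if matrix.scale != "log2":
        raise PipelineError(f"pearson_panel expects a log2 matrix, got {matrix.scale}")
    genes = _collapse_genes(matrix)
    pred = resolve_predicate(group)
    label = group if isinstance(group, str) else getattr(group, "__name__", "custom")
    members = [s.sample_id for s in samples
               if pred(s) and s.sample_id in matrix.sample_ids]
    if len(members) < 3:
        raise CohortError(f"group {label!r} has fewer than 3 samples")
    for sym in [anchor, *panel]:
        if sym not in genes.index:
            raise PipelineError(f"gene {sym!r} not present in the matrix")

    x = genes.loc[anchor, members].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for sym in panel:
        y = genes.loc[sym, members].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            out.append(CorrelationResult(anchor, sym, label, float("nan"), float("nan"),
                                         len(members), degenerate=True))
            continue
        r, p = pearson_with_p(x, y)
        if permutation > 0:
            null = np.array([
                np.corrcoef(x, rng.permutation(y))[0, 1] for _ in range(permutation)
            ])
            p = float((np.sum(np.abs(null) >= abs(r)) + 1) / (permutation + 1))
        out.append(CorrelationResult(anchor, sym, label, r, p, len(members)))
    return out


def category_crosstab(
    gene_table: pd.DataFrame,
    oncology_map: Mapping[str, set[str]],
    pituitary_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Mark genes with category membership; flag the cross-list subset.

    ``gene_table`` needs columns symbol / fold_change / p_value.  The output
    adds one boolean column per category and ``in_cross_subset``: True for
    genes carrying at least one mark in *each* of the two maps.  Unmapped
    genes simply get empty marks.
    """
    if "symbol" not in gene_table.columns:
        raise PipelineError("gene table needs a 'symbol' column")
    df = gene_table.copy()
    onc_cols = list(oncology_map)
    pit_cols = list(pituitary_map)
    for cat, members in {**oncology_map, **pituitary_map}.items():
        df[cat] = df["symbol"].isin(members)
    df["in_cross_subset"] = df[onc_cols].any(axis=1) & df[pit_cols].any(axis=1)
    return df


def candidates_frame(candidates: Sequence[IntegrationCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.symbol, c.chromosome, c.arm, round(c.fold_change, 3), c.p_value,
             ",".join(c.supporting_samples))
            for c in candidates
        ],
        columns=["symbol", "chromosome", "arm", "fold_change", "p_value",
                 "supporting_samples"],
    )
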