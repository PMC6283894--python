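"""Per-chromosome enrichment of deregulated genes: the Δ statistic.

For chromosome λ,

    Δ(λ) = 100 · [ n_dereg(λ) / N_dereg  −  G(λ) / G_total ]

i.e. the chromosome's share of the deregulated gene list minus its share of
all annotated genes, in percentage points.  Both denominators run over the
*complete* annotation and deregulated set, so over all chromosomes the Δ
values sum to zero exactly; the conventional report restricts the rows to
autosomes (where the sum is generally non-zero, since sex-chromosome genes
stay in the denominators).

Chromosomes are then ranked by decreasing Δ and annotated with the distance
from the median Δ of the reported rows.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    AUTOSOMES,
    CHROMOSOMES,
    ChromosomeEnrichment,
    GeneAnnotation,
    PipelineError,
)


def delta_statistic(
    deregulated: Iterable[str],
    annotation: Sequence[GeneAnnotation],
    chromosomes: str | Sequence[str] = "autosomes",
) -> list[ChromosomeEnrichment]:
    """Δ per selected chromosome; full precision, rounding is for display only.

    ``chromosomes`` may be "autosomes" (default), "all", or an explicit
    sequence of bare chromosome tokens.  Selection filters the output rows
    only — the deregulated-set and annotation totals always cover everything.
    """
    dereg = set(deregulated)
    if not dereg:
        raise PipelineError("no deregulated genes: Δ statistic undefined")
    chrom_of = {a.symbol: a.chromosome for a in annotation}
    unknown = sorted(dereg - chrom_of.keys())
    if unknown:
        raise PipelineError(f"deregulated symbols missing from annotation: {unknown[:10]}")

    if chromosomes == "autosomes":
        selected: Sequence[str] = AUTOSOMES
    elif chromosomes == "all":
        selected = CHROMOSOMES
    else:
        selected = list(chromosomes)

    g_total = len(annotation)
    n_total = len(dereg)
    genes_per_chrom: dict[str, int] = {}
    for a in annotation:
        genes_per_chrom[a.chromosome] = genes_per_chrom.get(a.chromosome, 0) + 1
    dereg_per_chrom: dict[str, int] = {}
    for sym in dereg:
        c = chrom_of[sym]
        dereg_per_chrom[c] = dereg_per_chrom.get(c, 0) + 1

    rows = []
    for chrom in selected:
        n_d = dereg_per_chrom.get(chrom, 0)
        delta = 100.0 * (n_d / n_total - genes_per_chrom.get(chrom, 0) / g_total)
        rows.append(ChromosomeEnrichment(chromosome=chrom, n_deregulated=n_d,
                                         delta_percent=delta))
    return rows


def rank_by_median_distance(
    rows: Sequence[ChromosomeEnrichment],
) -> tuple[list[ChromosomeEnrichment], float]:
    """Sort rows by decreasing Δ and fill in the distance from the median Δ.

    The median is taken over the supplied rows (mean of the middle two for an
    even count).  Returns (ranked rows, median).
    """
    if not rows:
        raise PipelineError("cannot rank an empty enrichment table")
    median = float(np.median([r.delta_percent for r in rows]))
    ranked = sorted(rows, key=lambda r: (-r.delta_percent, r.chromosome))
    return [
        ChromosomeEnrichment(
            chromosome=r.chromosome,
            n_deregulated=r.n_deregulated,
            delta_percent=r.delta_percent,
            distance_from_median=abs(r.delta_percent - median),
        )
        for r in ranked
    ], median


def permutation_pvalues(
    deregulated: Iterable[str],
    annotation: Sequence[GeneAnnotation],
    n_permutations: int = 1000,
    seed: int = 0,
    chromosomes: str | Sequence[str] = "autosomes",
) -> pd.DataFrame:
    """Optional resampling extension (not part of the replicated analysis).

    Permutes the deregulated-set labels over the annotation and reports, per
    chromosome, the fraction of permutations with Δ at least as extreme
    (one-sided, enrichment) as observed.
    """
    dereg = set(deregulated)
    observed = {r.chromosome: r.delta_percent
                for r in delta_statistic(dereg, annotation, chromosomes)}
    symbols = np.array([a.symbol for a in annotation])
    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in observed}
    for _ in range(n_permutations):
        perm = rng.choice(symbols, size=len(dereg), replace=False)
        for row in delta_statistic(perm, annotation, chromosomes):
            if row.delta_percent >= observed[row.chromosome]:
                hits[row.chromosome] += 1
    return pd.DataFrame(
        {
            "chromosome": list(observed),
            "delta_percent": [observed[c] for c in observed],
            "p_permutation": [(hits[c] + 1) / (n_permutations + 1) for c in observed],
        }
    )


def enrichment_frame(
    ranked: Sequence[ChromosomeEnrichment], median: float
) -> pd.DataFrame:
    """Display table: Δ rounded to 2 decimals, distances alongside."""
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in ranked],
            "n_deregulated": [r.n_deregulated for r in ranked],
            "delta_percent": [round(r.delta_percent, 2) for r in ranked],
            "distance_from_median": [round(r.distance_from_median, 4) for r in ranked],
            "median_delta_percent": round(median, 2),
        }
    )
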