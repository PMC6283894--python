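"""Small reference tables shipped with the package.

These are transcriptions of published summary tables for the 30-tumor
lactotroph cohort (and its 13-tumor CGH subset), not quantities the pipeline
computes: the per-chromosome deregulated-gene Δ table, the per-tumor
chromosome gain/loss event list, and the functional-category membership of
the 32 cross-list candidate genes.  They serve as inputs for arithmetic
recomputation and as category tables for the integration stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

ONCOLOGY_CATEGORIES = (
    "angiogenesis",
    "cell_growth_proliferation",
    "cell_death_survival",
    "cell_morphology",
    "cellular_movement",
    "development",
)
PITUITARY_CATEGORIES = (
    "endocrine_system",
    "estrogen_signaling",
    "pituitary_tumors",
    "sexual_dimorphism",
)


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def chromosome_deregulation() -> pd.DataFrame:
    """Per-autosome deregulated-gene counts and Δ percentages (22 rows)."""
    df = _load("chromosome_deregulation.tsv", dtype={"chromosome": str})
    df["n_deregulated"] = df["n_deregulated"].astype(int)
    df["delta_percent"] = df["delta_percent"].astype(float)
    return df


def cgh_cohort_events() -> pd.DataFrame:
    """Per-tumor chromosome/arm gain and loss tokens for the 13-tumor CGH cohort."""
    df = _load("cgh_cohort_events.tsv", dtype=str).fillna("")
    for col in ("gains", "losses"):
        df[col] = df[col].map(lambda s: tuple(t for t in s.split(",") if t))
    df["clinical_behavior"] = df["clinical_behavior"].map(
        lambda s: tuple(t for t in s.split(",") if t)
    )
    return df


def gene_categories() -> pd.DataFrame:
    """The 32 candidate genes with fold change, p-value and category marks."""
    df = _load("gene_categories.tsv", dtype={"chromosome": str})
    for col in ONCOLOGY_CATEGORIES + PITUITARY_CATEGORIES:
        df[col] = df[col].astype(bool)
    return df


def category_maps() -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """The oncology-process and pituitary-function category → gene-set maps."""
    df = gene_categories()
    onc = {c: set(df.loc[df[c], "symbol"]) for c in ONCOLOGY_CATEGORIES}
    pit = {c: set(df.loc[df[c], "symbol"]) for c in PITUITARY_CATEGORIES}
    return onc, pit
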