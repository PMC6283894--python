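"""Domain types shared by every stage of the pipeline.

The objects here are deliberately thin: plain dataclasses with validation in
``__post_init__`` (or a ``validate`` method for the container types), so that
readers, the simulator and the analysis stages all speak the same vocabulary
— samples, gene annotations, probe intensity matrices, copy-number segments.

Conventions fixed once, package-wide:

* genomic coordinates are 1-based and inclusive on both ends;
* chromosome tokens are bare ("1".."22", "X", "Y"), normalized from an
  optional "chr" prefix at parse time;
* sex is "M"/"F"; the clinicopathological grade is one of
  1a, 1b, 2a, 2b, 2b->3 (2b->3 marks a grade-2b tumor reclassified as
  malignant after metastasis during follow-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")
GRADES: tuple[str, ...] = ("1a", "1b", "2a", "2b", "2b->3")
#: grades counted as aggressive/malignant in group contrasts
AGGRESSIVE_GRADES: frozenset[str] = frozenset({"2b", "2b->3"})
SCALES: tuple[str, ...] = ("raw", "normalized", "log2")


class PipelineError(ValueError):
    """Base class for all validation and analysis errors raised here."""


class ParseError(PipelineError):
    """Malformed on-disk input (bad cell, unknown token, duplicate id)."""


class CohortError(PipelineError):
    """A cohort/contrast that cannot support the requested analysis."""


def normalize_chromosome(token: str) -> str:
    """Return the bare chromosome token, accepting an optional 'chr' prefix."""
    tok = token.strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok.upper() in ("X", "Y"):
        return tok.upper()
    if tok not in AUTOSOMES:
        raise ParseError(f"unknown chromosome token {token!r}")
    return tok


@dataclass
class SampleRecord:
    """One tumor sample with the clinical fields that drive group contrasts."""

    sample_id: str
    sex: str
    grade: str
    invasive: bool
    era_ir_score: int | None = None
    tumor_size_mm: float | None = None
    clinical_behavior: tuple[str, ...] = ()
    age_years: float | None = None
    mitotic_count: float | None = None
    ki67_percent: float | None = None
    p53_percent: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ParseError(f"sample {self.sample_id}: sex must be M or F, got {self.sex!r}")
        if self.grade not in GRADES:
            raise ParseError(f"sample {self.sample_id}: unknown grade {self.grade!r}")
        if self.grade == "2b->3" and "metastasis" not in self.clinical_behavior:
            raise PipelineError(
                f"sample {self.sample_id}: grade 2b->3 requires a 'metastasis' behavior tag"
            )
        if self.era_ir_score is not None and not 0 <= self.era_ir_score <= 12:
            raise PipelineError(
                f"sample {self.sample_id}: ERα IR score {self.era_ir_score} outside [0, 12]"
            )
        if self.tumor_size_mm is not None and self.tumor_size_mm <= 0:
            raise PipelineError(f"sample {self.sample_id}: tumor size must be positive")

    @property
    def aggressive(self) -> bool:
        return self.grade in AGGRESSIVE_GRADES


def check_cohort(samples: Sequence[SampleRecord]) -> None:
    """Validate cohort-level invariants (unique sample ids)."""
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            raise PipelineError(f"duplicate sample id {s.sample_id!r} in cohort")
        seen.add(s.sample_id)


# Common subgroup predicates, usable wherever a sample filter is expected.
Predicate = Callable[[SampleRecord], bool]

PREDICATES: dict[str, Predicate] = {
    "all": lambda s: True,
    "male": lambda s: s.sex == "M",
    "female": lambda s: s.sex == "F",
    "aggressive": lambda s: s.aggressive,
    "non_aggressive": lambda s: not s.aggressive,
    "aggressive_male": lambda s: s.aggressive and s.sex == "M",
    "aggressive_female": lambda s: s.aggressive and s.sex == "F",
}


def resolve_predicate(pred: str | Predicate) -> Predicate:
    if callable(pred):
        return pred
    try:
        return PREDICATES[pred]
    except KeyError:
        raise PipelineError(
            f"unknown group predicate {pred!r}; known: {sorted(PREDICATES)}"
        ) from None


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval: symbol, chromosome, arm, 1-based inclusive span."""

    symbol: str
    chromosome: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ParseError(f"{self.symbol}: unknown chromosome {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ParseError(f"{self.symbol}: arm must be p or q, got {self.arm!r}")
        if self.start > self.end:
            raise ParseError(f"{self.symbol}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ParseError(f"{self.symbol}: coordinates are 1-based, got start {self.start}")


def check_annotation(annotation: Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    """Validate symbol uniqueness; return a symbol -> record index."""
    index: dict[str, GeneAnnotation] = {}
    for rec in annotation:
        if rec.symbol in index:
            raise PipelineError(f"duplicate gene symbol {rec.symbol!r} in annotation")
        index[rec.symbol] = rec
    return index


def genes_per_chromosome(annotation: Sequence[GeneAnnotation]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in annotation:
        counts[rec.chromosome] = counts.get(rec.chromosome, 0) + 1
    return counts


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity matrix plus probe metadata.

    ``values`` is a DataFrame indexed by probe id with one column per sample.
    ``scale`` records where the matrix sits in the preprocessing chain.
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str] = field(default_factory=dict)
    negative_control_probes: frozenset[str] = frozenset()
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise PipelineError(f"unknown scale {self.scale!r}")
        self.negative_control_probes = frozenset(self.negative_control_probes)
        self.validate()

    def validate(self) -> None:
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise PipelineError("expression matrix contains non-finite values")
        if self.scale in ("raw", "normalized") and (vals < 0).any():
            raise PipelineError("intensities must be non-negative")
        probes = set(self.values.index)
        stray = self.negative_control_probes - probes
        if stray:
            raise PipelineError(f"control probes absent from matrix: {sorted(stray)[:5]}")
        overlap = self.negative_control_probes & self.probe_to_gene.keys()
        if overlap:
            raise PipelineError(
                f"probes mapped to genes cannot be negative controls: {sorted(overlap)[:5]}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ParseError(f"duplicate probe ids: {dups[:5]}")
        if self.scale == "normalized":
            med = self.values.median(axis=0)
            bad = med.index[(med - 1.0).abs() > 1e-9].tolist()
            if bad:
                raise PipelineError(f"normalized samples with median != 1: {bad[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def gene_probes(self) -> list[str]:
        return [p for p in self.values.index if p in self.probe_to_gene]

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            probe_to_gene=self.probe_to_gene,
            negative_control_probes=self.negative_control_probes,
            scale=scale,
        )


@dataclass
class CopyNumberMatrix:
    """Per-probe copy-number estimates: probe metadata plus sample columns.

    ``probes`` has columns probe_id / chromosome / position; ``copies`` is
    indexed identically with one column per sample.  Female Y probes are NaN
    (the chromosome is absent, not at zero copies).
    """

    probes: pd.DataFrame
    copies: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chromosome", "position"}
        if not required <= set(self.probes.columns):
            raise PipelineError(f"probe table needs columns {sorted(required)}")
        if len(self.probes) != len(self.copies):
            raise PipelineError("probe table and copy table differ in length")
        for chrom, grp in self.probes.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise PipelineError(f"probe positions not strictly increasing on chr{chrom}")

    @property
    def sample_ids(self) -> list[str]:
        return self.copies.columns.tolist()

    def profile(self, sample_id: str, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        """Positions and copy values for one sample on one chromosome (NaN dropped)."""
        mask = (self.probes["chromosome"] == chromosome).to_numpy()
        pos = self.probes.loc[mask, "position"].to_numpy()
        vals = self.copies.loc[mask, sample_id].to_numpy(dtype=float)
        keep = np.isfinite(vals)
        return pos[keep], vals[keep]


@dataclass
class Segment:
    """A run of consecutive copy-number probes sharing one mean level."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    mean_copies: float
    call: str = "uncalled"
    arm_label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PipelineError("segment start > end")
        if self.n_probes < 1:
            raise PipelineError("segment must cover at least one probe")
        if self.call not in ("gain", "loss", "neutral", "uncalled"):
            raise PipelineError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class DEResult:
    """Per-gene two-group differential-expression outcome (group A vs B)."""

    symbol: str
    mean_log2_a: float
    mean_log2_b: float
    fold_change: float
    p_value: float
    deregulated: bool
    direction: str  # up / down / none
    degenerate: bool = False


@dataclass(frozen=True)
class ChromosomeEnrichment:
    """One per-chromosome row of the deregulated-gene Δ statistic."""

    chromosome: str
    n_deregulated: int
    delta_percent: float
    distance_from_median: float = float("nan")


@dataclass(frozen=True)
class RecurrenceSummary:
    """How many samples of a group carry a given gain/loss on a chrom or arm."""

    group: str
    target: str  # chromosome or chromosome-arm token, e.g. "11" or "19p"
    event: str  # gain / loss
    count: int
    denominator: int

    def __post_init__(self) -> None:
        if self.event not in ("gain", "loss"):
            raise PipelineError(f"event must be gain or loss, got {self.event!r}")
        if self.count > self.denominator:
            raise PipelineError("recurrence count exceeds group size")


@dataclass(frozen=True)
class IntegrationCandidate:
    """A gene both upregulated in a subgroup and sitting on a recurrent gain."""

    symbol: str
    chromosome: str
    arm: str
    fold_change: float
    p_value: float
    supporting_samples: tuple[str, ...]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of two variables within a sample group."""

    gene_a: str
    gene_b: str
    group: str
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool = False


def sex_baseline_copies(chromosome: str, sex: str) -> float:
    """Expected germline copy number of ``chromosome`` for a sample of ``sex``.

    Autosomes are diploid; males carry one X and one Y; females carry two X
    and no Y (returned as NaN so Y probes drop out of female profiles).
    """
    if chromosome in AUTOSOMES:
        return 2.0
    if chromosome == "X":
        return 1.0 if sex == "M" else 2.0
    if chromosome == "Y":
        return 1.0 if sex == "M" else math.nan
    raise PipelineError(f"unknown chromosome {chromosome!r}")
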