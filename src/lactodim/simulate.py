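"""Synthetic cohorts, expression arrays and copy-number profiles.

The generator plants the statistical structure the downstream stages are
designed to detect, at the scale of the study cohort it emulates: 20 male and
10 female prolactinoma samples, a ~55,000-probe single-channel expression
array with 100 negative-control probes, 140 sex-differential genes (120 up
in men, 20 down) spread over the genome with chromosome 19 the most enriched,
group-restricted gene–gene correlations around the CTAG2 aggressiveness
panel, an ERα-immunoreactivity/ESR1-mRNA latent correlation, and segmental
copy-number events (a 19p gain confined to aggressive male samples, a
chromosome-11 loss in aggressive samples of both sexes).

Everything is deterministic under ``(seed, config)``; each generator stage
derives its own child seed so stages can be re-run independently.

Noise model: homoscedastic Gaussian in log2 space for expression (so the
power of the downstream t-test/fold-change filter is analytically
checkable), Gaussian in copy-number space for the SNP-array emulation.
Planted differential genes anchor their lower-expressed group at the
gene-probe baseline with the higher group above it, so planted signal stays
detectable regardless of effect size.  Negative-control probes are
log2-normal, centered three between-gene SDs below the baseline, which
separates signal from background under the default mean + 2·SD detection
threshold by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AUTOSOMES,
    CohortError,
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    PipelineError,
    SampleRecord,
    check_annotation,
    resolve_predicate,
    sex_baseline_copies,
)

# Approximate chromosome lengths and centromere positions (Mb); used to lay
# out synthetic gene and probe coordinates and to define p/q arm intervals.
CHROM_MB: dict[str, tuple[float, float]] = {
    "1": (249, 125), "2": (243, 93), "3": (198, 91), "4": (190, 50),
    "5": (182, 48), "6": (171, 60), "7": (159, 60), "8": (145, 45),
    "9": (138, 49), "10": (134, 40), "11": (135, 53), "12": (133, 36),
    "13": (114, 18), "14": (107, 17), "15": (102, 19), "16": (90, 37),
    "17": (83, 25), "18": (80, 18), "19": (59, 26), "20": (64, 28),
    "21": (47, 13), "22": (51, 15), "X": (155, 61), "Y": (57, 10),
}

#: default number of annotated genes per chromosome (rough protein-coding census)
DEFAULT_GENES_PER_CHROMOSOME: dict[str, int] = {
    "1": 2000, "2": 1200, "3": 1100, "4": 750, "5": 900, "6": 1000,
    "7": 900, "8": 700, "9": 780, "10": 730, "11": 1300, "12": 1000,
    "13": 320, "14": 600, "15": 600, "16": 850, "17": 1150, "18": 270,
    "19": 1400, "20": 550, "21": 230, "22": 440, "X": 850, "Y": 60,
}

# Named genes the defaults refer to, with chromosome and arm.
NAMED_GENES: dict[str, tuple[str, str]] = {
    # autosomal candidates from the 32-gene cross-category list
    "BHLHE41": ("12", "p"), "CDK8": ("13", "q"), "CHL1": ("3", "p"),
    "ENC1": ("5", "q"), "ERBIN": ("5", "q"), "ETS2": ("21", "q"),
    "EXT1": ("8", "q"), "EZR": ("6", "q"), "FOXA1": ("14", "q"),
    "FOXQ1": ("6", "p"), "GADD45G": ("9", "q"), "ISL1": ("5", "q"),
    "LTBP1": ("2", "p"), "MYH7": ("14", "q"), "NMU": ("4", "q"),
    "OBSCN": ("1", "q"), "PITX1": ("5", "q"), "PPID": ("4", "q"),
    "PTGS1": ("9", "q"), "PTPRZ1": ("7", "q"), "ROBO1": ("3", "p"),
    "SLC12A4": ("16", "q"), "SLC2A11": ("22", "q"), "SNCB": ("5", "q"),
    "SOSTDC1": ("7", "p"), "STAP2": ("19", "p"), "TSPAN8": ("12", "q"),
    # chromosome 19p genes on the recurrently gained arm
    "CRB3": ("19", "p"), "FAM138F": ("19", "p"), "MATK": ("19", "p"),
    # X-linked candidates
    "CTAG2": ("X", "q"), "FGF13": ("X", "q"), "VEGFD": ("X", "p"),
    "SLC6A8": ("X", "q"), "DDX3P1": ("X", "q"), "FRMPD4": ("X", "p"),
    "TMEM35A": ("X", "q"),
    # Y-linked male-specific genes
    "DDX3Y": ("Y", "q"), "EIF1AY": ("Y", "q"), "KDM5D": ("Y", "q"),
    "NLGN4Y": ("Y", "q"), "PRKY": ("Y", "p"), "RPS4Y1": ("Y", "p"),
    "RPS4Y2": ("Y", "q"), "TTTY14": ("Y", "q"), "TXLNGY": ("Y", "q"),
    "USP9Y": ("Y", "q"), "ZFY": ("Y", "p"),
    # estrogen receptor gene and the CTAG2 aggressiveness panel
    "ESR1": ("6", "q"), "ADAMTS6": ("5", "q"), "AURKB": ("17", "p"),
    "CCNB1": ("5", "q"), "CENPE": ("4", "q"), "PTTG1": ("5", "q"),
}

# Signed fold changes (linear convention, |fc| >= 1) of the named planted
# differential genes: the 32 candidate genes with their reported values,
# the three extra 19p genes, and plausible magnitudes for the remaining
# X/Y-linked genes.
NAMED_PLANTED_FC: dict[str, float] = {
    "BHLHE41": 2.077, "CDK8": 2.599, "CHL1": 3.117, "CTAG2": 2.332,
    "ENC1": 2.023, "ERBIN": 2.008, "ETS2": 2.366, "EXT1": 2.181,
    "EZR": -2.199, "FGF13": 3.419, "FOXA1": 2.35, "FOXQ1": 5.758,
    "GADD45G": -2.656, "ISL1": 2.163, "KDM5D": 18.032, "LTBP1": 2.246,
    "MYH7": -4.706, "NMU": 3.336, "OBSCN": 2.596, "PITX1": 2.459,
    "PPID": 2.261, "PTGS1": 2.554, "PTPRZ1": 2.393, "ROBO1": 2.033,
    "SLC12A4": 3.348, "SLC2A11": 2.342, "SLC6A8": 2.577, "SNCB": 2.022,
    "SOSTDC1": 6.814, "STAP2": 2.122, "TSPAN8": 3.232, "VEGFD": 2.27,
    "CRB3": 2.4, "FAM138F": 2.1, "MATK": 2.9,
    "DDX3P1": 2.2, "FRMPD4": 2.1, "TMEM35A": 2.3,
    "DDX3Y": 8.0, "EIF1AY": 6.0, "NLGN4Y": 4.0, "PRKY": 3.0,
    "RPS4Y1": 12.0, "RPS4Y2": 5.0, "TTTY14": 4.0, "TXLNGY": 6.0,
    "USP9Y": 7.0, "ZFY": 5.0,
}

# Per-autosome planted-gene totals (named + filler) emulating the observed
# chromosomal distribution of the 140 deregulated genes.
AUTOSOME_PLANTED_TOTALS: dict[str, int] = {
    "19": 12, "3": 10, "2": 12, "5": 8, "13": 3, "9": 6, "8": 5, "16": 6,
    "7": 7, "1": 13, "11": 8, "4": 5, "6": 6, "14": 4, "21": 1, "18": 1,
    "20": 2, "17": 3, "12": 2, "22": 1, "15": 1, "10": 1,
}

# chromosomes receiving one down-regulated filler inside the totals above
_DOWN_FILLER_CHROMS = ("1", "2", "19", "11", "3", "7", "16", "8", "6", "9", "4", "5")
# five extra down-regulated fillers beyond the per-autosome totals, bringing
# the planted set to 140 genes (120 up / 20 down)
_EXTRA_DOWN_CHROMS = ("1", "2", "3", "5", "19")

# Group-restricted correlations of the CTAG2 anchor with its
# aggressiveness-marker panel (per-sex target Pearson r).
DEFAULT_PANEL_R: dict[str, tuple[float, float]] = {
    # gene: (r in tumors from women, r in tumors from men)
    "ADAMTS6": (0.32, 0.47),
    "AURKB": (0.24, 0.93),
    "CCNB1": (0.19, 0.87),
    "CENPE": (-0.02, 0.78),
    "PTTG1": (-0.15, 0.80),
}


@dataclass(frozen=True)
class PlantedGene:
    symbol: str
    log2_fc: float  # male-vs-female difference of group means in log2


@dataclass(frozen=True)
class PlantedSegment:
    chromosome: str
    arm: str | None  # None = whole chromosome
    copies: float
    samples: tuple[str, ...]


@dataclass(frozen=True)
class PlantedCorrelation:
    anchor: str
    partner: str
    group: str  # predicate name, e.g. "male"
    r: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise PipelineError(f"target correlation {self.r} outside [-1, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_male: int = 20
    n_female: int = 10
    n_probes: int = 55_000
    n_controls: int = 100
    genes_per_chromosome: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CHROMOSOME)
    )
    planted_de: Sequence[PlantedGene] | None = None  # None -> default 140-gene set
    noise_sd_log2: float = 0.25
    gene_spread_log2: float = 1.0  # between-gene baseline spread (log2)
    baseline_intensity_log2: float = 6.0
    control_sd_log2: float = 0.3
    control_offset_sds: float = 3.0  # controls centered this many gene-spread SDs below baseline
    sample_scale_sd_log2: float = 0.5  # per-array brightness factor removed by normalization
    planted_correlations: Sequence[PlantedCorrelation] | None = None
    era_esr1_r: float | None = 0.817  # latent ERα-IR / ESR1-mRNA correlation
    esr1_sd_log2: float = 0.7
    planted_segments: Sequence[PlantedSegment] | None = None  # None -> defaults
    cna_probes_per_chromosome: int = 120
    cna_noise_sd: float = 0.25
    grade_counts: Mapping[str, Mapping[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.genes_per_chromosome is None:
            self.genes_per_chromosome = dict(DEFAULT_GENES_PER_CHROMOSOME)
        if self.n_controls >= self.n_probes:
            raise PipelineError("n_controls must be smaller than n_probes")
        if self.noise_sd_log2 < 0 or self.control_sd_log2 <= 0:
            raise PipelineError("noise SDs must be non-negative (controls: positive)")


DEFAULT_GRADE_COUNTS: dict[str, dict[str, int]] = {
    "F": {"1a": 6, "1b": 1, "2a": 1, "2b": 2},
    "M": {"1a": 4, "1b": 1, "2a": 8, "2b": 5, "2b->3": 2},
}

_BEHAVIOR_BY_GRADE = {
    "2b->3": ("recurrences", "metastasis", "death"),
    "2b": ("recurrence",),
}

# mean/SD of the clinical continuous variables by sex (mean matches the
# emulated cohort; SD = reported standard error times sqrt(group n))
_CLINICAL = {
    "F": {"age": (35, 9.5), "size": (11, 3.2), "era": (7, 3.2),
          "mitoses": (1, 3.2), "ki67": (0.8, 1.6), "p53": (0.3, 0.3)},
    "M": {"age": (51, 9.0), "size": (27, 13.0), "era": (3, 4.5),
          "mitoses": (4, 4.5), "ki67": (2.5, 3.1), "p53": (0.6, 0.9)},
}


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _grades_for(sex: str, n: int, config: SimulationConfig,
                rng: np.random.Generator) -> list[str]:
    counts = (config.grade_counts or DEFAULT_GRADE_COUNTS).get(sex, {})
    if sum(counts.values()) == n:
        grades = [g for g, c in counts.items() for _ in range(c)]
    else:  # cohort size differs from the emulated margins: sample proportionally
        base = DEFAULT_GRADE_COUNTS[sex]
        labels = list(base)
        probs = np.array([base[g] for g in labels], dtype=float)
        grades = list(rng.choice(labels, size=n, p=probs / probs.sum()))
    rng.shuffle(grades)
    return grades


def simulate_cohort(config: SimulationConfig) -> list[SampleRecord]:
    """Generate the clinical sample sheet of the emulated cohort."""
    if config.n_male < 1 or config.n_female < 1:
        raise CohortError("need at least one sample of each sex")
    rng = _rng(config, 1)
    samples: list[SampleRecord] = []
    for sex, n, prefix in (("M", config.n_male, "M"), ("F", config.n_female, "F")):
        grades = _grades_for(sex, n, config, rng)
        par = _CLINICAL[sex]
        for i, grade in enumerate(grades, start=1):
            era = int(np.clip(round(rng.normal(*par["era"])), 0, 12))
            samples.append(
                SampleRecord(
                    sample_id=f"{prefix}{i:02d}",
                    sex=sex,
                    grade=grade,
                    invasive=grade in ("2a", "2b", "2b->3"),
                    era_ir_score=era,
                    tumor_size_mm=float(np.clip(rng.normal(*par["size"]), 2.0, None)),
                    clinical_behavior=_BEHAVIOR_BY_GRADE.get(grade, ()),
                    age_years=float(np.clip(rng.normal(*par["age"]), 18.0, 90.0)),
                    mitotic_count=float(np.clip(rng.normal(*par["mitoses"]), 0.0, None)),
                    ki67_percent=float(np.clip(rng.normal(*par["ki67"]), 0.0, None)),
                    p53_percent=float(np.clip(rng.normal(*par["p53"]), 0.0, None)),
                )
            )
    return samples


def arm_interval(chromosome: str, arm: str) -> tuple[int, int]:
    """1-based inclusive bp interval of a chromosome arm in the synthetic layout."""
    length_mb, cen_mb = CHROM_MB[chromosome]
    cen = int(cen_mb * 1e6)
    if arm == "p":
        return 1, cen
    return cen + 1, int(length_mb * 1e6)


def build_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Deterministic synthetic gene annotation with the named genes placed."""
    annotation: list[GeneAnnotation] = []
    gene_length = 20_000
    for chrom, total in config.genes_per_chromosome.items():
        named_here = [s for s, (c, _) in NAMED_GENES.items() if c == chrom]
        by_arm: dict[str, list[str]] = {"p": [], "q": []}
        for sym in named_here:
            by_arm[NAMED_GENES[sym][1]].append(sym)
        for arm in ("p", "q"):
            lo, hi = arm_interval(chrom, arm)
            syms = sorted(by_arm[arm])
            for k, sym in enumerate(syms, start=1):
                start = lo + int((hi - lo) * k / (len(syms) + 1))
                annotation.append(GeneAnnotation(sym, chrom, arm, start, start + gene_length))
        n_fill = total - len(named_here)
        if n_fill < 0:
            raise PipelineError(f"chr{chrom}: gene count below number of named genes")
        length_mb, cen_mb = CHROM_MB[chrom]
        length = int(length_mb * 1e6)
        cen = int(cen_mb * 1e6)
        spacing = length // (n_fill + 1)
        for i in range(1, n_fill + 1):
            start = i * spacing
            arm = "p" if start <= cen else "q"
            annotation.append(
                GeneAnnotation(f"G{chrom}_{i:04d}", chrom, arm,
                               start, min(start + gene_length, length))
            )
    check_annotation(annotation)
    return annotation


def default_planted_de(annotation: Sequence[GeneAnnotation]) -> list[PlantedGene]:
    """The default 140-gene planted set: 120 up in men, 20 down.

    Named genes carry their reported fold changes; anonymous fillers complete
    the per-chromosome totals with magnitudes cycling over [2.46, 5.66]-fold
    so every planted gene clears the 2-fold filter with high power at the
    default noise level.  On chromosome 19 fillers are restricted to the q
    arm, keeping the gained p arm's upregulated genes exactly the four named
    candidates.
    """
    by_chrom_arm: dict[tuple[str, str], list[str]] = {}
    for rec in annotation:
        if rec.symbol.startswith("G"):
            by_chrom_arm.setdefault((rec.chromosome, rec.arm), []).append(rec.symbol)
    for syms in by_chrom_arm.values():
        syms.sort()

    planted = [
        PlantedGene(sym, math.copysign(math.log2(abs(fc)), fc))
        for sym, fc in NAMED_PLANTED_FC.items()
    ]
    named_per_chrom: dict[str, int] = {}
    for sym in NAMED_PLANTED_FC:
        c = NAMED_GENES[sym][0]
        named_per_chrom[c] = named_per_chrom.get(c, 0) + 1

    down_budget = {c: _DOWN_FILLER_CHROMS.count(c) + _EXTRA_DOWN_CHROMS.count(c)
                   for c in set(_DOWN_FILLER_CHROMS) | set(_EXTRA_DOWN_CHROMS)}
    counter = 0
    for chrom in AUTOSOMES:
        total = AUTOSOME_PLANTED_TOTALS.get(chrom, 0) + _EXTRA_DOWN_CHROMS.count(chrom)
        n_fill = total - named_per_chrom.get(chrom, 0)
        if chrom == "19":
            pool = by_chrom_arm.get((chrom, "q"), [])
        else:
            pool = by_chrom_arm.get((chrom, "p"), []) + by_chrom_arm.get((chrom, "q"), [])
        if n_fill > len(pool):
            raise PipelineError(f"chr{chrom}: not enough filler genes to plant")
        n_down = min(down_budget.get(chrom, 0), n_fill)
        for j in range(n_fill):
            mag = 1.3 + 1.2 * (counter % 7) / 6.0  # |log2 fc| in [1.3, 2.5]
            sign = -1.0 if j < n_down else 1.0
            planted.append(PlantedGene(pool[j], sign * mag))
            counter += 1
    return planted


def default_planted_correlations() -> list[PlantedCorrelation]:
    out = []
    for gene, (r_f, r_m) in DEFAULT_PANEL_R.items():
        out.append(PlantedCorrelation("CTAG2", gene, "female", r_f))
        out.append(PlantedCorrelation("CTAG2", gene, "male", r_m))
    return out


def default_planted_segments(cohort: Sequence[SampleRecord]) -> list[PlantedSegment]:
    """Default copy-number events derived from the cohort.

    A 19p gain (3.2 copies) confined to aggressive male samples, and a
    whole-chromosome-11 loss (1.0 copies) in aggressive samples of both sexes
    except one aggressive female, mirroring the most-but-not-all recurrence
    pattern of the emulated cohort.
    """
    aggressive = [s.sample_id for s in cohort if s.aggressive]
    aggressive_m = [s.sample_id for s in cohort if s.aggressive and s.sex == "M"]
    aggressive_f = [s.sample_id for s in cohort if s.aggressive and s.sex == "F"]
    loss_samples = aggressive[:]
    if aggressive_f:
        loss_samples.remove(aggressive_f[-1])
    return [
        PlantedSegment("19", "p", 3.2, tuple(aggressive_m)),
        PlantedSegment("11", None, 1.0, tuple(loss_samples)),
    ]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_expression(
    config: SimulationConfig,
    cohort: Sequence[SampleRecord],
    annotation: Sequence[GeneAnnotation] | None = None,
) -> ExpressionMatrix:
    """Generate the raw probe × sample intensity matrix."""
    if not cohort:
        raise CohortError("cohort is empty")
    if annotation is None:
        annotation = build_annotation(config)
    symbols = [a.symbol for a in annotation]
    symbol_set = set(symbols)

    planted = list(config.planted_de) if config.planted_de is not None \
        else default_planted_de(annotation)
    missing = [p.symbol for p in planted if p.symbol not in symbol_set]
    if missing:
        raise PipelineError(f"planted symbols absent from annotation: {missing[:5]}")
    correlations = list(config.planted_correlations) if config.planted_correlations is not None \
        else (default_planted_correlations() if {"CTAG2", "AURKB"} <= symbol_set else [])
    for pc in correlations:
        if pc.anchor not in symbol_set or pc.partner not in symbol_set:
            raise PipelineError(f"correlation genes {pc.anchor}/{pc.partner} not annotated")

    n_genes = len(symbols)
    n_anon = config.n_probes - n_genes - config.n_controls
    if n_anon < 0:
        raise PipelineError("n_probes too small for annotation plus controls")

    rng = _rng(config, 2)
    sexes = np.array([s.sex for s in cohort])
    male = sexes == "M"
    n_samples = len(cohort)

    planted_fc = {p.symbol: p.log2_fc for p in planted}
    fixed_mean = set(planted_fc)
    fixed_mean.update(pc.partner for pc in correlations)
    fixed_mean.update(pc.anchor for pc in correlations)
    if config.era_esr1_r is not None:
        fixed_mean.add("ESR1")

    base = config.baseline_intensity_log2
    gene_means = base + config.gene_spread_log2 * rng.standard_normal(n_genes)
    idx = {s: i for i, s in enumerate(symbols)}
    for sym in fixed_mean:
        gene_means[idx[sym]] = base  # planted genes sit at the detection-safe baseline

    log2 = gene_means[:, None] + config.noise_sd_log2 * rng.standard_normal(
        (n_genes, n_samples)
    )
    # sex effect: the lower-expressed group sits at baseline, the higher
    # group |fc| above it, so the M−F difference of log2 means equals fc
    for sym, fc in planted_fc.items():
        high = male if fc > 0 else ~male
        log2[idx[sym], high] += abs(fc)

    # group-restricted correlations via a shared latent factor
    for pc in correlations:
        grp = np.array([resolve_predicate(pc.group)(s) for s in cohort])
        if grp.sum() < 3 or config.noise_sd_log2 == 0:
            continue
        za = _standardize(log2[idx[pc.anchor], grp])
        eps = rng.standard_normal(grp.sum())
        target_mean = log2[idx[pc.partner], grp].mean()
        log2[idx[pc.partner], grp] = target_mean + config.noise_sd_log2 * (
            pc.r * za + math.sqrt(1.0 - pc.r**2) * eps
        )

    # ESR1 tracks the (standardized) ERα immunoreactivity scores
    if config.era_esr1_r is not None and "ESR1" in idx:
        ir = np.array([s.era_ir_score if s.era_ir_score is not None else np.nan
                       for s in cohort], dtype=float)
        ir = np.where(np.isfinite(ir), ir, np.nanmean(ir))
        z = _standardize(ir)
        r = config.era_esr1_r
        eps = rng.standard_normal(n_samples)
        log2[idx["ESR1"], :] = base + config.esr1_sd_log2 * (
            r * z + math.sqrt(1.0 - r**2) * eps
        )

    anon = base + config.gene_spread_log2 * rng.standard_normal(n_anon)[:, None] \
        + config.noise_sd_log2 * rng.standard_normal((n_anon, n_samples))
    ctrl_center = base - config.control_offset_sds * config.gene_spread_log2
    ctrl = ctrl_center + config.control_sd_log2 * rng.standard_normal(
        (config.n_controls, n_samples)
    )

    scale = config.sample_scale_sd_log2 * rng.standard_normal(n_samples)
    full = np.vstack([log2, anon, ctrl]) + scale[None, :]
    probe_ids = (
        [f"PR_{s}" for s in symbols]
        + [f"P_{i:06d}" for i in range(1, n_anon + 1)]
        + [f"NEG_{i:03d}" for i in range(1, config.n_controls + 1)]
    )
    values = pd.DataFrame(
        np.exp2(full), index=pd.Index(probe_ids, name="probe_id"),
        columns=[s.sample_id for s in cohort],
    )
    return ExpressionMatrix(
        values=values,
        probe_to_gene={f"PR_{s}": s for s in symbols},
        negative_control_probes=frozenset(
            f"NEG_{i:03d}" for i in range(1, config.n_controls + 1)
        ),
        scale="raw",
    )


def simulate_cna_profiles(
    config: SimulationConfig,
    cohort: Sequence[SampleRecord],
    annotation: Sequence[GeneAnnotation] | None = None,
) -> CopyNumberMatrix:
    """Generate probe-level copy-number profiles with the planted segments."""
    if not cohort:
        raise CohortError("cohort is empty")
    planted = list(config.planted_segments) if config.planted_segments is not None \
        else default_planted_segments(cohort)
    sex_of = {s.sample_id: s.sex for s in cohort}
    for seg in planted:
        if seg.chromosome not in CHROM_MB:
            raise PipelineError(f"planted segment on unknown chromosome {seg.chromosome!r}")
        for sid in seg.samples:
            if sid not in sex_of:
                raise PipelineError(f"planted segment references unknown sample {sid!r}")
            if seg.chromosome == "Y" and sex_of[sid] == "F":
                raise PipelineError(f"cannot plant a Y segment for female sample {sid}")

    rng = _rng(config, 3)
    n = config.cna_probes_per_chromosome
    rows = []
    for chrom, (length_mb, _) in CHROM_MB.items():
        length = int(length_mb * 1e6)
        spacing = length // (n + 1)
        for i in range(1, n + 1):
            rows.append((f"CN_{chrom}_{i:04d}", chrom, i * spacing))
    probes = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])

    chrom_arr = probes["chromosome"].to_numpy()
    pos_arr = probes["position"].to_numpy()
    copies = np.empty((len(probes), len(cohort)))
    for j, s in enumerate(cohort):
        baseline = np.array([sex_baseline_copies(c, s.sex) for c in chrom_arr])
        col = baseline + config.cna_noise_sd * rng.standard_normal(len(probes))
        col[~np.isfinite(baseline)] = np.nan
        copies[:, j] = col
    for seg in planted:
        if seg.arm is None:
            lo, hi = 1, int(CHROM_MB[seg.chromosome][0] * 1e6)
        else:
            lo, hi = arm_interval(seg.chromosome, seg.arm)
        mask = (chrom_arr == seg.chromosome) & (pos_arr >= lo) & (pos_arr <= hi)
        for sid in seg.samples:
            j = [s.sample_id for s in cohort].index(sid)
            copies[mask, j] = seg.copies + config.cna_noise_sd * rng.standard_normal(
                int(mask.sum())
            )
    copies = np.where(np.isnan(copies), np.nan, np.clip(copies, 0.0, None))
    return CopyNumberMatrix(
        probes=probes,
        copies=pd.DataFrame(copies, columns=[s.sample_id for s in cohort]),
    )


def simulate_dataset(config: SimulationConfig):
    """Convenience: cohort, annotation, raw expression and CNA profiles."""
    cohort = simulate_cohort(config)
    annotation = build_annotation(config)
    expr = simulate_expression(config, cohort, annotation)
    cna = simulate_cna_profiles(config, cohort, annotation)
    return cohort, annotation, expr, cna
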