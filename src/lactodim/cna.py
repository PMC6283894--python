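"""Copy-number estimation, segmentation, gain/loss calling, recurrence.

Copy numbers are estimated per probe as baseline · tumor/reference against a
normal-tissue reference pool, with the germline baseline 2 on autosomes and
sex-adjusted on X/Y.  Profiles are segmented by exact penalized
least-squares changepoint detection: the segmentation minimizing

    Σ_segments SSE(segment) + penalty · (number of segments)

found by dynamic programming (O(n²), exact — no heuristic pruning), with a
configurable minimum segment size to suppress single-probe artifacts.
Segments are then called gain when the mean exceeds 2.7 copies and loss
below 1.3 copies (cutoffs on the diploid scale; on sex chromosomes they are
rescaled by baseline/2, e.g. male X gain above 1.35).  Recurrence summaries
count, per sample group, how many samples carry at least one called event
overlapping a chromosome or arm.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AUTOSOMES,
    CopyNumberMatrix,
    GeneAnnotation,
    PipelineError,
    Predicate,
    RecurrenceSummary,
    SampleRecord,
    Segment,
    resolve_predicate,
    sex_baseline_copies,
)

DEFAULT_GAIN_CUTOFF = 2.7
DEFAULT_LOSS_CUTOFF = 1.3
DEFAULT_MIN_SEGMENT_PROBES = 3


def estimate_copies(
    tumor: pd.DataFrame,
    reference: pd.Series,
    probes: pd.DataFrame,
    sample_sex: Mapping[str, str],
) -> CopyNumberMatrix:
    """Per-probe copy estimates: baseline · tumor intensity / reference pool.

    ``tumor`` is probe × sample raw intensities aligned with ``probes``
    (columns probe_id / chromosome / position); ``reference`` is the pooled
    normal intensity per probe.  Female Y probes are set to NaN and a count
    of excluded values is implied by the NaNs.
    """
    if len(tumor) != len(probes) or len(reference) != len(probes):
        raise PipelineError("tumor, reference and probe tables must be probe-aligned")
    ref = reference.to_numpy(dtype=float)
    if (ref <= 0).any():
        raise PipelineError("reference pool intensities must be strictly positive")
    chrom = probes["chromosome"].to_numpy()
    out = np.empty(tumor.shape)
    for j, sid in enumerate(tumor.columns):
        sex = sample_sex.get(str(sid))
        if sex not in ("M", "F"):
            raise PipelineError(f"unknown sex for sample {sid!r}")
        baseline = np.array([sex_baseline_copies(c, sex) for c in chrom])
        out[:, j] = baseline * tumor[sid].to_numpy(dtype=float) / ref
    return CopyNumberMatrix(
        probes=probes.reset_index(drop=True),
        copies=pd.DataFrame(out, columns=tumor.columns),
    )


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust probe-noise SD from first differences (median absolute diff)."""
    diffs = np.diff(np.asarray(values, dtype=float))
    if len(diffs) == 0:
        return 0.0
    mad = float(np.median(np.abs(diffs)))
    # |d| with d ~ N(0, 2σ²) has median sqrt(2)·0.6745·σ
    return mad / (math.sqrt(2.0) * 0.6745)


def default_penalty(values: np.ndarray) -> float:
    """2·σ̂²·log n with σ̂ from first differences (BIC-flavoured)."""
    n = len(values)
    sigma = estimate_noise_sd(values)
    return max(2.0 * sigma * sigma * math.log(max(n, 2)), 1e-12)


def segment_profile(
    positions: Sequence[int],
    copies: Sequence[float],
    sample_id: str,
    chromosome: str,
    penalty: float | None = None,
    min_probes: int = DEFAULT_MIN_SEGMENT_PROBES,
) -> list[Segment]:
    """Exact penalized least-squares segmentation of one sample-chromosome.

    Probes must be position-sorted.  Returns uncalled segments jointly
    covering every probe; segment boundaries sit on probe positions.
    """
    pos = np.asarray(positions, dtype=np.int64)
    y = np.asarray(copies, dtype=float)
    if len(pos) != len(y) or len(y) == 0:
        raise PipelineError("need equal-length, non-empty position/copy arrays")
    if np.any(np.diff(pos) <= 0):
        raise PipelineError("probes must be sorted by strictly increasing position")
    n = len(y)
    min_probes = max(1, min(min_probes, n))
    if penalty is None:
        penalty = default_penalty(y)

    # prefix sums for O(1) within-segment SSE
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i: int, j: int) -> float:  # probes i..j-1
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    back = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    for j in range(min_probes, n + 1):
        i_hi = j - min_probes + 1
        cand_i = np.arange(0, i_hi)
        cand_i = cand_i[(cand_i == 0) | (cand_i >= min_probes)]
        lens = j - cand_i
        s = cs[j] - cs[cand_i]
        costs = best[cand_i] + (cs2[j] - cs2[cand_i]) - s * s / lens + penalty
        k = int(np.argmin(costs))
        best[j] = costs[k]
        back[j] = cand_i[k]
    if not np.isfinite(best[n]):  # n < min_probes handled by clamp above
        raise PipelineError("no feasible segmentation")

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(back[bounds[-1]]))
    bounds.reverse()
    segments = []
    for i, j in zip(bounds, bounds[1:]):
        segments.append(
            Segment(
                sample_id=sample_id,
                chromosome=chromosome,
                start=int(pos[i]),
                end=int(pos[j - 1]),
                n_probes=j - i,
                mean_copies=float(y[i:j].mean()),
            )
        )
    return segments


def segment_all(
    cn: CopyNumberMatrix,
    penalty: float | None = None,
    min_probes: int = DEFAULT_MIN_SEGMENT_PROBES,
) -> list[Segment]:
    """Segment every sample × chromosome profile of a copy-number matrix."""
    out: list[Segment] = []
    for sid in cn.sample_ids:
        for chrom in cn.probes["chromosome"].unique():
            pos, vals = cn.profile(sid, str(chrom))
            if len(pos) == 0:
                continue
            out.extend(
                segment_profile(pos, vals, sid, str(chrom),
                                penalty=penalty, min_probes=min_probes)
            )
    return out


def call_segments(
    segments: Iterable[Segment],
    sample_sex: Mapping[str, str],
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
) -> list[Segment]:
    """Gain/loss/neutral calls with strict-inequality cutoff semantics.

    Cutoffs are stated on the diploid scale and rescaled by baseline/2 on
    sex chromosomes.  Calling is idempotent: it depends only on mean_copies
    and the baseline.
    """
    if not loss_cutoff < 2.0 < gain_cutoff:
        raise PipelineError(
            f"cutoffs must straddle the diploid baseline: loss {loss_cutoff}, gain {gain_cutoff}"
        )
    out = []
    for seg in segments:
        sex = sample_sex.get(seg.sample_id)
        if sex is None:
            raise PipelineError(f"unknown sex for sample {seg.sample_id!r}")
        baseline = sex_baseline_copies(seg.chromosome, sex)
        if not math.isfinite(baseline):
            raise PipelineError(
                f"segment on chr{seg.chromosome} for female sample {seg.sample_id}"
            )
        scale = baseline / 2.0
        call = "neutral"
        if seg.mean_copies > gain_cutoff * scale:
            call = "gain"
        elif seg.mean_copies < loss_cutoff * scale:
            call = "loss"
        out.append(
            Segment(
                sample_id=seg.sample_id,
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                n_probes=seg.n_probes,
                mean_copies=seg.mean_copies,
                call=call,
                arm_label=seg.arm_label,
            )
        )
    return out


def assign_arms(
    segments: Iterable[Segment], arm_intervals: Mapping[tuple[str, str], tuple[int, int]]
) -> list[Segment]:
    """Label each segment with the arm(s) it overlaps ("p", "q" or "pq")."""
    out = []
    for seg in segments:
        arms = ""
        for arm in ("p", "q"):
            iv = arm_intervals.get((seg.chromosome, arm))
            if iv and seg.start <= iv[1] and seg.end >= iv[0]:
                arms += arm
        out.append(
            Segment(
                sample_id=seg.sample_id, chromosome=seg.chromosome,
                start=seg.start, end=seg.end, n_probes=seg.n_probes,
                mean_copies=seg.mean_copies, call=seg.call, arm_label=arms,
            )
        )
    return out


def arm_intervals_from_annotation(
    annotation: Sequence[GeneAnnotation],
) -> dict[tuple[str, str], tuple[int, int]]:
    """Arm intervals spanned by annotated genes, per (chromosome, arm)."""
    out: dict[tuple[str, str], tuple[int, int]] = {}
    for a in annotation:
        key = (a.chromosome, a.arm)
        lo, hi = out.get(key, (a.start, a.end))
        out[key] = (min(lo, a.start), max(hi, a.end))
    return out


def _token_matches(event_token: str, target: str) -> bool:
    """Whole-chromosome tokens match either arm; arm tokens match their chromosome."""
    event_token = event_token.strip().rstrip("#")
    if event_token == target:
        return True
    ec, ea = _split_token(event_token)
    tc, ta = _split_token(target)
    if ec != tc:
        return False
    # either side at chromosome level subsumes the other
    return ea is None or ta is None


def _split_token(token: str) -> tuple[str, str | None]:
    if token and token[-1] in ("p", "q"):
        return token[:-1], token[-1]
    return token, None


def segment_event_tokens(seg: Segment) -> list[str]:
    """Tokens a called segment contributes: its chromosome-arm(s), or the
    whole chromosome when it spans both arms."""
    if seg.arm_label in ("pq", ""):
        return [seg.chromosome]
    return [f"{seg.chromosome}{a}" for a in seg.arm_label]


def recurrence_by_group(
    segments: Sequence[Segment],
    samples: Sequence[SampleRecord],
    groups: Mapping[str, str | Predicate],
    targets: Sequence[str],
) -> list[RecurrenceSummary]:
    """Count samples per group carrying ≥1 called gain/loss on each target.

    ``targets`` are chromosome or chromosome-arm tokens (e.g. "11", "19p").
    A sample is counted once per (group, target, event) regardless of how
    many of its segments overlap.
    """
    known = {s.sample_id for s in samples}
    for seg in segments:
        if seg.sample_id not in known:
            raise PipelineError(f"segment references unknown sample {seg.sample_id!r}")
    events: dict[tuple[str, str], set[str]] = {}
    for seg in segments:
        if seg.call not in ("gain", "loss"):
            continue
        for token in segment_event_tokens(seg):
            events.setdefault((seg.sample_id, seg.call), set()).add(token)

    out = []
    for label, pred in groups.items():
        pred = resolve_predicate(pred)
        members = [s.sample_id for s in samples if pred(s)]
        for target in targets:
            for event in ("gain", "loss"):
                count = sum(
                    1
                    for sid in members
                    if any(_token_matches(tok, target)
                           for tok in events.get((sid, event), ()))
                )
                out.append(
                    RecurrenceSummary(group=label, target=target, event=event,
                                      count=count, denominator=len(members))
                )
    return out


def recurrence_from_events(
    event_table: pd.DataFrame,
    group: Predicate | None = None,
    target: str = "11",
    event: str = "loss",
) -> tuple[int, int]:
    """(count, denominator) for a karyotype-style per-tumor event table.

    The table needs columns tumor_id / sex / grade / clinical_behavior plus
    ``gains`` and ``losses`` holding tuples of chromosome/arm tokens, as
    returned by :func:`lactodim.datasets.cgh_cohort_events`.  ``group``
    filters rows via a SampleRecord-like view of the clinical columns.
    """
    col = {"gain": "gains", "loss": "losses"}[event]
    rows = []
    for r in event_table.itertuples(index=False):
        rec = SampleRecord(
            sample_id=r.tumor_id, sex=r.sex, grade=r.grade,
            invasive=r.grade in ("2a", "2b", "2b->3"),
            clinical_behavior=tuple(r.clinical_behavior),
        )
        if group is None or group(rec):
            rows.append(getattr(r, col))
    count = sum(1 for toks in rows if any(_token_matches(t, target) for t in toks))
    return count, len(rows)


def recurrence_frame(rows: Sequence[RecurrenceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group, r.target, r.event, r.count, r.denominator) for r in rows],
        columns=["group", "target", "event", "count", "denominator"],
    )
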