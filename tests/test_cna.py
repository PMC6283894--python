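"""Copy estimation, exact changepoint segmentation, calling, recurrence."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from lactodim import datasets
from lactodim.cna import (
    call_segments,
    default_penalty,
    estimate_copies,
    recurrence_by_group,
    recurrence_from_events,
    segment_profile,
)
from lactodim.model import PipelineError, SampleRecord, Segment


class TestEstimateCopies:
    def _tables(self, chrom="1", n=5):
        probes = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chromosome": [chrom] * n,
            "position": np.arange(1, n + 1) * 1000,
        })
        return probes

    def test_equal_intensities_give_baseline(self):
        probes = self._tables()
        tumor = pd.DataFrame({"S1": [3.0] * 5})
        ref = pd.Series([3.0] * 5)
        cn = estimate_copies(tumor, ref, probes, {"S1": "F"})
        assert np.allclose(cn.copies["S1"], 2.0)

    def test_doubled_intensity_gives_four_copies(self):
        probes = self._tables()
        tumor = pd.DataFrame({"S1": [6.0] * 5})
        ref = pd.Series([3.0] * 5)
        cn = estimate_copies(tumor, ref, probes, {"S1": "M"})
        assert np.allclose(cn.copies["S1"], 4.0)

    def test_male_x_baseline(self):
        probes = self._tables(chrom="X")
        tumor = pd.DataFrame({"S1": [3.0] * 5})
        ref = pd.Series([3.0] * 5)
        cn = estimate_copies(tumor, ref, probes, {"S1": "M"})
        assert np.allclose(cn.copies["S1"], 1.0)

    def test_nonpositive_reference_rejected(self):
        probes = self._tables()
        with pytest.raises(PipelineError, match="positive"):
            estimate_copies(pd.DataFrame({"S1": [1.0] * 5}), pd.Series([0.0] * 5),
                            probes, {"S1": "F"})


def _brute_force_segmentation(y, penalty, max_segments=4, min_probes=1):
    """Enumerate all segmentations up to max_segments; return (cost, bounds)."""
    n = len(y)
    y = np.asarray(y, dtype=float)

    def seg_cost(i, j):
        block = y[i:j]
        return float(((block - block.mean()) ** 2).sum())

    best = (np.inf, None)
    for k in range(1, max_segments + 1):
        for cuts in itertools.combinations(range(1, n), k - 1):
            bounds = [0, *cuts, n]
            if any(b - a < min_probes for a, b in zip(bounds, bounds[1:])):
                continue
            cost = sum(seg_cost(a, b) for a, b in zip(bounds, bounds[1:])) + penalty * k
            if cost < best[0] - 1e-12:
                best = (cost, bounds)
    return best


class TestSegmentation:
    def test_flat_profile_single_segment(self):
        pos = np.arange(1, 51) * 10
        segs = segment_profile(pos, np.full(50, 2.0), "S1", "1", penalty=0.5)
        assert len(segs) == 1
        assert segs[0].mean_copies == 2.0
        assert (segs[0].start, segs[0].end) == (10, 500)

    def test_noise_free_step_exact_breakpoint(self):
        y = np.r_[np.full(50, 2.0), np.full(50, 4.0)]
        pos = np.arange(1, 101) * 100
        segs = segment_profile(pos, y, "S1", "1", penalty=1.0)
        assert len(segs) == 2
        assert segs[0].end == 5000 and segs[1].start == 5100
        assert segs[0].mean_copies == 2.0 and segs[1].mean_copies == 4.0

    def test_unsorted_probes_rejected(self):
        with pytest.raises(PipelineError, match="sorted"):
            segment_profile([3, 2, 1], [2.0, 2.0, 2.0], "S1", "1")

    @pytest.mark.parametrize("n,seed", [(8, 0), (20, 1), (35, 2), (50, 3), (50, 4)])
    def test_matches_exhaustive_search(self, n, seed):
        """DP optimum equals brute-force enumeration on instances <= 50 probes."""
        rng = np.random.default_rng(seed)
        y = np.full(n, 2.0)
        if n >= 20:  # plant up to two steps
            y[n // 3: 2 * n // 3] = 3.2
        y = y + 0.3 * rng.standard_normal(n)
        pos = np.arange(1, n + 1) * 50
        penalty = max(default_penalty(y), 0.5)
        segs = segment_profile(pos, y, "S", "1", penalty=penalty, min_probes=1)
        lengths = [s.n_probes for s in segs]
        starts = np.cumsum([0, *lengths])
        dp_cost = penalty * len(segs) + sum(
            float(((y[i:j] - y[i:j].mean()) ** 2).sum())
            for i, j in zip(starts[:-1], starts[1:])
        )
        bf_cost, bf_bounds = _brute_force_segmentation(y, penalty, max_segments=4)
        assert len(segs) <= 3  # instances built to need at most 3 segments
        assert dp_cost == pytest.approx(bf_cost, abs=1e-9)
        dp_bounds = [0, *np.cumsum([s.n_probes for s in segs])]
        assert list(dp_bounds) == list(bf_bounds)

    def test_min_probes_respected_against_oracle(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.full(10, 2.0), np.full(2, 5.0), np.full(10, 2.0)]
        y = y + 0.1 * rng.standard_normal(len(y))
        pos = np.arange(1, len(y) + 1)
        segs = segment_profile(pos, y, "S", "1", penalty=0.3, min_probes=3)
        assert all(s.n_probes >= 3 for s in segs)
        bf_cost, _ = _brute_force_segmentation(y, 0.3, max_segments=5, min_probes=3)
        dp_cost = 0.3 * len(segs)
        i = 0
        for s in segs:
            block = y[i:i + s.n_probes]
            dp_cost += float(((block - block.mean()) ** 2).sum())
            i += s.n_probes
        assert dp_cost == pytest.approx(bf_cost, abs=1e-9)

    def test_penalty_monotonicity(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.full(30, 2.0), np.full(30, 3.5)] + 0.3 * rng.standard_normal(60)
        pos = np.arange(1, 61)
        counts = [
            len(segment_profile(pos, y, "S", "1", penalty=pen, min_probes=1))
            for pen in (0.05, 0.2, 1.0, 5.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_breakpoint_recovery_rate(self):
        """Breakpoint within +/-2 probes in >=95% of 100 replicates
        (step 2.0 -> 3.2, sd 0.3, 20 probes per side)."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            y = np.r_[np.full(20, 2.0), np.full(20, 3.2)] + 0.3 * rng.standard_normal(40)
            segs = segment_profile(np.arange(1, 41), y, "S", "1")
            bounds = np.cumsum([s.n_probes for s in segs])[:-1]
            if any(abs(int(b) - 20) <= 2 for b in bounds):
                hits += 1
        assert hits >= 95


class TestCalling:
    SEX = {"S1": "M", "S2": "F"}

    def _seg(self, mean, chrom="1", sample="S2"):
        return Segment(sample, chrom, 1, 100, 10, mean)

    @pytest.mark.parametrize(
        "mean,expected",
        [(3.1, "gain"), (1.2, "loss"), (2.0, "neutral"), (2.7, "neutral"), (1.3, "neutral")],
    )
    def test_autosomal_cutoffs_strict(self, mean, expected):
        (called,) = call_segments([self._seg(mean)], self.SEX)
        assert called.call == expected

    def test_sex_chromosome_cutoffs_scaled(self):
        (gain,) = call_segments([self._seg(1.4, chrom="X", sample="S1")], self.SEX)
        assert gain.call == "gain"  # male X gain above 1.35
        (neutral,) = call_segments([self._seg(1.3, chrom="X", sample="S1")], self.SEX)
        assert neutral.call == "neutral"
        (loss,) = call_segments([self._seg(0.6, chrom="X", sample="S1")], self.SEX)
        assert loss.call == "loss"

    def test_idempotent(self):
        once = call_segments([self._seg(3.0)], self.SEX)
        twice = call_segments(once, self.SEX)
        assert once == twice

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(PipelineError):
            call_segments([self._seg(2.0)], self.SEX, gain_cutoff=1.5, loss_cutoff=2.5)


class TestRecurrence:
    def test_reference_event_table_counts(self):
        """Recurrence counts recomputed from the per-tumor event table:
        19p gain in exactly the 3 aggressive male tumors, chromosome-11 loss
        in 5 of the 6 aggressive/malignant tumors, and 2 male tumors with
        metastasis."""
        events = datasets.cgh_cohort_events()
        count, denom = recurrence_from_events(
            events, group=lambda s: s.sex == "M" and s.aggressive,
            target="19p", event="gain",
        )
        assert (count, denom) == (3, 3)
        count, denom = recurrence_from_events(
            events, group=lambda s: s.aggressive, target="11", event="loss",
        )
        assert (count, denom) == (5, 6)
        n_meta = sum(
            1 for r in events.itertuples(index=False)
            if r.sex == "M" and "metastasis" in r.clinical_behavior
        )
        assert n_meta == 2

    def test_empty_segment_list_counts_zero(self):
        samples = [SampleRecord("S1", "M", "1a", False)]
        rows = recurrence_by_group([], samples, groups={"all": "all"}, targets=["1"])
        assert all(r.count == 0 for r in rows)

    def test_whole_chromosome_event_matches_arm_target(self):
        samples = [SampleRecord("S1", "M", "2b", True)]
        seg = Segment("S1", "11", 1, 2_000_000, 30, 1.0, call="loss", arm_label="pq")
        rows = {(r.target, r.event): r.count
                for r in recurrence_by_group([seg], samples,
                                             groups={"all": "all"},
                                             targets=["11", "11p", "11q"])}
        assert rows[("11", "loss")] == 1
        assert rows[("11p", "loss")] == 1  # chromosome-level event subsumes the arm
        assert rows[("11", "gain")] == 0

    def test_unknown_sample_rejected(self):
        samples = [SampleRecord("S1", "M", "1a", False)]
        seg = Segment("GHOST", "1", 1, 10, 3, 3.0, call="gain")
        with pytest.raises(PipelineError, match="GHOST"):
            recurrence_by_group([seg], samples, groups={"all": "all"}, targets=["1"])
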