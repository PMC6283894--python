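"""Signed fold change, Student's t, and the joint deregulation filter."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lactodim.de import (
    deregulated_counts,
    select_deregulated,
    signed_fold_change,
    student_t,
    subgroup_contrast,
)
from lactodim.model import CohortError, ExpressionMatrix, SampleRecord
from lactodim.preprocess import preprocess
from lactodim.simulate import PlantedGene, SimulationConfig, simulate_cohort, \
    simulate_expression
from tests.conftest import small_genes


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(3.0, 1.0, 4.0), (1.0, 3.0, -4.0), (2.0, 2.0, 1.0), (1.0, 0.0, 2.0)],
    )
    def test_examples(self, a, b, expected):
        assert signed_fold_change(a, b) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_never_inside_unit_interval_and_antisymmetric(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        # swapping groups negates the fold change (to float precision)
        assert signed_fold_change(b, a) == pytest.approx(-fc if abs(fc) > 1 else 1.0,
                                                         rel=1e-9)


class TestStudentT:
    def test_identical_groups_p_one(self):
        p, degenerate = student_t([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0 and degenerate

    def test_clear_separation_tiny_p(self):
        a = [0.0, 1e-6, -1e-6, 2e-6]
        b = [1.0, 1.0 + 1e-6, 1.0 - 1e-6, 1.0]
        p, _ = student_t(a, b)
        assert p < 1e-4

    def test_pooled_variance_value(self):
        # frozen from the closed-form pooled-variance t: t = -1.2247, df = 4
        p, _ = student_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert p == pytest.approx(0.2878, abs=2e-4)

    def test_small_group_rejected(self):
        with pytest.raises(CohortError):
            student_t([1.0], [1.0, 2.0])


def _planted_matrix(seed: int, n_up=120, n_down=20, noise=0.25, n_genes=1000):
    genes = {"1": n_genes}
    symbols = [f"G1_{i:04d}" for i in range(1, n_up + n_down + 1)]
    planted = [PlantedGene(s, 2.0) for s in symbols[:n_up]] + \
              [PlantedGene(s, -2.0) for s in symbols[n_up:]]
    cfg = SimulationConfig(
        seed=seed, n_probes=n_genes + 100, genes_per_chromosome=genes,
        planted_de=planted, noise_sd_log2=noise, planted_correlations=[],
        era_esr1_r=None,
    )
    cohort = simulate_cohort(cfg)
    expr = simulate_expression(cfg, cohort)
    log2m, det = preprocess(expr)
    return cohort, log2m, det, set(symbols[:n_up]), set(symbols[n_up:])


class TestSelectDeregulated:
    def test_recovers_planted_up_down_counts(self):
        cohort, log2m, det, up, down = _planted_matrix(seed=21)
        res = select_deregulated(log2m, cohort, detection=det)
        total, n_up, n_down = deregulated_counts(res)
        assert abs(n_up - 120) <= 5
        assert abs(n_down - 20) <= 5
        assert total == n_up + n_down

    def test_null_pass_rate_bounded(self):
        """Joint p<=0.05 & |FC|>=2 filter passes <= 6% of 10,000 null genes;
        the t-test alone rejects within 1.5 points of alpha."""
        cfg = SimulationConfig(
            seed=40, n_probes=10_100, genes_per_chromosome={"1": 10_000},
            planted_de=[], planted_correlations=[], era_esr1_r=None,
        )
        cohort = simulate_cohort(cfg)
        expr = simulate_expression(cfg, cohort)
        log2m, det = preprocess(expr)
        res = select_deregulated(log2m, cohort, detection=det)
        assert len(res) >= 9000
        dereg_rate = sum(r.deregulated for r in res) / len(res)
        t_rate = sum(r.p_value <= 0.05 for r in res) / len(res)
        assert dereg_rate <= 0.06
        assert abs(t_rate - 0.05) <= 0.015

    def test_antitone_in_alpha_and_fc_min(self):
        cohort, log2m, det, *_ = _planted_matrix(seed=22, n_genes=400, n_up=40, n_down=10)
        loose = {r.symbol for r in select_deregulated(log2m, cohort, detection=det)
                 if r.deregulated}
        strict_alpha = {r.symbol for r in
                        select_deregulated(log2m, cohort, alpha=0.01, detection=det)
                        if r.deregulated}
        strict_fc = {r.symbol for r in
                     select_deregulated(log2m, cohort, fc_min=4.0, detection=det)
                     if r.deregulated}
        assert strict_alpha <= loose
        assert strict_fc <= loose

    def test_label_swap_negates_fold_changes(self):
        cohort, log2m, det, *_ = _planted_matrix(seed=23, n_genes=300, n_up=20, n_down=5)
        swapped = [
            SampleRecord(s.sample_id, "F" if s.sex == "M" else "M", s.grade,
                         s.invasive, s.era_ir_score, s.tumor_size_mm,
                         s.clinical_behavior)
            for s in cohort
        ]
        res = {r.symbol: r for r in select_deregulated(log2m, cohort, detection=det)}
        res_sw = {r.symbol: r for r in select_deregulated(log2m, swapped, detection=det)}
        for sym in res:
            assert res_sw[sym].fold_change == pytest.approx(-res[sym].fold_change, rel=1e-9)
            assert res_sw[sym].p_value == pytest.approx(res[sym].p_value, rel=1e-9)

    def test_noise_free_recovery_exact(self):
        cfg = SimulationConfig(
            seed=0, n_probes=600, genes_per_chromosome=small_genes(15),
            planted_de=[PlantedGene("G1_0001", 2.0), PlantedGene("G2_0001", -1.5)],
            noise_sd_log2=0.0, sample_scale_sd_log2=0.0, gene_spread_log2=0.0,
            planted_correlations=[], era_esr1_r=None,
        )
        cohort = simulate_cohort(cfg)
        expr = simulate_expression(cfg, cohort)
        log2m, det = preprocess(expr)
        res = {r.symbol: r for r in select_deregulated(log2m, cohort, detection=det)}
        assert res["G1_0001"].fold_change == pytest.approx(4.0, rel=1e-9)
        assert res["G2_0001"].fold_change == pytest.approx(-(2**1.5), rel=1e-9)

    def test_planted_recovery_rate_across_seeds(self):
        """>=95% of genes planted at 4-fold (sd 0.25, n 20 vs 10) recovered,
        over 10 replicate seeds."""
        recovered = total = 0
        for seed in range(10):
            cohort, log2m, det, up, down = _planted_matrix(seed=100 + seed,
                                                           n_genes=300, n_up=30, n_down=10)
            res = {r.symbol for r in select_deregulated(log2m, cohort, detection=det)
                   if r.deregulated}
            planted = up | down
            recovered += len(planted & res)
            total += len(planted)
        assert recovered / total >= 0.95


class TestSubgroupContrast:
    def test_consistent_with_full_cohort(self):
        cohort, log2m, det, *_ = _planted_matrix(seed=24, n_genes=300, n_up=20, n_down=5)
        res = {r.symbol: r for r in select_deregulated(log2m, cohort)}
        fc, p = subgroup_contrast(log2m, cohort, "G1_0001")
        assert fc == pytest.approx(res["G1_0001"].fold_change, rel=1e-12)
        assert p == pytest.approx(res["G1_0001"].p_value, rel=1e-12)

    def test_excluding_affected_subgroup_shrinks_fold_change(self):
        # plant a gene high only in aggressive females; removing them moves |FC| toward 1
        cfg = SimulationConfig(
            seed=5, n_probes=2000, genes_per_chromosome=small_genes(),
            planted_de=[], planted_correlations=[], era_esr1_r=None, noise_sd_log2=0.1,
        )
        cohort = simulate_cohort(cfg)
        expr = simulate_expression(cfg, cohort)
        agg_f = [s.sample_id for s in cohort if s.sex == "F" and s.aggressive]
        expr.values.loc["PR_G3_0001", agg_f] *= 16.0
        log2m, _ = preprocess(expr)
        fc_all, _ = subgroup_contrast(log2m, cohort, "G3_0001")
        fc_excl, _ = subgroup_contrast(
            log2m, cohort, "G3_0001",
            include=lambda s: not (s.sex == "F" and s.aggressive),
        )
        assert abs(fc_excl) < abs(fc_all)

    def test_too_small_group_rejected(self):
        cohort, log2m, det, *_ = _planted_matrix(seed=25, n_genes=200, n_up=5, n_down=2)
        with pytest.raises(CohortError):
            subgroup_contrast(log2m, cohort, "G1_0001",
                              include=lambda s: s.sex == "M" or s.sample_id == "F01")
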