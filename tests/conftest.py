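from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lactodim.model import ExpressionMatrix, GeneAnnotation, SampleRecord
from lactodim.simulate import SimulationConfig, simulate_cohort


def small_genes(per_chrom: int = 60) -> dict[str, int]:
    """A reduced annotation size map still large enough for the named genes."""
    return {c: per_chrom for c in [str(i) for i in range(1, 23)] + ["X", "Y"]}


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_probes=2000,
        genes_per_chromosome=small_genes(),
        cna_probes_per_chromosome=40,
    )


@pytest.fixture
def default_cohort() -> list[SampleRecord]:
    return simulate_cohort(SimulationConfig(seed=3))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "S1": [1.0, 2.0, 3.0, 0.1],
            "S2": [2.0, 4.0, 6.0, 0.2],
        },
        index=pd.Index(["PR_A", "PR_B", "PR_C", "NEG_1"], name="probe_id"),
    )
    return ExpressionMatrix(
        values=values,
        probe_to_gene={"PR_A": "A", "PR_B": "B", "PR_C": "C"},
        negative_control_probes=frozenset({"NEG_1"}),
        scale="raw",
    )


def toy_annotation(counts: dict[str, int], arm_split: float = 0.5) -> list[GeneAnnotation]:
    """``counts[chrom]`` evenly spaced genes on a 100 Mb toy chromosome."""
    out = []
    for chrom, n in counts.items():
        for i in range(n):
            start = 1 + i * (100_000_000 // max(n, 1))
            arm = "p" if start < arm_split * 100_000_000 else "q"
            out.append(GeneAnnotation(f"{chrom}_g{i}", chrom, arm, start, start + 1000))
    return out
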