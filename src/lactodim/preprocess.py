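"""Array preprocessing: median normalization, detection calling, log2.

The chain mirrors single-channel expression-array practice: each array is
scaled so its median intensity is exactly 1, a per-array detection threshold
is derived from the negative-control probes (mean + k·SD of their normalized
intensities, sample SD with the n−1 denominator), probes below it are
flagged "absent", and intensities are then converted to log2 with a small
floor guarding zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, PipelineError

DEFAULT_K_SD = 2.0
DEFAULT_LOG2_FLOOR = 2.0**-10


@dataclass
class DetectionResult:
    """Per-sample detection thresholds and the probe × sample present flags."""

    threshold_per_sample: dict[str, float]
    present: pd.DataFrame  # boolean, same shape/labels as the matrix
    k_sd: float

    def present_fraction(self, probes: list[str] | None = None) -> float:
        block = self.present if probes is None else self.present.loc[probes]
        return float(block.to_numpy().mean())


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide every sample column by its own median so the median becomes 1."""
    if matrix.scale != "raw":
        raise PipelineError(f"median_normalize expects a raw matrix, got {matrix.scale}")
    medians = matrix.values.median(axis=0)
    bad = medians.index[medians <= 0].tolist()
    if bad:
        raise PipelineError(f"samples with non-positive median intensity: {bad}")
    return matrix.with_values(matrix.values / medians, scale="normalized")


def detection_call(matrix: ExpressionMatrix, k_sd: float = DEFAULT_K_SD) -> DetectionResult:
    """Flag probes present/absent against the control-derived threshold.

    threshold(sample) = mean + k_sd·SD of that sample's negative-control
    normalized intensities; a probe is present iff its normalized intensity
    strictly exceeds the threshold.
    """
    if matrix.scale != "normalized":
        raise PipelineError(f"detection_call expects a normalized matrix, got {matrix.scale}")
    controls = sorted(matrix.negative_control_probes)
    if not controls:
        raise PipelineError(
            "matrix has no negative-control probes; supply an explicit threshold instead"
        )
    ctrl = matrix.values.loc[controls]
    mean = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1).fillna(0.0)  # single control: zero spread
    thresholds = mean + k_sd * sd
    present = matrix.values.gt(thresholds, axis=1)
    return DetectionResult(
        threshold_per_sample=thresholds.to_dict(), present=present, k_sd=k_sd
    )


def log2_transform(
    matrix: ExpressionMatrix, floor: float = DEFAULT_LOG2_FLOOR
) -> ExpressionMatrix:
    """log2 of normalized intensities, flooring values below ``floor``."""
    if matrix.scale != "normalized":
        raise PipelineError(f"log2_transform expects a normalized matrix, got {matrix.scale}")
    if floor <= 0:
        raise PipelineError("floor must be positive")
    return matrix.with_values(np.log2(matrix.values.clip(lower=floor)), scale="log2")


def preprocess(
    matrix: ExpressionMatrix,
    k_sd: float = DEFAULT_K_SD,
    floor: float = DEFAULT_LOG2_FLOOR,
) -> tuple[ExpressionMatrix, DetectionResult]:
    """Run the full chain raw → normalized → (detection, log2)."""
    normalized = median_normalize(matrix)
    detection = detection_call(normalized, k_sd=k_sd)
    return log2_transform(normalized, floor=floor), detection
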