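"""Normalizations used by the follow-up validation assays.

Small, fully specified formulas: percent-of-control reporter expression,
percent internalized receptors, and firefly/Renilla biosensor normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class AssayBatch:
    """One assay batch: control-sgRNA measurements plus test samples."""

    control_values: Sequence[float]
    test_values: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.control_values) == 0:
            raise ValidationError("a batch needs at least one control value")
        if float(np.mean(self.control_values)) <= 0:
            raise ValidationError("control mean must be positive")


def percent_of_control(batch: AssayBatch) -> dict[str, float]:
    """Express each test sample as a percentage of the batch's mean control
    value (the control mean is set to 100%)."""
    control_mean = float(np.mean(batch.control_values))
    return {
        sample: 100.0 * value / control_mean
        for sample, value in batch.test_values.items()
    }


def percent_internalized(surface_before: float, surface_after: float) -> float:
    """% internalized receptors = 100 - (surface after / surface before) x 100."""
    if surface_before <= 0:
        raise ValidationError("pre-drug surface signal must be positive")
    if surface_after < 0:
        raise ValidationError("post-drug surface signal must be non-negative")
    return 100.0 - (surface_after / surface_before) * 100.0


def normalize_biosensor(
    firefly_timecourse: Sequence[float], renilla: float
) -> np.ndarray:
    """Divide a firefly-luciferase cAMP timecourse by the Renilla expression
    control signal."""
    if renilla <= 0:
        raise ValidationError("Renilla signal must be positive")
    return np.asarray(firefly_timecourse, dtype=float) / renilla
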