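"""Small relative-quantification utilities: 2^-ddCt and densitometry.

Both follow the same normalization logic: a target signal is first
normalized to an internal reference (beta-actin Ct, or a loading-control
band) within each sample, then expressed relative to a calibrator
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values of the target and reference genes for one sample."""

    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for value in (self.ct_target, self.ct_reference):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"Ct values must be finite and positive: {value}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class DensitometrySignal:
    """A band intensity and its loading-control intensity (a.u.)."""

    band_intensity: float
    loading_control_intensity: float

    def __post_init__(self):
        if self.loading_control_intensity <= 0:
            raise ValueError("loading control intensity must be positive")

    @property
    def normalized(self) -> float:
        return self.band_intensity / self.loading_control_intensity


def ddct(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression 2^-ddCt of a sample against a calibrator.

    ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_calibrator.
    """
    return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)


def normalized_ratio(
    numerator: DensitometrySignal, denominator: DensitometrySignal
) -> float:
    """Loading-control-normalized band ratio, e.g. pAKT/AKT with each
    band first divided by its beta-actin signal.  Invariant under a
    common scaling of all four intensities."""
    if denominator.band_intensity == 0:
        raise ValueError("denominator band intensity is zero")
    return numerator.normalized / denominator.normalized
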