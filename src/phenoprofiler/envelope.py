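"""Significance envelopes from historical vehicle controls.

The envelope for a readout is a symmetric interval [-h, +h] around 0 on the
log10-ratio scale, sized so that it covers the stated fraction (default 95%)
of the historical vehicle-control distribution for that (system, biomarker).
Readouts inside the envelope are treated as assay noise; readouts strictly
outside are candidate hits.

Two estimators are provided.  ``normal`` assumes Gaussian control noise and
sets h = z_{1-(1-c)/2} * s, with s the sample standard deviation; ``empirical``
takes the symmetrized max-absolute (1-c)/2 and 1-(1-c)/2 sample quantiles.
This is a tolerance band for individual readouts, not a confidence interval
of the control mean: a mean CI would shrink with control count and flag
nearly every treated readout.  The band is centered at 0 (no change), not at
the control mean; controls define width only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .data_io import VehicleControlSet

__all__ = ["Envelope", "EnvelopeSet", "estimate_envelopes", "classify_readout", "classify_value"]

logger = logging.getLogger(__name__)

Method = Literal["normal", "empirical"]
Classification = Literal["inside", "up", "down"]


@dataclass(frozen=True)
class Envelope:
    """Symmetric significance bounds [-half_width, +half_width] for one readout."""

    system: str
    biomarker: str
    half_width: float
    method: str = "normal"
    n_controls: int = 0

    def __post_init__(self) -> None:
        if not (self.half_width >= 0):
            raise ValueError(f"half_width must be >= 0, got {self.half_width}")


@dataclass
class EnvelopeSet:
    """Per-readout envelopes with a default width for readouts lacking history."""

    envelopes: dict[tuple[str, str], Envelope] = field(default_factory=dict)
    default_half_width: float = 0.1

    def get(self, system: str, biomarker: str) -> Envelope:
        """Always yields a usable envelope (specific or default)."""
        key = (system, biomarker)
        if key in self.envelopes:
            return self.envelopes[key]
        return Envelope(system, biomarker, self.default_half_width, method="default")

    def __len__(self) -> int:
        return len(self.envelopes)


def _half_width(samples: np.ndarray, method: Method, alpha: float, z: float) -> float:
    if method == "normal":
        return float(z * samples.std(ddof=1))
    if method == "empirical":
        lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(max(abs(lo), abs(hi)))
    raise ValueError(f"unknown envelope method {method!r}")


def estimate_envelopes(
    controls: VehicleControlSet,
    method: Method = "normal",
    confidence: float = 0.95,
    default_half_width: float = 0.1,
) -> EnvelopeSet:
    """Estimate per-(system, biomarker) envelopes from vehicle controls.

    Readouts with fewer than two control replicates fall back to
    ``default_half_width`` (logged); zero-variance controls give a zero-width
    envelope, under which any nonzero readout is significant.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    alpha = 1.0 - confidence
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))  # loop-invariant
    out = EnvelopeSet(default_half_width=default_half_width)
    for (system, biomarker), samples in controls.samples.items():
        arr = np.asarray(samples, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite control value for ({system}, {biomarker})")
        if arr.size < 2:
            logger.warning(
                "(%s, %s): %d control(s) < 2; using default half-width %g",
                system, biomarker, arr.size, default_half_width,
            )
            continue
        out.envelopes[(system, biomarker)] = Envelope(
            system, biomarker, _half_width(arr, method, alpha, z), method, int(arr.size)
        )
    return out


def classify_value(value: float, half_width: float) -> Classification:
    """'up'/'down' for values strictly outside [-h, +h]; boundaries are inside."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite readout value {value!r}")
    if value > half_width:
        return "up"
    if value < -half_width:
        return "down"
    return "inside"


def classify_readout(value: float, envelope: Envelope) -> Classification:
    """Classify one treated readout against its significance envelope."""
    return classify_value(value, envelope.half_width)
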