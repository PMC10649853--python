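"""Synthetic panels with known ground truth.

Emulates the layout of the reference screening panel — 12 stimulated cell
systems, ~12 biomarkers each (~148 readouts total, plus one viability channel
per system), 4 ascending doses — with Gaussian vehicle noise on the log10
scale and injected dose-response effects of controlled shape and amplitude.
Every pipeline stage is exercisable against the recorded truth without any
external data.

Signal shapes (on the log10-ratio scale, before noise):

* ``monotone_up`` / ``monotone_down``: a step of +/- amplitude at all doses
  from the onset index up.
* ``u_shape``: amplitude at an interior peak dose, half-amplitude at its
  neighbors, zero elsewhere — mimicking a compound whose activity falls off
  again at the top tested concentration.
* ``threshold_onset``: a linear ramp from zero at the dose before onset to
  full amplitude at the top dose.
* ``null``: identically zero.

Noise is independent across doses and readouts (no within-series
correlation).  The recorded ``expected_annotations`` are what the annotation
rules yield on the *noise-free* signal under a stated envelope half-width, so
as noise goes to zero the pipeline must recover them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .annotation import AnnotatedActivity, AnnotationConfig, annotate_activities
from .data_io import CompoundProfile, VehicleControlSet, load_panel
from .envelope import EnvelopeSet

__all__ = [
    "EffectSpec",
    "PanelSpec",
    "SyntheticTruth",
    "RecoverySummary",
    "generate_controls",
    "generate_profile",
    "evaluate_recovery",
]

SHAPES = ("null", "monotone_up", "monotone_down", "u_shape", "threshold_onset")


@dataclass(frozen=True)
class EffectSpec:
    """One injected dose-response effect on a single readout."""

    system: str
    biomarker: str
    shape: str
    amplitude: float
    onset_dose_index: int = 1
    #: sign of the response; monotone shapes derive it from the shape name,
    #: u_shape/threshold_onset default to "up".
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape == "null" and self.amplitude != 0:
            raise ValueError("null effects must have amplitude 0")

    @property
    def sign(self) -> float:
        if self.shape == "monotone_down":
            return -1.0
        if self.shape == "monotone_up":
            return 1.0
        return -1.0 if self.direction == "down" else 1.0

    def signal(self, n_doses: int) -> np.ndarray:
        """Noise-free log10-ratio signal over the ascending dose grid."""
        idx = np.arange(n_doses)
        if self.shape == "null":
            return np.zeros(n_doses)
        if self.shape in ("monotone_up", "monotone_down"):
            return self.sign * self.amplitude * (idx >= self.onset_dose_index)
        if self.shape == "u_shape":
            peak = self.onset_dose_index
            if not 0 < peak < n_doses - 1:
                raise ValueError("u_shape peak must be at an interior dose")
            out = np.zeros(n_doses)
            out[peak] = self.amplitude
            out[peak - 1] = out[peak + 1] = self.amplitude / 2.0
            return self.sign * out
        # threshold_onset: linear ramp from the onset to the top dose
        ramp = np.clip(
            (idx - self.onset_dose_index + 1) / max(n_doses - self.onset_dose_index, 1), 0, 1
        )
        return self.sign * self.amplitude * ramp


@dataclass(frozen=True)
class PanelSpec:
    """Layout and noise model of one synthetic panel."""

    n_systems: int = 12
    biomarkers_per_system: int = 12
    doses: tuple[float, ...] = (1.9, 5.6, 17.0, 50.0)
    noise_sd: float = 0.025
    control_replicates: int = 100
    seed: int = 0
    include_viability: bool = True

    def __post_init__(self) -> None:
        if self.n_systems < 1 or self.biomarkers_per_system < 1:
            raise ValueError("panel dimensions must be positive")
        if len(self.doses) < 2 or any(b >= a for b, a in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly ascending, length >= 2")
        if self.noise_sd < 0 or self.control_replicates < 2:
            raise ValueError("noise_sd >= 0 and control_replicates >= 2 required")

    @property
    def systems(self) -> tuple[str, ...]:
        panel = [s.id for s in load_panel()]
        if self.n_systems <= len(panel):
            return tuple(panel[: self.n_systems])
        extra = [f"S{i:02d}" for i in range(len(panel) + 1, self.n_systems + 1)]
        return tuple(panel + extra)

    def biomarkers(self, system: str) -> tuple[str, ...]:
        return tuple(f"BM{i:02d}" for i in range(1, self.biomarkers_per_system + 1))

    def readouts(self) -> list[tuple[str, str]]:
        """All (system, biomarker) soluble readouts (viability channels extra)."""
        return [(s, b) for s in self.systems for b in self.biomarkers(s)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Injected effects plus the annotations they imply in the noise-free limit."""

    effects: tuple[EffectSpec, ...]
    expected_annotations: frozenset[tuple[str, str, str]]


@dataclass(frozen=True)
class RecoverySummary:
    """Confusion summary of called vs. expected (system, biomarker, direction)."""

    n_true_positive: int
    n_false_positive: int
    n_false_negative: int
    n_true_negative: int
    sensitivity: float
    specificity: float
    false_annotation_rate: float


def _controls_rng(spec: PanelSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0])


def _profile_rng(spec: PanelSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1])


def generate_controls(spec: PanelSpec) -> VehicleControlSet:
    """Historical vehicle controls: N(0, noise_sd) per readout, seeded."""
    rng = _controls_rng(spec)
    controls = VehicleControlSet()
    readouts = spec.readouts()
    if spec.include_viability:
        readouts = readouts + [(s, "SRB") for s in spec.systems]
    draws = rng.normal(0.0, spec.noise_sd, size=(len(readouts), spec.control_replicates))
    for (system, biomarker), row in zip(readouts, draws):
        controls.samples[(system, biomarker)] = [float(v) for v in row]
    return controls


def expected_annotations(
    spec: PanelSpec,
    effects: Sequence[EffectSpec],
    envelope_half_width: float,
    cfg: AnnotationConfig | None = None,
) -> frozenset[tuple[str, str, str]]:
    """Annotations the rules yield on the noise-free signal (the ground truth)."""
    profile, _ = generate_profile(
        replace(spec, noise_sd=0.0), effects, compound="truth", _record_truth=False
    )
    envelopes = EnvelopeSet(default_half_width=envelope_half_width)
    called = annotate_activities(profile, envelopes, cfg or AnnotationConfig())
    return frozenset((a.system, a.biomarker, a.direction) for a in called)


def generate_profile(
    spec: PanelSpec,
    effects: Iterable[EffectSpec] = (),
    compound: str = "synthetic",
    envelope_half_width: float | None = None,
    cfg: AnnotationConfig | None = None,
    _record_truth: bool = True,
) -> tuple[CompoundProfile, SyntheticTruth]:
    """Generate one compound profile: injected signal plus independent noise.

    ``envelope_half_width`` states the envelope under which the recorded
    ground-truth annotations are computed; by default it is the noise model's
    own 95% normal band, 1.959964 * noise_sd (or 0.1 for a noiseless panel).
    """
    effects = tuple(effects)
    readouts = set(spec.readouts())
    for eff in effects:
        if (eff.system, eff.biomarker) not in readouts:
            raise ValueError(f"effect references unknown readout ({eff.system}, {eff.biomarker})")

    n = len(spec.doses)
    signal: dict[tuple[str, str], np.ndarray] = {
        key: np.zeros(n) for key in spec.readouts()
    }
    for eff in effects:
        signal[(eff.system, eff.biomarker)] = signal[(eff.system, eff.biomarker)] + eff.signal(n)

    rng = _profile_rng(spec)
    values: dict[tuple[str, str, float], float] = {}
    classes: dict[tuple[str, str], str] = {}
    for (system, biomarker), sig in sorted(signal.items()):
        noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
        for dose, value in zip(spec.doses, sig + noise):
            values[(system, biomarker, dose)] = float(value)
        classes[(system, biomarker)] = "soluble"
    if spec.include_viability:
        for system in spec.systems:
            noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
            for dose, value in zip(spec.doses, noise):
                values[(system, "SRB", dose)] = float(value)
            classes[(system, "SRB")] = "viability"

    profile = CompoundProfile(compound, spec.doses, values, classes)
    if not _record_truth:
        return profile, SyntheticTruth(effects, frozenset())
    if envelope_half_width is None:
        envelope_half_width = 1.959964 * spec.noise_sd if spec.noise_sd > 0 else 0.1
    truth = SyntheticTruth(
        effects, expected_annotations(spec, effects, envelope_half_width, cfg)
    )
    return profile, truth


def evaluate_recovery(
    called: Iterable[AnnotatedActivity] | Iterable[tuple[str, str, str]],
    truth: SyntheticTruth,
    n_readouts: int | None = None,
) -> RecoverySummary:
    """Confusion summary matching on (system, biomarker, direction).

    ``n_readouts`` sizes the negative universe (two direction slots per
    readout); when omitted it is inferred from the union of called and
    expected entries, which makes specificity degenerate but leaves
    sensitivity and counts exact.  The false-annotation rate is false
    positives per readout.
    """
    called_set = {
        (c.system, c.biomarker, c.direction) if isinstance(c, AnnotatedActivity) else tuple(c)
        for c in called
    }
    expected = set(truth.expected_annotations)
    tp = len(called_set & expected)
    fp = len(called_set - expected)
    fn = len(expected - called_set)
    if n_readouts is None:
        n_readouts = len({(s, b) for s, b, _ in called_set | expected})
    n_slots = 2 * n_readouts
    tn = max(n_slots - tp - fp - fn, 0)
    sensitivity = tp / len(expected) if expected else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return RecoverySummary(
        n_true_positive=tp,
        n_false_positive=fp,
        n_false_negative=fn,
        n_true_negative=tn,
        sensitivity=sensitivity,
        specificity=specificity,
        false_annotation_rate=fp / n_readouts if n_readouts else 0.0,
    )
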