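"""Simulation benchmarks of the calling rules on synthetic panels.

Two standard experiments, used by the analysis drivers and the acceptance
harness:

* :func:`null_calibration` — large all-null panel; measures the achieved
  outside-envelope rate (nominally 1 - confidence) and the per-readout
  dose-dependent false-annotation rate, together with the analytic union
  bound 3 p^2 (three adjacent dose pairs on a 4-dose grid, each needing two
  same-side outside calls).
* :func:`recovery_benchmark` — many small panels with injected monotone
  effects; measures sensitivity and the per-readout false-annotation rate of
  the full annotation rule against the recorded ground truth.
"""

from __future__ import annotations


from dataclasses import dataclass

from .annotation import AnnotationConfig, annotate_activities
from .envelope import EnvelopeSet, estimate_envelopes
from .synthetic import EffectSpec, PanelSpec, evaluate_recovery, generate_controls, generate_profile

__all__ = ["NullCalibrationResult", "RecoveryResult", "null_calibration", "recovery_benchmark"]

_Z95_SD = 1.959964  # normal 95% band in units of the noise sd


@dataclass(frozen=True)
class NullCalibrationResult:
    n_readouts: int
    n_classifications: int
    outside_rate: float
    n_activities: int
    activity_rate_per_readout: float
    analytic_bound: float  # 3 p^2 with p the achieved outside rate


@dataclass(frozen=True)
class RecoveryResult:
    n_seeds: int
    n_expected_total: int
    n_true_positive: int
    n_false_positive: int
    n_readouts_total: int
    sensitivity: float
    false_annotation_rate: float


def null_calibration(
    n_readouts: int = 25_000,
    seed: int = 0,
    noise_sd: float = 0.025,
    control_replicates: int = 100,
    confidence: float = 0.95,
    cfg: AnnotationConfig | None = None,
) -> NullCalibrationResult:
    """Outside-envelope and false-annotation rates on an all-null panel.

    The panel has ``n_readouts`` readouts at 4 doses (so 4 x n_readouts
    classifications); envelopes are estimated per readout from
    ``control_replicates`` vehicle draws with the normal method.
    """
    per_system = max(n_readouts // 10, 1)
    spec = PanelSpec(
        n_systems=10,
        biomarkers_per_system=per_system,
        noise_sd=noise_sd,
        control_replicates=control_replicates,
        seed=seed,
        include_viability=False,
    )
    controls = generate_controls(spec)
    envelopes = estimate_envelopes(controls, method="normal", confidence=confidence)
    profile, _ = generate_profile(spec, [], compound="null", _record_truth=False)

    outside = total = 0
    for system, biomarker in profile.readouts():
        half_width = envelopes.get(system, biomarker).half_width
        for value in profile.series(system, biomarker):
            total += 1
            outside += abs(value) > half_width
    activities = annotate_activities(profile, envelopes, cfg or AnnotationConfig())
    n_read = len(profile.readouts())
    p = outside / total
    return NullCalibrationResult(
        n_readouts=n_read,
        n_classifications=total,
        outside_rate=p,
        n_activities=len(activities),
        activity_rate_per_readout=len(activities) / n_read,
        analytic_bound=3.0 * p * p,
    )


def _monotone_effects(spec: PanelSpec, amplitude: float) -> list[EffectSpec]:
    """Two monotone effects (one per direction) in every system, onset at dose 2."""
    effects = []
    for system in spec.systems:
        effects.append(EffectSpec(system, "BM01", "monotone_down", amplitude, 1))
        effects.append(EffectSpec(system, "BM02", "monotone_up", amplitude, 1))
    return effects


def recovery_benchmark(
    n_seeds: int = 500,
    base_seed: int = 0,
    amplitude: float = 0.3,
    noise_sd: float = 0.025,
    n_systems: int = 4,
    biomarkers_per_system: int = 6,
    cfg: AnnotationConfig | None = None,
) -> RecoveryResult:
    """Replicate recovery of injected monotone effects across seeds.

    The envelope is the noise model's own 95% band (1.959964 * noise_sd),
    held fixed, so the experiment isolates the annotation rule from envelope
    estimation error.
    """
    cfg = cfg or AnnotationConfig()
    half_width = _Z95_SD * noise_sd if noise_sd > 0 else 0.1
    envelopes = EnvelopeSet(default_half_width=half_width)
    tp = fp = expected_total = readouts_total = 0
    for i in range(n_seeds):
        spec = PanelSpec(
            n_systems=n_systems,
            biomarkers_per_system=biomarkers_per_system,
            noise_sd=noise_sd,
            seed=(base_seed + i) % 2**31,
            include_viability=False,
        )
        profile, truth = generate_profile(
            spec, _monotone_effects(spec, amplitude), envelope_half_width=half_width, cfg=cfg
        )
        called = annotate_activities(profile, envelopes, cfg)
        n_readouts = len(profile.readouts())
        summary = evaluate_recovery(called, truth, n_readouts=n_readouts)
        tp += summary.n_true_positive
        fp += summary.n_false_positive
        expected_total += len(truth.expected_annotations)
        readouts_total += n_readouts
    return RecoveryResult(
        n_seeds=n_seeds,
        n_expected_total=expected_total,
        n_true_positive=tp,
        n_false_positive=fp,
        n_readouts_total=readouts_total,
        sensitivity=tp / expected_total if expected_total else 1.0,
        false_annotation_rate=fp / readouts_total if readouts_total else 0.0,
    )
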