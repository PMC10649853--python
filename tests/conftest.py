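import pytest

from phenoprofiler import CompoundProfile, VehicleControlSet


def make_profile(series_map, doses=(1.0, 2.0, 3.0, 4.0), compound="cmpd", classes=None):
    """Build a CompoundProfile from {(system, biomarker): [values in dose order]}."""
    classes = classes or {}
    values = {}
    for (system, biomarker), series in series_map.items():
        assert len(series) == len(doses)
        for dose, value in zip(doses, series):
            values[(system, biomarker, dose)] = float(value)
    return CompoundProfile(compound, tuple(doses), values, dict(classes))


def make_controls(samples_map):
    """Build a VehicleControlSet from {(system, biomarker): [replicates]}."""
    controls = VehicleControlSet()
    for key, samples in samples_map.items():
        controls.samples[key] = [float(v) for v in samples]
    return controls


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def controls_factory():
    return make_controls
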