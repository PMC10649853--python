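"""Hit calling, dose-dependent run annotation, and cytotoxicity rules."""



import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoprofiler import (
    AnnotationConfig,
    EnvelopeSet,
    annotate_activities,
    apply_broad_cytotox_exclusion,
    call_hits,
    flag_cytotoxicity,
    label_modulated,
)
from phenoprofiler.annotation import AnnotatedActivity

from conftest import make_profile
from oracle_scanner import brute_force_activities

DOSES = (1.0, 2.0, 3.0, 4.0)


def envelopes(half_width):
    return EnvelopeSet(default_half_width=half_width)


class TestCallHits:
    def test_zero_values_are_never_hits(self):
        profile = make_profile({("3C", "MCP-1"): [0, 0, 0, 0]})
        assert call_hits(profile, envelopes(0.0)) == []

    def test_hit_requires_both_envelope_and_effect_size(self):
        profile = make_profile({("3C", "MCP-1"): [0.0, 0.0, 0.0, 0.15]})
        hits = call_hits(profile, envelopes(0.098))
        assert len(hits) == 1
        assert (hits[0].dose, hits[0].direction) == (4.0, "up")

    def test_large_effect_inside_wide_envelope_is_not_a_hit(self):
        profile = make_profile({("3C", "MCP-1"): [0.0, 0.0, 0.0, 0.105]})
        assert call_hits(profile, envelopes(0.12)) == []

    def test_small_effect_outside_narrow_envelope_is_not_a_hit(self):
        profile = make_profile({("3C", "MCP-1"): [0.0, 0.0, 0.0, 0.08]})
        assert call_hits(profile, envelopes(0.05)) == []

    def test_viability_readouts_can_be_switched_out_of_tallies(self):
        profile = make_profile(
            {("3C", "SRB"): [0, 0, 0, -0.2]},
            classes={("3C", "SRB"): "viability"},
        )
        assert len(call_hits(profile, envelopes(0.05))) == 1
        cfg = AnnotationConfig(include_viability_readouts=False)
        assert call_hits(profile, envelopes(0.05), cfg) == []


class TestAnnotateActivities:
    def test_three_dose_up_run(self):
        profile = make_profile({("3C", "X"): [0.02, 0.12, 0.15, 0.08]})
        acts = annotate_activities(profile, envelopes(0.05))
        assert len(acts) == 1
        act = acts[0]
        assert act.direction == "up"
        assert act.supporting_doses == (2.0, 3.0, 4.0)
        assert act.max_abs_log10_ratio == pytest.approx(0.15)

    def test_alternating_signs_never_annotate(self):
        profile = make_profile({("3C", "X"): [0.12, -0.12, 0.12, -0.12]})
        assert annotate_activities(profile, envelopes(0.05)) == []

    def test_run_without_effect_size_peak_is_rejected(self):
        profile = make_profile({("3C", "X"): [0.08, 0.09, 0.0, 0.0]})
        assert annotate_activities(profile, envelopes(0.05)) == []

    def test_opposite_runs_give_two_activities(self):
        profile = make_profile({("3C", "X"): [0.12, 0.15, -0.15, -0.12]})
        acts = annotate_activities(profile, envelopes(0.05))
        assert {a.direction for a in acts} == {"up", "down"}

    def test_maximal_run_reported_once_not_as_overlapping_pairs(self):
        profile = make_profile({("3C", "X"): [0.12, 0.15, 0.2, 0.18]})
        acts = annotate_activities(profile, envelopes(0.05))
        assert len(acts) == 1
        assert acts[0].supporting_doses == DOSES

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.4, 0.4, allow_nan=False), min_size=4, max_size=4),
        st.floats(0.01, 0.12),
    )
    def test_agrees_with_brute_force_window_scanner(self, series, half_width):
        doses = tuple(float(i + 1) for i in range(len(series)))
        profile = make_profile({("3C", "X"): series}, doses=doses)
        got = sorted(
            (a.direction, tuple(doses.index(d) for d in a.supporting_doses),
             a.max_abs_log10_ratio)
            for a in annotate_activities(profile, envelopes(half_width))
        )
        expected = brute_force_activities(series, half_width)
        assert got == expected

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.4, 0.4, allow_nan=False), min_size=4, max_size=5),
        st.floats(0.01, 0.09),
    )
    def test_every_activity_contains_a_hit(self, series, half_width):
        doses = tuple(float(i + 1) for i in range(len(series)))
        profile = make_profile({("3C", "X"): series}, doses=doses)
        env = envelopes(half_width)
        hits = {(h.dose, h.direction) for h in call_hits(profile, env)}
        for act in annotate_activities(profile, env):
            assert any((d, act.direction) in hits for d in act.supporting_doses)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.4, 0.4, allow_nan=False), min_size=4, max_size=4),
        st.integers(0, 3),
    )
    def test_removing_a_dose_from_the_series_never_adds_activities(self, series, drop):
        # removal keeps the grid slot (as broad-cytotox exclusion does), so a
        # removed interior dose breaks adjacency and can only break runs
        profile = make_profile({("3C", "X"): series})
        smaller = profile.with_excluded([DOSES[drop]])
        env = envelopes(0.05)
        assert len(annotate_activities(smaller, env)) <= len(
            annotate_activities(profile, env)
        )


class TestCytotoxicity:
    def test_single_viability_drop_flags_cytotoxic(self):
        profile = make_profile(
            {("3C", "SRB"): [0, 0, 0, -0.31]}, classes={("3C", "SRB"): "viability"}
        )
        flags = flag_cytotoxicity(profile)
        assert [(f.system, f.dose, f.kind) for f in flags] == [("3C", 4.0, "cytotoxic")]

    def test_exact_threshold_does_not_flag(self):
        profile = make_profile(
            {("3C", "SRB"): [0, 0, 0, -0.3]}, classes={("3C", "SRB"): "viability"}
        )
        assert flag_cytotoxicity(profile) == []

    def test_low_density_proliferation_readout_flags_antiproliferative_only(self):
        profile = make_profile(
            {("SAg", "T cell proliferation"): [0, 0, -0.15, -0.15]},
            classes={("SAg", "T cell proliferation"): "proliferation"},
        )
        flags = flag_cytotoxicity(profile)
        assert {f.kind for f in flags} == {"antiproliferative"}
        assert {f.dose for f in flags} == {3.0, 4.0}

    def test_no_viability_readouts_no_flags(self):
        profile = make_profile({("3C", "MCP-1"): [0, 0, 0, -0.5]})
        assert flag_cytotoxicity(profile) == []


class TestBroadCytotoxExclusion:
    @staticmethod
    def _tox_profile(n_toxic_systems, dose_index=3):
        series = {}
        classes = {}
        systems = ["3C", "4H", "LPS", "SAg"]
        for i, system in enumerate(systems):
            values = [0.0] * 4
            if i < n_toxic_systems:
                values[dose_index] = -0.5
            series[(system, "SRB")] = values
            classes[(system, "SRB")] = "viability"
            series[(system, "MCP-1")] = [0.0, 0.15, 0.2, 0.25]
        return make_profile(series, classes=classes)

    def test_no_flags_leaves_profile_unchanged(self):
        profile = self._tox_profile(0)
        out, excluded = apply_broad_cytotox_exclusion(profile, flag_cytotoxicity(profile))
        assert out is profile
        assert excluded == []

    def test_three_systems_exclude_the_dose_everywhere(self):
        profile = self._tox_profile(3)
        out, excluded = apply_broad_cytotox_exclusion(profile, flag_cytotoxicity(profile))
        assert excluded == [4.0]
        assert out.active_doses == (1.0, 2.0, 3.0)
        assert all(h.dose != 4.0 for h in call_hits(out, envelopes(0.05)))

    def test_two_systems_are_not_broad(self):
        profile = self._tox_profile(2)
        _, excluded = apply_broad_cytotox_exclusion(profile, flag_cytotoxicity(profile))
        assert excluded == []

    def test_excluded_interior_dose_breaks_run_adjacency(self):
        profile = self._tox_profile(3, dose_index=2)  # dose 3.0 becomes toxic
        series = {("BE3C", "tPA"): [0.0, 0.15, 0.2, 0.15]}
        profile2 = make_profile({**{k: profile.series(*k) for k in profile.readouts()}, **series},
                                classes=profile.readout_class)
        out, excluded = apply_broad_cytotox_exclusion(profile2, flag_cytotoxicity(profile2))
        assert excluded == [3.0]
        acts = [a for a in annotate_activities(out, envelopes(0.05)) if a.biomarker == "tPA"]
        # doses 2 and 4 are outside but no longer consecutive across the gap
        assert all(set(a.supporting_doses) != {2.0, 4.0} for a in acts)
        assert acts == []

    def test_all_doses_excluded_yields_empty_active_grid(self):
        series = {("3C", "SRB"): [-0.5] * 4, ("4H", "SRB"): [-0.5] * 4, ("LPS", "SRB"): [-0.5] * 4}
        classes = {k: "viability" for k in series}
        profile = make_profile(series, classes=classes)
        out, excluded = apply_broad_cytotox_exclusion(profile, flag_cytotoxicity(profile))
        assert excluded == [1.0, 2.0, 3.0, 4.0]
        assert out.active_doses == ()
        assert annotate_activities(out, envelopes(0.0)) == []


class TestLabelModulated:
    @staticmethod
    def _act(system, biomarker, direction):
        return AnnotatedActivity(system, biomarker, direction, (1.0, 2.0), 0.2)

    def test_up_and_down_in_different_systems(self):
        acts = [self._act("3C", "X", "down"), self._act("MyoF", "X", "up")]
        assert label_modulated(acts) == {"X"}

    def test_all_down_is_not_modulated(self):
        acts = [self._act("3C", "X", "down"), self._act("MyoF", "X", "down")]
        assert label_modulated(acts) == set()

    def test_both_directions_in_one_system_only_is_not_modulated(self):
        acts = [self._act("3C", "X", "down"), self._act("3C", "X", "up")]
        assert label_modulated(acts) == set()


class TestConfigValidation:
    def test_defaults_are_the_reference_thresholds(self):
        cfg = AnnotationConfig()
        assert cfg.effect_size_threshold == 0.1
        assert cfg.cytotox_threshold == -0.3
        assert cfg.antiproliferative_threshold == -0.1
        assert cfg.broad_cytotox_min_systems == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"effect_size_threshold": 0.0},
            {"min_consecutive": 1},
            {"cytotox_threshold": -0.05},
            {"antiproliferative_threshold": 0.1},
        ],
    )
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnnotationConfig(**kwargs)
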