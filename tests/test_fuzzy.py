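"""Unit and property tests for the generic fuzzy controller algebra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homeoloop.fuzzy import (
    OUTPUT_CENTERS,
    ConfigurationError,
    FuzzySetSpec,
    MeasurementError,
    MembershipModel,
    build_membership,
    evaluate,
    inference,
    update_actuator,
)

SPEC = FuzzySetSpec(30.0, 40.0, 50.0, slope_scale=1.0)
MODEL = build_membership(SPEC)


def symmetric_specs():
    """Specs whose bounds are mirror images about the target."""
    return st.tuples(
        st.floats(-100, 100), st.floats(0.5, 50), st.floats(0.01, 10)
    ).map(lambda p: FuzzySetSpec(p[0] - p[1], p[0], p[0] + p[1], slope_scale=p[2]))


def general_specs():
    return st.tuples(
        st.floats(-100, 100),
        st.floats(0.5, 50),
        st.floats(0.5, 50),
        st.floats(0.01, 10),
    ).map(lambda p: FuzzySetSpec(p[0] - p[1], p[0], p[0] + p[2], slope_scale=p[3]))


class TestMembership:
    def test_centers_sit_at_setpoints_and_midpoints(self):
        assert MODEL.value_classes.centers == (30.0, 35.0, 40.0, 45.0, 50.0)
        assert MODEL.slope_classes.centers == (-2.0, -1.0, 0.0, 1.0, 2.0)

    @pytest.mark.parametrize(
        "x, label, expected",
        [
            (40.0, "normal", 1.0),  # target is the "normal" center
            (37.5, "low", 0.5),  # midpoint of adjacent centers 35 and 40
            (37.5, "normal", 0.5),
            (25.0, "critically low", 1.0),  # shouldered beyond the outer center
            (55.0, "critically high", 1.0),
            (40.0, "low", 0.0),
            (40.0, "high", 0.0),
        ],
    )
    def test_grades_at_landmark_points(self, x, label, expected):
        assert MODEL.value_classes.grade(label, x) == pytest.approx(expected)

    @given(general_specs(), st.floats(-200, 200))
    def test_ruspini_partition(self, spec, x):
        """Grades sum to 1 and at most two classes are active anywhere."""
        grades = build_membership(spec).value_classes.grades(x)
        assert sum(grades) == pytest.approx(1.0)
        assert sum(g > 0 for g in grades) <= 2
        assert all(0.0 <= g <= 1.0 for g in grades)

    @given(symmetric_specs(), st.floats(0, 60))
    def test_mirror_symmetry_about_target(self, spec, d):
        """low at target-d mirrors high at target+d (and the critical pair)."""
        part = build_membership(spec).value_classes
        t = spec.target
        assert part.grade("low", t - d) == pytest.approx(part.grade("high", t + d), abs=1e-12)
        assert part.grade("critically low", t - d) == pytest.approx(
            part.grade("critically high", t + d), abs=1e-12
        )

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            FuzzySetSpec(50.0, 40.0, 60.0, slope_scale=1.0)
        with pytest.raises(ConfigurationError):
            FuzzySetSpec(30.0, 40.0, 50.0, slope_scale=0.0)


class TestEvaluate:
    def test_at_target_with_zero_slope_factor_is_exactly_zero(self):
        assert evaluate(MODEL, 40.0, 0.0, +1) == 0.0

    def test_boundary_value_saturates_factor(self):
        # only "critically low" x "steady" fires -> consequent "strong increase"
        assert evaluate(MODEL, 30.0, 0.0, +1) == pytest.approx(1.0)
        assert evaluate(MODEL, 50.0, 0.0, +1) == pytest.approx(-1.0)
        assert evaluate(MODEL, 25.0, 0.0, +1) == pytest.approx(1.0)

    def test_polarity_flips_the_factor(self):
        # a ventilator-style loop: high variable asks for MORE actuator
        assert evaluate(MODEL, 50.0, 0.0, -1) == pytest.approx(1.0)
        assert evaluate(MODEL, 40.0, 0.0, -1) == 0.0

    def test_slope_alone_drives_the_factor(self):
        # steady value but rising fast -> pull back
        assert evaluate(MODEL, 40.0, 2.0, +1) == pytest.approx(-1.0)
        assert evaluate(MODEL, 40.0, -2.0, +1) == pytest.approx(1.0)

    def test_antisymmetry_on_value_slope_grid(self):
        """factor(target+d, s) == -factor(target-d, -s) on a 21x21 grid."""
        for d in np.linspace(0.0, 10.0, 21):
            for s in np.linspace(-2.0, 2.0, 21):
                f_plus = evaluate(MODEL, 40.0 + d, s, +1)
                f_minus = evaluate(MODEL, 40.0 - d, -s, +1)
                assert f_plus == pytest.approx(-f_minus, abs=1e-12)

    @given(symmetric_specs(), st.floats(-2, 2))
    def test_monotone_nonincreasing_in_value(self, spec, slope_rel):
        """More of the variable never asks for more infusion."""
        model = build_membership(spec)
        slope = slope_rel * spec.slope_scale
        grid = np.linspace(spec.lower_bound - 1, spec.upper_bound + 1, 41)
        factors = [evaluate(model, float(v), slope, +1) for v in grid]
        assert all(b <= a + 1e-12 for a, b in zip(factors, factors[1:]))

    def test_factor_always_within_unit_interval(self):
        for v in np.linspace(0, 80, 33):
            for s in np.linspace(-5, 5, 21):
                assert -1.0 <= evaluate(MODEL, float(v), float(s), +1) <= 1.0

    def test_nonfinite_input_raises_measurement_error(self):
        with pytest.raises(MeasurementError):
            evaluate(MODEL, float("nan"), 0.0, +1)
        with pytest.raises(MeasurementError):
            evaluate(MODEL, 40.0, float("inf"), +1)

    def test_fired_rules_are_audited(self):
        _, fired = inference(MODEL, 37.5, 0.0)
        assert {(r.value_class, r.output_class) for r in fired} == {
            ("low", "increase"),
            ("normal", "hold"),
        }
        assert all(0 < r.strength <= 1 for r in fired)


def centroid_oracle(consequent_strengths):
    """Independent Mamdani centroid: clipped output triangles, max-aggregated,
    integrated on a 41-point grid.

    Output classes are unit triangles of half-width 0.5 at centers
    {-1, -0.5, 0, +0.5, +1}; the grid spans [-2, 2] so every triangle's
    support is interior and symmetric about its on-grid center.
    """
    z = np.linspace(-2.0, 2.0, 41)
    agg = np.zeros_like(z)
    for center, w in zip(OUTPUT_CENTERS, consequent_strengths):
        mu = np.minimum(np.maximum(0.0, 1.0 - np.abs(z - center) / 0.5), w)
        agg = np.maximum(agg, mu)
    return float(np.sum(z * agg) / np.sum(agg))


class TestDefuzzification:
    @pytest.mark.parametrize("k", range(5))
    @pytest.mark.parametrize("strength", [0.25, 0.5, 1.0])
    def test_singleton_consequent_matches_centroid_oracle(self, k, strength):
        """Weighted-mean defuzzification equals the integrated Mamdani
        centroid whenever a single consequent fires."""
        strengths = [0.0] * 5
        strengths[k] = strength
        oracle = centroid_oracle(strengths)
        weighted_mean = sum(
            w * c for w, c in zip(strengths, OUTPUT_CENTERS)
        ) / sum(strengths)
        assert weighted_mean == pytest.approx(oracle, abs=1e-9)
        assert weighted_mean == OUTPUT_CENTERS[k]

    def test_crisp_inputs_reproduce_singleton_oracle_through_evaluate(self):
        # crisp memberships: value at a class center, slope at a class center
        for value, expected in [(30.0, 1.0), (35.0, 0.5), (40.0, 0.0), (45.0, -0.5), (50.0, -1.0)]:
            strengths = [0.0] * 5
            strengths[OUTPUT_CENTERS.index(expected)] = 1.0
            assert evaluate(MODEL, value, 0.0, +1) == pytest.approx(
                centroid_oracle(strengths), abs=1e-9
            )


class TestUpdateActuator:
    @pytest.mark.parametrize(
        "current, factor, expected",
        [
            (10.0, 0.0, 10.0),  # zero factor is the identity
            (10.0, 1.0, 15.0),  # +1 at gain 0.5 -> +50%
            (10.0, -1.0, 5.0),
            (80.0, 1.0, 100.0),  # clipped at the upper limit
        ],
    )
    def test_multiplicative_update(self, current, factor, expected):
        assert update_actuator(current, factor, 0.5, (0.0, 100.0)) == expected

    def test_restart_floor_revives_a_stopped_pump(self):
        assert update_actuator(0.0, 1.0, 0.5, (0.0, 100.0), restart_floor=2.0) == 2.0
        # no restart on a non-positive factor
        assert update_actuator(0.0, 0.0, 0.5, (0.0, 100.0), restart_floor=2.0) == 0.0
        assert update_actuator(0.0, -0.5, 0.5, (0.0, 100.0), restart_floor=2.0) == 0.0

    @given(
        st.floats(0, 100),
        st.floats(-1, 1),
        st.floats(0.01, 2),
    )
    def test_never_leaves_limits_and_zero_factor_is_fixed_point(self, rate, factor, gain):
        new = update_actuator(rate, factor, gain, (0.0, 100.0), restart_floor=2.0)
        assert 0.0 <= new <= 100.0
        assert update_actuator(rate, 0.0, gain, (0.0, 100.0)) == min(100.0, max(0.0, rate))

    def test_invalid_limits_and_gain_rejected(self):
        with pytest.raises(ConfigurationError):
            update_actuator(1.0, 0.0, 0.5, (10.0, 0.0))
        with pytest.raises(ConfigurationError):
            update_actuator(1.0, 0.0, -0.5, (0.0, 10.0))
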