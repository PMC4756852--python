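"""Trace extraction, recruitment calling, threshold estimation, kinetics
fits and the permutation test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from laserddr import (
    IntensityTrace,
    RoiSpec,
    call_recruitment,
    compare_groups,
    extract_trace,
    fit_kinetics,
    relative_increase,
    threshold_power,
    transient_peak_time,
)
from laserddr.errors import (
    DegenerateInputError,
    InvalidArgumentError,
)

ROI = RoiSpec(damage_rect=(2, 4, 2, 6), background_rect=(6, 8, 2, 6))


def make_stack(n_frames=6, shape=(10, 10), fill=100.0):
    return np.full((n_frames, *shape), fill, dtype=float)


def make_trace(times, normalized, background=100.0):
    times = np.asarray(times, float)
    norm = np.asarray(normalized, float)
    return IntensityTrace(times, background * (1 + norm), np.full_like(norm, background))


class TestExtractTrace:
    def test_uniform_stack_gives_zero_contrast(self):
        trace = extract_trace(make_stack(), ROI)
        assert np.allclose(trace.normalized, 0.0)

    def test_twofold_damage_signal_gives_one(self):
        stack = make_stack()
        stack[3, 2:4, 2:6] = 200.0
        trace = extract_trace(stack, ROI)
        assert trace.normalized[3] == pytest.approx(1.0)
        assert np.allclose(np.delete(trace.normalized, 3), 0.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_gain_invariance(self, gain):
        stack = make_stack()
        stack[:, 2:4, 2:6] = 150.0
        a = extract_trace(stack, ROI).normalized
        b = extract_trace(stack * gain, ROI).normalized
        assert np.allclose(a, b, atol=1e-9)

    def test_mask_precedence_over_rect(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        roi = RoiSpec(damage_rect=(2, 4, 2, 6), damage_mask=mask, background_rect=(6, 8, 2, 6))
        stack = make_stack()
        stack[:, 0, 0] = 300.0
        assert np.allclose(extract_trace(stack, roi).normalized, 2.0)

    def test_roi_out_of_bounds(self):
        roi = RoiSpec(damage_rect=(0, 20, 0, 2), background_rect=(6, 8, 2, 6))
        with pytest.raises(InvalidArgumentError):
            extract_trace(make_stack(), roi)

    def test_overlapping_rois_rejected(self):
        roi = RoiSpec(damage_rect=(2, 6, 2, 6), background_rect=(5, 8, 2, 6))
        with pytest.raises(InvalidArgumentError):
            extract_trace(make_stack(), roi)

    def test_nonpositive_background_is_degenerate(self):
        stack = make_stack()
        stack[2, 6:8, 2:6] = 0.0
        with pytest.raises(DegenerateInputError):
            extract_trace(stack, ROI)


class TestRelativeIncrease:
    def test_flat_trace_is_zero(self):
        trace = make_trace(range(5), [0, 0, 0, 0, 0])
        assert relative_increase(trace, 2) == pytest.approx(0.0)

    def test_half_increase(self):
        trace = IntensityTrace(
            np.arange(4.0), np.array([100.0, 100, 150, 120]), np.full(4, 100.0)
        )
        assert relative_increase(trace, 2) == pytest.approx(0.5)

    def test_requires_pre_and_post_frames(self):
        trace = make_trace(range(3), [0, 0, 0])
        with pytest.raises(InvalidArgumentError):
            relative_increase(trace, 0)
        with pytest.raises(InvalidArgumentError):
            relative_increase(trace, 3)


class TestCallRecruitment:
    def test_flat_trace_not_recruited(self):
        call = call_recruitment(make_trace(range(10), np.zeros(10)), window_min=9)
        assert not call.recruited
        assert call.onset_time_min is None

    def test_onset_at_first_sustained_crossing(self):
        norm = [0, 0, 0, 0.05, 0.2, 0.3, 0.4, 0.5]
        call = call_recruitment(make_trace(range(8), norm), window_min=7)
        assert call.recruited
        assert call.onset_time_min == 4.0
        assert call.peak_value == pytest.approx(0.5)

    def test_single_frame_spike_is_not_sustained(self):
        norm = [0, 0, 0.5, 0, 0, 0]
        call = call_recruitment(make_trace(range(6), norm), window_min=5)
        assert not call.recruited

    def test_signal_outside_window_ignored(self):
        norm = [0, 0, 0, 0, 0, 0, 0.5, 0.5]
        call = call_recruitment(make_trace(range(8), norm), window_min=5)
        assert not call.recruited

    def test_monotone_in_detection_level(self):
        norm = [0, 0.05, 0.15, 0.25, 0.3, 0.28]
        trace = make_trace(range(6), norm)
        recruited = [
            call_recruitment(trace, window_min=5, detection_level=lv).recruited
            for lv in (0.01, 0.1, 0.2, 0.29, 1.0)
        ]
        # once lost at some level, never regained at a higher one
        assert recruited == sorted(recruited, reverse=True)


def brute_force_threshold(per_power, majority):
    qualifying = [
        p for p, calls in per_power.items()
        if sum(bool(c) for c in calls) / len(calls) > majority
    ]
    return min(qualifying) if qualifying else None


class TestThresholdPower:
    def test_majority_scan_example(self):
        calls = {20: [False] * 8, 25: [True] * 5 + [False] * 3, 60: [True] * 8}
        assert threshold_power(calls) == 25

    def test_exact_half_is_below_threshold(self):
        assert threshold_power({20: [True] * 4 + [False] * 4}) is None

    def test_single_power(self):
        assert threshold_power({60: [True] * 8}) == 60

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            threshold_power({})

    def test_agrees_with_brute_force_oracle(self, rng):
        powers = [20, 25, 60, 85, 100]
        for _ in range(300):
            per_power = {
                p: list(rng.random(rng.integers(1, 12)) < rng.random()) for p in powers
            }
            majority = float(rng.uniform(0.2, 0.8))
            assert threshold_power(per_power, majority) == brute_force_threshold(
                per_power, majority
            )


class TestFitKinetics:
    def test_noiseless_saturating_rise_recovered_exactly(self):
        t = np.arange(0.0, 30.0, 0.5)
        y = 1.0 * (1 - np.exp(-t / 5.0))
        fit = fit_kinetics(make_trace(t, y), "saturating_rise")
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.tau_on_min == pytest.approx(5.0, rel=1e-6)
        assert fit.baseline == pytest.approx(0.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_noiseless_transient_pulse_recovered(self):
        t = np.arange(0.0, 6.0, 0.1)[1:]
        y = 0.9 * (np.exp(-t / 2.0) - np.exp(-t / 0.5))
        fit = fit_kinetics(make_trace(t, y), "transient_pulse")
        assert fit.tau_on_min == pytest.approx(0.5, rel=1e-4)
        assert fit.tau_off_min == pytest.approx(2.0, rel=1e-4)

    def test_transient_peak_matches_closed_form(self):
        tau_on, tau_off = 0.5, 2.0
        t_star = transient_peak_time(tau_on, tau_off)
        assert t_star == pytest.approx(
            tau_on * tau_off * np.log(tau_off / tau_on) / (tau_off - tau_on)
        )
        t = np.linspace(0.01, 6, 2000)
        y = np.exp(-t / tau_off) - np.exp(-t / tau_on)
        assert t[np.argmax(y)] == pytest.approx(t_star, abs=5e-3)

    def test_unknown_model_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_kinetics(make_trace(range(6), np.zeros(6)), "sigmoid")

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_kinetics(make_trace(range(4), np.zeros(4)), "saturating_rise")


class TestCompareGroups:
    def test_identical_groups_give_one(self):
        assert compare_groups([1.0, 2, 3], [1.0, 2, 3], 2000, seed=0) == pytest.approx(
            1.0, abs=0.05
        )

    def test_degenerate_constant_data(self):
        assert compare_groups([5.0] * 4, [5.0] * 4, 100, seed=0) == 1.0

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        assert compare_groups(a, b, 10_000, seed=1) < 0.01

    def test_reproducible_given_seed(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        assert compare_groups(a, b, 5000, seed=7) == compare_groups(a, b, 5000, seed=7)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
            if compare_groups(a, b, 999, seed=rng.integers(2**31)) < 0.05:
                rejections += 1
        # binomial(400, 0.05): 3 sigma is ~0.033
        assert rejections / n_sim == pytest.approx(0.05, abs=0.035)

    def test_groups_too_small_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_groups([1.0], [1.0, 2.0])
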