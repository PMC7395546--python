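"""Pulse detection against an exhaustive oracle, interval statistics, gates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_peaks
from erkpulse.pulses import (
    ExponentialFit,
    InsufficientDataError,
    PulseParams,
    PulseSet,
    classify_pulse_class,
    detect_pulses,
    fit_exponential,
    gate_basal,
    interpulse_intervals,
)
from erkpulse.simulate import SimConfig, simulate_trace, _raised_cosine

RAW = PulseParams(smoothing_window_min=0.0, min_prominence=0.05, min_separation_min=10.0)


def test_constant_trace_has_no_pulses(make_trace):
    ps = detect_pulses(make_trace(np.full(50, 1.1)))
    assert ps.n_pulses == 0 and ps.frequency_per_h == 0.0
    assert interpulse_intervals(ps).size == 0


def test_three_injected_bumps_recovered_exactly():
    cfg = SimConfig(seed=0, pulse_rate_per_h=0.0, noise_sd=0.0, duration_h=12.0)
    tr = simulate_trace(cfg)
    tr.ratio = tr.ratio + _raised_cosine(tr.times_h, np.array([2.0, 6.0, 10.0]), 0.25, 0.3)
    ps = detect_pulses(tr, RAW)
    assert np.allclose(ps.peak_times_h, [2.0, 6.0, 10.0])
    assert np.allclose(interpulse_intervals(ps), [4.0, 4.0])
    assert np.allclose(ps.amplitudes, 0.3)  # prominence above the flat basal
    assert np.allclose(ps.durations_h, 0.25 / 2, atol=0.05)  # FWHM of the raised cosine
    assert ps.frequency_per_h == pytest.approx(3 / 12.0)


def test_too_short_trace_rejected(make_trace):
    with pytest.raises(InsufficientDataError):
        detect_pulses(make_trace([1.0, 1.1]))


def test_non_uniform_sampling_resampled_with_warning():
    times = np.array([0.0, 1 / 12, 2 / 12, 4 / 12, 5 / 12, 6 / 12, 8 / 12])
    from erkpulse.traces import Trace

    tr = Trace("nu", times, np.ones(7))
    with pytest.warns(UserWarning, match="non-uniform"):
        ps = detect_pulses(tr, RAW)
    assert ps.n_pulses == 0


def _grid_trace(y) -> "object":
    from erkpulse.traces import Trace

    y = np.asarray(y, dtype=float)
    return Trace("h0", np.arange(y.size) * 5 / 60.0, y)


@settings(derandomize=True, max_examples=300, deadline=None)
@given(
    y=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=50),
    prom=st.sampled_from([0.0, 0.05, 0.2, 0.5]),
    distance=st.sampled_from([1, 2, 4]),
)
def test_detector_matches_exhaustive_oracle(y, prom, distance):
    """Peak indices agree with a brute-force scan (strict local maxima +
    greedy distance selection + prominence filter) on arbitrary short traces."""
    tr = _grid_trace(y)
    params = PulseParams(0.0, prom, distance * 5.0)  # 5-min sampling
    got = detect_pulses(tr, params).peak_times_h
    expected = tr.times_h[oracle_peaks(y, prom, distance)]
    assert np.array_equal(got, expected)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(y=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=40))
def test_raising_prominence_never_increases_peak_count(y):
    tr = _grid_trace(y)
    counts = [
        detect_pulses(tr, PulseParams(0.0, p, 5.0)).n_pulses for p in (0.0, 0.1, 0.3, 0.6)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_intervals_are_successive_differences():
    ps = PulseSet("c", [1.0, 2.5, 4.0], [0.1] * 3, [0.2] * 3, span_h=10.0)
    assert np.allclose(interpulse_intervals(ps), [1.5, 1.5])
    single = PulseSet("c", [1.0], [0.1], [0.2], span_h=10.0)
    assert interpulse_intervals(single).size == 0


def test_exponential_fit_mle_and_ks_reject_degenerate_intervals():
    fit = fit_exponential(np.full(20, 2.0))
    assert isinstance(fit, ExponentialFit)
    assert fit.mean_interval_h == pytest.approx(2.0)
    assert fit.rate_per_h == pytest.approx(0.5)
    assert fit.ks_p < 0.01  # constant intervals are decidedly not exponential


def test_exponential_fit_recovers_simulated_rate():
    """Mean of n=1000 Exp(1.5 h) draws lies in [1.38, 1.62] h in >= 95% of runs
    (CLT: 1.5 +- 3 * 1.5/sqrt(1000) ~ [1.36, 1.64])."""
    hits = 0
    for seed in range(40):
        x = np.random.default_rng(seed).exponential(1.5, 1000)
        fit = fit_exponential(x)
        hits += 1.38 <= fit.mean_interval_h <= 1.62
    assert hits >= 38


def test_exponential_fit_needs_ten_intervals():
    with pytest.raises(InsufficientDataError):
        fit_exponential([1.0] * 5)


@pytest.mark.parametrize(
    "freq,expected",
    [(1.4, "low"), (1.6, "high"), (0.0, "low"), (1.5, "high")],
)
def test_pulse_class_threshold(freq, expected):
    assert classify_pulse_class(freq) == expected


@pytest.mark.parametrize("ratio,expected", [(1.25, "high"), (1.15, "low"), (1.2, "high")])
def test_basal_gate(ratio, expected):
    assert gate_basal(ratio) == expected


def test_gates_reject_invalid_inputs():
    with pytest.raises(ValueError):
        classify_pulse_class(-0.1)
    with pytest.raises(ValueError):
        gate_basal(0.0)


def test_detected_frequency_increases_with_generator_rate():
    """Detected frequency must respond monotonically to the true pulse rate
    even though overlapping pulses make it a biased (under-)count."""
    from erkpulse.simulate import simulate_cohort

    means = []
    for rate in (0.25, 0.75, 1.5):
        cohort = simulate_cohort([SimConfig(seed=21, pulse_rate_per_h=rate)], 25)
        means.append(np.mean([detect_pulses(t).frequency_per_h for t in cohort]))
    assert means[0] < means[1] < means[2]
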