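"""Generator contracts: determinism, pulse statistics, spatial processes."""

import numpy as np
import pytest
from scipy import stats

from erkpulse.pulses import detect_pulses
from erkpulse.simulate import (
    ConfigError,
    SimConfig,
    SpatialSimConfig,
    draw_pulse_times,
    simulate_cohort,
    simulate_spatial_pattern,
    simulate_trace,
)
from erkpulse.spatial import FieldOfInterest, rdf


MEAN_INTERVAL_H = 1.52  # generator default: mean interpulse interval


def test_no_stochastic_terms_gives_constant_basal_trace():
    tr = simulate_trace(SimConfig(seed=0, pulse_rate_per_h=0.0, noise_sd=0.0, basal_level=1.0))
    assert np.all(tr.ratio == 1.0)
    assert len(tr) == 24 * 12 + 1  # 5-min sampling over 24 h


def test_fixed_seed_reproduces_trace_and_cohort():
    cfg = SimConfig(seed=11)
    a, b = simulate_trace(cfg), simulate_trace(cfg)
    assert np.array_equal(a.ratio, b.ratio) and np.array_equal(a.times_h, b.times_h)

    c1 = simulate_cohort([cfg], 4)
    c2 = simulate_cohort([cfg], 4)
    assert all(np.array_equal(x.ratio, y.ratio) for x, y in zip(c1, c2))


def test_cohort_counts_labels_and_distinct_streams():
    cfgs = [SimConfig(seed=1, label="a"), SimConfig(seed=2, label="b")]
    cohort = simulate_cohort(cfgs, 3)
    assert len(cohort) == 6
    assert [t.label for t in cohort] == ["a"] * 3 + ["b"] * 3
    assert len({t.cell_id for t in cohort}) == 6
    # per-trace sub-seeds give different realizations
    assert not np.array_equal(cohort[0].ratio, cohort[1].ratio)
    with pytest.raises(ConfigError):
        simulate_cohort([], 3)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        simulate_trace(SimConfig(sampling_interval_min=0))
    with pytest.raises(ConfigError):
        simulate_trace(SimConfig(pulse_rate_per_h=5.0, pulse_duration_h=0.25))
    with pytest.raises(ConfigError):
        simulate_trace(SimConfig(reporter_onset_model="coupled_to_pulse_shutdown"))


def test_interpulse_intervals_exponential_ks_over_seeded_runs():
    """Generated gaps are exponential at the configured rate: a KS test at
    alpha=0.01 should pass in >= 95% of 100 seeded runs."""
    rate = 1.0 / MEAN_INTERVAL_H
    passes = 0
    for seed in range(100):
        ev = draw_pulse_times(np.random.default_rng(seed), rate, 400.0)
        p = stats.kstest(np.diff(ev), "expon", args=(0.0, 1.0 / rate)).pvalue
        passes += p > 0.01
    assert passes >= 95


def test_pooled_interval_mean_matches_finite_window_expectation():
    """The pooled gap mean in a finite window T is mu*(T-2mu)/(T-mu) for
    exponential gaps (censoring of the first and last partial gaps); it
    converges to the configured 1.52 h as T grows."""
    mu, T = MEAN_INTERVAL_H, 24.0
    gaps = np.concatenate(
        [np.diff(draw_pulse_times(np.random.default_rng(s), 1.0 / mu, T)) for s in range(600)]
    )
    assert gaps.size >= 5000
    expected = mu * (T - 2 * mu) / (T - mu)
    assert np.mean(gaps) == pytest.approx(expected, rel=0.03)

    long_gaps = np.concatenate(
        [np.diff(draw_pulse_times(np.random.default_rng(s), 1.0 / mu, 1500.0)) for s in range(8)]
    )
    assert np.mean(long_gaps) == pytest.approx(mu, rel=0.02)


def test_realized_pulse_count_rate_converges_to_configured_rate():
    rate, T, n = 1.0 / MEAN_INTERVAL_H, 24.0, 400  # ~6300 expected pulses
    total = sum(draw_pulse_times(np.random.default_rng(s), rate, T).size for s in range(n))
    assert total / (n * T) == pytest.approx(rate, rel=0.1)


def test_negative_control_cohort_has_nearly_no_detected_pulses():
    """Pulse-free traces with small noise emulate the mutated biosensor: the
    detector should report a mean frequency close to the generator truth 0."""
    cohort = simulate_cohort([SimConfig(seed=5, pulse_rate_per_h=0.0, noise_sd=0.02)], 30)
    freqs = [detect_pulses(tr).frequency_per_h for tr in cohort]
    assert np.mean(freqs) < 0.1


def test_reporter_rises_only_after_pulse_shutdown():
    cfg = SimConfig(seed=9, reporter_onset_model="coupled_to_pulse_shutdown", shutdown_time_h=10.0)
    tr = simulate_trace(cfg)
    before = tr.times_h <= 10.0
    assert np.all(tr.reporter[before] == 0.0)
    assert np.all(np.diff(tr.reporter[~before]) > 0)
    # pulses stop after shutdown: the late trace is basal + noise only
    late = tr.ratio[tr.times_h > 10.0 + cfg.pulse_duration_h]
    assert np.all(np.abs(late - cfg.basal_level) < 6 * cfg.noise_sd)


def test_spatial_points_inside_field_and_deterministic():
    field = FieldOfInterest.rectangle(500, 300)
    for process, marks in [("csr", "independent"), ("thomas_cluster", "clustered_low_pulse")]:
        cfg = SpatialSimConfig(seed=3, n_points=400, field=field, process=process, mark_model=marks)
        pat = simulate_spatial_pattern(cfg)
        assert len(pat.points) == 400
        assert pat.field.contains(pat.points["x_um"], pat.points["y_um"]).all()
        again = simulate_spatial_pattern(cfg)
        assert pat.points.equals(again.points)


def test_single_point_pattern_is_degenerate_for_rdf():
    cfg = SpatialSimConfig(seed=1, n_points=1)
    pat = simulate_spatial_pattern(cfg)
    assert len(pat.points) == 1
    with pytest.raises(ValueError):
        rdf(pat.points, cfg.field)


def test_clustered_marks_require_cluster_process():
    with pytest.raises(ConfigError):
        SpatialSimConfig(process="csr", mark_model="clustered_low_pulse").validate()
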