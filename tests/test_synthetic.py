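import numpy as np
import pytest
from scipy import stats

from adtfnet.synthetic import (
    ConnectivitySchedule,
    ScheduleEntry,
    SimulationConfig,
    UnstableScheduleError,
    assert_stable,
    coefficient_tensor,
    companion_spectral_radius,
    default_schedule,
    make_leadfield,
    project_to_scalp,
    simulate_dataset,
    simulate_rts,
    simulate_tv_mvar,
)


def test_empty_schedule_gives_uncoupled_nodes():
    config = SimulationConfig(n_nodes=2, n_epochs=20, osc_freqs=(10.0, 7.0), seed=0)
    x = simulate_tv_mvar(ConnectivitySchedule(()), config)
    a = x[0].ravel()
    b = x[1].ravel()
    assert a.size >= 3000
    for lag in (0, 1, 2):
        r = np.corrcoef(a[lag:], b[: b.size - lag])[0, 1]
        assert abs(r) < 0.1


def test_scheduled_coefficient_recovered_by_regression():
    config = SimulationConfig(n_nodes=2, n_epochs=100, osc_freqs=(10.0, 7.0), seed=1)
    sch = ConnectivitySchedule((ScheduleEntry(0, 1, 1, 0.5, -0.2, 1.0),))
    x = simulate_tv_mvar(sch, config)
    # regress node 1 on its own lags and node 0's lag-1, pooled over epochs
    y = x[1, 2:, :].ravel()
    Z = np.stack(
        [x[1, 1:-1, :].ravel(), x[1, :-2, :].ravel(), x[0, 1:-1, :].ravel()], axis=1
    )
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    assert abs(beta[2] - 0.5) < 0.05


def test_simulation_is_seed_deterministic():
    config = SimulationConfig(n_nodes=2, n_epochs=5, osc_freqs=(10.0, 7.0), seed=3)
    sch = default_schedule()
    c4 = SimulationConfig(n_epochs=5, seed=3)
    assert np.array_equal(simulate_tv_mvar(sch, c4), simulate_tv_mvar(sch, c4))
    assert np.array_equal(
        simulate_tv_mvar(ConnectivitySchedule(()), config),
        simulate_tv_mvar(ConnectivitySchedule(()), config),
    )


def test_unstable_schedule_rejected_with_diagnosis():
    config = SimulationConfig(n_nodes=2, n_epochs=5, osc_freqs=(10.0, 7.0), seed=0)
    sch = ConnectivitySchedule(
        (
            ScheduleEntry(0, 1, 1, 0.9, 0.0, 1.0),
            ScheduleEntry(1, 0, 1, 0.9, 0.0, 1.0),
        )
    )
    with pytest.raises(UnstableScheduleError, match="spectral radius"):
        simulate_tv_mvar(sch, config)


def test_schedule_lag_beyond_order_rejected():
    config = SimulationConfig(n_nodes=2, n_epochs=5, osc_freqs=(10.0, 7.0), p_true=2)
    sch = ConnectivitySchedule((ScheduleEntry(0, 1, 3, 0.2, 0.0, 1.0),))
    with pytest.raises(ValueError, match="lag"):
        coefficient_tensor(sch, config)


def test_default_schedule_is_stable_everywhere():
    config = SimulationConfig()
    tensor = coefficient_tensor(default_schedule(), config, coupling_scale=1.2)
    rho = assert_stable(tensor, config.epoch_times)
    assert rho < 1.0


def test_scheduled_values_materialized_on_half_open_interval():
    config = SimulationConfig()
    tensor = coefficient_tensor(default_schedule(), config)
    t = config.epoch_times
    a = tensor[2, 0, 0, :]  # V1 -> STG lag-1 weight over time
    assert np.all(a[(t >= 0.25) & (t < 0.9)] == 0.25)
    assert np.all(a[(t < 0.25) | (t >= 0.9)] == 0.0)


def test_companion_radius_scalar_case():
    coeffs = np.array([[[0.5]]])  # AR(1), a = 0.5
    assert companion_spectral_radius(coeffs) == pytest.approx(0.5)


def test_leadfield_full_rank_and_unit_columns():
    L = make_leadfield(4, 4, seed=0)
    assert np.linalg.matrix_rank(L) == 4
    assert np.abs(np.linalg.norm(L, axis=0) - 1.0).max() < 1e-12
    assert np.array_equal(L, make_leadfield(4, 4, seed=0))
    assert not np.array_equal(L, make_leadfield(4, 4, seed=1))


def test_leadfield_impossible_rank_errors():
    with pytest.raises(ValueError, match="rank"):
        make_leadfield(3, 4)


def test_project_to_scalp_noiseless_limit():
    rng = np.random.default_rng(0)
    sources = rng.normal(size=(4, 300, 2))
    L = make_leadfield(8, 4, seed=0)
    rec = project_to_scalp(sources, L, sensor_snr=np.inf)
    assert np.allclose(rec.data, np.einsum("cs,ste->cte", L, sources))


def test_project_to_scalp_realized_power_ratio():
    rng = np.random.default_rng(1)
    sources = rng.normal(size=(4, 300, 100))
    L = make_leadfield(8, 4, seed=1)
    rec = project_to_scalp(sources, L, sensor_snr=4.0, seed=5)
    clean = np.einsum("cs,ste->cte", L, sources)
    noise = rec.data - clean
    ratio = np.mean(clean**2) / np.mean(noise**2)
    assert abs(ratio - 4.0) < 0.4


def test_project_zero_sources_gives_pure_unit_noise():
    sources = np.zeros((4, 300, 10))
    L = make_leadfield(8, 4, seed=2)
    rec = project_to_scalp(sources, L, sensor_snr=4.0, seed=3)
    assert abs(rec.data.std() - 1.0) < 0.05


def test_project_invalid_snr_errors():
    with pytest.raises(ValueError):
        project_to_scalp(np.zeros((2, 300, 1)), make_leadfield(4, 2), sensor_snr=0.0)


def test_rts_noiseless_is_exactly_linear():
    flows = np.array([0.8, 1.0, 1.1, 0.9, 1.2])
    rts = simulate_rts(flows, target_r=1.0, noise_sd=0.0)
    assert stats.pearsonr(flows, rts).statistic == pytest.approx(1.0)
    rts_neg = simulate_rts(flows, target_r=-1.0, noise_sd=0.0)
    assert stats.pearsonr(flows, rts_neg).statistic == pytest.approx(-1.0)


def test_rts_monte_carlo_calibration():
    rng = np.random.default_rng(9)
    rs = []
    rs0 = []
    for s in range(200):
        flows = rng.normal(1.0, 0.1, 15)
        rts = simulate_rts(flows, target_r=-0.55, noise_sd=15.0, seed=s)
        rs.append(stats.pearsonr(flows, rts).statistic)
        rts0 = simulate_rts(flows, target_r=0.0, noise_sd=15.0, seed=s)
        rs0.append(stats.pearsonr(flows, rts0).statistic)
    assert abs(np.mean(rs) - (-0.55)) < 0.1
    assert abs(np.mean(rs0)) < 0.1


def test_rts_mean_in_plausible_range():
    rts = simulate_rts(np.array([0.8, 1.0, 1.2]), target_r=-0.55, noise_sd=15.0)
    assert 230.0 < rts.mean() < 330.0


def test_rts_degenerate_inputs_error():
    with pytest.raises(ValueError):
        simulate_rts(np.ones(5))  # constant flows
    with pytest.raises(ValueError):
        simulate_rts(np.array([1.0, 2.0]))  # too few subjects
    with pytest.raises(ValueError):
        simulate_rts(np.array([1.0, 2.0, 3.0]), target_r=1.5)


def test_simulate_dataset_deterministic_and_consistent():
    config = SimulationConfig(n_subjects=3, n_epochs=5, seed=12)
    d1 = simulate_dataset(config)
    d2 = simulate_dataset(config)
    assert len(d1.subjects) == 3
    assert np.array_equal(d1.rts, d2.rts)
    for s1, s2 in zip(d1.subjects, d2.subjects):
        assert np.array_equal(s1.scalp.data, s2.scalp.data)
        assert np.array_equal(s1.sources_truth, s2.sources_truth)
        assert s1.scalp.n_channels == config.n_channels
        assert s1.scalp.n_samples == config.n_samples
        assert 0.7 <= s1.coupling_scale <= 1.2
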