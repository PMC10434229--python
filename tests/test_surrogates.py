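import numpy as np
import pytest
from scipy import stats

from adtfnet.surrogates import (
    build_null,
    phase_randomize,
    phase_randomize_epochs,
    signed_rank_p_greater,
    threshold_network,
)
from adtfnet.synthetic import (
    ConnectivitySchedule,
    ScheduleEntry,
    SimulationConfig,
    simulate_tv_mvar,
)


def test_phase_randomization_preserves_amplitude_spectrum():
    rng = np.random.default_rng(0)
    for n_samples in (300, 301):  # even (Nyquist bin) and odd lengths
        x = rng.normal(size=(3, n_samples))
        y = phase_randomize(x, np.random.default_rng(1))
        assert np.abs(np.abs(np.fft.rfft(y)) - np.abs(np.fft.rfft(x))).max() < 1e-9
        assert np.abs(y.mean(axis=-1) - x.mean(axis=-1)).max() < 1e-9
        assert np.isrealobj(y)


def test_phase_randomization_seed_behavior():
    x = np.random.default_rng(2).normal(size=(2, 128))
    y1 = phase_randomize(x, 10)
    y2 = phase_randomize(x, 10)
    y3 = phase_randomize(x, 11)
    assert np.array_equal(y1, y2)
    assert not np.array_equal(y1, y3)
    assert np.abs(np.abs(np.fft.rfft(y3)) - np.abs(np.fft.rfft(y1))).max() < 1e-9


def test_phase_randomization_input_validation():
    with pytest.raises(ValueError):
        phase_randomize(np.array([[1.0, np.nan, 0.0, 0.0]]), 0)
    with pytest.raises(ValueError):
        phase_randomize(np.zeros((1, 3)), 0)


def test_phase_randomize_epochs_shape_and_spectrum():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(2, 300, 5))
    out = phase_randomize_epochs(data, 4)
    assert out.shape == data.shape
    spec_in = np.abs(np.fft.rfft(data, axis=1))
    spec_out = np.abs(np.fft.rfft(out, axis=1))
    assert np.abs(spec_in - spec_out).max() < 1e-9


def _coupled_subject(seed, n_epochs=60):
    config = SimulationConfig(
        n_nodes=2, n_epochs=n_epochs, osc_freqs=(10.0, 7.0), seed=seed
    )
    sch = ConnectivitySchedule((ScheduleEntry(0, 1, 1, 0.5, -0.2, 1.0),))
    return simulate_tv_mvar(sch, config, rng=np.random.default_rng(seed))


def test_build_null_single_surrogate_valid_range():
    data = _coupled_subject(0, n_epochs=20)
    null = build_null(data, p=2, n_surrogates=1, seed=0)
    assert null.values.shape[-1] == 1
    assert null.values.min() >= 0.0 and null.values.max() <= 1.0
    assert np.isfinite(null.values).all()


def test_build_null_reproducible_and_destroys_coupling():
    from adtfnet.adtf import adtf
    from adtfnet.tvar import fit_mvaar_kalman

    data = _coupled_subject(1)
    null = build_null(data, p=2, n_surrogates=20, seed=5)
    null2 = build_null(data, p=2, n_surrogates=20, seed=5)
    assert np.array_equal(null.values, null2.values)
    observed = adtf(fit_mvaar_kalman(data, p=2, uc=1e-3)).upsilon2
    post = slice(100, None)
    q95 = np.quantile(null.values[1, 0, post, :], 0.95, axis=-1)
    # observed flow on the true edge exceeds the null band at active times
    assert np.mean(observed[1, 0, post] > q95) > 0.9


def test_signed_rank_matches_scipy_oracle():
    rng = np.random.default_rng(6)
    d = rng.normal(0.3, 1.0, size=(40, 15))
    p_vec = signed_rank_p_greater(d)
    for row, p in zip(d, p_vec):
        expected = stats.wilcoxon(row, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(expected, rel=1e-10)


def test_signed_rank_handles_zeros_via_fallback():
    d = np.array([[0.0, 1.0, 2.0, -1.0, 3.0, 0.5, 1.5, -0.2]])
    expected = stats.wilcoxon(d[0], alternative="greater", method="exact").pvalue
    assert signed_rank_p_greater(d)[0] == pytest.approx(expected)


def _toy_network(n_subj=6, n_surr=40, bump=0.0, seed=0):
    """Hand-built observed/null stacks: 2 nodes, 3 time points."""
    from adtfnet.surrogates import SurrogateNull

    rng = np.random.default_rng(seed)
    observed, nulls = [], []
    for s in range(n_subj):
        null_vals = rng.uniform(0.0, 0.1, size=(2, 2, 3, n_surr))
        obs = rng.uniform(0.0, 0.1, size=(2, 2, 3))
        obs[1, 0, :] += bump  # candidate edge 0 -> 1
        observed.append(obs)
        nulls.append(SurrogateNull(values=null_vals, n_surrogates=n_surr, seed=s))
    return observed, nulls


def test_threshold_bonferroni_family_size():
    observed, nulls = _toy_network()
    net = threshold_network(observed, nulls, times=np.arange(3) / 250.0)
    assert net.m == 2  # n(n-1) for 2 nodes
    four = [np.random.default_rng(s).uniform(size=(4, 4, 3)) for s in range(6)]
    from adtfnet.surrogates import SurrogateNull

    nulls4 = [
        SurrogateNull(np.random.default_rng(s).uniform(size=(4, 4, 3, 20)), 20, s)
        for s in range(6)
    ]
    net4 = threshold_network(four, nulls4, times=np.arange(3) / 250.0)
    assert net4.m == 12
    assert net4.alpha / net4.m == pytest.approx(0.05 / 12)


def test_threshold_observed_below_null_never_fires():
    observed, nulls = _toy_network(bump=0.0, seed=1)
    for obs in observed:
        obs -= 1.0  # strictly below every null value
    net = threshold_network(observed, nulls, times=np.arange(3) / 250.0)
    assert not net.mask.any()


def test_threshold_strong_edge_fires_and_diagonal_never():
    observed, nulls = _toy_network(n_subj=10, bump=5.0, seed=2)
    net = threshold_network(observed, nulls, times=np.arange(3) / 250.0)
    assert net.mask[1, 0].all()
    assert not net.mask[0, 1].any()
    assert not net.mask[np.arange(2), np.arange(2), :].any()


def test_threshold_alpha_monotonicity():
    observed, nulls = _toy_network(n_subj=10, bump=0.08, seed=3)
    small = threshold_network(observed, nulls, np.arange(3) / 250.0, alpha=0.01)
    large = threshold_network(observed, nulls, np.arange(3) / 250.0, alpha=0.10)
    assert np.all(large.mask[small.mask])  # growing alpha never removes an edge


def test_threshold_small_group_signed_rank_errors():
    observed, nulls = _toy_network(n_subj=4)
    with pytest.raises(ValueError, match="quantile"):
        threshold_network(observed, nulls, np.arange(3) / 250.0)
    net = threshold_network(
        observed, nulls, np.arange(3) / 250.0, group_test="quantile"
    )
    assert net.mask.shape == (2, 2, 3)


def test_threshold_input_validation():
    observed, nulls = _toy_network()
    with pytest.raises(ValueError):
        threshold_network(observed[:3], nulls, np.arange(3) / 250.0)
    with pytest.raises(ValueError):
        threshold_network(observed, nulls, np.arange(3) / 250.0, correction="fdr")
    with pytest.raises(ValueError):
        threshold_network(observed, nulls, np.arange(3) / 250.0, group_test="anova")


def test_group_threshold_flags_shared_coupling_not_reverse():
    """15 subjects sharing a 1 -> 2 coupling: the true edge is flagged at
    active times and its reverse is not, across replicate datasets."""
    from adtfnet.adtf import adtf
    from adtfnet.tvar import fit_mvaar_kalman

    hits = 0
    n_reps = 5
    for rep in range(n_reps):
        observed, nulls = [], []
        for s in range(15):
            data = _coupled_subject(seed=1000 * rep + s, n_epochs=40)
            model = fit_mvaar_kalman(data, p=2, uc=1e-3)
            idx = np.arange(100, 300, 5)
            observed.append(adtf(model, time_indices=idx).upsilon2)
            nulls.append(
                build_null(data, p=2, n_surrogates=30, seed=rep * 100 + s,
                           time_indices=idx)
            )
        net = threshold_network(observed, nulls, times=idx / 250.0 - 0.2)
        if net.mask[1, 0].any() and not net.mask[0, 1].any():
            hits += 1
    assert hits >= 4
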