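"""Numba kernels for the hot loops (multi-trial Kalman fit, AR simulation).

The Kalman measurement update is written in information form: with Z the
(epochs x n*p) lagged design at time t and sigma^2 the tracked innovation
scale, the posterior state covariance is (P^-1 + Z'Z/sigma^2)^-1. For the
ensemble sizes used here (E ~ 100, n*p ~ 8) this is the same update as the
textbook gain form but O((np)^3) instead of O(E^3) per step.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def kalman_tv_mvar(data, p, uc, sigma2_floor=1e-12):
    """Track time-varying MVAR coefficients across an epoch ensemble.

    Parameters
    ----------
    data : float64 (n, T, E)
        Node time series, epochs as independent realizations.
    p : int
        Model order.
    uc : float
        Update constant: state-noise variance added to each diagonal element
        of the coefficient covariance per step, and the smoothing rate of the
        innovation covariance.

    Returns
    -------
    coeffs : (n, n*p, T) coefficient trajectory; columns blocked by lag,
        block j holds the lag-(j+1) matrix.
    innov : (n, n, T) exponentially smoothed innovation covariance.
    status : int, -1 on success, else the time index where the state
        diverged (non-finite values).
    """
    n, T, E = data.shape
    d = n * p
    C = np.zeros((n, d))
    P = np.eye(d)
    coeffs = np.zeros((n, d, T))
    innov = np.zeros((n, n, T))

    # innovation covariance initialized at the empirical data covariance
    flat = np.ascontiguousarray(data).reshape(n, T * E)
    mu = np.empty(n)
    for i in range(n):
        mu[i] = flat[i].mean()
    V = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            V[i, j] = ((flat[i] - mu[i]) * (flat[j] - mu[j])).mean()

    for t in range(p, T):
        Z = np.empty((E, d))
        for j in range(p):
            Z[:, j * n : (j + 1) * n] = data[:, t - 1 - j, :].T
        for i in range(d):
            P[i, i] += uc
        sigma2 = np.trace(V) / n
        if sigma2 < sigma2_floor:
            sigma2 = sigma2_floor
        Pinv = np.linalg.inv(P)
        G = Z.T @ Z
        Ppost = np.linalg.inv(Pinv + G / sigma2)
        Y = data[:, t, :]
        B = Z.T @ np.ascontiguousarray(Y.T)
        C = np.ascontiguousarray(
            (Ppost @ (Pinv @ np.ascontiguousarray(C.T) + B / sigma2)).T
        )
        P = Ppost
        if not np.all(np.isfinite(C)):
            return coeffs, innov, t
        err = Y - C @ Z.T
        V = (1.0 - uc) * V + uc * (err @ np.ascontiguousarray(err.T) / E)
        coeffs[:, :, t] = C
        innov[:, :, t] = V

    # burn-in: no full lag history inside the epoch; hold the first estimate
    for t in range(p):
        coeffs[:, :, t] = coeffs[:, :, p]
        innov[:, :, t] = innov[:, :, p]
    return coeffs, innov, -1


@njit(cache=True)
def simulate_var_epochs(coeff_tpnn, innovations, burn_pnn, n_burn):
    """Drive a time-varying VAR with given innovations, one epoch at a time.

    coeff_tpnn : (T, p, n, n) coefficients on the epoch time axis.
    innovations : (n, T + n_burn, E) unit-variance white noise.
    burn_pnn : (p, n, n) stationary coefficients used during the burn-in
        run-up so the process is stationary at the first epoch sample.
    """
    T, p, n, _ = coeff_tpnn.shape
    E = innovations.shape[2]
    total = T + n_burn
    out = np.zeros((n, T, E))
    for e in range(E):
        x = np.zeros((total, n))
        for t in range(total):
            acc = innovations[:, t, e].copy()
            for j in range(p):
                tj = t - 1 - j
                if tj < 0:
                    continue
                A = burn_pnn[j] if t < n_burn else coeff_tpnn[t - n_burn, j]
                acc += A @ x[tj]
            x[t] = acc
        out[:, :, e] = x[n_burn:].T
    return out
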