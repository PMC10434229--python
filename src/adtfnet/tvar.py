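"""Time-varying MVAR estimation: multi-trial Kalman tracking and order selection.

The model is X(t) = sum_{j=1..p} A_j(t) X(t-j) + eta(t) with coefficients
A_j(t) evolving as a random walk. The Kalman filter treats the vectorized
coefficients as the state and, at every time point, performs one measurement
update against the whole epoch ensemble simultaneously, so the coefficient
trajectory is time-locked to the stimulus. The update constant ``uc`` is the
state-noise variance per step and also the exponential-smoothing rate of the
innovation covariance estimate. Fitting is deterministic given the data.

Model order is selected on a stationary fit: pooled least squares over all
epochs, scored by the Schwarz Bayesian criterion
SBC(p) = N log det(residual covariance) + p n^2 log N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import kalman_tv_mvar


@dataclass
class TVARModel:
    p: int
    coeffs: np.ndarray          # (n, n, p, T)
    innovation_cov: np.ndarray  # (n, n, T)
    uc: float
    sampling_rate: float
    burn_in: int                # leading samples without a full lag history

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[3]


@dataclass
class OrderSelection:
    candidate_orders: list[int]
    sbc_scores: np.ndarray
    chosen: int


def _lagged_design(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled regression arrays: targets (N, n) and design (N, n*p).

    Stacks all epochs; predictor block j holds X(t-1-j).
    """
    n, T, E = data.shape
    Y = data[:, p:, :].reshape(n, -1).T
    Z = np.concatenate(
        [data[:, p - 1 - j : T - 1 - j, :].reshape(n, -1) for j in range(p)], axis=0
    ).T
    return Y, Z


def ls_mvar(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stationary MVAR fit by pooled least squares.

    Returns coefficients (n, n, p) and the residual covariance (n, n).
    """
    n, T, E = data.shape
    if T <= p:
        raise ValueError(f"{T} samples cannot support order p={p}")
    Y, Z = _lagged_design(data, p)
    coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ coef
    sigma = resid.T @ resid / max(resid.shape[0] - Z.shape[1], 1)
    return coef.T.reshape(n, p, n).transpose(0, 2, 1), sigma


def select_model_order(data: np.ndarray, p_range) -> OrderSelection:
    """Pick the MVAR order minimizing the Schwarz Bayesian criterion.

    Ties break toward the smaller order.
    """
    p_range = sorted(int(p) for p in p_range)
    if not p_range:
        raise ValueError("p_range is empty")
    n, T, E = data.shape
    if T <= max(p_range) * n:
        raise ValueError(
            f"{T} samples too few for order {max(p_range)} with {n} nodes"
        )
    scores = []
    for p in p_range:
        Y, Z = _lagged_design(data, p)
        coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ coef
        N = resid.shape[0]
        sigma = resid.T @ resid / N
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf  # degenerate fit: perfectly explained, prefer it
        k = p * n * n
        scores.append(N * logdet + k * np.log(N))
    scores = np.asarray(scores)
    chosen = p_range[int(np.argmin(scores))]
    return OrderSelection(list(p_range), scores, chosen)


def fit_mvaar_kalman(
    data: np.ndarray, p: int, uc: float = 1e-3, sampling_rate: float = 250.0
) -> TVARModel:
    """Kalman-filter fit of the time-varying MVAR coefficients.

    ``data`` is (nodes, samples, epochs); all epochs enter each measurement
    update as an ensemble. State initialization: zero coefficients, identity
    state covariance. The first ``p`` samples have no complete lag history
    and are flagged as burn-in (their coefficients repeat the first estimate).
    """
    data = np.ascontiguousarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("data must be (nodes, samples, epochs)")
    n, T, E = data.shape
    if p < 1:
        raise ValueError("p must be >= 1")
    if T <= p:
        raise ValueError(f"{T} samples cannot support order p={p}")
    if uc <= 0:
        raise ValueError("uc must be positive")
    flat_coeffs, innov, status = kalman_tv_mvar(data, p, uc)
    if status >= 0:
        raise FloatingPointError(
            f"Kalman state diverged at sample index {status}; "
            "check input scaling or reduce uc"
        )
    # columns are blocked by lag: block j is the lag-(j+1) matrix
    coeffs = flat_coeffs.reshape(n, p, n, T).transpose(0, 2, 1, 3)
    return TVARModel(
        p=p, coeffs=np.ascontiguousarray(coeffs), innovation_cov=innov,
        uc=float(uc), sampling_rate=float(sampling_rate), burn_in=p,
    )


def save_tvar(model: TVARModel, path) -> None:
    """Serialize as an array container plus JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, coeffs=model.coeffs, innovation_cov=model.innovation_cov)
    meta = {
        "p": model.p, "uc": model.uc, "sampling_rate": model.sampling_rate,
        "burn_in": model.burn_in,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_tvar(path) -> TVARModel:
    path = Path(path)
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return TVARModel(
        p=meta["p"], coeffs=arrays["coeffs"], innovation_cov=arrays["innovation_cov"],
        uc=meta["uc"], sampling_rate=meta["sampling_rate"], burn_in=meta["burn_in"],
    )
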