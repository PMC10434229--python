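"""Regularized minimum-norm source estimation and ROI time-series extraction.

The inverse operator maps scalp potentials x(t) to cortical source activity
phi(t) = W x(t), with

    W = Cs A' (A Cs A' + mu^2 Cn)^-1,     mu^2 = tr(A Cs A') / (tr(Cn) snr^2)

where A is the lead field (channels x sources), Cs and Cn the source and
noise covariances, and snr the assumed amplitude signal-to-noise ratio.
ROI time series are means over the member sources resolved from MNI
coordinates against a source-space coordinate table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocessing import EpochedRecording

logger = logging.getLogger(__name__)


@dataclass
class InverseModel:
    A: np.ndarray          # lead field, channels x sources
    Cs: np.ndarray         # source covariance
    Cn: np.ndarray         # noise covariance
    snr: float
    mu2: float             # squared regularization parameter
    W: np.ndarray          # inverse operator, sources x channels


@dataclass
class SourceActivity:
    """Estimated cortical activity phi, shape (sources, samples, epochs)."""

    phi: np.ndarray
    sampling_rate: float
    tmin: float = -0.2

    @property
    def epoch_times(self) -> np.ndarray:
        return self.tmin + np.arange(self.phi.shape[1]) / self.sampling_rate


@dataclass
class ROI:
    name: str
    xyz_mm: np.ndarray
    radius_mm: float
    source_indices: np.ndarray | None = None


@dataclass
class ROISet:
    rois: list[ROI]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def resolve(self, source_coords: np.ndarray) -> "ROISet":
        """Assign source indices to each ROI by Euclidean distance (mm).

        Sources within the ROI radius are members; when none fall inside,
        the single nearest source is used and a warning is logged.
        """
        coords = np.asarray(source_coords, dtype=float)
        for roi in self.rois:
            dist = np.linalg.norm(coords - roi.xyz_mm[None, :], axis=1)
            inside = np.flatnonzero(dist <= roi.radius_mm)
            if inside.size == 0:
                inside = np.array([int(np.argmin(dist))])
                logger.warning(
                    "ROI %s: no source within %.1f mm, using nearest at %.1f mm",
                    roi.name, roi.radius_mm, dist[inside[0]],
                )
            roi.source_indices = inside
        return self


def load_roi_table(path=None, condition: str | None = None) -> ROISet:
    """Read an ROI definition table (name, x_mm, y_mm, z_mm, radius_mm).

    Without ``path`` the packaged table of four attention/integration ROIs
    (TPJ, STG, A1, V1 per cue visual field) is used; ``condition`` selects
    the ``LVF`` or ``RVF`` rows when the table carries a condition column.
    """
    if path is None:
        with resources.files("adtfnet.data").joinpath("roi_table.csv").open() as fh:
            df = pd.read_csv(fh)
        condition = condition or "LVF"
    else:
        df = pd.read_csv(path)
    if condition is not None and "condition" in df.columns:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("ROI table selection is empty")
    rois = [
        ROI(row["name"], np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
            float(row.radius_mm))
        for _, row in df.iterrows()
    ]
    return ROISet(rois)


def load_source_space(path) -> np.ndarray:
    """Read source coordinates (source_id, x_mm, y_mm, z_mm) -> (S, 3) array."""
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def estimate_noise_covariance(
    rec: EpochedRecording, window: tuple[float, float] = (-0.2, 0.0)
) -> np.ndarray:
    """Empirical channel covariance over (window samples x epochs).

    Channels are demeaned over the pooled window; the result is symmetrized
    and a diagonal loading of 1e-12 * trace / n is added.
    """
    t = rec.epoch_times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError(f"window {window} selects no samples")
    if rec.n_epochs < 2:
        raise ValueError("need >= 2 epochs for a noise covariance")
    X = rec.data[:, mask, :].reshape(rec.n_channels, -1)
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[1]
    if n < 2:
        raise ValueError("too few samples in the noise window")
    C = X @ X.T / (n - 1)
    C = 0.5 * (C + C.T)
    C += np.eye(rec.n_channels) * (1e-12 * np.trace(C) / rec.n_channels)
    return C


def compute_inverse_operator(
    A: np.ndarray,
    Cs: np.ndarray | None = None,
    Cn: np.ndarray | None = None,
    snr: float = 3.0,
) -> InverseModel:
    """Build the regularized minimum-norm operator W.

    ``Cs`` defaults to the identity (no source prior), ``Cn`` to the
    identity noise model. When ``Cn`` has zero trace the problem is treated
    as noiseless (mu^2 = 0).
    """
    A = np.asarray(A, dtype=float)
    n_chan, n_src = A.shape
    Cs = np.eye(n_src) if Cs is None else np.asarray(Cs, dtype=float)
    Cn = np.eye(n_chan) if Cn is None else np.asarray(Cn, dtype=float)
    if Cs.shape != (n_src, n_src) or Cn.shape != (n_chan, n_chan):
        raise ValueError("covariance shapes do not match the lead field")
    if snr <= 0:
        raise ValueError("snr must be positive")
    ACsAT = A @ Cs @ A.T
    tr_cn = np.trace(Cn)
    mu2 = 0.0 if tr_cn == 0 else float(np.trace(ACsAT) / (tr_cn * snr**2))
    M = ACsAT + mu2 * Cn
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"(A Cs A' + mu^2 Cn) is not invertible (condition number {cond:.3g})"
        )
    W = Cs @ A.T @ np.linalg.inv(M)
    return InverseModel(A=A, Cs=Cs, Cn=Cn, snr=float(snr), mu2=mu2, W=W)


def apply_inverse(model: InverseModel, rec: EpochedRecording) -> SourceActivity:
    """phi = W x, applied per sample and epoch (exactly linear)."""
    if rec.n_channels != model.W.shape[1]:
        raise ValueError(
            f"recording has {rec.n_channels} channels, operator expects {model.W.shape[1]}"
        )
    phi = np.einsum("sc,cte->ste", model.W, rec.data)
    return SourceActivity(phi, rec.sampling_rate, rec.tmin)


def extract_roi_timeseries(phi: SourceActivity, rois: ROISet) -> np.ndarray:
    """Mean source series per ROI: (n_rois, samples, epochs), in ROISet order."""
    out = []
    for roi in rois.rois:
        if roi.source_indices is None or len(roi.source_indices) == 0:
            raise ValueError(f"ROI {roi.name} is unresolved; call ROISet.resolve first")
        out.append(phi.phi[roi.source_indices].mean(axis=0))
    return np.stack(out, axis=0)
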