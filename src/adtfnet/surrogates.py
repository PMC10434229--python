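"""Surrogate-data null distribution and group-level edge significance.

The null model destroys all cross-node causal structure while preserving
each node's power spectrum: every node series is Fourier phase randomized
independently, the full time-varying fit and ADTF integration are re-run,
and the integrated flows form the empirical per-subject null.

Edge significance is decided in two stages. Per subject, each edge/time
flow is referred to its own surrogate distribution: the per-subject
significance threshold is the null quantile at the Bonferroni-corrected
level 1 - alpha/m with m = n(n-1) directed edges. At the group level a
one-sided Wilcoxon signed-rank test of observed minus per-subject null
median is Bonferroni corrected over the same family; an edge/time point is
declared significant when the group test passes at alpha / m AND the
group-median flow exceeds the group-median per-subject threshold. The
quantile gate is what bounds the family-wise error over the (strongly
correlated, uncorrected) time axis: a chance group-level rank alignment at
a single time point cannot fire unless the typical subject's flow also sits
in the extreme tail of its own null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .adtf import DEFAULT_BAND, DEFAULT_FREQS, adtf
from .tvar import fit_mvaar_kalman


@dataclass
class SurrogateNull:
    """Integrated-ADTF null draws, shape (n, n, T, n_surrogates)."""

    values: np.ndarray
    n_surrogates: int
    seed: int


@dataclass
class SignificantNetwork:
    mask: np.ndarray                 # (n, n, T) bool, diagonal always False
    alpha: float
    correction: str
    m: int                           # Bonferroni family size
    per_edge_threshold: np.ndarray   # (n, n, T) group-median null quantile
    p_group: np.ndarray              # (n, n, T) signed-rank p-values
    observed_median: np.ndarray      # (n, n, T) group-median flow
    times: np.ndarray                # seconds


def phase_randomize(series: np.ndarray, rng) -> np.ndarray:
    """Randomize Fourier phases per row, preserving amplitude spectra.

    Positive-frequency phases are replaced by i.i.d. uniform draws; DC and
    (for even lengths) Nyquist coefficients stay real, so the output is real
    with exactly the input amplitude spectrum.
    """
    series = np.asarray(series, dtype=float)
    if not np.isfinite(series).all():
        raise ValueError("input contains non-finite values")
    n_samples = series.shape[-1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples to randomize phases")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spec = np.fft.rfft(series, axis=-1)
    n_bins = spec.shape[-1]
    hi = n_bins - 1 if n_samples % 2 == 0 else n_bins  # keep Nyquist real if present
    phases = rng.uniform(0.0, 2 * np.pi, size=spec.shape[:-1] + (hi - 1,))
    spec[..., 1:hi] *= np.exp(1j * phases)
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def phase_randomize_epochs(data: np.ndarray, rng) -> np.ndarray:
    """Independently phase-randomize every (node, epoch) series.

    ``data`` is (n, T, E); randomizing per epoch keeps the surrogate
    ensemble exchangeable with the observed one.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return phase_randomize(np.moveaxis(data, 1, 2), rng).transpose(0, 2, 1)


def build_null(
    data: np.ndarray,
    p: int,
    uc: float = 1e-3,
    sampling_rate: float = 250.0,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    n_surrogates: int = 200,
    seed: int = 0,
    time_indices: np.ndarray | None = None,
) -> SurrogateNull:
    """Re-run fit + ADTF on phase-randomized copies of one subject's data."""
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    freqs = DEFAULT_FREQS if freqs is None else freqs
    rng = np.random.default_rng(seed)
    values = None
    for s in range(n_surrogates):
        surro = phase_randomize_epochs(data, rng)
        try:
            model = fit_mvaar_kalman(surro, p=p, uc=uc, sampling_rate=sampling_rate)
            ups2 = adtf(model, freqs=freqs, band=band, time_indices=time_indices).upsilon2
        except Exception as exc:  # annotate with the surrogate index
            raise RuntimeError(f"surrogate {s} failed: {exc}") from exc
        if values is None:
            values = np.empty(ups2.shape + (n_surrogates,))
        values[..., s] = ups2
    return SurrogateNull(values=values, n_surrogates=n_surrogates, seed=seed)


def _signed_rank_counts(n: int) -> np.ndarray:
    """Exact null distribution of the Wilcoxon W+ statistic for n pairs."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[: max_w + 1 - k].copy()
    return counts


def signed_rank_p_greater(d: np.ndarray) -> np.ndarray:
    """Vectorized one-sided exact Wilcoxon signed-rank p-values.

    ``d`` has subjects on the last axis; returns P(W+ >= observed) under the
    symmetric null, the exact distribution with average ranks for ties.
    Cells containing exact zeros fall back to the scipy implementation
    (zero differences need the zero-handling convention).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[-1]
    ranks = stats.rankdata(np.abs(d), axis=-1)
    w_plus = np.where(d > 0, ranks, 0.0).sum(axis=-1)
    counts = _signed_rank_counts(n)
    tail = np.cumsum(counts[::-1])[::-1] / counts.sum()
    idx = np.ceil(w_plus - 1e-9).astype(int)  # average ranks can give half-integers
    p = tail[np.clip(idx, 0, len(tail) - 1)]
    zero_cells = np.any(d == 0, axis=-1)
    if np.any(zero_cells):
        flat = d[zero_cells].reshape(-1, n)
        fixed = np.array([
            stats.wilcoxon(row, alternative="greater", method="exact").pvalue
            if np.any(row != 0) else 1.0
            for row in flat
        ])
        p[zero_cells] = fixed
    return p


def threshold_network(
    observed: list[np.ndarray],
    nulls: list[SurrogateNull],
    times: np.ndarray,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    time_correction: bool = False,
    group_test: str = "signed-rank",
) -> SignificantNetwork:
    """Group-level significant directed edges from subject flows and nulls.

    ``observed`` holds one (n, n, T) integrated-ADTF array per subject and
    ``nulls`` the matching surrogate distributions. The Bonferroni family is
    the n(n-1) directed edges; set ``time_correction`` to additionally divide
    by the number of time points. ``group_test`` is ``"signed-rank"`` (needs
    >= 5 subjects) or ``"quantile"``, which keeps only the per-subject
    surrogate-quantile gate for small groups.
    """
    if len(observed) < 1 or len(observed) != len(nulls):
        raise ValueError("need matched observed/null arrays for >= 1 subject")
    n_subj = len(observed)
    if group_test not in ("signed-rank", "quantile"):
        raise ValueError(f"unknown group_test {group_test!r}")
    if group_test == "signed-rank" and n_subj < 5:
        raise ValueError(
            f"{n_subj} subjects is too few for the signed-rank stage (the "
            "exact test has no power below 5 pairs); use the exact "
            "quantile-only test via group_test='quantile'"
        )
    obs = np.stack(observed, axis=-1)            # (n, n, T, S_subj)
    null_vals = np.stack([nl.values for nl in nulls], axis=-1)  # (n, n, T, S_surr, S_subj)
    n = obs.shape[0]
    m = n * (n - 1)
    if correction == "bonferroni":
        level = alpha / m / (obs.shape[2] if time_correction else 1)
    elif correction == "none":
        level = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")

    thresh = np.median(np.quantile(null_vals, 1 - level, axis=3), axis=-1)
    obs_median = np.median(obs, axis=-1)
    if group_test == "signed-rank":
        null_median = np.median(null_vals, axis=3)   # (n, n, T, S_subj)
        p_group = signed_rank_p_greater(obs - null_median)
        mask = (p_group < level) & (obs_median > thresh)
    else:
        p_group = np.full(obs_median.shape, np.nan)
        mask = obs_median > thresh
    mask[np.arange(n), np.arange(n), :] = False
    return SignificantNetwork(
        mask=mask, alpha=alpha, correction=correction, m=m,
        per_edge_threshold=thresh, p_group=p_group,
        observed_median=obs_median, times=np.asarray(times, dtype=float),
    )
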