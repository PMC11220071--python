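"""Population-level summaries: PSTHs, trajectory geometry, signal variance.

Event PSTHs are trial-averaged, Gaussian-smoothed (sigma = 30 ms) firing
rates around task events; full-trial PSTHs are built by stitching the
context-entry, odour, response and outcome event PSTHs on a common clock
(aligned to the first odour inhalation) and averaging where they overlap.

Population activity is pooled into an array ``X`` of shape
(neurons, contexts, odours, time, trials); its trial average ``Xbar`` feeds
Pearson-correlation similarity matrices and PCA trajectories.  The
signal-variance decomposition subtracts an estimate of the residual trial
noise in ``Xbar`` from its total variance, per neuron and rebalanced for
unequal trial counts across conditions, yielding the fraction of
trial-averaged variance that reflects condition structure rather than
finite-sampling noise; dimensionality is the number of principal components
needed to reach that fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "event_psth",
    "stitch_trial_psth",
    "population_correlation_matrix",
    "pca_trajectories",
    "signal_variance_decomposition",
    "dimensionality_estimate",
    "spikecount_cv",
]


def event_psth(
    spike_times: list,
    event_times: np.ndarray,
    window: tuple[float, float],
    sigma: float = 0.030,
    bin_size: float = 0.010,
    *,
    subtract_mean: bool = False,
):
    """Trial-averaged firing rate around events, Gaussian-smoothed.

    ``spike_times`` holds one array of spike times per trial (same clock as
    ``event_times``, one event per trial; trials with NaN events are
    skipped).  Returns (bin centres relative to the event, rate in Hz).
    The integral of the rate over the window equals the mean number of
    spikes per trial in the window (smoothing uses reflection padding, which
    preserves mass).
    """
    event_times = np.asarray(event_times, dtype=float)
    keep = np.isfinite(event_times)
    if not keep.any():
        raise ValueError("need at least one event")
    lo, hi = window
    edges = np.arange(lo, hi + bin_size / 2, bin_size)
    centres = edges[:-1] + bin_size / 2
    acc = np.zeros(centres.size)
    n_events = 0
    for times, t0 in zip(spike_times, event_times):
        if not np.isfinite(t0):
            continue
        rel = np.asarray(times, dtype=float) - t0
        acc += np.histogram(rel, bins=edges)[0]
        n_events += 1
    rate = acc / (n_events * bin_size)
    rate = gaussian_filter1d(rate, sigma / bin_size, mode="reflect")
    if subtract_mean:
        rate = rate - rate.mean()
    return centres, rate


def stitch_trial_psth(segments: list, bin_size: float = 0.010):
    """Average overlapping, time-aligned event PSTHs into one trial PSTH.

    ``segments`` is a list of ``(alignment_time, centres, rates)`` where
    ``alignment_time`` places each event PSTH on a common clock (e.g. C, O,
    L, R at -0.43, 0, 1.38, 1.96 s relative to first odour inhalation for
    expert sessions).  Overlap regions are the pointwise mean of the
    contributing segments; a gap between segments is an error listing the
    uncovered intervals.
    """
    if not segments:
        raise ValueError("no segments to stitch")
    starts, stops = [], []
    for t0, centres, rates in segments:
        centres = np.asarray(centres)
        starts.append(t0 + centres[0])
        stops.append(t0 + centres[-1])
    lo = min(starts)
    hi = max(stops)
    grid = np.arange(0, round((hi - lo) / bin_size) + 1) * bin_size + lo
    total = np.zeros(grid.size)
    count = np.zeros(grid.size)
    for t0, centres, rates in segments:
        centres = np.asarray(centres) + t0
        idx = np.round((centres - lo) / bin_size).astype(int)
        total[idx] += np.asarray(rates)
        count[idx] += 1
    if (count == 0).any():
        gaps = grid[count == 0]
        raise ValueError(
            f"segments leave gaps in the stitched PSTH near t = {gaps[:5]}"
        )
    return grid, total / count


def population_correlation_matrix(
    vectors: np.ndarray, min_std: float = 1e-12
) -> np.ndarray:
    """Pearson correlations between population activity vectors.

    ``vectors`` is (n_vectors, n_neurons): one row per (condition, time)
    pair.  Zero-variance rows give NaN entries (flagged, not an error).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[1] < 2:
        raise ValueError("need at least 2 neurons")
    sd = vectors.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vectors)
    corr[sd < min_std, :] = np.nan
    corr[:, sd < min_std] = np.nan
    return corr


@dataclass
class PCAResult:
    components: np.ndarray  # (n_neurons, n_components)
    trajectories: np.ndarray  # (n_components, C, O, T)
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray


def pca_trajectories(xbar: np.ndarray, n_components: int = 3) -> PCAResult:
    """Condition-averaged population trajectories in PC space.

    ``xbar`` is (N, C, O, T), row-centred internally; SVD of the reshaped
    (N, C*O*T) matrix gives the components, and projections reshaped back
    give per-condition time trajectories through the top components.
    """
    xbar = np.asarray(xbar, dtype=float)
    if not np.isfinite(xbar).all():
        raise ValueError("xbar must be finite")
    N, C, O, T = xbar.shape
    flat = xbar.reshape(N, C * O * T)
    flat = flat - flat.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(flat, full_matrices=False)
    k = min(n_components, N)
    proj = (U.T @ flat)[:k]  # scores of each component over conditions/time
    var = S**2
    return PCAResult(
        components=U[:, :k],
        trajectories=proj.reshape(k, C, O, T),
        explained_variance_ratio=var / var.sum() if var.sum() > 0 else var,
        singular_values=S,
    )


def signal_variance_decomposition(X: np.ndarray, trial_counts: np.ndarray | None = None):
    """Split trial-averaged variance into signal and residual noise.

    ``X`` is (N, C, O, T, K) with NaN padding for missing trials (or
    ``trial_counts`` of shape (N, C, O) given explicitly).  Per neuron the
    trial-averaged array is centred over conditions and time; the total
    variance is its sum of squares.  The average noise variance across
    conditions, divided by the per-neuron mean trial count (the rebalancing
    that lets sequentially recorded neurons with different trial counts be
    pooled), scaled back by the number of condition-time points, estimates
    the noise remaining in the trial averages:

        total   = sum_{n,o,c,t} (Xbar - <Xbar>_{o,c,t})^2
        Cn      = mean_{o,c,t} [ sum_k (X - Xbar)^2 / K_{n,o,c} ]
        Theta   = O*C*T * sum_n Cn / mean_{o,c}(K_{n,o,c})
        SigVar  = total - Theta

    Returns ``(total, Theta, SigVar, fraction)`` with
    ``fraction = 100 * (1 - Theta/total)`` in percent.

    Raises if any condition has fewer than 2 trials for some neuron.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 5:
        raise ValueError("X must be (neurons, contexts, odours, time, trials)")
    N, C, O, T, K = X.shape
    finite = np.isfinite(X)
    counts = finite.all(axis=3).sum(axis=-1)  # (N, C, O): trials present
    if trial_counts is not None:
        counts = np.asarray(trial_counts)
    low = np.argwhere(counts < 2)
    if low.size:
        n, c, o = low[0]
        raise ValueError(
            f"neuron {n}, context {c}, odour {o} has fewer than 2 trials"
        )
    with np.errstate(invalid="ignore"):
        xbar = np.nanmean(X, axis=-1)  # (N, C, O, T)
    centred = xbar - xbar.reshape(N, -1).mean(axis=1)[:, None, None, None]
    total = float((centred**2).sum())

    dev2 = np.nansum((X - xbar[..., None]) ** 2, axis=-1)  # (N, C, O, T)
    per_condition = dev2 / counts[..., None]
    c_tilde = per_condition.reshape(N, -1).mean(axis=1)  # avg noise var per neuron
    mean_counts = counts.reshape(N, -1).mean(axis=1)
    theta = float(C * O * T * np.sum(c_tilde / mean_counts))
    sigvar = total - theta
    fraction = 100.0 * (1.0 - theta / total) if total > 0 else np.nan
    return total, theta, sigvar, fraction


def dimensionality_estimate(xbar: np.ndarray, signal_fraction: float) -> int:
    """Smallest number of principal components whose cumulative explained
    variance reaches ``signal_fraction`` percent of the total."""
    if not (0 < signal_fraction <= 100):
        raise ValueError("signal_fraction must be in (0, 100]")
    xbar = np.asarray(xbar, dtype=float)
    flat = xbar.reshape(xbar.shape[0], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    var = np.linalg.svd(flat, compute_uv=False) ** 2
    if var.sum() == 0:
        return 0
    cum = 100.0 * np.cumsum(var) / var.sum()
    return int(np.searchsorted(cum, signal_fraction - 1e-9) + 1)


def spikecount_cv(counts: np.ndarray) -> np.ndarray:
    """Trial-to-trial coefficient of variation of spike counts.

    ``counts`` is (..., trials); the CV (sd/mean across trials) is returned
    per leading index, NaN where the mean count is zero (flagged, not an
    error)."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] < 2:
        raise ValueError("need at least 2 trials")
    mean = counts.mean(axis=-1)
    sd = counts.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return cv
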