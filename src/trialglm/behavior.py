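"""Behavioural performance, respiration processing and position tuning.

Task performance in the GO/NO-GO discrimination is summarised with signal
detection theory: sensitivity ``d' = Z(hit rate) - Z(false-alarm rate)`` and
response bias ``criterion = -(Z(hit rate) + Z(FA rate))/2``, where ``Z`` is
the inverse normal CDF.  Hit/FA rates of exactly 0 or 1 are nudged by the
standard 1/(2N) correction before the transform.

Respiration traces (negative airflow = inhalation) are smoothed with a
second-order Savitzky-Golay filter in 100-ms frames, locally detrended by
subtracting a 1-s median-filtered copy, and inhalation onsets are the
negative-going zero crossings preceding large negative peaks; inhalations
within the 1-s window after odour onset are odour inhalations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import norm

from .session import SessionBundle, TrialEvents

__all__ = [
    "OutcomeCounts",
    "RespirationTrace",
    "dprime_criterion",
    "sdt_metrics",
    "detect_inhalations",
    "label_odour_inhalations",
    "classify_trial_outcome",
    "classify_trial_outcomes",
    "outcome_counts",
    "position_occupancy_map",
]


@dataclass(frozen=True)
class OutcomeCounts:
    """Trial outcome tallies of one session."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("outcome counts must be non-negative")

    @property
    def n_go_type(self) -> int:
        return self.hits + self.misses

    @property
    def n_nogo_type(self) -> int:
        return self.false_alarms + self.correct_rejections

    def rates(self) -> tuple[float, float]:
        """(hit rate, FA rate) with the 1/(2N) extreme-rate correction."""
        if self.n_go_type == 0 or self.n_nogo_type == 0:
            raise ValueError("need at least one trial in each category")

        def corrected(k: int, n: int) -> float:
            rate = k / n
            if rate == 0.0:
                return 1.0 / (2 * n)
            if rate == 1.0:
                return 1.0 - 1.0 / (2 * n)
            return rate

        return (
            corrected(self.hits, self.n_go_type),
            corrected(self.false_alarms, self.n_nogo_type),
        )


def dprime_criterion(hit_rate: float, fa_rate: float) -> tuple[float, float]:
    """Sensitivity and bias from hit and false-alarm rates.

    ``d' = Z(H) - Z(F)``; ``criterion = -(Z(H) + Z(F))/2``.  ``d' = 0`` is
    chance; negative criterion means a bias toward GO responses.  Rates must
    lie strictly inside (0, 1) — apply a correction first if needed.
    """
    for name, rate in (("hit_rate", hit_rate), ("fa_rate", fa_rate)):
        if not (0.0 < rate < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1), got {rate}")
    z_h = norm.ppf(hit_rate)
    z_f = norm.ppf(fa_rate)
    return float(z_h - z_f), float(-0.5 * (z_h + z_f))


def sdt_metrics(counts: OutcomeCounts) -> tuple[float, float]:
    """``(d', criterion)`` from outcome counts (with extreme-rate guard)."""
    hit_rate, fa_rate = counts.rates()
    return dprime_criterion(hit_rate, fa_rate)


# ---------------------------------------------------------------------------
# respiration


@dataclass
class RespirationTrace:
    """Uniformly sampled airflow; negative airflow corresponds to
    inhalation (sensor convention)."""

    sample_times: np.ndarray
    airflow: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        x = np.asarray(self.airflow, dtype=float)
        if t.size != x.size:
            raise ValueError("sample_times and airflow differ in length")
        if t.size >= 3:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("sampling must be uniform")
        self.sample_times = t
        self.airflow = x

    @property
    def fs(self) -> float:
        return 1.0 / float(np.diff(self.sample_times[:2])[0])


def detect_inhalations(
    trace: RespirationTrace,
    *,
    smooth_window: float = 0.100,
    detrend_window: float = 1.0,
    peak_mad_factor: float = 3.0,
    min_interval: float = 0.05,
) -> np.ndarray:
    """Inhalation onset times from an airflow trace.

    The trace is Savitzky-Golay smoothed (order 2, ``smooth_window``
    frames), detrended by subtracting its ``detrend_window`` median-filtered
    copy, and onsets are the last negative-going zero crossings before
    negative peaks larger than ``peak_mad_factor`` median absolute
    deviations.  Detection is invariant to positive rescaling of the trace.
    A flat trace yields no onsets (not an error); NaNs are an error.
    """
    x = trace.airflow
    if not np.isfinite(x).all():
        raise ValueError("airflow contains NaN or infinite samples")
    fs = trace.fs
    if fs < 100:
        raise ValueError(f"sampling rate must be >= 100 Hz, got {fs:.1f}")
    if x.size <= int(detrend_window * fs):
        raise ValueError("trace shorter than the detrending window")
    win = int(round(smooth_window * fs))
    win += 1 - win % 2  # odd frame length
    smoothed = savgol_filter(x, window_length=max(win, 5), polyorder=2)
    trend = median_filter(smoothed, size=int(round(detrend_window * fs)), mode="reflect")
    detrended = smoothed - trend

    mad = float(np.median(np.abs(detrended - np.median(detrended))))
    if mad == 0.0:
        return np.empty(0)
    threshold = peak_mad_factor * mad
    peaks, _ = find_peaks(
        -detrended, height=threshold, distance=max(1, int(min_interval * fs))
    )
    onsets = []
    for p in peaks:
        before = detrended[:p]
        crossings = np.flatnonzero((before[:-1] >= 0) & (before[1:] < 0))
        if crossings.size:
            onsets.append(trace.sample_times[crossings[-1] + 1])
    return np.unique(onsets)


def label_odour_inhalations(
    onsets: np.ndarray, t_odour_on: float, window: float = 1.0
) -> np.ndarray:
    """Boolean mask of onsets inside the 1-s window starting immediately
    after odour arrival: ``t_odour_on < t <= t_odour_on + window``."""
    onsets = np.asarray(onsets, dtype=float)
    return (onsets > t_odour_on) & (onsets <= t_odour_on + window)


# ---------------------------------------------------------------------------
# trial outcomes


def classify_trial_outcome(trial_type: str, licked_after_odour: bool) -> str:
    """GO/NO-GO outcome label: HIT/MISS in rewarded-combination trials,
    FA/CR elsewhere."""
    from .session import TRIAL_TYPES

    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}")
    if trial_type == "OR-CR":
        return "HIT" if licked_after_odour else "MISS"
    return "FA" if licked_after_odour else "CR"


def classify_trial_outcomes(trials: list[TrialEvents]) -> list[str]:
    """Outcome labels from trial type and post-odour licking."""
    return [
        classify_trial_outcome(
            t.trial_type, t.t_first_lick_after_odour is not None
        )
        for t in trials
    ]


def outcome_counts(bundle: SessionBundle) -> OutcomeCounts:
    outcomes = classify_trial_outcomes(bundle.trials)
    return OutcomeCounts(
        hits=outcomes.count("HIT"),
        misses=outcomes.count("MISS"),
        false_alarms=outcomes.count("FA"),
        correct_rejections=outcomes.count("CR"),
    )


# ---------------------------------------------------------------------------
# occupancy-normalised position tuning


def position_occupancy_map(
    counts: np.ndarray,
    position: np.ndarray,
    dt: float,
    bin_cm: float,
    extent: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate per position bin, normalised by occupancy time.

    ``rate(bin) = spikes emitted in bin / time spent in bin``; bins the
    animal never visited are NaN (undefined), not zero.  Returns
    (bin edges, rates).
    """
    counts = np.asarray(counts)
    position = np.asarray(position, dtype=float)
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    if counts.size != position.size:
        raise ValueError("counts and position are not aligned")
    if position.size == 0:
        raise ValueError("zero total occupancy")
    lo, hi = extent if extent is not None else (0.0, position.max() + 1e-9)
    edges = np.arange(lo, hi + bin_cm, bin_cm)
    idx = np.clip(np.digitize(position, edges) - 1, 0, edges.size - 2)
    n_bins = edges.size - 1
    occupancy = np.bincount(idx, minlength=n_bins) * dt
    spikes = np.bincount(idx, weights=counts, minlength=n_bins)
    if occupancy.sum() == 0:
        raise ValueError("zero total occupancy")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, spikes / occupancy, np.nan)
    return edges, rate
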