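"""Synthetic task sessions and ground-truth Poisson spiking.

Emulates a head-fixed virtual-corridor GO/NO-GO task: on each trial the
animal runs down an approaching aisle, enters one of two visual contexts
where a 1-s odour pulse is delivered, and then chooses to lick (GO) or not
(NO-GO) in a reward zone.  Four trial types arise from crossing two odours
with two contexts; only the rewarded odour in the rewarded context (OR-CR)
pays out.  The generator produces trial event tables, position/speed traces,
respiration (inhalation) point processes and lick trains, and can then drive
Poisson spike counts from known kernels so that every downstream analysis
stage has a ground truth to recover.

Timing is under operant control of the simulated animal: per-trial running
speed, reaction times and sniff phases are randomised, which decorrelates
task variables across trials — the property that makes multi-variable kernel
estimation identifiable in the first place.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_TYPES",
    "SessionConfig",
    "TrialEvents",
    "SessionBundle",
    "SpikeTrain",
    "GroundTruthModel",
    "simulate_trial_events",
    "make_ground_truth_kernels",
    "simulate_spikes",
    "write_session",
    "read_session",
]

#: the four odour x context combinations; only OR-CR is rewarded
TRIAL_TYPES = ("OR-CR", "OR-CU", "OU-CR", "OU-CU")

OUTCOMES = ("HIT", "MISS", "FA", "CR")


def odour_of(trial_type: str) -> str:
    """'R' or 'U' odour identity of a trial type."""
    return trial_type[1]


def context_of(trial_type: str) -> str:
    """'R' or 'U' context identity of a trial type."""
    return trial_type[-1]


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of a simulated session.

    Geometry is in cm (83-cm aisle, 33-cm context zone, then a reward zone),
    times in seconds, rates in Hz.  ``bin_size`` is the spike-count /
    regressor resolution (10 ms).  ``behavior_policy`` selects the GO
    probabilities per trial type: the ``expert`` policy concentrates GO
    responses in rewarded-odour/rewarded-context trials (P=0.95 vs 0.05),
    reproducing a d' of about 3.3; the ``first_session`` policy licks
    indiscriminately (P=0.8 everywhere).
    """

    n_trials: int = 200
    trial_type_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    aisle_length: float = 83.0
    context_length: float = 33.0
    reward_zone_length: float = 52.0
    odour_pulse: float = 1.0
    bin_size: float = 0.010
    sniff_rate: float = 4.0
    sniff_anticipation_gain: float = 1.3
    sniff_min_interval: float = 0.12
    speed_mean: float = 25.0
    speed_trial_sd_frac: float = 0.20
    speed_jitter_frac: float = 0.12
    speed_min: float = 2.0
    lick_rate: float = 7.0
    lick_bout: float = 1.2
    reaction_time_mean: float = 1.1
    reaction_time_sd: float = 0.30
    behavior_policy: str = "expert"
    go_prob_override: dict | None = None
    inter_trial_interval: float = 2.0
    reward_volume_ul: float = 10.0  # metadata only
    max_trial_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.trial_type_probs, dtype=float)
        if probs.shape != (4,) or not np.isfinite(probs).all() or (probs < 0).any():
            raise ValueError("trial_type_probs must be 4 finite non-negative values")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("trial_type_probs must sum to 1")
        for name in (
            "aisle_length",
            "context_length",
            "reward_zone_length",
            "odour_pulse",
            "bin_size",
            "sniff_rate",
            "speed_mean",
            "lick_rate",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value}")
        if self.behavior_policy not in ("expert", "first_session"):
            raise ValueError(f"unknown behavior_policy {self.behavior_policy!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def corridor_length(self) -> float:
        return self.aisle_length + self.context_length + self.reward_zone_length

    def go_probabilities(self) -> dict[str, float]:
        if self.go_prob_override is not None:
            return {t: float(self.go_prob_override[t]) for t in TRIAL_TYPES}
        if self.behavior_policy == "expert":
            return {t: (0.95 if t == "OR-CR" else 0.05) for t in TRIAL_TYPES}
        return {t: 0.80 for t in TRIAL_TYPES}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trial_type_probs"] = list(self.trial_type_probs)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class TrialEvents:
    """Events of one trial; all times in seconds relative to trial start
    (``t_start`` is the wall-clock start of the trial within the session).

    Optional events are ``None`` when absent: ``t_reward`` exists iff the
    outcome is HIT; the first odour inhalation can be missing on trials where
    no inhalation fell inside the 1-s odour pulse.
    """

    trial_id: int
    trial_type: str
    t_start: float
    duration: float
    t_context_entry: float
    t_context_exit: float
    t_odour_on: float
    t_first_odour_inhalation: float | None
    t_first_lick_after_odour: float | None
    t_reward: float | None
    inhalation_times: np.ndarray
    lick_times: np.ndarray
    outcome: str

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not (self.t_context_entry <= self.t_odour_on <= self.t_context_exit):
            raise ValueError("require context entry <= odour onset <= context exit")
        if (self.t_reward is not None) != (self.outcome == "HIT"):
            raise ValueError("t_reward must be present iff outcome is HIT")

    def __eq__(self, other) -> bool:  # array fields need explicit comparison
        if not isinstance(other, TrialEvents):
            return NotImplemented
        for name in (
            "trial_id",
            "trial_type",
            "t_start",
            "duration",
            "t_context_entry",
            "t_context_exit",
            "t_odour_on",
            "t_first_odour_inhalation",
            "t_first_lick_after_odour",
            "t_reward",
            "outcome",
        ):
            if getattr(self, name) != getattr(other, name):
                return False
        return np.array_equal(self.inhalation_times, other.inhalation_times) and (
            np.array_equal(self.lick_times, other.lick_times)
        )


@dataclass
class SpikeTrain:
    """Binned spike counts of one unit on the session's global bin grid."""

    unit_id: str
    counts: np.ndarray
    rate: np.ndarray | None = None  # underlying rate (Hz), when simulated

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if (counts < 0).any():
            raise ValueError("spike counts must be non-negative")
        self.counts = counts.astype(np.int64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return self.unit_id == other.unit_id and np.array_equal(
            self.counts, other.counts
        )


@dataclass
class SessionBundle:
    """One simulated (or loaded) session.

    ``position``/``speed`` hold one array per trial sampled at the bin
    resolution; spike counts live on the concatenated within-trial bin grid
    (trial boundaries are hard: kernels never span them, and the inter-trial
    'teletransport' gap carries no bins).
    """

    config: SessionConfig
    trials: list[TrialEvents]
    position: list[np.ndarray]
    speed: list[np.ndarray]
    units: dict[str, SpikeTrain] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return self.config.bin_size

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_bins(self) -> np.ndarray:
        return np.array([p.size for p in self.position])

    @property
    def total_bins(self) -> int:
        return int(self.n_bins.sum())

    @property
    def bin_trial(self) -> np.ndarray:
        """Trial index of every global bin."""
        return np.repeat(np.arange(self.n_trials), self.n_bins)

    @property
    def bin_time(self) -> np.ndarray:
        """Within-trial start time of every global bin."""
        return np.concatenate([np.arange(n) * self.dt for n in self.n_bins])

    def trial_slices(self) -> list[slice]:
        edges = np.concatenate([[0], np.cumsum(self.n_bins)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    @property
    def max_speed(self) -> float:
        return float(max(s.max() for s in self.speed))

    def trial_types(self) -> np.ndarray:
        return np.array([t.trial_type for t in self.trials])

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.config == other.config
            and self.trials == other.trials
            and all(np.array_equal(a, b) for a, b in zip(self.position, other.position))
            and all(np.array_equal(a, b) for a, b in zip(self.speed, other.speed))
            and self.units == other.units
        )


# ---------------------------------------------------------------------------
# trial/behaviour simulation


def _simulate_kinematics(config: SessionConfig, rng: np.random.Generator):
    """Speed and position until the corridor end (ignoring GO stops)."""
    from scipy.signal import lfilter

    dt = config.bin_size
    horizon = int(round(config.max_trial_duration / dt))
    scale = config.speed_mean * float(
        rng.lognormal(mean=0.0, sigma=config.speed_trial_sd_frac)
    )
    rho = 0.98
    noise = rng.standard_normal(horizon)
    ou = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], noise)
    speeds = np.maximum(
        config.speed_min, scale * (1.0 + config.speed_jitter_frac * ou)
    )
    position = np.cumsum(speeds) * dt
    position = np.concatenate([[0.0], position[:-1]])
    return speeds, position


def _first_crossing(position: np.ndarray, threshold: float, dt: float) -> float | None:
    idx = np.searchsorted(position, threshold)
    if idx >= position.size:
        return None
    return idx * dt


def _simulate_inhalations(
    config: SessionConfig,
    rng: np.random.Generator,
    duration: float,
    anticipation_window: tuple[float, float] | None,
) -> np.ndarray:
    """Renewal process of inhalation onsets; gamma-shaped intervals give
    regular sniffing, optionally faster inside the anticipation window."""
    times = []
    t = float(rng.uniform(0.0, 1.0 / config.sniff_rate))
    while t < duration:
        times.append(t)
        rate = config.sniff_rate
        if anticipation_window is not None and (
            anticipation_window[0] <= t < anticipation_window[1]
        ):
            rate *= config.sniff_anticipation_gain
        interval = rng.gamma(shape=4.0, scale=1.0 / (4.0 * rate))
        t += max(config.sniff_min_interval, interval)
    return np.asarray(times)


def simulate_trial_events(config: SessionConfig) -> SessionBundle:
    """Generate a full session of trial events and behaviour traces (no
    spikes).

    Raises
    ------
    ValueError
        On invalid configuration, or if the animal cannot reach the context
        zone within the trial duration cap (e.g. vanishing speed).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.bin_size
    probs = np.asarray(config.trial_type_probs, dtype=float)
    go_prob = config.go_probabilities()
    context_end = config.aisle_length + config.context_length

    trials: list[TrialEvents] = []
    positions: list[np.ndarray] = []
    speeds: list[np.ndarray] = []
    t_wall = 0.0

    for trial_id in range(config.n_trials):
        trial_type = TRIAL_TYPES[rng.choice(4, p=probs)]
        spd, pos = _simulate_kinematics(config, rng)
        t_entry = _first_crossing(pos, config.aisle_length, dt)
        t_exit = _first_crossing(pos, context_end, dt)
        t_end_run = _first_crossing(pos, config.corridor_length, dt)
        if t_entry is None or t_exit is None or t_end_run is None:
            raise ValueError(
                "animal never traversed the corridor within "
                f"{config.max_trial_duration} s (trial {trial_id}); "
                "check the speed parameters"
            )
        t_odour_on = t_entry

        anticipation = None
        if (
            config.behavior_policy == "expert"
            and context_of(trial_type) == "R"
            and config.sniff_anticipation_gain > 1.0
        ):
            anticipation = (max(0.0, t_entry - 1.0), t_entry + 1.0)
        inhal = _simulate_inhalations(
            config, rng, config.max_trial_duration, anticipation
        )
        in_pulse = inhal[(inhal > t_odour_on) & (inhal <= t_odour_on + config.odour_pulse)]
        t_first_odour_inh = float(in_pulse[0]) if in_pulse.size else None

        go = bool(rng.random() < go_prob[trial_type]) and t_first_odour_inh is not None

        t_first_lick = None
        t_reward = None
        lick_times = np.empty(0)
        if go:
            reaction = float(
                rng.lognormal(
                    mean=np.log(config.reaction_time_mean),
                    sigma=config.reaction_time_sd / config.reaction_time_mean,
                )
            )
            t_first_lick = max(t_first_odour_inh + reaction, t_exit + 0.05)
            licks = [t_first_lick]
            while licks[-1] - t_first_lick < config.lick_bout:
                gap = max(0.05, rng.normal(1.0 / config.lick_rate, 0.02))
                licks.append(licks[-1] + gap)
            lick_times = np.asarray(licks)
            duration = t_first_lick + config.lick_bout + 0.3
            if trial_type == "OR-CR":
                outcome = "HIT"
                t_reward = float(lick_times[1])  # reward on the second lick
            else:
                outcome = "FA"
        else:
            duration = t_end_run
            outcome = "MISS" if trial_type == "OR-CR" else "CR"

        n_bins = int(np.ceil(duration / dt))
        n_bins = min(n_bins, spd.size)
        duration = n_bins * dt
        spd_t = spd[:n_bins].copy()
        pos_t = pos[:n_bins].copy()
        if go:
            stop_bin = min(n_bins - 1, int(t_first_lick / dt))
            spd_t[stop_bin:] = 0.0
            pos_t[stop_bin:] = pos_t[stop_bin]
        lick_times = lick_times[lick_times < duration]
        inhal = inhal[inhal < duration]

        trials.append(
            TrialEvents(
                trial_id=trial_id,
                trial_type=trial_type,
                t_start=t_wall,
                duration=duration,
                t_context_entry=t_entry,
                t_context_exit=t_exit,
                t_odour_on=t_odour_on,
                t_first_odour_inhalation=t_first_odour_inh,
                t_first_lick_after_odour=t_first_lick,
                t_reward=t_reward,
                inhalation_times=inhal,
                lick_times=lick_times,
                outcome=outcome,
            )
        )
        positions.append(pos_t)
        speeds.append(spd_t)
        t_wall += duration + config.inter_trial_interval

    return SessionBundle(
        config=config, trials=trials, position=positions, speed=speeds
    )


# ---------------------------------------------------------------------------
# ground-truth models and Poisson spiking


@dataclass
class GroundTruthModel:
    """Known kernels (basis coefficients per kernel) plus a log-rate bias.

    Kernels are stored as coefficients in their declared bases, so every
    kernel lies exactly in its basis span by construction.
    """

    kernels: dict[str, np.ndarray]
    bias: float
    variables: tuple[str, ...]

    def kernel_values(self, bases: dict) -> dict[str, np.ndarray]:
        return {
            name: bases[name].reconstruct(coef) for name, coef in self.kernels.items()
        }


def _smooth_coefficients(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.standard_normal(n)
    taper = np.array([0.25, 0.5, 0.25])
    for _ in range(2):
        w = np.convolve(w, taper, mode="same")
    return w


def make_ground_truth_kernels(
    variable_set,
    bases: dict,
    seed: int,
    *,
    target_rate_hz: float = 8.0,
    amplitude_range: tuple[float, float] | None = None,
    amplitude_by_variable: dict | None = None,
    occupancy: dict | None = None,
    occupancy_power: float = 0.5,
) -> GroundTruthModel:
    """Draw smooth random kernels for the requested variables.

    Each kernel is a smoothed Gaussian coefficient vector rescaled to a
    random peak absolute log-rate modulation.  By default the peak is drawn
    LogNormal(log 0.5, 0.7): a median peak gain of ~1.65x with substantial
    mass at near-silent kernels (gain ~1) and occasional strong ones —
    emulating a pool of kernels previously fitted to cortical recordings,
    which contains many weak and a few strong modulations.  Pass
    ``amplitude_range=(lo, hi)`` to draw the peak uniformly instead, or
    ``amplitude_by_variable={variable: (lo, hi)}`` to control individual
    variables (e.g. to guarantee one clearly detectable primary kernel per
    neuron, the way any neuron contributing fitted kernels to a real pool
    must have had at least one detectable modulation).  The bias is
    ``log(target_rate_hz)``: the baseline rate with all kernels silent.

    ``occupancy`` (per-kernel coefficient exposure, see
    :func:`trialglm.design.kernel_occupancy`) optionally tapers the drawn
    kernels toward zero in coefficients the task rarely exercises.  This
    emulates drawing simulation kernels from a pool of kernels previously
    *fitted* to recordings: a fitted kernel cannot carry structure in value
    bins the animal never occupied, and simulation kernels that did would
    be unrecoverable by construction rather than by any failure of the
    estimator.

    An empty variable set gives a bias-only (constant-rate) model.
    """
    from .design import KERNELS_OF, MODEL_VARIABLES  # local import; no cycle at load

    variable_set = tuple(variable_set)
    for var in variable_set:
        if var not in MODEL_VARIABLES:
            raise ValueError(f"unknown model variable {var!r}")
    rng = np.random.default_rng(seed)
    kernels: dict[str, np.ndarray] = {}
    for var in variable_set:
        for kernel_name in KERNELS_OF[var]:
            basis = bases[kernel_name]
            coef = _smooth_coefficients(rng, basis.n)
            if occupancy is not None and kernel_name in occupancy:
                occ = np.asarray(occupancy[kernel_name], dtype=float)
                ref = np.quantile(occ[occ > 0], 0.75) if (occ > 0).any() else 1.0
                taper = np.clip(occ / max(ref, 1e-12), 0.0, 1.0) ** occupancy_power
                coef = coef * taper
            values = basis.reconstruct(coef)
            peak = np.abs(values).max()
            if peak > 0:
                var_range = (amplitude_by_variable or {}).get(var, amplitude_range)
                if var_range is None:
                    target = rng.lognormal(mean=np.log(0.5), sigma=0.7)
                else:
                    target = rng.uniform(*var_range)
                coef = coef * (target / peak)
            kernels[kernel_name] = coef
    return GroundTruthModel(
        kernels=kernels, bias=float(np.log(target_rate_hz)), variables=variable_set
    )


def simulate_spikes(
    model: GroundTruthModel, design, seed: int, unit_id: str = "sim"
) -> SpikeTrain:
    """Sample Poisson spike counts from ``exp(sum_i (k_i (x) x_i) + bias)``.

    The rate is a deterministic function of (model, design); only the
    Poisson draw uses ``seed``.  Counts in bin ``t`` are Poisson with mean
    ``rate_t * dt``.
    """
    w = np.zeros(design.n_columns)
    for kernel_name, coef in model.kernels.items():
        sl = design.kernel_slices[kernel_name]
        if (sl.stop - sl.start) != len(coef):
            raise ValueError(
                f"kernel {kernel_name!r} has {len(coef)} coefficients but the "
                f"design expects {sl.stop - sl.start}"
            )
        w[sl] = coef
    w[design.kernel_slices["Bias"]] = model.bias
    eta = design.X @ w
    mean_counts = np.exp(eta) * design.dt
    bad = np.flatnonzero(~np.isfinite(mean_counts) | (mean_counts > 1e6))
    if bad.size:
        raise FloatingPointError(
            f"rate overflow at bin {bad[0]} (kernel output {eta[bad[0]]:.2f})"
        )
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mean_counts)
    return SpikeTrain(unit_id=unit_id, counts=counts, rate=np.exp(eta))


# ---------------------------------------------------------------------------
# session bundle I/O (directory of TSV tables + manifest)

_EVENT_COLUMNS = [
    "trial_id",
    "trial_type",
    "t_start",
    "duration",
    "t_context_entry",
    "t_context_exit",
    "t_odour_on",
    "t_first_odour_inhalation",
    "t_first_lick_after_odour",
    "t_reward",
    "outcome",
]


def events_frame(bundle: SessionBundle) -> pd.DataFrame:
    rows = []
    for tr in bundle.trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "trial_type": tr.trial_type,
                "t_start": tr.t_start,
                "duration": tr.duration,
                "t_context_entry": tr.t_context_entry,
                "t_context_exit": tr.t_context_exit,
                "t_odour_on": tr.t_odour_on,
                "t_first_odour_inhalation": tr.t_first_odour_inhalation,
                "t_first_lick_after_odour": tr.t_first_lick_after_odour,
                "t_reward": tr.t_reward,
                "outcome": tr.outcome,
            }
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_session(bundle: SessionBundle, path) -> Path:
    """Write a bundle as a directory of TSV tables plus ``manifest.yaml``.

    Times are written at full precision (shortest round-tripping decimal),
    so ``read_session(write_session(x)) == x``.  Simulated rates are not
    persisted; only spike counts are.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    events_frame(bundle).to_csv(path / "events.tsv", sep="\t", index=False)

    def _point_table(attr):
        rows = [
            {"trial_id": tr.trial_id, "t": t}
            for tr in bundle.trials
            for t in getattr(tr, attr)
        ]
        return pd.DataFrame(rows, columns=["trial_id", "t"])

    _point_table("inhalation_times").to_csv(
        path / "inhalations.tsv", sep="\t", index=False
    )
    _point_table("lick_times").to_csv(path / "licks.tsv", sep="\t", index=False)

    traces = pd.DataFrame(
        {
            "trial_id": bundle.bin_trial,
            "bin": np.concatenate([np.arange(n) for n in bundle.n_bins]),
            "position": np.concatenate(bundle.position),
            "speed": np.concatenate(bundle.speed),
        }
    )
    traces.to_csv(path / "traces.tsv", sep="\t", index=False)

    spike_rows = []
    for unit_id, train in bundle.units.items():
        nz = np.flatnonzero(train.counts)
        bin_trial = bundle.bin_trial
        offsets = np.concatenate([[0], np.cumsum(bundle.n_bins)])
        for g in nz:
            tr = int(bin_trial[g])
            spike_rows.append(
                {
                    "unit_id": unit_id,
                    "trial_id": tr,
                    "bin": int(g - offsets[tr]),
                    "count": int(train.counts[g]),
                }
            )
    pd.DataFrame(spike_rows, columns=["unit_id", "trial_id", "bin", "count"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False
    )

    manifest = {
        "format": "trialglm-session/1",
        "config": bundle.config.to_dict(),
        "config_hash": bundle.config.content_hash(),
        "n_trials": bundle.n_trials,
        "units": sorted(bundle.units),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table {table!r} is missing column(s): {', '.join(missing)}")


def read_session(path) -> SessionBundle:
    """Load a bundle written by :func:`write_session`, with validation."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml in {path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["trial_type_probs"] = tuple(cfg_dict["trial_type_probs"])
    config = SessionConfig(**cfg_dict)

    events = pd.read_csv(path / "events.tsv", sep="\t", float_precision="round_trip")
    _require_columns(events, _EVENT_COLUMNS, "events.tsv")
    inhal = pd.read_csv(path / "inhalations.tsv", sep="\t", float_precision="round_trip")
    _require_columns(inhal, ["trial_id", "t"], "inhalations.tsv")
    licks = pd.read_csv(path / "licks.tsv", sep="\t", float_precision="round_trip")
    _require_columns(licks, ["trial_id", "t"], "licks.tsv")
    traces = pd.read_csv(path / "traces.tsv", sep="\t", float_precision="round_trip")
    _require_columns(traces, ["trial_id", "bin", "position", "speed"], "traces.tsv")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t")
    _require_columns(spikes, ["unit_id", "trial_id", "bin", "count"], "spikes.tsv")

    def _opt(value):
        return None if pd.isna(value) else float(value)

    trials = []
    positions = []
    speeds = []
    for _, row in events.sort_values("trial_id").iterrows():
        tid = int(row.trial_id)
        if row.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {row.trial_type!r} in events.tsv")
        inh_t = np.sort(inhal.loc[inhal.trial_id == tid, "t"].to_numpy(float))
        lick_t = np.sort(licks.loc[licks.trial_id == tid, "t"].to_numpy(float))
        if inh_t.size and inh_t[0] < 0:
            raise ValueError(f"negative inhalation time in trial {tid}")
        if lick_t.size and lick_t[0] < 0:
            raise ValueError(f"negative lick time in trial {tid}")
        trials.append(
            TrialEvents(
                trial_id=tid,
                trial_type=str(row.trial_type),
                t_start=float(row.t_start),
                duration=float(row.duration),
                t_context_entry=float(row.t_context_entry),
                t_context_exit=float(row.t_context_exit),
                t_odour_on=float(row.t_odour_on),
                t_first_odour_inhalation=_opt(row.t_first_odour_inhalation),
                t_first_lick_after_odour=_opt(row.t_first_lick_after_odour),
                t_reward=_opt(row.t_reward),
                inhalation_times=inh_t,
                lick_times=lick_t,
                outcome=str(row.outcome),
            )
        )
        tr_rows = traces[traces.trial_id == tid].sort_values("bin")
        positions.append(tr_rows.position.to_numpy(float))
        speeds.append(tr_rows.speed.to_numpy(float))

    bundle = SessionBundle(
        config=config, trials=trials, position=positions, speed=speeds
    )
    offsets = np.concatenate([[0], np.cumsum(bundle.n_bins)])
    units: dict[str, SpikeTrain] = {}
    for unit_id, grp in spikes.groupby("unit_id"):
        counts = np.zeros(bundle.total_bins, dtype=np.int64)
        if (grp["count"] < 0).any():
            raise ValueError(f"negative spike count for unit {unit_id}")
        if (grp["bin"] < 0).any():
            raise ValueError(f"negative spike bin (time) for unit {unit_id}")
        g_bins = offsets[grp.trial_id.to_numpy(int)] + grp.bin.to_numpy(int)
        counts[g_bins] = grp["count"].to_numpy(int)
        units[str(unit_id)] = SpikeTrain(unit_id=str(unit_id), counts=counts)
    bundle.units = units
    return bundle


def spike_times_from_counts(
    bundle: SessionBundle, counts: np.ndarray, seed: int = 0
) -> list[np.ndarray]:
    """Per-trial spike times (uniform within each 10-ms bin) from binned
    counts — convenience for PSTH-style analyses that want point events."""
    rng = np.random.default_rng(seed)
    out = []
    for sl, _n in zip(bundle.trial_slices(), bundle.n_bins):
        c = counts[sl]
        nz = np.flatnonzero(c)
        times = np.concatenate(
            [
                (b + rng.random(int(c[b]))) * bundle.dt
                for b in nz
            ]
        ) if nz.size else np.empty(0)
        out.append(np.sort(times))
    return out
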