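"""Design matrices for multi-variable Poisson encoding models.

The firing rate of a neuron is modelled as ``exp(sum_i (k_i (x) x_i)_t)``
where each task variable ``x_i`` enters either as a train of delta events
convolved with an event kernel, or as a one-hot "animal state" vector
(binned position or speed) weighted by a tuning kernel.  Kernels live in
raised-cosine bases, so each variable contributes a block of columns — one
per basis coefficient — to the design matrix.  A constant bias column is
always appended.

The eight model variables (and their kernels):

================  =======  ==================================================
Inhal             event    10 bases on a 460-ms window after every inhalation
Odour             event    O_R / O_U: 10 bases, 460 ms after each odour
                           inhalation (inhalations during the 1-s pulse)
Licks             event    15 bases, 360 ms after each lick
Reward            event    15 bases, 360 ms after reward delivery
preGO             event    22 bases on the 2000 ms *before* the first lick
                           that follows odour stimulation (acausal support)
modOdour          event    modO_R / modO_U: 20 bases, 1500 ms after the first
                           odour inhalation, active only in rewarded-context
                           trials (odour-by-context interaction)
Context           tuning   C_R / C_U: position in 4-cm bins over the whole
                           corridor (42 bases), one kernel per context
Speed             tuning   1-cm/s bins up to the session's maximum speed
================  =======  ==================================================

Three variables (Odour, modOdour, Context) are pairs: the pair is selected
or removed as one variable, but each member keeps its own kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .basis import BasisSet, raised_cosine_basis
from .session import SessionBundle, context_of, odour_of

__all__ = [
    "MODEL_VARIABLES",
    "KERNELS_OF",
    "VariableSpec",
    "DesignMatrix",
    "default_variable_specs",
    "build_bases",
    "assemble_design_matrix",
]

MODEL_VARIABLES = (
    "Inhal",
    "Odour",
    "Licks",
    "Reward",
    "preGO",
    "modOdour",
    "Context",
    "Speed",
)

#: kernels belonging to each variable (paired variables carry two kernels)
KERNELS_OF = {
    "Inhal": ("Inhal",),
    "Odour": ("O_R", "O_U"),
    "Licks": ("Licks",),
    "Reward": ("Reward",),
    "preGO": ("preGO",),
    "modOdour": ("modO_R", "modO_U"),
    "Context": ("C_R", "C_U"),
    "Speed": ("Speed",),
    "Bias": ("Bias",),
}


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one model variable.

    ``support`` is a time window in seconds for event kernels (negative lags
    allowed for acausal kernels such as preGO) or a value range for tuning
    kernels (cm for position, cm/s for speed).  ``value_bin`` is the tuning
    discretization step (4 cm for position, 1 cm/s for speed).
    """

    name: str
    kind: str  # 'event' | 'tuning' | 'bias'
    n_bases: int
    support: tuple[float, float]
    value_bin: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("event", "tuning", "bias"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_bases < 1:
            raise ValueError("n_bases must be >= 1")
        if self.support[1] <= self.support[0]:
            raise ValueError("support must be a nonempty interval")
        if self.kind == "tuning" and not self.value_bin:
            raise ValueError("tuning variables need a value_bin")

    @property
    def kernels(self) -> tuple[str, ...]:
        return KERNELS_OF[self.name]


def default_variable_specs(bundle: SessionBundle) -> dict[str, VariableSpec]:
    """The standard 8-variable parametrization for a session.

    The number of position bases follows from the corridor length at 4-cm
    bins (42 for the default 168-cm corridor); the number of speed bases
    follows from the session's maximum running speed at 1-cm/s bins.
    """
    corridor = bundle.config.corridor_length
    n_pos = int(round(corridor / 4.0))
    n_speed = max(1, int(np.ceil(bundle.max_speed / 1.0)))
    return {
        "Inhal": VariableSpec("Inhal", "event", 10, (0.0, 0.46)),
        "Odour": VariableSpec("Odour", "event", 10, (0.0, 0.46)),
        "Licks": VariableSpec("Licks", "event", 15, (0.0, 0.36)),
        "Reward": VariableSpec("Reward", "event", 15, (0.0, 0.36)),
        "preGO": VariableSpec("preGO", "event", 22, (-2.0, 0.0)),
        "modOdour": VariableSpec("modOdour", "event", 20, (0.0, 1.5)),
        "Context": VariableSpec("Context", "tuning", n_pos, (0.0, corridor), 4.0),
        "Speed": VariableSpec("Speed", "tuning", n_speed, (0.0, float(n_speed)), 1.0),
    }


def build_bases(specs: dict[str, VariableSpec], dt: float) -> dict[str, BasisSet]:
    """One raised-cosine :class:`BasisSet` per kernel name (plus Bias)."""
    bases: dict[str, BasisSet] = {}
    for spec in specs.values():
        if spec.kind == "event":
            basis = raised_cosine_basis(spec.n_bases, spec.support, "event", dx=dt)
        else:
            lo, hi = spec.support
            n_bins = int(round((hi - lo) / spec.value_bin))
            centres = lo + (np.arange(n_bins) + 0.5) * spec.value_bin
            basis = raised_cosine_basis(
                spec.n_bases, (centres[0], centres[-1]) if n_bins > 1 else (lo, hi),
                "tuning",
                domain=centres,
            )
        for kernel_name in spec.kernels:
            bases[kernel_name] = basis
    bases["Bias"] = raised_cosine_basis(1, (0.0, 1.0), "event", domain=np.array([0.5]))
    return bases


@dataclass
class DesignMatrix:
    """Column blocks of regressors for one session.

    ``blocks`` maps variable name -> sparse (T x p_var) block (paired
    variables hold both kernels side by side); ``kernel_slices`` locates each
    kernel's columns inside the stacked matrix ``X``; ``masks`` marks, per
    variable, the time bins where its block has any nonzero entry (the bins
    over which that kernel contributed to the rate — used by the
    contribution metric).
    """

    variables: tuple[str, ...]
    blocks: dict[str, sp.csr_matrix]
    bases: dict[str, BasisSet]
    specs: dict[str, VariableSpec]
    masks: dict[str, np.ndarray]
    dt: float
    bin_trial: np.ndarray
    bin_time: np.ndarray
    _X: sp.csr_matrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.col_slices: dict[str, slice] = {}
        self.kernel_slices: dict[str, slice] = {}
        start = 0
        for var in (*self.variables, "Bias"):
            width = self.blocks[var].shape[1]
            self.col_slices[var] = slice(start, start + width)
            kernels = KERNELS_OF[var]
            k_width = width // len(kernels)
            for i, kernel_name in enumerate(kernels):
                self.kernel_slices[kernel_name] = slice(
                    start + i * k_width, start + (i + 1) * k_width
                )
            start += width
        self.n_columns = start

    @property
    def n_rows(self) -> int:
        return self.blocks["Bias"].shape[0]

    @property
    def X(self) -> sp.csr_matrix:
        if self._X is None:
            self._X = sp.hstack(
                [self.blocks[v] for v in (*self.variables, "Bias")], format="csr"
            )
        return self._X

    @property
    def penalty_mask(self) -> np.ndarray:
        """1 for ridge-penalized (kernel) columns, 0 for the bias column."""
        mask = np.ones(self.n_columns)
        mask[self.col_slices["Bias"]] = 0.0
        return mask

    def subset(self, variables) -> "DesignMatrix":
        """Design restricted to ``variables`` (bias always kept)."""
        variables = tuple(v for v in MODEL_VARIABLES if v in set(variables))
        unknown = set(variables) - set(self.variables)
        if unknown:
            raise ValueError(f"variables not in this design: {sorted(unknown)}")
        if variables == self.variables:
            return self
        return DesignMatrix(
            variables=variables,
            blocks=self.blocks,
            bases=self.bases,
            specs=self.specs,
            masks=self.masks,
            dt=self.dt,
            bin_trial=self.bin_trial,
            bin_time=self.bin_time,
        )

    def rows(self, row_mask: np.ndarray) -> sp.csr_matrix:
        return self.X[row_mask]

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (row, column, value) export for inspection."""
        coo = self.X.tocoo()
        kernel_of_col = np.empty(self.n_columns, dtype=object)
        for kernel_name, sl in self.kernel_slices.items():
            kernel_of_col[sl] = kernel_name
        return pd.DataFrame(
            {
                "row": coo.row,
                "col": coo.col,
                "kernel": kernel_of_col[coo.col],
                "value": coo.data,
            }
        )


# ---------------------------------------------------------------------------
# block construction


def event_block(
    event_bins: np.ndarray,
    event_trials: np.ndarray,
    basis: BasisSet,
    trial_starts: np.ndarray,
    trial_ends: np.ndarray,
    n_rows: int,
    dt: float,
) -> sp.csr_matrix:
    """Convolve delta trains with basis bumps.

    ``event_bins`` are global bin indices of the events; each event places a
    copy of every bump at its own latency, truncated at the boundaries of
    the event's trial (kernels never leak across trials).
    """
    lag_offsets = np.round(basis.domain / dt).astype(int)
    n_lags = lag_offsets.size
    if event_bins.size == 0:
        return sp.csr_matrix((n_rows, basis.n))
    rows = event_bins[:, None] + lag_offsets[None, :]
    lo = trial_starts[event_trials][:, None]
    hi = trial_ends[event_trials][:, None]
    valid = (rows >= lo) & (rows < hi)
    cols = np.broadcast_to(np.arange(n_lags), rows.shape)
    lag_indicator = sp.coo_matrix(
        (np.ones(int(valid.sum())), (rows[valid], cols[valid])),
        shape=(n_rows, n_lags),
    ).tocsr()
    return (lag_indicator @ sp.csr_matrix(basis.B)).tocsr()


def tuning_block(
    values: np.ndarray,
    active: np.ndarray,
    basis: BasisSet,
    value_bin: float,
    lo: float,
    n_rows: int,
) -> sp.csr_matrix:
    """One-hot animal-state vectors weighted by the tuning basis."""
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return sp.csr_matrix((n_rows, basis.n))
    n_value_bins = basis.domain.size
    vbin = np.clip(
        np.floor((values[idx] - lo) / value_bin).astype(int), 0, n_value_bins - 1
    )
    onehot = sp.coo_matrix(
        (np.ones(idx.size), (idx, vbin)), shape=(n_rows, n_value_bins)
    ).tocsr()
    return (onehot @ sp.csr_matrix(basis.B)).tocsr()


def _event_bins(bundle: SessionBundle, times_per_trial) -> tuple[np.ndarray, np.ndarray]:
    """Global bin index and trial index for per-trial event times."""
    offsets = np.concatenate([[0], np.cumsum(bundle.n_bins)])
    bins, trials = [], []
    for trial_idx, times in enumerate(times_per_trial):
        for t in np.atleast_1d(times):
            if t is None:
                continue
            b = int(np.floor(t / bundle.dt))
            if t < 0 or b >= bundle.n_bins[trial_idx]:
                raise ValueError(
                    f"event at t={t:.3f}s falls outside trial {trial_idx} "
                    f"({bundle.n_bins[trial_idx]} bins)"
                )
            bins.append(offsets[trial_idx] + b)
            trials.append(trial_idx)
    return np.asarray(bins, dtype=int), np.asarray(trials, dtype=int)


def _odour_inhalations(trial, pulse: float) -> np.ndarray:
    t = trial.inhalation_times
    return t[(t > trial.t_odour_on) & (t <= trial.t_odour_on + pulse)]


def assemble_design_matrix(
    bundle: SessionBundle,
    variables=None,
    specs: dict[str, VariableSpec] | None = None,
    *,
    odour_override: str | None = None,
    context_override: str | None = None,
) -> DesignMatrix:
    """Build the stacked design matrix for a session.

    ``odour_override`` / ``context_override`` ('R' or 'U') relabel every
    trial's odour or context when routing events into the identity-split
    kernels; decoding uses this to build the two counterfactual designs that
    differ only in the decoded variable's category.
    """
    if variables is None:
        variables = MODEL_VARIABLES
    variables = tuple(variables)
    if len(set(variables)) != len(variables):
        raise ValueError("duplicated variable names in request")
    for var in variables:
        if var not in MODEL_VARIABLES:
            raise ValueError(f"unknown model variable {var!r}")
    variables = tuple(v for v in MODEL_VARIABLES if v in variables)
    if specs is None:
        specs = default_variable_specs(bundle)
    bases = build_bases(specs, bundle.dt)

    n_rows = bundle.total_bins
    offsets = np.concatenate([[0], np.cumsum(bundle.n_bins)])
    trial_starts = offsets[:-1]
    trial_ends = offsets[1:]
    pulse = bundle.config.odour_pulse

    def trial_odour(trial) -> str:
        return odour_override or odour_of(trial.trial_type)

    def trial_context(trial) -> str:
        return context_override or context_of(trial.trial_type)

    def _events_for(kernel_name: str) -> list:
        out = []
        for trial in bundle.trials:
            if kernel_name == "Inhal":
                out.append(trial.inhalation_times)
            elif kernel_name in ("O_R", "O_U"):
                want = kernel_name[-1]
                out.append(
                    _odour_inhalations(trial, pulse)
                    if trial_odour(trial) == want
                    else np.empty(0)
                )
            elif kernel_name == "Licks":
                out.append(trial.lick_times)
            elif kernel_name == "Reward":
                out.append(
                    np.array([trial.t_reward]) if trial.t_reward is not None else np.empty(0)
                )
            elif kernel_name == "preGO":
                out.append(
                    np.array([trial.t_first_lick_after_odour])
                    if trial.t_first_lick_after_odour is not None
                    else np.empty(0)
                )
            elif kernel_name in ("modO_R", "modO_U"):
                want = kernel_name[-1]
                gated = trial_context(trial) == "R" and trial_odour(trial) == want
                out.append(
                    np.array([trial.t_first_odour_inhalation])
                    if gated and trial.t_first_odour_inhalation is not None
                    else np.empty(0)
                )
            else:  # pragma: no cover
                raise KeyError(kernel_name)
        return out

    position = np.concatenate(bundle.position)
    speed = np.concatenate(bundle.speed)
    bin_trial = bundle.bin_trial
    trial_ctx = np.array([trial_context(t) for t in bundle.trials])

    blocks: dict[str, sp.csr_matrix] = {}
    masks: dict[str, np.ndarray] = {}
    for var in variables:
        spec = specs[var]
        sub_blocks = []
        for kernel_name in spec.kernels:
            basis = bases[kernel_name]
            if spec.kind == "event":
                bins, trs = _event_bins(bundle, _events_for(kernel_name))
                sub_blocks.append(
                    event_block(
                        bins, trs, basis, trial_starts, trial_ends, n_rows, bundle.dt
                    )
                )
            else:
                if var == "Context":
                    want = kernel_name[-1]
                    active = trial_ctx[bin_trial] == want
                    sub_blocks.append(
                        tuning_block(position, active, basis, spec.value_bin, 0.0, n_rows)
                    )
                else:  # Speed
                    if speed.max() > specs["Speed"].support[1] + 1e-9:
                        raise ValueError(
                            "speed exceeds the declared maximum of the Speed spec"
                        )
                    active = np.ones(n_rows, dtype=bool)
                    sub_blocks.append(
                        tuning_block(speed, active, basis, spec.value_bin, 0.0, n_rows)
                    )
        block = sp.hstack(sub_blocks, format="csr") if len(sub_blocks) > 1 else sub_blocks[0]
        blocks[var] = block
        masks[var] = np.asarray(block.getnnz(axis=1) > 0)

    blocks["Bias"] = sp.csr_matrix(np.ones((n_rows, 1)))
    masks["Bias"] = np.ones(n_rows, dtype=bool)

    return DesignMatrix(
        variables=variables,
        blocks=blocks,
        bases=bases,
        specs=specs,
        masks=masks,
        dt=bundle.dt,
        bin_trial=bin_trial,
        bin_time=bundle.bin_time,
    )


def kernel_occupancy(design: DesignMatrix) -> dict[str, np.ndarray]:
    """Per-kernel, per-coefficient exposure: the column sums of each
    kernel's design block.  Coefficients with near-zero exposure (value bins
    the animal rarely occupies, lags truncated by trial boundaries) are
    barely constrained by any fit."""
    occ = {}
    for var in design.variables:
        block = design.blocks[var]
        colsum = np.asarray(np.abs(block).sum(axis=0)).ravel()
        kernels = KERNELS_OF[var]
        width = block.shape[1] // len(kernels)
        for i, kernel_name in enumerate(kernels):
            occ[kernel_name] = colsum[i * width : (i + 1) * width]
    return occ
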