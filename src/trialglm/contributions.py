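"""Per-variable contributions to a neuron's encoding model.

The contribution of variable ``x_i`` is the spike-normalised log-likelihood
increase of the selected model over the same model refit without ``x_i``,
restricted to the time bins where kernel ``k_i`` actually contributed to the
rate (the variable's valid-bin mask), in bits per spike:

    C_i = sum_{t in mask_i} [ (r_t log(l_t dt) - l_t dt)
                            - (r_t log(l~_t dt) - l~_t dt) ]
          / ( log(2) * (1 + sum_{t in mask_i} r_t) )

The ``+1`` in the normaliser guards bins-without-spikes; removing a variable
means a full refit of the reduced model, not a zeroing of its weights.
Relative contributions divide each C_i by the sum over included variables;
the resulting profile (over all 8 candidate variables, zeros for variables
outside the selected model) is the feature vector used for selectivity
clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import MODEL_VARIABLES, KERNELS_OF, DesignMatrix
from .glm import GLMFit, fit_map, predict_rate

__all__ = [
    "ContributionProfile",
    "variable_contribution",
    "relative_contributions",
    "contribution_profile",
    "kernel_gain",
]


@dataclass
class ContributionProfile:
    """Absolute (bits/spike) and relative contributions per variable."""

    variables: tuple[str, ...]
    contribution: dict[str, float]
    relative: dict[str, float]

    def vector(self, order=MODEL_VARIABLES) -> np.ndarray:
        """Relative contributions as a fixed-order feature vector (zeros for
        variables absent from the model)."""
        return np.array([self.relative.get(v, 0.0) for v in order])


def variable_contribution(
    fit_full: GLMFit,
    fit_reduced: GLMFit,
    design: DesignMatrix,
    counts: np.ndarray,
    variable: str,
    row_mask: np.ndarray | None = None,
) -> float:
    """Bits-per-spike contribution of ``variable``.

    ``fit_reduced`` must be the model refit with ``variable`` removed.  The
    sums run over the variable's valid-bin mask (optionally intersected
    with ``row_mask``, e.g. a split-half trial restriction); with no spikes
    in the mask the denominator reduces to ``log 2`` exactly.  An empty
    mask yields a contribution of 0 (with a warning).
    """
    if variable not in fit_full.variables:
        raise ValueError(f"{variable!r} is not in the fitted model")
    if variable in fit_reduced.variables:
        raise ValueError(f"{variable!r} is still present in the reduced fit")
    mask = design.masks[variable]
    if row_mask is not None:
        mask = mask & row_mask
    if not mask.any():
        warnings.warn(f"variable {variable!r} has an empty valid-bin mask")
        return 0.0
    counts = np.asarray(counts)
    lam_full = predict_rate(fit_full, design)
    lam_red = predict_rate(fit_reduced, design)
    dt = design.dt
    r = counts[mask]
    mu_f = lam_full[mask] * dt
    mu_r = lam_red[mask] * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        term_f = np.where(r > 0, r * np.log(mu_f), 0.0) - mu_f
        term_r = np.where(r > 0, r * np.log(mu_r), 0.0) - mu_r
    numerator = float((term_f - term_r).sum())
    denominator = np.log(2.0) * (1.0 + float(r.sum()))
    return numerator / denominator


def relative_contributions(contribution: dict[str, float]) -> dict[str, float]:
    """Normalise each contribution by the sum over included variables."""
    if not contribution:
        raise ValueError("no included variables")
    total = sum(contribution.values())
    if total == 0:
        raise ValueError("contributions sum to zero; relative values undefined")
    if total < 0:
        raise ValueError(
            "contributions sum to a negative value; relative contributions "
            "would fall outside [0, 1] (weak model flagged)"
        )
    return {v: c / total for v, c in contribution.items()}


def contribution_profile(
    design: DesignMatrix,
    counts: np.ndarray,
    fit_full: GLMFit,
    *,
    reduced_fits: dict[str, GLMFit] | None = None,
    row_mask: np.ndarray | None = None,
) -> ContributionProfile:
    """Contributions of every variable in the selected model.

    Each variable is removed in turn (paired kernels removed together) and
    the reduced model refit at the same ridge strength, warm-started from
    the full fit's remaining weights.  ``row_mask`` restricts both the
    refits and the contribution sums to a subset of time bins (used by
    split-half analyses).
    """
    counts = np.asarray(counts)
    variables = fit_full.variables
    contribution: dict[str, float] = {}
    for var in variables:
        if reduced_fits is not None and var in reduced_fits:
            fit_red = reduced_fits[var]
        else:
            keep = tuple(v for v in variables if v != var)
            d_red = design.subset(keep)
            w0 = np.zeros(d_red.n_columns)
            for v in (*keep, "Bias"):
                w0[d_red.col_slices[v]] = fit_full.w[fit_full.col_slices[v]]
            fit_red = fit_map(
                design, counts, fit_full.xi, variables=keep, w0=w0,
                row_mask=row_mask,
            )
        contribution[var] = variable_contribution(
            fit_full, fit_red, design, counts, var, row_mask=row_mask
        )
    relative = relative_contributions(contribution) if contribution else {}
    return ContributionProfile(
        variables=variables, contribution=contribution, relative=relative
    )


def kernel_gain(fit: GLMFit, variable: str) -> dict[str, tuple[np.ndarray, float]]:
    """Multiplicative gain curves ``exp(k(t))`` and their amplitudes.

    Amplitude is ``max_t |gain(t) - 1|``: 0 for a silent kernel, and the
    peak fractional rate modulation otherwise.  Returns one entry per kernel
    of the variable (paired variables have two).
    """
    if variable not in fit.variables:
        raise ValueError(f"{variable!r} is not in the fitted model")
    out = {}
    for kernel_name in KERNELS_OF[variable]:
        values = fit.bases[kernel_name].reconstruct(fit.kernel_weights(kernel_name))
        gain = np.exp(values)
        out[kernel_name] = (gain, float(np.abs(gain - 1.0).max()))
    return out
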