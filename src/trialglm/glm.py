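"""Poisson GLM fitting, regularisation, cross-validation and model selection.

Per neuron, spike counts ``r_t`` in 10-ms bins are modelled as Poisson with
mean ``lambda_t * dt`` and ``log lambda_t = (X w)_t`` for a design matrix
``X`` of kernel-basis regressors.  Weights are the mode of the posterior
under a ridge (Gaussian) prior on kernel weights (the bias is unpenalized):

    L(w) = sum_t [ r_t log(lambda_t dt) - lambda_t dt ] - xi ||w_kernels||^2

The objective is concave, so Newton ascent with backtracking line search
finds the unique optimum.  The ridge strength ``xi`` is chosen by empirical
Bayes: the Laplace approximation to the marginal likelihood is maximised
over a logarithmic grid, on all trials at once.  Model performance is the
10-fold cross-validated held-out log-likelihood, folds split by trial and
each fold normalised by its spike count; model complexity is chosen by a
forward search that adds variables while a one-sided signed-rank test over
the 10 paired folds shows significant improvement (p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import wilcoxon

from .design import MODEL_VARIABLES, DesignMatrix

__all__ = [
    "GLMFit",
    "CVPerformance",
    "RidgeSelection",
    "ForwardSelectionResult",
    "DEFAULT_XI_GRID",
    "poisson_log_likelihood",
    "fit_map",
    "predict_rate",
    "select_ridge_by_evidence",
    "make_trial_folds",
    "crossvalidated_performance",
    "signed_rank_improvement",
    "forward_model_selection",
    "validate_exponential_nonlinearity",
]

#: 13 logarithmically spaced ridge strengths, 1e-2 .. 1e4
DEFAULT_XI_GRID = np.logspace(-2, 4, 13)


def poisson_log_likelihood(
    counts: np.ndarray,
    rate: np.ndarray,
    dt: float,
    include_constant: bool = False,
) -> float:
    """``sum_t [r_t log(rate_t dt) - rate_t dt]`` (optionally ``- log r_t!``).

    Rates must be strictly positive wherever a spike was counted.
    """
    counts = np.asarray(counts)
    rate = np.asarray(rate, dtype=float)
    mu = rate * dt
    if np.any((mu <= 0) & (counts > 0)):
        raise ValueError("zero or negative rate in a bin with spikes")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(mu), 0.0)
    ll = float(term.sum() - mu.sum())
    if include_constant:
        from scipy.special import gammaln

        ll -= float(gammaln(counts + 1.0).sum())
    return ll


@dataclass
class GLMFit:
    """A fitted per-neuron encoding model.

    ``w`` is aligned with the columns of ``design.subset(variables)``:
    kernel blocks in canonical variable order, bias last.  Kernels are
    reproduced exactly from the basis and their weight slice.
    """

    variables: tuple[str, ...]
    w: np.ndarray
    xi: float
    col_slices: dict[str, slice]
    kernel_slices: dict[str, slice]
    bases: dict = field(repr=False)
    n_iter: int = 0
    grad_norm: float = np.nan
    converged: bool = True
    objective_path: np.ndarray | None = field(default=None, repr=False)
    cv: "CVPerformance | None" = None

    @property
    def bias(self) -> float:
        return float(self.w[self.col_slices["Bias"]][0])

    def kernel_weights(self, kernel_name: str) -> np.ndarray:
        return self.w[self.kernel_slices[kernel_name]]

    def kernels(self) -> dict[str, np.ndarray]:
        """Reconstructed kernel values on each kernel's domain grid."""
        out = {}
        for var in self.variables:
            from .design import KERNELS_OF

            for kernel_name in KERNELS_OF[var]:
                out[kernel_name] = self.bases[kernel_name].reconstruct(
                    self.kernel_weights(kernel_name)
                )
        return out

    def with_weights(self, w: np.ndarray) -> "GLMFit":
        new = GLMFit(
            variables=self.variables,
            w=np.asarray(w, dtype=float),
            xi=self.xi,
            col_slices=self.col_slices,
            kernel_slices=self.kernel_slices,
            bases=self.bases,
            n_iter=self.n_iter,
            grad_norm=self.grad_norm,
            converged=self.converged,
        )
        return new


def predict_rate(fit: GLMFit, design: DesignMatrix) -> np.ndarray:
    """Rate series ``exp(X w)`` (Hz) for the fit's variable set."""
    d = design.subset(fit.variables)
    if d.n_columns != fit.w.size:
        raise ValueError(
            f"design has {d.n_columns} columns for {fit.variables}, "
            f"fit carries {fit.w.size} weights"
        )
    return np.exp(d.X @ fit.w)


# ---------------------------------------------------------------------------
# MAP estimation (Newton ascent with line search)


def _penalized_objective(X, counts, dt, w, xi, pen):
    eta = X @ w
    with np.errstate(over="ignore"):
        mu = np.exp(eta) * dt
    if not np.all(np.isfinite(mu)):
        return -np.inf, eta, mu
    f = float(counts @ eta - mu.sum() - xi * np.sum(pen * w * w))
    return f, eta, mu


def fit_map(
    design: DesignMatrix,
    counts: np.ndarray,
    xi: float,
    variables=None,
    *,
    row_mask: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GLMFit:
    """Maximum-a-posteriori weights for one model.

    The penalized log-likelihood is concave, so any two starting points
    reach the same optimum; convergence is declared when the gradient's
    max-norm falls below ``tol``.

    ``row_mask`` restricts fitting to a subset of time bins (used by
    cross-validation to hold trials out).
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    d = design.subset(variables) if variables is not None else design
    X = d.X
    counts = np.asarray(counts, dtype=float)
    if counts.size != X.shape[0]:
        raise ValueError("counts and design are not aligned")
    if row_mask is not None:
        X = X[row_mask]
        counts = counts[row_mask]
    pen = d.penalty_mask
    dt = d.dt

    if w0 is None:
        w = np.zeros(d.n_columns)
        mean_rate = max(counts.mean() / dt, 1e-4)
        w[d.col_slices["Bias"]] = np.log(mean_rate)
    else:
        w = np.asarray(w0, dtype=float).copy()

    f, eta, mu = _penalized_objective(X, counts, dt, w, xi, pen)
    path = [f]
    grad_norm = np.inf
    converged = False
    X = X.tocsr()
    Xt = X.T.tocsr()
    row_nnz = np.diff(X.indptr)
    X_scaled = X.copy()  # rows rescaled by the current mean in place
    for iteration in range(1, max_iter + 1):
        grad = Xt @ (counts - mu) - 2.0 * xi * pen * w
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol:
            converged = True
            break
        X_scaled.data = X.data * np.repeat(mu, row_nnz)
        H = (Xt @ X_scaled).toarray()
        H[np.diag_indices_from(H)] += 2.0 * xi * pen + 1e-12
        try:
            chol = cho_factor(H, lower=True)
            step = cho_solve(chol, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"singular Hessian at iteration {iteration}; "
                "try a larger ridge strength"
            ) from err
        t = 1.0
        accepted = False
        g_dot_s = float(grad @ step)
        for _ in range(40):
            f_new, eta_new, mu_new = _penalized_objective(
                X, counts, dt, w + t * step, xi, pen
            )
            if f_new >= f + 1e-4 * t * g_dot_s:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            # gradient tiny relative to curvature: treat as converged
            converged = grad_norm < 1e-3
            break
        improvement = f_new - f
        w = w + t * step
        f, eta, mu = f_new, eta_new, mu_new
        path.append(f)
        if improvement < 1e-10 * (abs(f) + 1.0):
            # at the optimum to floating precision (ill-conditioned blocks
            # can leave a gradient component that no step can reduce)
            converged = True
            break
    else:
        iteration = max_iter

    if not converged and grad_norm > 1e-3:
        raise RuntimeError(
            f"Newton ascent did not converge: {iteration} iterations, "
            f"|grad|_max = {grad_norm:.3g}, objective = {f:.6g}"
        )
    return GLMFit(
        variables=d.variables,
        w=w,
        xi=float(xi),
        col_slices=d.col_slices,
        kernel_slices={k: s for k, s in d.kernel_slices.items()},
        bases=d.bases,
        n_iter=iteration,
        grad_norm=grad_norm,
        converged=converged,
        objective_path=np.asarray(path),
    )


# ---------------------------------------------------------------------------
# ridge selection by Laplace evidence


@dataclass
class RidgeSelection:
    xi: float
    grid: np.ndarray
    log_evidence: np.ndarray
    fits: list = field(default_factory=list, repr=False)


def _laplace_log_evidence(design: DesignMatrix, counts, fit: GLMFit) -> float:
    d = design.subset(fit.variables)
    X = d.X.tocsr()
    mu = np.exp(X @ fit.w) * design.dt
    pen = d.penalty_mask
    X_scaled = X.copy()
    X_scaled.data = X.data * np.repeat(mu, np.diff(X.indptr))
    H = (X.T @ X_scaled).toarray()
    H[np.diag_indices_from(H)] += 2.0 * fit.xi * pen
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise RuntimeError(
            "negative-definite Hessian in evidence computation; "
            "try a larger ridge floor"
        )
    counts = np.asarray(counts, dtype=float)
    ll = float(counts @ (X @ fit.w) - mu.sum())
    n_pen = int(pen.sum())
    p_total = fit.w.size
    return (
        ll
        - fit.xi * float(np.sum(pen * fit.w * fit.w))
        + 0.5 * n_pen * np.log(fit.xi / np.pi)
        + 0.5 * p_total * np.log(2.0 * np.pi)
        - 0.5 * logdet
    )


def select_ridge_by_evidence(
    design: DesignMatrix,
    counts: np.ndarray,
    xi_grid: np.ndarray = DEFAULT_XI_GRID,
    variables=None,
) -> RidgeSelection:
    """Empirical-Bayes ridge strength: maximise the Laplace-approximated
    marginal likelihood over ``xi_grid``, fitting on all trials at once."""
    xi_grid = np.asarray(xi_grid, dtype=float)
    if xi_grid.size == 0:
        raise ValueError("xi_grid must be nonempty")
    if np.any(xi_grid <= 0):
        raise ValueError("the evidence is defined only for xi > 0")
    d = design.subset(variables) if variables is not None else design
    log_ev = np.empty(xi_grid.size)
    fits = []
    w0 = None
    for i, xi in enumerate(xi_grid):
        fit = fit_map(d, counts, xi, w0=w0)
        w0 = fit.w
        log_ev[i] = _laplace_log_evidence(d, counts, fit)
        fits.append(fit)
    best = int(np.argmax(log_ev))
    return RidgeSelection(
        xi=float(xi_grid[best]), grid=xi_grid, log_evidence=log_ev, fits=fits
    )


# ---------------------------------------------------------------------------
# cross-validated performance


@dataclass
class CVPerformance:
    """Held-out log-likelihoods, one per fold, each normalised by the number
    of spikes in the fold (guarded to 1 for silent folds, which are
    flagged)."""

    fold_ll: np.ndarray
    folds: list
    zero_spike_folds: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.fold_ll.mean())


def make_trial_folds(n_trials: int, n_folds: int = 10, seed: int = 0) -> list:
    """Seeded random partition of trials into ``n_folds`` near-equal sets."""
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_trials)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def crossvalidated_performance(
    design: DesignMatrix,
    counts: np.ndarray,
    xi: float,
    variables=None,
    *,
    n_folds: int = 10,
    seed: int = 0,
    folds: list | None = None,
    w_warm: np.ndarray | None = None,
) -> CVPerformance:
    """10-fold cross-validation with folds split by trial (trials are never
    split across folds)."""
    d = design.subset(variables) if variables is not None else design
    counts = np.asarray(counts)
    n_trials = int(d.bin_trial.max()) + 1
    if folds is None:
        folds = make_trial_folds(n_trials, n_folds, seed)
    if w_warm is None:
        w_warm = fit_map(d, counts, xi).w
    fold_ll = np.empty(len(folds))
    zero_flags = np.zeros(len(folds), dtype=bool)
    for i, fold_trials in enumerate(folds):
        test_rows = np.isin(d.bin_trial, fold_trials)
        fit = fit_map(d, counts, xi, row_mask=~test_rows, w0=w_warm)
        rate = np.exp(d.X[test_rows] @ fit.w)
        ll = poisson_log_likelihood(counts[test_rows], rate, d.dt)
        n_spikes = int(counts[test_rows].sum())
        if n_spikes == 0:
            zero_flags[i] = True
        fold_ll[i] = ll / max(1, n_spikes)
    return CVPerformance(fold_ll=fold_ll, folds=folds, zero_spike_folds=zero_flags)


def signed_rank_improvement(better: np.ndarray, reference: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p-value that the paired fold
    performances in ``better`` exceed ``reference`` (median difference > 0).
    Exact distribution at the 10-fold sample size."""
    diff = np.asarray(better) - np.asarray(reference)
    if np.allclose(diff, 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon(better, reference, alternative="greater")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# forward model selection


@dataclass
class SelectionStep:
    candidate_means: dict
    chosen: str
    p_value: float
    accepted: bool


@dataclass
class ForwardSelectionResult:
    variables: tuple[str, ...]
    fit: GLMFit
    xi: float
    cv: CVPerformance
    steps: list


def _n_columns(design: DesignMatrix, variables) -> int:
    return design.subset(variables).n_columns


def forward_model_selection(
    design: DesignMatrix,
    counts: np.ndarray,
    *,
    xi: float | None = None,
    xi_grid: np.ndarray = DEFAULT_XI_GRID,
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
    candidates=None,
) -> ForwardSelectionResult:
    """Greedy forward search over task variables.

    Starting from a constant-rate (bias-only) reference, at every step each
    remaining variable is added in turn, its 10-fold held-out performance is
    measured with the shared fold assignment, and the best candidate is kept
    only if the one-sided signed-rank test across the paired folds is
    significant at ``alpha``.  Neurons whose best single-variable model does
    not beat the constant-rate model end with zero selected variables.
    Ties in mean fold performance go to the candidate with fewer basis
    coefficients.
    """
    counts = np.asarray(counts)
    if candidates is None:
        candidates = [v for v in MODEL_VARIABLES if v in design.variables]
    n_trials = int(design.bin_trial.max()) + 1
    folds = make_trial_folds(n_trials, n_folds, seed)
    reselect_xi = xi is None
    if xi is None:
        # anchor the ridge scale on the best single-variable model: a quick
        # CV pass at a provisional mid-grid strength finds it, then the
        # Laplace evidence of that model sets xi for the whole search
        xi0 = float(np.median(xi_grid))
        provisional = {
            var: crossvalidated_performance(
                design, counts, xi0, variables=(var,), folds=folds
            ).mean
            for var in candidates
        }
        anchor = max(provisional, key=provisional.get)
        xi = select_ridge_by_evidence(
            design, counts, xi_grid, variables=(anchor,)
        ).xi

    current: tuple[str, ...] = ()
    current_fit = fit_map(design, counts, xi, variables=())
    cv_current = crossvalidated_performance(
        design, counts, xi, variables=(), folds=folds, w_warm=current_fit.w
    )
    steps: list[SelectionStep] = []
    remaining = list(candidates)
    while remaining:
        results = {}
        fits = {}
        for var in remaining:
            trial_vars = tuple(v for v in MODEL_VARIABLES if v in (*current, var))
            d_cand = design.subset(trial_vars)
            w0 = np.zeros(d_cand.n_columns)
            for v in (*current, "Bias"):
                w0[d_cand.col_slices[v]] = current_fit.w[current_fit.col_slices[v]]
            fits[var] = fit_map(design, counts, xi, variables=trial_vars, w0=w0)
            results[var] = crossvalidated_performance(
                design, counts, xi, variables=trial_vars, folds=folds,
                w_warm=fits[var].w,
            )
        means = {v: r.mean for v, r in results.items()}
        best_mean = max(means.values())
        tied = [v for v, m in means.items() if np.isclose(m, best_mean, atol=0.0)]
        best = min(tied, key=lambda v: _n_columns(design, (*current, v)))
        p = signed_rank_improvement(results[best].fold_ll, cv_current.fold_ll)
        accepted = p < alpha
        steps.append(
            SelectionStep(
                candidate_means=means, chosen=best, p_value=p, accepted=accepted
            )
        )
        if not accepted:
            break
        current = tuple(v for v in MODEL_VARIABLES if v in (*current, best))
        cv_current = results[best]
        current_fit = fits[best]
        remaining.remove(best)

    if reselect_xi and current:
        # the final estimate uses the evidence-optimal ridge for the
        # *selected* model, fit on all trials at once
        xi = select_ridge_by_evidence(design, counts, xi_grid, variables=current).xi
    final_fit = fit_map(design, counts, xi, variables=current)
    final_fit.cv = cv_current
    return ForwardSelectionResult(
        variables=current, fit=final_fit, xi=float(xi), cv=cv_current, steps=steps
    )


# ---------------------------------------------------------------------------
# exponential-nonlinearity validation


def validate_exponential_nonlinearity(
    fit: GLMFit,
    design: DesignMatrix,
    counts: np.ndarray,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Bin the kernel output (log-rate) and compare the observed spike rate
    per bin with the exponential prediction.

    Returns a table with one row per occupied bin: the bin centre ``g``,
    occupancy, observed rate (Hz), predicted rate ``exp(g)`` and a 95%
    Poisson interval for the observed rate under the prediction.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    d = design.subset(fit.variables)
    g = d.X @ fit.w
    counts = np.asarray(counts)
    edges = np.linspace(g.min(), g.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(g, edges) - 1, 0, n_bins - 1)
    rows = []
    from scipy.stats import poisson as poisson_dist

    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        spikes = int(counts[sel].sum())
        centre = float(g[sel].mean())
        observed = spikes / (n * d.dt)
        predicted = float(np.exp(centre))
        expected_spikes = predicted * n * d.dt
        lo, hi = poisson_dist.ppf([0.025, 0.975], max(expected_spikes, 1e-12))
        rows.append(
            {
                "bin": b,
                "g_centre": centre,
                "n_bins_occupied": n,
                "n_spikes": spikes,
                "observed_rate": observed,
                "predicted_rate": predicted,
                "rate_lo95": lo / (n * d.dt),
                "rate_hi95": hi / (n * d.dt),
                "within_ci": bool(lo <= spikes <= hi),
            }
        )
    return pd.DataFrame(rows)
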