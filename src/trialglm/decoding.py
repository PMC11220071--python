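"""Single-trial decoding from fitted encoding models.

To decode a binary task variable (e.g. which odour was presented), the
observed spikes of a trial are scored under two counterfactual rate models
that differ only in the decoded variable's category (designs built with the
trial relabelled as category A or B).  The running log-likelihood ratio

    LLR(t) = sum_{t'<=t} [ r_t' (log l^A_t' - log l^B_t') - dt (l^A_t' - l^B_t') ]

is positive when the spikes so far are more probable under category A; with
equal priors the posterior is the logistic transform ``1/(1+exp(-LLR))``.
LLRs of simultaneously recorded (or pseudopopulation) neurons sum.

Also here: pseudopopulation accuracy curves with trial matching and label
shuffles, L2-logistic linear decoding as a GLM-independent control, kernel
ablation ("only-odour" models), and the regression of behavioural response
delay on decoded posteriors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .design import DesignMatrix
from .glm import GLMFit
from .session import SessionBundle

__all__ = [
    "DecodeResult",
    "llr_timecourse",
    "llr_at_time",
    "posterior_probability",
    "population_accuracy",
    "population_decode",
    "linear_classifier_decode",
    "ablate_kernels",
    "delay_regression",
]


def _llr_terms(fit: GLMFit, design_A: DesignMatrix, design_B: DesignMatrix, counts):
    dA = design_A.subset(fit.variables)
    dB = design_B.subset(fit.variables)
    if dA.n_columns != fit.w.size or dB.n_columns != fit.w.size:
        raise ValueError("designs do not match the fit's variable set")
    eta_A = dA.X @ fit.w
    eta_B = dB.X @ fit.w
    counts = np.asarray(counts)
    return counts * (eta_A - eta_B) - design_A.dt * (np.exp(eta_A) - np.exp(eta_B))


def llr_timecourse(
    fit: GLMFit,
    design_A: DesignMatrix,
    design_B: DesignMatrix,
    counts: np.ndarray,
    bundle: SessionBundle,
) -> list[np.ndarray]:
    """Cumulative LLR within each trial (one array per trial).

    Positive values favour category A.  Population LLRs are the elementwise
    sum of the per-neuron outputs.
    """
    terms = _llr_terms(fit, design_A, design_B, counts)
    return [np.cumsum(terms[sl]) for sl in bundle.trial_slices()]


def llr_at_time(
    fit: GLMFit,
    design_A: DesignMatrix,
    design_B: DesignMatrix,
    counts: np.ndarray,
    bundle: SessionBundle,
    *,
    t_rel: float = 0.5,
    align: str = "t_first_odour_inhalation",
) -> np.ndarray:
    """Per-trial LLR accumulated from trial start to ``align + t_rel``.

    The default evaluation point is 0.5 s after the first odour inhalation.
    Trials lacking the alignment event give NaN.
    """
    terms = _llr_terms(fit, design_A, design_B, counts)
    out = np.full(bundle.n_trials, np.nan)
    for i, (trial, sl) in enumerate(zip(bundle.trials, bundle.trial_slices())):
        t0 = getattr(trial, align)
        if t0 is None:
            continue
        stop = int(np.floor((t0 + t_rel) / bundle.dt)) + 1
        stop = min(stop, sl.stop - sl.start)
        out[i] = terms[sl][:stop].sum()
    return out


def accuracy_timecourse(
    fits: list,
    design_A: DesignMatrix,
    design_B: DesignMatrix,
    counts_list: list,
    bundle: SessionBundle,
    labels: np.ndarray,
    times: np.ndarray,
    *,
    align: str = "t_first_odour_inhalation",
) -> np.ndarray:
    """Population decoding accuracy as a function of time in the trial.

    For each offset in ``times`` (seconds relative to the per-trial
    alignment event), the cumulative population LLR from trial start to
    that point is scored against ``labels`` (True = category A).  Trials
    lacking the alignment event are skipped.
    """
    labels = np.asarray(labels, dtype=bool)
    times = np.asarray(times, dtype=float)
    per_unit = [
        _llr_terms(fit, design_A, design_B, counts)
        for fit, counts in zip(fits, counts_list)
    ]
    total_terms = np.sum(per_unit, axis=0)
    acc = np.empty(times.size)
    for j, t_rel in enumerate(times):
        llr = np.full(bundle.n_trials, np.nan)
        for i, (trial, sl) in enumerate(zip(bundle.trials, bundle.trial_slices())):
            t0 = getattr(trial, align)
            if t0 is None:
                continue
            stop = min(int(np.floor((t0 + t_rel) / bundle.dt)) + 1, sl.stop - sl.start)
            if stop > 0:
                llr[i] = total_terms[sl][:stop].sum()
        ok = ~np.isnan(llr)
        acc[j] = float(np.mean((llr[ok] > 0) == labels[ok]))
    return acc


def posterior_probability(llr: np.ndarray) -> np.ndarray:
    """Equal-prior posterior ``p(A | spikes)`` from the LLR, computed in a
    numerically stable way (never NaN, and ``p(A) + p(B) = 1``)."""
    llr = np.asarray(llr, dtype=float)
    out = np.empty_like(llr)
    pos = llr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-llr[pos]))
    e = np.exp(llr[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class DecodeResult:
    """Accuracy of sign-rule decoding from summed LLRs."""

    accuracy: float
    accuracy_by_size: dict = field(default_factory=dict)
    shuffle_accuracy: float = np.nan
    llr: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)
    n_trials_used: int = 0
    n_repeats: int = 1


def _match_trials(labels: np.ndarray, valid: np.ndarray, rng) -> np.ndarray:
    """Indices with equal trial counts per category (seeded down-sampling)."""
    idx_A = np.flatnonzero(valid & labels)
    idx_B = np.flatnonzero(valid & ~labels)
    n = min(idx_A.size, idx_B.size)
    if n < 2:
        raise ValueError("need at least 2 trials of each category after matching")
    keep = np.concatenate(
        [rng.choice(idx_A, n, replace=False), rng.choice(idx_B, n, replace=False)]
    )
    return np.sort(keep)


def population_accuracy(llr: np.ndarray, is_A: np.ndarray) -> float:
    """Fraction of trials whose summed-LLR sign matches the category."""
    total = llr.sum(axis=0) if llr.ndim == 2 else llr
    return float(np.mean((total > 0) == is_A))


def population_decode(
    llr_matrix: np.ndarray,
    labels: np.ndarray,
    *,
    sizes=None,
    n_repeats: int = 50,
    seed: int = 0,
    match_trials: bool = True,
) -> DecodeResult:
    """Accuracy of the sign rule for populations of increasing size.

    ``llr_matrix`` is (neurons x trials) of per-trial LLRs (NaN where a trial
    could not be evaluated); ``labels`` is True for category-A trials.  For
    each population size, neurons are sampled without replacement
    ``n_repeats`` times and accuracies averaged.  A label-shuffled control
    is evaluated at the full population size.
    """
    llr_matrix = np.atleast_2d(np.asarray(llr_matrix, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    n_units, n_trials = llr_matrix.shape
    rng = np.random.default_rng(seed)
    valid = ~np.isnan(llr_matrix).any(axis=0)
    keep = _match_trials(labels, valid, rng) if match_trials else np.flatnonzero(valid)
    L = llr_matrix[:, keep]
    y = labels[keep]

    accuracy = population_accuracy(L, y)
    acc_by_size = {}
    if sizes is not None:
        for size in sizes:
            if size > n_units:
                raise ValueError(
                    f"population size {size} exceeds the {n_units} available neurons"
                )
            reps = []
            for _ in range(n_repeats):
                members = rng.choice(n_units, size=size, replace=False)
                reps.append(population_accuracy(L[members], y))
            acc_by_size[int(size)] = float(np.mean(reps))

    perm = rng.permutation(y.size)
    shuffle_accuracy = population_accuracy(L, y[perm])
    return DecodeResult(
        accuracy=accuracy,
        accuracy_by_size=acc_by_size,
        shuffle_accuracy=shuffle_accuracy,
        llr=L,
        labels=y,
        n_trials_used=int(y.size),
        n_repeats=n_repeats,
    )


def linear_classifier_decode(
    responses: np.ndarray,
    labels: np.ndarray,
    *,
    sizes=None,
    n_repeats: int = 50,
    seed: int = 0,
    n_folds: int = 3,
    C: float = 1.0,
    shuffle_control: bool = True,
) -> DecodeResult:
    """L2-regularised logistic regression with 3-fold cross-validation.

    ``responses`` is (trials x neurons) of spike rates averaged over a
    response window; trials per class are equalised by seeded exclusion
    before fitting.  GLM-independent control for the LLR decoder.
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} trials for {n_folds}-fold CV"
        )
    keep = _match_trials(labels, np.ones(labels.size, dtype=bool), rng)
    X_all = responses[keep]
    y_all = labels[keep]
    n_units = responses.shape[1]

    def _cv_accuracy(X, y, rng_local):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True,
            random_state=int(rng_local.integers(2**31 - 1)),
        )
        accs = []
        for train, test in skf.split(X, y):
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(X[train], y[train])
            accs.append(clf.score(X[test], y[test]))
        return float(np.mean(accs))

    accuracy = _cv_accuracy(X_all, y_all, rng)
    acc_by_size = {}
    if sizes is not None:
        for size in sizes:
            if size > n_units:
                raise ValueError(
                    f"population size {size} exceeds the {n_units} available neurons"
                )
            reps = []
            for _ in range(n_repeats):
                members = rng.choice(n_units, size=size, replace=False)
                reps.append(_cv_accuracy(X_all[:, members], y_all, rng))
            acc_by_size[int(size)] = float(np.mean(reps))

    shuffle_accuracy = np.nan
    if shuffle_control:
        y_shuf = y_all[rng.permutation(y_all.size)]
        shuffle_accuracy = _cv_accuracy(X_all, y_shuf, rng)
    return DecodeResult(
        accuracy=accuracy,
        accuracy_by_size=acc_by_size,
        shuffle_accuracy=shuffle_accuracy,
        labels=y_all,
        n_trials_used=int(y_all.size),
        n_repeats=n_repeats,
    )


def ablate_kernels(fit: GLMFit, keep_variables) -> GLMFit:
    """Zero the weights of every variable not in ``keep_variables`` (the
    bias is always retained) — e.g. an "only odour" model that removes
    non-olfactory modulations from the rate prediction.

    A fit sharing no variables with the keep set passes through unchanged
    (with a warning).
    """
    keep = set(keep_variables)
    if not keep:
        raise ValueError("keep_variables must be nonempty")
    if not keep & set(fit.variables):
        warnings.warn(
            f"fit has none of {sorted(keep)}; returning the model unchanged"
        )
        return fit
    w = fit.w.copy()
    for var in fit.variables:
        if var not in keep:
            w[fit.col_slices[var]] = 0.0
    return fit.with_weights(w)


@dataclass
class DelayRegressionResult:
    params: np.ndarray  # intercept, p_OR, p_CR, interaction
    pvalues: np.ndarray
    interaction_p: float
    interaction_F_p: float
    r_squared: float
    interaction_correlation: float
    model: object = field(repr=False, default=None)


def delay_regression(
    delays: np.ndarray, p_or: np.ndarray, p_cr: np.ndarray
) -> DelayRegressionResult:
    """Multiple linear regression of behavioural response delay on decoded
    posteriors ``p(O_R|spikes)``, ``p(C_R|spikes)`` and their interaction.

    Reports ordinary-least-squares coefficients, the F-test of the
    interaction term, and the Pearson correlation between delay and the
    interaction product.
    """
    delays = np.asarray(delays, dtype=float)
    p_or = np.asarray(p_or, dtype=float)
    p_cr = np.asarray(p_cr, dtype=float)
    if delays.size < 10:
        raise ValueError("need at least 10 trials")
    if not (np.isfinite(delays).all() and np.isfinite(p_or).all() and np.isfinite(p_cr).all()):
        raise ValueError("predictors and delays must be finite")
    inter = p_or * p_cr
    X = np.column_stack([np.ones_like(delays), p_or, p_cr, inter])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    model = sm.OLS(delays, X).fit()
    f_test = model.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
    r = float(np.corrcoef(delays, inter)[0, 1])
    return DelayRegressionResult(
        params=np.asarray(model.params),
        pvalues=np.asarray(model.pvalues),
        interaction_p=float(model.pvalues[3]),
        interaction_F_p=float(f_test.pvalue),
        r_squared=float(model.rsquared),
        interaction_correlation=r,
        model=model,
    )
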