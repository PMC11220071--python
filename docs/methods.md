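# Methods

This note documents the models, numerical choices and design decisions
behind `trialglm`, and what the synthetic-data validation does and does not
establish.

## Encoding model

Spiking of each neuron is modelled in Δ = 10 ms bins as inhomogeneous
Poisson: `r_t ~ Poisson(λ_t Δ)` with `log λ_t = Σ_i (k_i ⊗ x_i)_t`. Eight
task variables enter the model, three of them as pairs whose two kernels
are selected and removed together:

| Variable | Kind   | Bases | Support |
|----------|--------|-------|---------|
| Inhal    | event  | 10    | 0–460 ms after every inhalation onset |
| Odour (O_R, O_U) | event | 10 each | 0–460 ms after each odour inhalation |
| Licks    | event  | 15    | 0–360 ms after each lick |
| Reward   | event  | 15    | 0–360 ms after reward delivery |
| preGO    | event  | 22    | 2000 ms *before* the first post-odour lick |
| modOdour (modO_R, modO_U) | event | 20 each | 0–1500 ms after the first odour inhalation, rewarded-context trials only |
| Context (C_R, C_U) | tuning | 42 each | corridor position in 4-cm bins, one kernel per context |
| Speed    | tuning | ≈max speed | 1-cm/s bins from 0 to the session maximum |
| Bias     | —      | 1     | constant column |

Kernels are parametrised by raised-cosine bumps with linearly spaced
centres, first and last centres at the support edges, and half-width equal
to the centre spacing (50% overlap). This makes the bumps a partition of
unity on the support, so a constant kernel is exactly representable and
tuning-block rows sum to 1. For tuning kernels the number of bases equals
the number of value bins, making the basis an identity on the bin grid; the
machinery still supports coarser bases. The number of Speed bases is
derived per session from the maximum running speed (≈35–60 for realistic
speeds), since a fixed count cannot fit every animal.

Conventions: time bins are half-open `[t, t+Δ)`, 0-based; position bins
half-open 4-cm intervals; events within Δ of the trial end are truncated,
not dropped; kernels never span trial boundaries (the inter-trial
"teletransport" gap carries no design rows). The preGO kernel is acausal by
construction — it uses the realised first post-odour lick time; the model
is descriptive, not causal, so conditioning on a future event is
legitimate. The modOdour pair is gated to rewarded-context trials: it
captures the odour-by-context interaction, while the Odour pair stays
active in all trials.

## Fitting and regularisation

The penalized log-likelihood `Σ_t [r_t log(λ_t Δ) − λ_t Δ] − ξ‖w‖²` is
concave; the unique MAP solution is found by Newton ascent with Cholesky
solves and backtracking (Armijo) line search. The bias column is excluded
from the ridge penalty: penalizing the baseline log-rate would bias
mean-rate recovery. Convergence is declared at gradient max-norm below
1e-6 (at most 200 iterations); near-singular curvature in rarely occupied
tuning bins can leave a small irreducible gradient component, so an
objective improvement below 1e-10·(|f|+1) also terminates (the optimum is
reached to floating precision). A tiny diagonal jitter stabilises the
Cholesky factorisation.

The ridge strength ξ is chosen by empirical Bayes on a logarithmic grid of
13 points spanning 1e-2–1e4, maximising the Laplace approximation to the
marginal likelihood (fit on all trials at once): `log E ≈ L(ŵ) +
(P_pen/2)·log(ξ/π) + (P/2)·log 2π − ½·log det H`, with `H` the negative
Hessian of the log-posterior at the mode. Because the evidence of a model
containing hundreds of irrelevant columns is maximised by a very large ξ
(which then over-shrinks the relevant kernels), ξ is *not* selected on the
full 8-variable design. Instead the forward search anchors ξ on the best
single-variable model (found by a quick CV pass at the grid median),
carries that ξ through the search, and re-selects ξ by evidence on the
final selected model for the reported fit.

## Model selection

Performance is 10-fold cross-validated held-out log-likelihood, folds
assigned by seeded random partition of *trials* (a trial is never split),
each fold normalised by its spike count (guarded to 1 for silent folds,
which are flagged). The forward search starts from a constant-rate
reference, adds the best-performing candidate variable, and accepts it only
if a one-sided Wilcoxon signed-rank test over the 10 paired fold
performances is significant at 0.05 (the test is read as the paired
signed-rank test; exact distribution at n = 10). Ties in mean fold
performance go to the candidate with fewer basis coefficients. Neurons
whose best single-variable model does not beat the constant-rate model end
with zero selected variables ("not modulated").

## Contributions

The contribution of variable `x_i` is the spike-normalised log-likelihood
increase of the selected model over the model *refit* without `x_i`
(removing a pair removes both kernels), with sums restricted to the
variable's valid-bin mask `{t_{k_i}}` — the bins where its design block is
nonzero — and normaliser `log(2)·(1 + Σ r_t)` so the value is in bits per
spike and defined even for silent masks. Relative contributions divide by
the summed contributions of the included variables; a negative total
(possible for very weak models) is raised as an error rather than silently
producing fractions outside [0, 1].

## Decoding

For a binary variable, two designs are assembled that differ only in the
decoded variable's category (every trial relabelled as A or as B; for
odour decoding the interaction kernels swap with the odour label, for
context decoding they gate on/off with the context label). The cumulative
LLR of the observed spikes under the fit's rate models,
`Σ_{t'≤t} [r_t'(log λ^A − log λ^B) − Δ(λ^A − λ^B)]`, decides the category
by sign; neurons sum; the equal-prior posterior is the logistic transform
of the LLR, computed in log space. Accuracy at a time point uses the
running LLR from trial start to that point (default evaluation 0.5 s after
the first odour inhalation). Trial counts are matched across categories by
seeded down-sampling; pseudopopulation curves sample neurons without
replacement, 50 repeats by default; label shuffles provide chance
controls. Kernel ablation ("only odour" models) zeroes the weights of
non-kept variables while retaining the bias — a rate-model edit, not a
refit — matching the idea of removing contributions from the model.
The linear-classifier route (L2 logistic regression, 3-fold stratified CV,
responses averaged over a 0.5-s post-inhalation window) is deliberately
independent of the GLM so decoding differences cannot come from model
goodness-of-fit.

## Signal variance and dimensionality

Pooled activity is an array `X` of shape (neurons, contexts, odours, time,
trials), trial averages `X̄`, with per-neuron centring over conditions and
time. The total variance is the sum of squares of the centred `X̄`. The
residual-noise estimate per neuron is the *average* over condition-time
points of the per-condition mean squared deviation from the trial mean,
divided by the neuron's mean trial count (the rebalancing that lets
sequentially recorded neurons with unequal trial counts pool), scaled back
by the number of condition-time points. As printed in the source
formulas, the sum over conditions appears both inside the per-neuron term
and as an overall factor, which double-counts by C·O·T and would make the
signal variance strongly negative for any realistic data; the
implementation uses the consistent reading (the text defines the
per-neuron term as an *average* noise variance across conditions). The
1/K normalisation is kept as printed, so the noise estimate carries a
(K−1)/K bias — visible as a ~5% positive signal fraction on pure-noise
data at K = 20 trials. Dimensionality is the smallest number of principal
components whose cumulative explained variance reaches the signal
fraction.

## Clustering

Relative-contribution profiles (8-vectors, zeros for unselected variables;
only neurons with ≥1 selected variable participate) are compared by
correlation distance `1 − r`, clustered by UPGMA, and cut at a height
threshold; clusters with fewer than 3 neurons are discarded. Threshold
selection maximises split-half generalisability: trials are split in half,
profiles refit per half, both halves clustered, and the co-membership
matrix induced by assigning one half's profiles to the other half's
cluster centroids is correlated (upper triangles) with that half's own
co-membership matrix, both directions averaged. Design choices: centroids
are arithmetic means of member profiles and "closest" uses the same
correlation distance as the clustering (keeping the pipeline
metric-consistent); a degenerate partition (everything in one cluster, or
everything discarded) has a constant co-membership triangle and scores NaN
rather than a spurious 1; the shuffle control permutes the test half's
*cluster labels* (permuting the profiles themselves would permute both
matrices consistently and is vacuous). The default threshold grid is 21
points spanning 0.5–3.0. The 2-D embedding uses non-metric MDS with
Kruskal's normalised stress-1, on Euclidean dissimilarities by default —
the embedding metric is deliberately allowed to differ from the clustering
metric.

## Synthetic sessions

The generator emulates the task geometry (83-cm aisle, 33-cm context zone,
52-cm reward zone — 42 four-cm position bins in total), a 1-s odour pulse
at context entry, sniffing as a gamma-interval renewal process (4 Hz, with
mild pre-odour acceleration in rewarded-context trials under the expert
policy), per-trial lognormal running-speed scales with smooth within-trial
fluctuations (mean 25 cm/s), lognormal reaction times (~1.1 s) and 7-Hz
lick bouts, and Bernoulli GO policies: expert P(GO|rewarded combination) =
0.95 vs 0.05 elsewhere (reproducing d′ ≈ 3.3); first-session P(GO) = 0.8
everywhere. Inter-trial interval and lick-bout structure are config
parameters (the task literature does not pin them down). The per-trial
randomness of speeds, sniff phases and reaction times decorrelates the
regressors across trials — exactly the timing variability that makes
multi-variable kernel estimation identifiable.

Ground-truth kernels for validation are smoothed Gaussian coefficient
vectors rescaled to a random peak log-rate amplitude. The default
amplitude draw is LogNormal(log 0.5, 0.7) — median peak gain ≈1.65 with
substantial mass near gain 1 — emulating a pool of kernels fitted to real
recordings, which contains many weak modulations and a few strong ones. In
the recovery experiment each neuron's primary variable draws a clearly
detectable amplitude (uniform 0.6–1.2): a neuron only contributes kernels
to a fitted pool if at least one of its modulations was detectable.
Tuning-kernel coefficients are tapered by design-column occupancy, because
a kernel fitted to data cannot carry structure in value bins the animal
never visits; leaving full-amplitude structure there would make the
simulation unrecoverable by construction rather than by any property of
the estimator.

What the generator does *not* emulate: spike-history dependence and
refractoriness, population coupling, slow drift and non-Poisson
overdispersion, sensor noise in respiration traces, or behavioural
lapses/satiation. Passing the validation suite therefore shows the
pipeline recovers the model class it assumes under realistic task timing;
it does not show the model class captures every property of cortical data.

## Kernel-recovery scoring

Recovery is scored per simulated neuron as the Pearson correlation between
the concatenated true and estimated kernel *curves* (values on each
kernel's domain grid), over the union of true and selected kernel names —
a missed or spurious kernel contributes zeros on one side and costs
correlation in proportion to its amplitude and support. Gains are scored
separately as the correlation of `exp(w)` over the individual basis
coefficients. With this design, recovery is limited less by estimation
noise than by the selection power available to sparse-event variables:
reward, pre-response and licking events exist only in the ~25% of expert
trials with a GO response, so a moderately strong kernel there can
contribute on the order of 1% of a neuron's spikes, below what the 10-fold
signed-rank criterion can reliably detect at 200 trials. Missing such a
kernel zeroes its stretch of the concatenation and caps that neuron's
correlation; medians around 0.94 ± 0.02 across experiment seeds are the
honest outcome under these conditions.

## Validation problem sizes

The simulation experiments are sized for a desk-scale single-CPU run: the
kernel-recovery experiment uses 30 neurons on one ~200-trial session
(median true-vs-estimated kernel correlation; several minutes), decoding
validation uses 10-neuron populations and 40 matched trials, the ablation
contrast uses 3-neuron populations over 20 seeds, and selection-validity
checks run 50 null and 30 single-variable forward searches on a 50-trial
session. The clustering checks run on synthetic profile sets (30–40
profiles), where ground truth is exact.
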