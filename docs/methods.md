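# Methods

## Problem and model

`bfmd` selects, from a high-dimensional predictor matrix `X` (n samples ×
T variables, e.g. gene expression) and a univariate outcome `Y`, a subset of
variables that forms a *balanced functional module*: a connected set of
mutually associated variables that jointly influence the outcome with no
internal sign conflict. Balance is the signed-graph notion: the module's
variables split into two camps A and B (promoters and suppressors of the
outcome) such that covariances are positive within camps, negative between
camps, and each variable's covariance with `Y` carries its camp's sign.

The detection statistic is the functional-covariance matrix

    W = Z'Z,    Z = H diag(c),    H = column-centered X,    c_i = Cov(x_i, Y),

whose (i, j) entry is (n−1) · Cov(x_i, Y) · Cov(x_i, x_j) · Cov(x_j, Y).
For a balanced module the three signs multiply to +, so in population the
module appears as an entrywise-positive submatrix of W, zero elsewhere. By
Perron theory the leading eigenvector of such a matrix is strictly positive
on the module and zero off it; with sampling noise the module is recovered
as a *sparse nonnegative* leading principal component of W.

Only sample moments with denominator n−1 are used; `Y` is centered but not
standardized (the construction is covariance-based, and the selection is
invariant to positive rescaling of `Y` anyway). Constant predictor columns
are an error at load time rather than being dropped silently, so indices
never desynchronize from variable names.

## Sparse nonnegative principal component

`sparse_positive_pc` maximizes q'Wq over unit-norm vectors with q ≥ 0 and
at most k nonzeros by projected (truncated) power iteration:

    q ← normalize( top-k( max(Wq, 0) ) )

The projection is the exact maximizer of the linearized objective over the
feasible set, so for PSD W the objective is non-decreasing across
iterations; the iteration stops when the relative objective change falls
below `tol = 1e-8` or after `max_iter = 1000` iterations. Ties at the k-th
largest entry keep the lower variable index (determinism). Matrix–vector
products go through the factor Z (O(nT) instead of O(T²)), and once the
active set has been stable for 3 iterations the iteration continues on the
k retained columns only, with a final full product verifying the fixed
point before the result is accepted.

The scheme is non-convex, so starting points matter. Standalone calls use a
deterministic multi-start: the top 6 dense eigenvectors of W (each in both
orientations, negatives clamped) plus an indicator of the k largest
diagonal entries, keeping the best objective. On random 8×8 PSD matrices
the test suite checks the result against a brute-force subset-enumeration
oracle at a 5% tolerance. Inside the k-sweep a single
eigenvector start suffices because each k is additionally warm-started from
the previous k's solution; warm chaining also makes the objective provably
non-decreasing in k.

## Balance evaluation and the choice of k

For a candidate module of size m, flatten the two sign patterns over its
m(m−1)/2 pairs — sign(Cov(x_i,Y)·Cov(x_j,Y)) versus sign(Cov(x_i,x_j)) —
and measure their agreement with Cohen's Kappa (computed by scikit-learn).
Kappa is 1 exactly when the empirical signs satisfy the two-camp structure.
Exactly-zero covariances are deterministically treated as + and flagged in
the report. When both sign vectors are constant and equal, Kappa is 0/0;
the metric then reports 1 for perfect observed agreement and 0 otherwise.

The sparsity level is chosen by sweeping all feasible k (default 2 …
min(T, n)) and picking the "most balanced" support. Raw Kappa cannot be the
ranking criterion across different module sizes: a support of 2–6
variables reaches Kappa = 1 by luck easily (few pairs), so maximizing Kappa
always returns a trivial fragment. The committed selection score is the
chance-corrected agreement margin

    score = WilsonLower95(observed agreement, n_pairs) − expected agreement,

i.e. a lower confidence bound on the observed pairwise sign agreement minus
Cohen's marginal-based chance term. The bound penalizes balance-by-luck on
few pairs and vanishes as n_pairs grows, so in the population limit the
ranking coincides with ranking by Kappa. In the degenerate single-camp case
the marginal chance term is uninformative (it would score a genuinely
balanced all-promoter module as pure chance), so the chance level reverts
to the sign coin-flip value 1/2. Ties are broken toward the larger support,
then the smaller k. The rule is isolated in `balance.balance_score` /
`balance.pick_optimal` so alternatives can be swapped in.

Under a true null (outcome independent of all predictors) the *selected*
supports still show inflated Kappa at small k — the sparse PC actively
seeks sign-consistent sets — decaying toward 0 as k grows; the balance
score stays low throughout. Kappa near 0 under the null holds for a
*fixed* module, not for adversarially selected ones.

## The thresholded-eigenvector baseline ("W" method)

The comparison method zeroes all negative entries of W, takes the leading
eigenvector of the result (sign fixed so its sum is positive), splits the
entries into two clusters by one-dimensional 2-means (10 seeded restarts,
best within-cluster sum of squares — equivalent to the optimal threshold
split), and returns the higher-mean cluster. It needs no sparsity
parameter but models sparsity only through the clustering, which makes it
over-select when the eigenvector is diffuse.

## Synthetic data

`sim.simulate` draws single-input-module (SIM) data: each module is a set
of observed variables driven by one latent hub, x_i = π_i β x₀ + ε_i with
x₀, ε_i ~ N(0, 1), edge signs π_i ∈ {−1, +1} (all +1 in same-sign mode),
and β = sqrt(r_m / (1 − r_m)) so the intramodular correlation is ±r_m.
Exactly one module's hub drives the outcome, Y = α x₀ + Σ_j α v_j + δ with
α = 1 and δ ~ N(0, σ_δ²). SNR is defined as α·sd(x₀)/σ_δ, hence
σ_δ = α/snr. Defaults follow the standard study design: 5 modules × 20
members, 1000 noise variables, 5 independent outcome-associated variables
(the v_j, entering Y with the hub's coefficient so each matches the hub's
SNR), 1105 variables in total.

Committed conventions where the design leaves freedom:

- noise variables are N(0, 1 + β²), variance-matched to module members so
  no method can select on marginal variance;
- independent variables are N(0, 1) additive contributors to Y,
  representing non-modular influences on the outcome;
- all errors Gaussian; columns are shuffled per seed with truth labels
  tracking the shuffle.

What the generator does *not* emulate about real omics data: heavy-tailed
and count-valued expression, correlated noise across irrelevant genes,
batch structure, and multiple functional modules influencing the outcome.
Passing the simulation study therefore demonstrates correct recovery under
the latent-hub model, not performance guarantees on arbitrary real data.

## Evaluation metrics

Per selection against ground truth: sensitivity (TP / true module size),
FDR (FP / selected), detected module size, and the normalized Hamming
distance 100·(FP + FN)/T (0 = perfect concordance, 100 = complete
discordance). Grid summaries report medians and quartiles with linear
interpolation (type 7), recorded in the output metadata; FDR is computed
per replicate and then summarized. Pooled summaries over the correlation
grid are available alongside per-cell ones.

## Problem sizes in the shipped studies

The simulation study in the test suite runs the n = 100, randomly-signed
design over r_m ∈ {0.1, …, 0.7} with 10 replicates per cell (both SNR 0.3
and 0.5); `scripts/acceptance.py` runs the same design at 50 replicates
per cell. Population-limit properties are checked through the exact
covariance entry point (`run_bfmd_from_covariance`), and large-sample
convergence at n = 5000 on a reduced variable set.

## Known limitations

- The k-selection rule ("optimally balanced") is a committed reading; the
  size-aware score above is one defensible formalization and is swappable.
- Strong multicollinearity between a module and outcome-associated
  non-module variables degrades the support of the sparse component.
- Runtime of the full k-sweep is O(|k-range| · nT) per dataset and grows
  with n through the feasible range's upper end min(T, n).
- Single module extraction only; no deflation for multiple functional
  modules.
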