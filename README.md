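# bfmd — balanced Functional Module Detection

`bfmd` selects, from a high-dimensional predictor matrix (e.g. gene
expression, samples × genes) and a univariate outcome (e.g. a clinical
measurement), a subset of variables forming a **balanced functional
module**: a set of mutually associated variables that jointly influence the
outcome with no internal sign conflicts. It is aimed at analysts who want
*variable selection for mechanism*, not prediction — the goal is the
complete, logically consistent set of outcome-relevant variables, which can
then be handed to graphical-model tooling for structure analysis.

## The idea

Balance is a signed-graph property: a module's variables split into two
camps A (promoters) and B (suppressors) such that covariances are positive
within camps, negative between camps, and each variable's covariance with
the outcome Y carries its camp's sign. For the statistic

    W = Z'Z,   Z = H diag(c),   H = column-centered X,   c_i = Cov(x_i, Y)

each entry W_ij ∝ Cov(x_i, Y) · Cov(x_i, x_j) · Cov(x_j, Y) is *positive*
on every pair inside a balanced module (the three signs multiply out), so
the module appears as an entrywise-positive submatrix of W — and, by the
Perron theorem, as a sparse nonnegative leading eigenvector of W. The
detector:

1. builds W in factored form from the data;
2. extracts a cardinality-k nonnegative sparse principal component of W by
   projected power iteration, for every feasible k (default 2 … min(T, n));
3. scores each candidate support with a balance metric — Cohen's Kappa
   between the pairwise sign patterns sign(c_i·c_j) and sign(Cov(x_i,x_j))
   — and keeps the most balanced support (a size-aware, chance-corrected
   agreement score arbitrates between candidates of different size);
4. reports the selected module with its loadings, Kappa, and the
   promoter/suppressor partition given by sign(Cov(x_i, Y)).

A comparison method ("W" baseline: zero the negative entries of W, take the
leading eigenvector, split by 1-D 2-means) and a single-input-module (SIM)
simulator with ground-truth labels are included, plus evaluation utilities
(sensitivity, FDR, module size, normalized Hamming distance). See
`docs/methods.md` for the model, committed conventions and limitations.

## Worked example

Simulate the standard study design (1105 variables: five 20-gene modules —
one functional — 1000 noise genes, 5 independent outcome-associated
variables; n = 100, intramodular correlation 0.6, SNR 0.5, random signs)
and detect the module:

```python
from bfmd import sim, detect, evaluate

ds = sim.simulate(sim.SimConfig(n=100, r_m=0.6, snr=0.5,
                                random_signs=True, seed=7))
sel = detect.run_bfmd(ds.X, ds.Y)
res = evaluate.score_selection(sel, ds)
print(sel.size, sel.k_opt, sel.balance.kappa, res.sensitivity, res.fdr)
```

prints (for this seed):

```
module size      : 17
chosen k         : 17
balance Kappa    : 1.000
promoters (A)    : 10
suppressors (B)  : 7
sensitivity      : 0.75
FDR              : 0.118
norm. Hamming    : 0.63
```

The detector recovered 15 of the 20 true module genes plus 2 impostors,
with a perfectly sign-consistent (Kappa = 1) partition into 10 promoters
and 7 suppressors. `sel.to_frame()` lists each selected variable with its
loading and camp; `sel.per_k` holds the full k-sweep diagnostics.

The same analysis runs from the shell on your own delimited-text data:

```
bfmd run --x expression.tsv --y outcome.tsv --out-prefix results/mymodule
bfmd run --x expression.tsv --y outcome.tsv --method W --out-prefix results/wbase
bfmd simulate --n 100 --r-m 0.5 --snr 0.3 --random-signs --seed 1 --out-prefix sim/toy
bfmd benchmark --snr 0.3 --reps 10 --seed 1 --out-prefix bench/run
```

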