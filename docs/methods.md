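# Methods

## The model

`neurocpm` implements connectome-based predictive modelling (CPM) of a
continuous behavioral score — here full-scale or verbal IQ — from
functional connectomes. A connectome is a symmetric R × R matrix of
correlation-like connection strengths between brain regions (R = 116
for the AAL atlas used in reporting); its E = R(R−1)/2 strict
upper-triangle entries are the *edges*, treated throughout as
independent candidate features.

For one training set of n subjects the pipeline:

1. **Screens every edge** by associating its weight vector with the
   score. The default screen is a robust simple regression
   (`score = a + b · weight`) fitted by iteratively reweighted least
   squares with Huber weighting; a plain Pearson screen is available.
   Each edge gets an association coefficient r (the weighted Pearson
   correlation under the final IRLS weights, sign-consistent with the
   slope) and a two-tailed p-value for the slope.
2. **Selects edges** with p below a raw threshold α (default 0.01 — no
   multiple-testing correction; the uncorrected threshold is part of
   the protocol) and splits them by the sign of r into a *positive
   network* and a *negative network*.
3. **Summarizes each subject** by two numbers: the sum of their edge
   weights over each network.
4. **Fits two univariate linear models** mapping the positive
   (respectively negative) summary value to the score.

Under leave-one-out cross-validation every subject is held out once;
steps 1–4 run on the remaining N−1 subjects and the held-out subject's
score is predicted from their own weights summed over the *training*
networks. Predicted-vs-observed agreement is reported as Pearson r, r²
and its two-tailed t-based p, separately for the positive and negative
models (the two are never merged or silently chosen between).

Because the selected networks can differ between folds, each edge f_k
is finally scored by its **normalized rank**

    score(f_k) = ( Σ_i δ_i(f_k) · |r_i(f_k)| ) / N ,

the selection-indicator-weighted mean absolute association across the N
folds (δ_i = 1 if the edge was selected in fold i). Each selected edge
contributes exactly one term per fold — its own |r| — so the score is
bounded by 1 and equals 0 iff the edge was never selected. The top five
edges per side, mapped to AAL ROI-pair names, are the reported
connections. Populations (ASD, NT) and targets (FIQ, VIQ) are always
modelled independently; cohorts are single-group by construction.

## Robust screen: estimator and inference

The robust loss is unspecified in the protocol's ancestry beyond
"robust regression", so the package uses the field's standard default:
Huber weights with tuning constant c = 1.345 (95% Gaussian efficiency),
residual scale 1.4826 × MAD about the median recomputed each iteration,
convergence when the largest coefficient change falls below 1e-8, cap
50 iterations (non-convergent edges keep their last iterate and are
counted in a warning). Tukey bisquare (c = 4.685) is available through
`CpmConfig(loss="bisquare")`.

Slope inference uses Huber's (1973) robust covariance — the same
convention as MATLAB `robustfit` and statsmodels `RLM` — with a
two-tailed t-test on n−2 degrees of freedom. A naive weighted-least-
squares standard error is *anti-conservative* here (the weights were
chosen to shrink exactly the large residuals): in null simulations it
selected 2.2% of edges at α = 1%, while the Huber covariance restores
0.96%, matching the Pearson screen's 0.89%. Degenerate cases: a
constant edge reports r = 0, p = 1 (never selected, never crashes a
6,670-edge sweep); an edge with zero residual MAD (exact fit) reports
its plain OLS/Pearson statistics.

With a wide tuning constant (no residual clipped) the robust screen
reduces *exactly* to the Pearson screen; at the default constant ~18%
of Gaussian residuals are always down-weighted, so on clean data the
two agree only to ~1e-2. Tests exercise both regimes.

## Summary-value convention

"Summing the positive values in the positive matrix" is read as summing
the *raw signed weights* of positively-correlated edges (an edge that
correlates positively with the score may still carry a negative weight
in some subject); this follows the summary-score convention of the
protocol family the pipeline belongs to. The literal clipped reading
(zero out weights whose sign disagrees with the network) is available
as `CpmConfig(summary="clipped")`. An empty network sums to exactly 0.

## Degenerate folds

A fold whose selected network is empty (or whose training summaries are
constant) cannot fit a line; its model predicts the training score mean.
Such folds count toward N rather than being dropped (dropping would
silently change N), and their count is reported. One consequence is
handled explicitly: when *every* fold is degenerate on a side, the
prediction vector contains only the leave-one-out training means, which
differ microscopically between folds and are perfectly anti-correlated
with the observed scores (slope −1/(N−1)) despite containing no model
at all. `evaluate_cvrun` reports that case as r = 0, p = 1 instead of a
spurious |r| = 1; `evaluate_predictions` applies the same convention
when predictions are exactly constant.

## Synthetic cohorts

The generator produces exactly the structure CPM assumes and nothing
more. For subject i and edge k, with a single seeded RNG stream:
y_i ~ Normal(μ, σ_y) (defaults 106.5 ± 15.2 score points, an ASD-like
IQ distribution); z_i the standardized score; background
w_ik ~ Normal(0, σ_e) with σ_e = 0.2; planted edges add ±β·z_i; all
weights pass through tanh (keeping them in (−1,1)); matrices are
assembled symmetric with unit diagonal. Optionally, a fraction of
*recorded* scores is corrupted by ±(shift · σ_y) with alternating sign —
score outliers, the failure mode the robust screen defends against; the
uncorrupted scores and planted indices are kept as ground truth.

Before the tanh squash the population edge-score correlation of a
planted edge is β/√(β²+σ_e²); `effect_for_correlation` inverts this,
and the default β targets a correlation of 0.4. The reference study
conditions used by the tests and the acceptance script are N = 150,
R = 20, five planted edges per sign at that coupling; null cohorts set
the coupling to zero.

What the generator does **not** emulate: BOLD time series, site or
motion effects, inter-edge covariance (edges are independent given the
score), and positive semidefiniteness of the matrices (entries are
bounded and symmetric but the matrix need not be PSD — no step of CPM
uses more than individual edges, so nothing relies on it). Passing
tests therefore show the pipeline recovers the linear edge-score
structure it assumes, not that real resting-state data satisfies those
assumptions.

## Null behavior of leave-one-out evaluation

On pure-noise cohorts the cross-validated predicted-vs-observed r is
*not* centered at zero: it is biased negative (each subject's exclusion
nudges the training coefficients away from them), and its spread widens
as the edge pool shrinks, because under the null the selected network
holds only 0–3 edges, each selected precisely because its sample |r|
exceeded the α-threshold (~0.21 at N = 150). At the desk-scale test
sizes (R = 20–30) the null r distribution has mean ≈ −0.1 to −0.2 and
SD ≈ 0.25; at the full atlas size (R = 116) it tightens to mean ≈ −0.02,
SD ≈ 0.16. The implementation was cross-checked against an independent
naive implementation (explicit loops, `scipy.stats.pearsonr`,
`numpy.polyfit`) with agreement to 13 decimals on a full run — the bias
is a property of the method, not of this code. Practical reading: a
single cross-validated r near ±0.2 at a few hundred edges is within
null range; permutation testing, not the t-based p alone, should settle
significance claims on real data.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script use the reference
conditions above (50 null cohorts at N = 100, R = 30 for screen
calibration; 10 seeds of N = 150, R = 20 for recovery, prediction and
robustness), chosen so the full suite completes in a few minutes while
keeping per-seed power high. The analysis scripts run the same pipeline
at full scale (R = 116, N = 202/226). Other fixed choices: edge order
is the row-major strict upper triangle (0-based); file-level asymmetry
up to 1e-6 is repaired by averaging, beyond it is an error naming the
worst cell; connectome round-trips regenerate the diagonal as 1;
ranking ties break by ascending edge index so reports are
byte-identical across reruns; manifest subject order is preserved after
missing-score exclusion, and a subject missing VIQ still participates
in FIQ analyses.

## Known limitations

- Only leave-one-out cross-validation is provided (the protocol's
  scheme); k-fold variants would change the method.
- Only univariate summary models; no regularized or nonlinear
  predictors.
- The t-based p attached to the cross-validated r treats the N
  predictions as independent draws, which cross-validation violates;
  see the null-behavior section.
- The AAL label table ships abbreviations only (no coordinates); graph
  drawing is left to downstream connectogram tools via the edge-list
  export.
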