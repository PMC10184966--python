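# Methods

## Model

`symptomnet` estimates a Gaussian graphical model (GGM) over 14 ordinal
questionnaire items: the seven GAD-7 anxiety items and the seven PSQI sleep
components, each scored 0-3. Nodes are symptoms; an edge is the partial
correlation between two symptoms conditional on all other symptoms. The
precision matrix Θ is estimated by the graphical lasso,

    max_Θ  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|,

with the diagonal unpenalized, and edge weights are the regularized partial
correlations w_ij = −Θ_ij / √(Θ_ii Θ_jj). The penalty λ is selected on a
log-spaced path by the Extended Bayesian Information Criterion,

    EBIC = −2L + E log n + 4γ E log p,

where E counts nonzero upper-triangular edges, L is the profile Gaussian
log-likelihood (n/2)(log det Θ − tr(SΘ)) (additive constants dropped — EBIC
differences are unaffected), and γ is the extra-penalty hyperparameter.

Assumptions: item responses discretize latent continuous variables that are
jointly Gaussian; respondents are independent; within a fitted group the
network is homogeneous.

## Correlation input

Ordinal 4-category items are summarized by **polychoric correlations** by
default: thresholds from the marginal category proportions, then pairwise ρ
by one-dimensional maximum likelihood over bivariate-normal rectangle
probabilities (computed exactly via Owen's T function). Pearson and Spearman
are selectable; covariate-adjusted re-estimation operates on continuous
residuals and therefore falls back to Pearson, and any comparison of an
adjusted network against an original is done against a same-method fit so
that method attenuation is not mistaken for a covariate effect. Non-PSD
estimates (possible with pairwise deletion or polychorics) are repaired by
eigenvalue clipping and re-standardization, and flagged.

## Solver

The graphical lasso is solved by block coordinate descent over columns with
an inner lasso coordinate descent (numba-compiled), warm-started along the
λ path. Convergence is declared when the maximum change in the working
covariance matrix falls below 1e-7 (inner tolerance one tenth of that);
non-convergence raises an error carrying the sweep trace. λ = 0 is computed
by direct matrix inversion. Edge weights below 1e-7 in absolute value are
exact zeros. The solver is validated in the test suite against scikit-learn's
independent implementation and against brute-force numerical maximization of
the penalized objective on 3-node problems.

Defaults: 100 log-spaced λ from max|S_ij| down to 1% of it; γ = 0.5. Both
follow common EBIC-glasso practice; γ trades false edges against sensitivity
(edge count is non-increasing in γ, a tested invariant). An optional
`threshold=True` applies the consistency bound √(log(p(p−1)/2)/n) to the
selected network: at n ≈ 11,000 the EBIC-selected penalty is small and
admits ~10-20% spurious edges among absent pairs, all with |w| < 0.03; the
thresholded variant suppresses essentially all of them while leaving edges
|w| ≥ 0.1 untouched (all of which are recovered with the correct sign).

## Centrality and predictability

* Expected influence: EI(v) = Σ_u w_vu (signed, one-step; a two-step option
  adds neighbours' EI).
* Bridge expected influence: the same sum restricted to edges crossing into
  the other community. The partition identity bEI + within-community EI = EI
  holds to machine precision and is tested.
* Strength: Σ_u |w_vu|; betweenness and closeness use shortest paths on
  distances 1/|w| (absolute value because weights can be negative);
  closeness is 1/Σd over reachable nodes (harmonic option for disconnected
  graphs); both are tested against exhaustive path enumeration on small
  graphs.
* Predictability: in-sample R² of regressing each item on its nonzero-edge
  neighbours, items treated as numeric. This is a nodewise Gaussian
  approximation of the mixed-graphical-model notion of predictability; on
  continuous data it matches the analytic value 1 − 1/(Θ_ii Σ_ii), while on
  0-3 ordinal data it is attenuated, so it underestimates the latent-scale
  quantity.

## Stability diagnostics

Nonparametric bootstrap (rows resampled with replacement, the full
EBIC-glasso pipeline re-run per replicate) gives 95% quantile CIs per edge
and difference tests: a pair differs when the bootstrap CI of its difference
excludes zero (α = 0.05 two-sided, no multiplicity correction — the
convention of the bootstrapped-difference methodology). The case-dropping
bootstrap subsamples without replacement at drop proportions
{0.10, 0.25, 0.50, 0.75} and correlates (Pearson) subsample centrality with
the full-sample centrality; the CS coefficient is the largest drop
proportion at which ≥ 95% of subsamples correlate ≥ 0.7. CS is reported on
the grid (a CS of 0.75 is the grid ceiling, not an interpolated value); a
degenerate subsample (empty network) contributes correlation 0.

## Group comparison

The permutation Network Comparison Test re-estimates both group networks
(each with its own EBIC-selected λ) under label shuffles of the pooled rows
that preserve group sizes. Statistics: M = max absolute edge-weight
difference (structure invariance) and S = absolute difference in global
strength (sum of |w|). P-values use the add-one convention
(1 + #{perm ≥ obs})/(1 + n_perm) and are never exactly zero. Per-edge
differences are tested against their own permutation distributions and
Holm-Bonferroni corrected; the family is all p(p−1)/2 pairs by default, or
the union of edges observed in either network (`edge_family="observed"`) —
with 1,000 permutations and the add-one convention the all-pairs family on
14 nodes cannot reach Holm-adjusted 0.05 (minimum adjusted p = 91/1001), so
per-edge discovery claims should use the observed family or more
permutations. The pooled rows are canonically sorted and the larger arm is
always assigned first, which makes every reported p-value exactly invariant
to swapping the two groups.

## Synthetic data generator

The generator emulates the study conditions, not the hospital data: 14
ordinal items in two communities from a latent-Gaussian copula with a known
sparse, predominantly positive partial-correlation structure. The default
truth plants 17 within-community edges (strongest: sleep duration-sleep
efficiency at 0.45; an anxiety hub at "nervousness") and four bridge edges
(strongest: nervousness-daytime dysfunction at 0.16, one small negative
edge), mirroring the strongest reported associations. The implied precision
matrix I − W is checked for positive definiteness; if planted weights break
it, off-diagonals are shrunk uniformly by 0.95 per iteration (at most 50,
factor recorded). Per-item thresholds are calibrated by least squares so
the discretized margins track the published item means/SDs (right-skewed
anxiety items, left-skewed sleep-timing components); calibration is
approximate because a three-threshold normal model cannot reach every
mean/SD pair. Covariates (sex, age group, education, employment) are drawn
independently of the items with the published demographic margins — so
covariate adjustment should be (and is, in tests) a near no-op, and planted
group differences are introduced explicitly via a modified truth instead.
Sampling is deterministic under a single seed with per-stage substreams.

What the generator does **not** emulate: the real items' dependence on
covariates, temporal trends, item-level missingness, or the true (unknown)
density of the hospital network. Passing recovery tests therefore shows the
estimator recovers structures of this sparsity and strength at these sample
sizes — not that the published network is correct. In particular the
synthetic average predictability (~0.1-0.2 on the ordinal scale) is well
below the 0.53 reported for the clinical sample, whose network is much
denser.

## Scoring conventions

GAD-7 total ≥ 5 flags at least mild anxiety; PSQI global > 7 flags poor
sleep quality and ≥ 10 flags clinical sleep problems (the published results
operationalize "more than 10" as ≥ 10, and that convention is followed).
Prevalence intervals are Wald with z = 1.959964 (Wilson available);
percentages are rounded half-up to 2 dp. Sources that mix rounding and
truncation (e.g. a printed 68.94% where the count ratio gives 68.948%) are
documented in tests rather than replicated. Group cross-tabulations use the
column-wise convention: the denominator is the total number of flagged
cases. Sample skewness is the adjusted Fisher-Pearson form and kurtosis is
excess kurtosis.

## Problem sizes in the test suite

Sizes were chosen to keep each check statistically meaningful at desk
scale: recovery and the thresholded false-edge invariant run 20 seeds at
n = 11,000 (the study's scale); bootstrap CI coverage uses 200 replicates
of a 3-node chain at n = 500 with B = 100; CS semantics use n = 2,000 with
B = 50 per drop level; NCT size uses 100 null replicates at 200
permutations (acceptance band = central 95% binomial region around 0.05);
NCT power uses 20 replicates at n = 2,000/group with 1,000 permutations and
the observed-edge Holm family. Permutation-heavy simulations use Pearson
correlations and a shortened λ path (20-40 values) — both exposed,
documented options.

## Known limitations

* Predictability on ordinal items is attenuated relative to the latent
  scale; no polyserial/threshold-model refit is attempted.
* Polychoric estimation is two-step pairwise ML; no standard errors are
  propagated into the glasso stage.
* Bootstrap quantile CIs for regularized edges inherit shrinkage bias;
  coverage is verified (~92-95%) only for the small designs tested.
* The NCT assumes exchangeability under the null within the pooled sample;
  covariate-driven heterogeneity would violate it.
* Raw 19-item PSQI scoring is out of scope; the pipeline operates on the
  seven 0-3 component scores.
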