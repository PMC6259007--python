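# Methods

## Model

`symnet` estimates Gaussian graphical models (GGMs) for ordinal symptom
data. The working assumption is that the p items are a discretization of a
latent multivariate normal; zeros of the precision matrix K encode
conditional independence, and the edge weights reported everywhere are
partial correlations ρ_ij = −k_ij/√(k_ii k_jj).

Estimation is ℓ1-penalized maximum likelihood ("graphical lasso"):
maximize log det K − tr(SK) − λ·Σ_{i≠j}|k_ij| over K ≻ 0, where S is the
item correlation matrix. Only off-diagonal entries are penalized, so the
working covariance keeps diag(W) = diag(S). The solver is block coordinate
descent (one lasso subproblem per column), numba-compiled, warm-started
along the penalty path. Model selection minimizes the extended BIC

    EBIC(λ) = −2·loglik + E·log n + 4·E·γ·log p,

with E the number of nonzero upper-triangle precision entries. The
log-likelihood is the Gaussian profile likelihood evaluated at (S, K̂(λ)).

### Estimation defaults and why

| parameter | default | rationale |
|---|---|---|
| correlation | Pearson on the 0–4 scores | deterministic and fast; the polychoric option (two-step ML: thresholds from marginal quantiles, then 1-D likelihood search over ρ) is available for ordinal fidelity but is ~100× slower per matrix |
| γ (EBIC) | 0.5 | the conservative standard in the psychometric-network literature; γ = 0 reduces to BIC |
| λ path | 100 log-spaced values from λ_max = max off-diag |S| down to λ_max/100 | λ_max provably yields the empty network, giving a complete sparse-to-dense path |
| edge clamp | \|ρ\| < 1e−10 → 0 | makes "edge present" well defined after floating-point soft-thresholding |
| PSD repair | clip eigenvalues at 1e−8, rescale to unit diagonal | pairwise polychoric matrices need not be PSD; repair is idempotent and flagged in the output |

λ = 0 is solved by the same coordinate-descent routine (the lasso
subproblems become exact linear solves in the limit), and agrees with
direct inversion of S to ~1e−12; `unregularized_partials` provides the
pseudo-inverse route used for sensitivity analyses.

Path solves use a relaxed convergence tolerance (1e−5 relative change of
the working covariance, 1e−8 inner) because EBIC selection is insensitive
at that scale; standalone `glasso()` calls default to 1e−8/1e−10, which is
what the oracle-equivalence tests exercise. Note that glasso solution
paths are only *near*-monotone in edge count: as λ decreases an edge can
transiently leave the model. The test suite therefore asserts
monotonicity with a small slack (dips of ≤ 3 edges) rather than exactly.

## Centrality

Strength Σ_j|w_ij|, expected influence Σ_j w_ij (one-step; two-step EI is
out of scope), and closeness/betweenness on the distance graph d_ij =
1/|w_ij| (zero-weight pairs are non-edges). Closeness is the standard
inverse-total-distance form (p−1)/Σ_j d(i,j), set to 0 when any node is
unreachable; betweenness is Freeman betweenness with fractional credit
among tied shortest paths (Brandes' algorithm; verified against exhaustive
path enumeration for small p). z-standardization uses the sample SD (n−1);
a constant index maps to all-zero z-scores.

## Bootstrap robustness

Edge accuracy uses resampling with replacement (B = 2000 by default) and
quantile CIs; case-dropping stability uses subsampling without replacement
at proportions 0.05–0.75 in steps of 0.05, recording the Pearson
correlation between subsample and full-sample centralities. The CS
coefficient implements "correlation ≥ 0.7 with 95% probability" as: the
5th percentile of the B correlations at proportion q is ≥ 0.7.
Proportions are scanned in increasing order and the largest
prefix-satisfying q is reported, so a single unstable intermediate
proportion caps the coefficient. Replicates whose centrality vector is
constant (e.g. an empty network) have no defined correlation; they are
recorded as missing and counted as failures in the CS condition — this is
what drives CS to 0 on independent-items data. Estimator failures inside
a replicate are retried (edge bootstrap) or recorded missing
(case-dropping), capped at 5% of B, never silently dropped.

The bootstrapped difference test compares two edges or two node
centralities from the same bootstrap run via the quantile CI of the
difference of draws; deliberately *no* multiple-testing correction is
applied, matching the convention of the tools this mirrors.

## Permutation comparison (two groups)

Cases are pooled and reassigned uniformly at random to groups of the
original sizes; both networks are re-estimated per permutation with the
full configured pipeline (including EBIC selection when
`estimator="regularized"`; the unregularized pseudo-inverse estimator is
provided for speed and sensitivity checks). Statistics: M = max pair
|w^A − w^B|, S = |Σ|w^A| − Σ|w^B||, global expected influence
|Σw^A − Σw^B| on signed sums, per-edge |differences| and per-node
expected-influence differences. p-values use the add-one convention
(1 + #{perm ≥ obs})/(1 + iterations) — with the default 1000 iterations
the smallest attainable p is ≈ 0.001 — and are uncorrected by default
(Holm by flag). The λ path range is recomputed per permuted dataset, not
pooled. `balance_groups` subsamples the larger group to the smaller n
without replacement, addressing the test's known size-imbalance
instability.

## Predictability

Nodewise in-sample R² from the linear regression of each item on all
others, with intercept. Under the latent GGM the population value is
R²_i = 1 − 1/(Σ_ii K_ii), which the estimate approaches at large n (the
acceptance script verifies agreement within 0.02 at n = 50,000). Items
share a common 0–4 severity scale, so the Gaussian nodewise model is used
rather than per-family mixed models; this is a deliberate simplification —
in-sample rather than cross-validated R², matching the "shared variance"
interpretation. A ridge fallback handles collinear designs.

## Synthetic data generator

The generator is a Gaussian copula. A target sparse partial-correlation
matrix P is turned into a precision matrix K = I − P (uniform diagonal
inflation with a recorded shrink factor if K is not PD); latent draws use
the correlation form of K⁻¹; each latent value is cut at four per-item
thresholds into 0–4. Thresholds come from a discretized normal: the
category distribution is N(μ, sd²) sliced at half-integer boundaries with
μ root-solved so the implied categorical mean equals the published item
mean *exactly*, then cumulative probabilities are mapped to standard-normal
quantiles. Master seeds spawn per-group child streams (numpy
SeedSequence), so adding a group never shifts existing draws.

### The 17-node presets

`preset_ptsd17` emulates the four published veteran subgroups (clinical,
subthreshold, low/high combat): thresholds per subgroup reproduce that
subgroup's published item means, and all share a base partial-correlation
structure with

* marquee edges E3:E4 (0.30, the strongest), C1:C2 (0.28), D5:D6 (0.25),
  D6:D7 (0.23), B2:B3 (0.20), plus B5:E2, B5:E3, B1:E1;
* a dense positive backbone: 0.0725 on two-thirds of the remaining non-D1
  pairs (deterministic (i+j) mod 3 pattern) with +0.032 within each DSM-IV
  cluster;
* a weakly connected amnesia node D1 (two edges of 0.16);
* in the high-combat preset, the intrusive-thoughts/irritability edge
  B1:E1 raised to 0.28.

The published edge matrices are not available, so these magnitudes are the
package's own design, fixed once by three considerations: the matrix must
be PD without inflation; nodewise predictability must land in the reported
40–60% band with D1 least and hypervigilance/startle most predictable
(symptom data carry a strong general factor, which is why a *dense weak*
backbone, not a few strong edges, is required — mean R² is governed by how
close the largest eigenvalue of P is to 1); and every nonzero edge must be
large enough (≥ 0.07) to be detectable at the sample sizes used in tests.
The presets are structurally, not numerically, faithful to the published
networks. Group connectivity differences are produced by
`two_group_scenario`'s `connectivity_scale`, which multiplies the second
group's partials.

`preset_strong8` is a small heterogeneous weighted-ring-with-chords
scenario whose centralities are nearly noiseless at n = 10,000; it is the
stability demonstration ("near-noiseless" CS ceiling).

### What the generator does not emulate

Ordinal scores attenuate latent correlations (by ~5–10% at these
magnitudes), and the generator makes no attempt at item-level skew beyond
matching means/SDs, response styles, missingness, criterion-based sample
selection, or temporal dynamics. Tests passing on this generator show the
estimators behave correctly under a faithful latent-GGM world, not that
any particular clinical dataset satisfies those assumptions.

## Summary-statistic tests

Welch t from printed (mean, SD, n) with Satterthwaite df, sign convention
(mean₂ − mean₁); Yates-corrected χ² for 2×2 tables (the published table
values match the corrected, not raw, statistic); two-sided variance-ratio
F with the larger variance in the numerator and p = 2·min(tails) (set to
1 at F = 1). Reproduction tolerance against printed tables is ±2%
relative, the attainable bound given inputs rounded to two decimals.

## Problem sizes in tests and the acceptance script

Structure recovery uses n = 5000 ordinal cases (edge-presence F1 ≈ 0.81–
0.84 across seeds); permutation calibration uses 200 null simulations ×
200 permutations at n = 300/group and 100 power simulations at
n = 500/group with the unregularized estimator inside the permutation
loop; stability uses B = 500 (strong scenario, n = 10,000) and B = 200
(independent items, n = 2000). These sizes give stable pass/fail behavior
for the documented thresholds while keeping a full run to a few minutes
on one CPU; analyses of record should prefer B = 2000 and ≥ 1000
permutations.

## Known limitations

* Pearson input correlations on 0–4 scores are the default; polychoric
  input is supported for estimation but not inside the permutation test.
* The permutation test assumes exchangeability of cases under the null and
  independent groups; no paired or covariate-adjusted variants.
* Networks are undirected and cross-sectional; nothing here supports
  causal or temporal claims.
* Betweenness and closeness on weighted psychological networks are known
  to be unstable; they are provided for completeness, with the CS
  machinery to quantify exactly how unstable they are.
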