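# Methods

## Generative model

All simulations draw from the standard two-level Gaussian random-intercept
model for a two-arm CRT: y_ij = β1·arm_j + u_j + e_ij with
u_j ~ N(0, ρ·σ²) and e_ij ~ N(0, (1−ρ)·σ²), total variance σ² = 1 by
default, so β1 equals the standardized mean difference. Clusters are
balanced (common size n1) and split equally across arms; an odd total
number of clusters puts the extra cluster in the intervention arm. Each
Monte-Carlo replicate r draws from an independent substream keyed by
(master seed, hypothesis, r, attempt), so results are identical regardless
of batch size or evaluation order, and re-simulated failures do not
perturb other replicates.

The synthetic example dataset (22 clusters × 12, β1 = 0.59, ρ = 0.042)
adds an age-like and a years-in-practice-like covariate and a 3-level
facility factor with small coefficients, purely to exercise the
covariate-adjusted fit; its generator seed is fixed so the realized
estimates resemble the generating values. The generator does **not**
emulate unequal cluster sizes, attrition, non-Gaussian outcomes or
covariate imbalance between arms, so passing tests demonstrate
correctness of the method under its own assumptions, not robustness of
real-data analyses to violations of them.

## Estimation

`fit_random_intercept` uses restricted maximum likelihood. For balanced
data with no covariates — the entire power/SSD path — the REML solution
has a closed form: σ̂²_e is the pooled within-cluster mean square, the
cluster-mean residual mean square (n2 − 2 degrees of freedom) estimates
σ²_u + σ²_e/n1, and GLS for a cluster-level treatment equals OLS on
cluster means. This is exact, roughly three orders of magnitude faster
than a numerical mixed-model fit, and is verified against statsmodels'
MixedLM in the test suite (the dual route is kept: the closed form is the
implementation, MixedLM the oracle). Covariate-adjusted or unbalanced data
go through MixedLM (Powell search first — it is much more robust near the
zero-variance boundary than the gradient optimizers — with an ML retry on
non-convergence). Negative cluster-variance solutions are clamped to zero
and the fit collapses to OLS; such singular fits are *retained*, because
discarding them would bias power estimates at small ICC. Satterthwaite
degrees of freedom and p-values are not computed; the Bayes-factor path
does not use them.

For unbalanced data the mean cluster size enters the effective-sample-size
formula N_eff = n1·n2/(1 + (n1−1)ρ), which assumes a common n1.

## Bayes factors

The one-parameter approximated adjusted fractional Bayes factor is used
throughout: posterior N(β̂1, SE²); prior N(0, SE²/b) centered at the
constraint boundary; b = J/N_eff with J ∈ {1, 2, 3}, default J = 1
(minimal training sample; larger J gives a more robust prior and is worth
a sensitivity analysis when evaluating H0). Fit and complexity are
posterior/prior masses for inequality hypotheses and densities at the
boundary for the equality hypothesis (a Savage–Dickey ratio — not an
interval approximation — which yields the exact closed form
BF_0u = √(N_eff/J) at β̂1 = 0). Consequences asserted by tests: complexity
of a one-sided hypothesis is exactly 0.5, so BF_1u ≤ 2; BF_0c = BF_0u
because the complement of a point null is the unconstrained; each PMP
column sums to 1. BF_1c is reported as +inf when the fit is exactly 1 in
floating point; finite published values of such entries arise only from
rounding the fit. All rounding is presentation-layer; internal computation
is unrounded. Multiparameter hypotheses (orderings of several effects) are
out of scope.

When Bayes factors are computed inside simulations, N_eff uses each
replicate's *estimated* ICC, mirroring how a real dataset would be
analyzed; `icc_for_neff="design"` switches to the known generating ICC for
sensitivity checks.

## Power and sample size determination

`estimate_power` simulates `reps` trials per hypothesis (default 1000),
fits each, computes BF_01/BF_10 (set 1) or BF_12 = BF_1c (set 2), and
returns exceedance proportions with binomial Monte-Carlo standard errors
√(p(1−p)/reps). Under H0 the generating effect is exactly 0; set 2
simulates under H1 only, since its hypotheses are complementary. Fit
failures are re-simulated from a fresh substream, capped at 5% of reps.

`find_sample_size` searches the free dimension over integers from the
minima (6 per cluster, 8 total clusters — below these a trial is rarely
worth fielding and variance components are barely estimable), doubling an
upper bracket until the criterion holds, then bisecting; a hard cap
(default 1000) turns an unreachable criterion into an error carrying the
search trace. All candidates share random-number streams (common random
numbers), which removes spurious non-monotonicity between candidates. A
candidate passes when its exceedance *point estimates* reach η; no
Monte-Carlo-error inflation is applied, so a boundary candidate with true
power very close to η can flip between adjacent integers across seeds —
the reported MC standard errors let users judge such cases, and the grid
runner's `reps` can be raised where it matters.

Problem sizes used by `scripts/acceptance.py` — 2000 replicates per
hypothesis for post-hoc power, 1000 per binary-search candidate for the
SSD runs — keep the full recomputation near one CPU-minute while holding
MC standard errors near 0.01.

## Known limitations

* The balanced-design closed form is exact only for the treatment-only
  model; covariate-adjusted power simulation is not implemented (the SSD
  model has treatment only).
* Unequal cluster sizes are accepted in analysis but not simulated;
  published guidance suggests roughly 11% more clusters when cluster sizes
  vary substantially.
* Sequential Bayesian designs, attrition-adjusted Bayesian SSD,
  cost-optimal allocation and non-Gaussian/ordinal outcome models are out
  of scope.
* The binary search assumes power is monotone in the searched dimension,
  which holds in expectation but can be violated locally by MC noise at
  small `reps`.
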