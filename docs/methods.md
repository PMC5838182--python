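# Methods

## The problem and the model

Regional misclassification in a cancer registry moves a case from the
patient's province of residence (the *sender*) into the registry of an
adjacent, better-equipped province (the *receiver*). `regmis` models one
sender–receiver pair at a time, on the cross-classification of sex and
four age bands (0–14, 15–49, 50–69, 70+ years; 8 covariate patterns).

Per stratum *r*, with person-years n_S,r and n_R,r:

    T_r ~ Poisson(λ_S,r · n_S,r)         true sender cases
    z_r | T_r ~ Binomial(T_r, θ)          misregistered at the receiver
    y_S,r = T_r − z_r                     observed sender count
    W_r ~ Poisson(λ_R,r · n_R,r)          true receiver cases
    y_R,r = W_r + z_r                     observed receiver count

θ ∈ (0,1) is the probability that a true sender case is registered in the
receiver's registry; it is common to all strata of a pair because one
misclassification rate is reported per pair. By Binomial thinning both
observed vectors are marginally Poisson:
y_S,r ~ Poisson((1−θ) λ_S,r n_S,r) and
y_R,r ~ Poisson(λ_R,r n_R,r + θ λ_S,r n_S,r).

Assumptions worth making explicit: misclassification is one-directional
within a pair (receiver residents are never registered at the sender);
cases misregister independently with a common θ across strata and
provinces' age/sex structure; exposures are known constants; pairs are
modelled independently even when they share a receiver.

## Priors

* **θ:** Beta(a, b) with (a, b) = κ·(100 − c, c) read off the sender's
  percent coverage c. The prior mean (100 − c)/100 is the coverage
  shortfall — the fraction of the sender's expected caseload that went
  missing — and the effective prior sample size is 100κ. κ (default 1) is
  a pure strength dial; it never moves the mean. Coverage at or above
  100% (or at 0) defines no shortfall and raises an elicitation error.
* **Rates:** λ ~ Gamma(shape, rate) per stratum, default shape 1 with the
  rate parameter chosen so the prior mean equals the crude pooled rate of
  the pair, floored at 0.5 expected cases (`crude_rate_prior`). This is a
  deliberately weak, data-scale prior: with shape 1 the prior variance
  equals the squared mean, so a handful of observed cases dominates it.
  Both hyperparameters are overridable.

## Posterior computation

All full conditionals are conjugate:

    z_r | ·   ~ Binomial(y_R,r, θ l_S / (l_R + θ l_S)),  l = λ·n
    θ | ·     ~ Beta(a + Σ z_r, b + Σ y_S,r)
    λ_S,r | · ~ Gamma(shape + y_S,r + z_r, rate + n_S,r)
    λ_R,r | · ~ Gamma(shape + y_R,r − z_r, rate + n_R,r)

The Gibbs sampler cycles z → θ → λ. Defaults: 10,000 iterations, 2,000
burn-in, thin 1, z initialized at 0, λ at the crude per-stratum rates
max(count, 0.5)/exposure (the 0.5 floor avoids a zero-rate absorbing
start), θ at its prior mean. Chains are bitwise reproducible given the
seed (`numpy.random.default_rng`). Summaries: posterior means, 2.5/97.5
percentile interval, per-stratum posterior-mean latent counts, effective
sample size via `arviz.ess` (a constant chain short-circuits to n), and
Monte-Carlo standard error sd/√ESS.

**Identifiability.** With separate per-province rates the likelihood
constrains only (1−θ)λ_S and λ_R + θλ_S n_S/n_R — ridges along which θ
can slide — so the θ posterior is prior-dominated; this is by design: the
analysis deliberately injects the coverage information through the prior.
The `shared_rates` variant sets λ_S,r = λ_R,r = λ_r (neighbouring
provinces share true incidence), giving two observables per stratum for
two parameters; θ is then identified and is recovered from data under a
flat Beta(1,1) prior. Under shared rates the λ conditional is
Gamma(shape + y_S,r + y_R,r, rate + n_S,r + n_R,r): z cancels, because
the latent split only moves cases between two registries with a common
rate. Both behaviours are asserted in the test suite. `shared_rates`
defaults to off, matching the two-vector formulation of the analysis.

**Enumeration oracle.** For validation, the Gamma rates integrate
analytically to negative-binomial marginals, leaving per-stratum weights
over z_r ∈ {0..y_R,r} whose θ-dependence is θ^z (1−θ)^{y_S}. Strata are
combined by convolving their weight polynomials in the total latent count
m, giving the exact posterior on a uniform midpoint grid (default 2001
points):

    p(θ | y) ∝ Beta(θ; a, b) (1−θ)^{Σ y_S} Σ_m A_m θ^m.

All products are evaluated in log space; the convolution renormalizes per
stratum to avoid under/overflow. A guard (Π (y_R,r + 1) ≤ 10^6) rejects
pairs too large to enumerate. E[z_r] is obtained the same way with
stratum r's polynomial reweighted by z. Note the model is *not*
symmetric under swapping the sender/receiver labels (thinning vs
superposition are structurally different roles), so no mirror identity is
available as a check; stratum-permutation invariance is used instead.

## Screening and pairing

Expected caseload = norm × population / 100,000 with norm 113 cases per
100,000 per year (an all-cancer registration norm; the correction itself
is applied to a single site's counts). Percent coverage = 100 ×
observed/expected. Roles use a strict threshold at 100% (equality within
1e-9 is neutral): the packaged 2008 coverage table contains exactly the
21 provinces that deviated, including one receiver at 101.19%, so a
tolerance band would misclassify fixture members. Each sender is paired
with its adjacent receiver of highest coverage, ties broken
lexicographically by province id; an explicit override list reproduces
the 14 published 2008 pairings where they differ from that rule (two of
the 14 do). Senders with no adjacent receiver are reported unpaired and
pass through uncorrected.

The packaged adjacency list is the analysis's neighbour relation, not
pure geography: it includes one pairing (Sistan – Razavi khorasan) that
reflects patient referral rather than a shared border.

## Correction and standardization

Corrected counts are y_S,r + z̄_r and y_R,r − z̄_r with z̄ the
posterior-mean latent counts — kept fractional internally, rounded only
for display — so the pair total is conserved per stratum to 1e-9. A
receiver serving several senders is corrected by summing z̄ across its
pairs; because the pairs are fitted independently this can in principle
over-subtract, which triggers a warning, and a sequential mode (receiver
counts updated after each fit, in sender order) is offered as the
conservative alternative. The default remains independent fitting, which
matches the one-pair-at-a-time analysis.

ASRs are direct standardizations Σ_age w_age (cases_age/pop_age) ×
100,000. Sex-specific ASRs standardize the four strata of that sex;
combined ASRs pool the sexes within each age band first. The default
weights are the WHO world standard collapsed to the four bands (0.2615,
0.5201, 0.1660, 0.0527, renormalized); the standard behind the published
table is unstated, so the weights are fully overridable and exact
reproduction of the published ASR levels is out of reach regardless —
only the direction pattern (senders rise, receivers fall) is checked.

## Synthetic registries

`generate` draws true counts Poisson(rate × population × years) per
stratum and thins each sender's true counts into its receivers
(multinomial across flows when a sender has several). It emulates exactly
the model's data-generating process — which is the point: every stage is
testable with known truth. It does *not* emulate features of real
registry data such as duplicate records, diagnostic-quality differences
by age, within-province rate heterogeneity, bidirectional patient flows,
or year-to-year drift; a pass on synthetic data therefore validates the
machinery, not the model's adequacy for any particular registry.

The semi-synthetic 2008-like scenario has 21 provinces, the published
coverage percentages, and the 14 published flows with θ_true set to each
sender's coverage shortfall. Province populations are synthetic
census-scale stand-ins (the true denominators were never published),
split by a young-population pyramid (28/57/12/3% across the four bands,
equal sexes). Per-stratum rates follow a liver-cancer-like age profile
(relative risks 0.05/0.5/3.5/8 across bands, male and female levels set
separately) calibrated in closed form so the *observed* (post-migration)
ASRs sit on the published before-correction column: sender true rates are
the published rates inflated by 1/(1−θ_true); receiver true rates are the
published rates minus the expected inflow, floored at 10% of the
published rate (heavy-inflow receivers are therefore approximated, not
matched). No fitting is involved in this calibration — it is arithmetic
on published inputs.

`recovery_experiment` runs repeated generate→fit cycles on one pair
(default: 8 strata, 300,000 person-years per stratum, expected 20–200
cases per stratum) and reports per-replicate posterior means, bias, RMSE
and 95%-interval coverage.

## Problem sizes and runtimes

The validation suite uses: a 2-stratum enumeration-feasible toy pair
(50,000 Gibbs iterations vs a 4001-point oracle grid, agreement within
0.01); 20 replicates of the shared-rates recovery experiment at 6,000
iterations each (|mean bias| ≤ 0.05 at θ_true = 0.4); 100 random pairs
for conservation; and 5 independent draws of the semi-synthetic scenario
with all 14 pairs fitted at 4,000 iterations (the direction pattern must
hold in every province). These sizes were chosen so the conjugate chains,
which mix within a few hundred iterations, are summarized with
Monte-Carlo error well below the tolerances being checked; the full suite
and the acceptance script each run in well under a minute on one CPU.

## Known limitations

* The published per-pair misclassification percentages and corrected ASRs
  cannot be reproduced numerically: the stratified counts and provincial
  populations behind them were never published. (The published before/after
  ASRs are also not mutually consistent with the published percentages
  under simple thinning algebra, so exact reproduction would be
  ill-defined even with the inputs.) Validation is therefore
  property-based plus the direction pattern.
* One θ per pair ignores possible age- or sex-dependent referral.
* Misclassification is one-directional per pair; no joint multi-pair
  model, no spatial smoothing (CAR priors, Moran statistics) — out of
  scope by design.
* ASRs are point estimates; no intervals are propagated to the corrected
  rates.
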