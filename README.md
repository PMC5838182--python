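# regmis — Bayesian correction of regional misclassification in cancer-registry data

Cancer registries often record a patient in the province where the cancer
was *diagnosed* rather than where the patient *lives*. Residents of
provinces with few medical facilities travel to better-equipped neighbours
for diagnosis and treatment, so the receiving province's registry is
inflated and the home province's deflated — a regional misclassification
error that distorts incidence maps and, through them, resource allocation.

`regmis` implements a correction pipeline for this problem, aimed at
registry analysts and spatial epidemiologists:

1. **Coverage screening.** Each province's observed all-cancer caseload is
   compared with the caseload expected from its catchment population under
   a national norm (113 cases per 100,000 per year by default). Provinces
   below 100% of expectation are *senders*, adjacent provinces above 100%
   are *receivers*, and each sender is paired with one adjacent receiver.
2. **Prior elicitation.** For a sender with percent coverage *c*, the
   misclassification probability θ — the chance that a true sender case is
   registered at the receiver — gets the informative prior
   θ ~ Beta(100 − *c*, *c*), whose mean (100 − *c*)/100 is exactly the
   coverage shortfall.
3. **Latent-count model.** Per sex × age-band stratum *r*:
   T_r ~ Poisson(λ_S,r n_S,r) true sender cases, of which
   z_r ~ Binomial(T_r, θ) are misregistered at the receiver, so the
   observed counts are y_S,r = T_r − z_r and y_R,r = W_r + z_r with
   W_r ~ Poisson(λ_R,r n_R,r). All full conditionals are conjugate
   (Binomial, Beta, Gamma), so the posterior is sampled by plain Gibbs.
   An exact enumeration oracle validates the sampler on small inputs.
4. **Correction and re-standardization.** Posterior-mean latent counts are
   returned to their home province and directly age-standardized rates
   (per 100,000, four age bands, WHO world-standard weights by default)
   are re-estimated before and after correction.

A synthetic-registry generator draws whole multi-province registry years
from exactly this data-generating process with known truth, including a
semi-synthetic 21-province scenario shaped like the 2008 Iranian registry
year that the packaged fixtures describe.

## Worked example

Fit one sender–receiver pair whose sender registered 53.90% of its
expected caseload (so the prior mean for θ is 0.461):

```python
import numpy as np
from regmis import PairData, PairMisclassificationModel, beta_from_coverage, reallocate

pair = PairData(
    y_S=[2, 9, 14, 6, 3, 12, 18, 8],      # sender counts, 8 sex x age strata
    y_R=[4, 21, 30, 12, 5, 26, 41, 16],   # receiver counts
    n_S=np.full(8, 150_000.0),             # person-years at risk
    n_R=np.full(8, 400_000.0),
)
prior = beta_from_coverage(53.90)          # Beta(46.10, 53.90)
est = PairMisclassificationModel(
    prior_a=prior.a, prior_b=prior.b,
    iterations=10_000, burn_in=2_000, random_state=42,
).fit(pair)
print(est.theta_mean_, est.theta_ci_, est.ess_theta_)
sender, receiver = reallocate(pair, est.summary_)
```

Output:

```
theta posterior mean: 0.446
95% interval: (0.353, 0.534)
ESS: 1437
corrected sender counts:   [ 3.6 16.  24.8 10.8  5.2 21.3 31.7 14.5]
corrected receiver counts: [ 2.4 14.  19.2  7.2  2.8 16.7 27.3  9.5]
```

The posterior mean 0.446 says that, combining the coverage-elicited prior
with the observed counts, an estimated 44.6% of the sender's true cases
were registered at the receiver; the corrected counts return the
posterior-mean latent cases to the sender while conserving the pair total
in every stratum. (With separate per-province rates θ is only weakly
identified and the posterior stays close to its prior; the
`shared_rates=True` variant, which assumes neighbouring provinces share
true incidence rates, identifies θ from the data alone.)

The same analysis is available from the shell:

```bash
regmis simulate --scenario 2008 --seed 7 --out data/
regmis coverage --table data/registry.csv --norm 113 --out coverage.csv
regmis fit --pair pair.csv --prior-from-coverage 53.90 --seed 42 --summary fit.json
regmis correct --tables data/registry.csv --adjacency fixture-2008 \
    --coverage data/coverage.csv --pairs fixture-2008 --out report.csv
regmis run --config config.yaml        # whole pipeline, manifest included
regmis config --defaults               # every knob and its default
```

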