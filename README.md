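# maternalqg

Quantitative genetics of maternal effects for a mother–offspring trait pair:
maternal **daily energy expenditure** (DEE, an energetic proxy for
parental-care effort) and **offspring growth rate**. The package is aimed at
evolutionary physiologists and quantitative geneticists who want to reason
about — and design studies for — the evolution of endothermic, high-turnover
phenotypes driven by parental care.

## The model

Both traits live on a standardized scale (mean 0, nominal variance 1). DEE is
an ordinary additive trait, while growth rate receives the mother's entire
DEE phenotype as part of its environment (a unidirectional maternal effect):

```
z_DEE = a_DEE + e_DEE
z_O   = a_O + e_O + z_DEE(dam)
```

Because offspring inherit half of the dam's genes, the total breeding value of
the maternally affected trait is `A = A_O + ½ A_DEE`, and the joint
per-generation responses to directional selection (gradients β_O on growth in
both sexes, β_DEE on DEE in mothers only) are

```
Δz̄_O   = [V_AO + 3/2·Cov(A_O,A_DEE) + 1/2·V_A(DEE)]·β_O + [V_A(DEE) + Cov(A_O,A_DEE)]·β_DEE/2
Δz̄_DEE = [1/2·V_A(DEE) + Cov(A_O,A_DEE)]·β_O + V_A(DEE)·β_DEE/2
```

Two consequences matter: growth rate can evolve with **zero** direct genetic
variance (through ½·V_A(DEE)·β_O), and a positive genetic covariance between
care and growth makes selection on either trait accelerate both — a
self-reinforcing route to elevated metabolic rates.

The package contains four layers:

- `maternalqg.model` — the closed-form machinery: parameter containers with
  positive-semidefiniteness validation, breeder's equation, total breeding
  value, joint responses with a labeled term decomposition, and the
  stationary kin covariances implied by the phenotype rule.
- `maternalqg.simulate` — an individual-based, discrete-generation forward
  simulator (infinitesimal-model inheritance, linear fitness, seeded and
  bit-reproducible) that validates the theory and generates pedigreed
  synthetic data.
- `maternalqg.estimate` — `MaternalMomentEstimator`, a scikit-learn-style
  estimator that recovers all five variance components from a two-generation
  pedigree by inverting the kin-covariance moment system, with family
  bootstrap uncertainty.
- `maternalqg.scenarios` — 0/1 scenario grids ("effect present/absent"),
  evaluated analytically or by simulation, rendered to TSV and bar charts.

## Worked example

```python
from maternalqg import (GeneticArchitecture, SelectionRegime,
                        predict_response, simulate_pedigree,
                        MaternalMomentEstimator)

arch = GeneticArchitecture(v_ao=1, v_adee=1, cov_a=0.5, v_eo=1, v_edee=1)
sel = SelectionRegime(beta_o=0.1, beta_dee=0.05)
pred = predict_response(arch, sel)
print(round(pred.delta_zo, 4), round(pred.delta_zdee, 4))
print(pred.terms_zo)

ped = simulate_pedigree(arch, n_families=5000, seed=11)
est = MaternalMomentEstimator(n_bootstrap=500, random_state=0).fit(ped)
print({k: round(v, 3) for k, v in est.estimate_.raw.items()})
```

prints

```
0.2625 0.125
{'direct': 0.1, 'cov_via_beta_o': 0.075, 'maternal_var_via_beta_o': 0.05,
 'cov_via_beta_dee': 0.0125, 'maternal_var_via_beta_dee': 0.025}
{'v_ao': 1.082, 'v_adee': 1.018, 'cov_a': 0.517, 'v_eo': 0.894, 'v_edee': 0.982}
```

The growth response 0.2625 decomposes into its direct (V_AO·β_O = 0.1),
covariance-mediated (0.075 + 0.0125) and maternal-variance-mediated
(0.05 + 0.025) parts; the estimator recovers the generating components
(1, 1, 0.5, 1, 1) from 5000 simulated families to within sampling error.

The same operations are exposed on the command line:

```
maternalqg predict  --config model.yaml
maternalqg simulate --config model.yaml --seed 1 --out sim/ --save-pedigree
maternalqg estimate --pedigree sim/pedigree_rep0.tsv --bootstrap 500 --seed 1
maternalqg scenarios --figure all --engine analytic --out scenarios/
```

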