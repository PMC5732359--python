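# Methods

## Model and assumptions

Two standardized traits: maternal daily energy expenditure (DEE), `z_DEE =
a_DEE + e_DEE`, and offspring growth rate, `z_O = a_O + e_O + z_DEE(dam)`.
The maternal-effect coefficient is fixed at 1 — the mother's entire DEE
phenotype enters the offspring's environment — and no general coefficient is
exposed; users who want a weaker maternal pathway should scale `v_adee` and
`v_edee` instead. The maternal effect is strictly unidirectional: nothing in
the offspring feeds back into the dam's DEE, and DEE itself has no maternal
effect on DEE (the simulator has no code path for either). Standard
infinitesimal-model assumptions apply: many genes of small additive effect,
no dominance or epistasis, weak directional selection, discrete
non-overlapping generations.

With mother–offspring relatedness r = ½, the total breeding value of a
maternally affected trait is `A = A_O + ½A_DEE`, and the joint one-generation
responses to gradients (β_O on growth, both sexes; β_DEE on DEE, mothers
only) are

    Δz̄_O   = [V_AO + 3/2·C + 1/2·V_A(DEE)]·β_O + [V_A(DEE) + C]·β_DEE/2
    Δz̄_DEE = [1/2·V_A(DEE) + C]·β_O + V_A(DEE)·β_DEE/2

with `C = Cov(A_O, A_DEE)`. The β_DEE terms carry ½ because selection on
expressed DEE reaches mothers only; `maternal_response_both_sexes` provides
the unsexed variant `V_A(DEE)·β_DEE` for designs where DEE (or a correlate)
is selected in both sexes. Whether these formulas describe the first
generation or a steady rate is settled empirically here: the simulator shows
the windowed (post-transient) per-generation response converges on them, so
the package documents them as the asymptotic per-generation rate.

All variances are interpreted on the standardized scale; nothing is
rescaled. Note that the model-implied stationary phenotypic variance of
growth is `V_AO + V_EO + V_A(DEE) + V_E(DEE) + C`, which exceeds 1 whenever
the maternal pathway contributes; the scenario runner warns once when
implied phenotypic variances differ from 1, and gradients are interpreted
per trait unit, not per realized SD.

## Stationary kin covariances

From the phenotype rule and r = ½ transmission under random mating:

| statistic | expectation |
|---|---|
| var(z_DEE) | V_A(DEE) + V_E(DEE) |
| var(z_O) | V_AO + V_EO + var(z_DEE) + C |
| cov(z_DEE,dam; z_DEE,off) | ½·V_A(DEE) |
| cov(z_DEE,dam; z_O,off) | ½·C + var(z_DEE) |
| cov(z_O,sire; z_O,off) | ½·V_AO + ¼·C |

The dam–growth covariance contains the dam's full phenotypic variance
because her phenotype *is* part of the offspring trait; the sire–offspring
covariance picks up a ¼·C grand-maternal term because the sire's own
maternal environment covaries with the genes he transmits. Every coefficient
is verified against neutral simulation at 3 Monte-Carlo SE in the test
suite.

## Forward simulator

- **Founders.** Each founder receives a virtual parental pair drawn from the
  stationary distribution: breeding values are midparent-plus-segregation of
  virtual parents, and the virtual dam's z_DEE is the founder's maternal
  input. Generation 0 therefore already has the stationary variances *and*
  the stationary cross-covariances (Cov(m, a_O) = ½C), so kin covariances
  hold from the first generation and no variance deficit needs to burn away.
  A 5-generation neutral burn-in before selection is nonetheless the default
  (configurable).
- **Inheritance.** Offspring breeding values are midparent plus a bivariate
  Mendelian segregation deviation. Two schemes are provided.
  `segregation_variance="stationary"` (default) draws the deviation with
  covariance `G0 − Cov(realized midparents)`, holding the population's
  additive covariance matrix at its founder value G0 every generation — the
  constant-genetic-components assumption under which the analytic responses
  are derived, and the right oracle for validating them.
  `"constant"` uses the textbook fixed `G0/2`; under directional selection
  it builds negative gametic-phase disequilibrium (the Bulmer effect), and
  measured at 1000 replicates the all-effects unit scenario then falls
  ~2.5% short of the constant-G prediction — real physics, but a property of
  a different (LD-tracking) model than the one the closed forms describe.
  The residual deviation under the default scheme is ≈ −0.5% (second-order
  within-generation covariance deficits along the maternal path, which
  cannot be restored without distorting the maternal effect itself).
- **Fitness and mating.** `w = max(0, 1 + β_O(z_O − z̄_O) + [female]
  β_DEE(z_DEE − z̄_DEE))`; centering at the current generation means keeps
  realized Lande–Arnold gradients (partial regressions of relative fitness
  on the centered phenotypes, reported every generation) equal to the
  nominal betas throughout a run. Parents are sampled with probability
  proportional to w *with replacement* and paired at random with equal
  litter sizes; this makes the expected selected-parent shift exactly
  `cov(w, z)/w̄`. Strict monogamy (`monogamous=True`) samples distinct
  parents without replacement — under neutrality the two coincide, and the
  neutral pedigree generator uses monogamy for a clean family structure; but
  when half the pool is retained without replacement, inclusion
  probabilities are no longer proportional to fitness (attenuation ≈ ln 2 at
  a retained fraction of ½), so monogamy is not the default for selected
  runs.
- **Sexes.** Balanced each generation; both sexes carry and transmit a_dee;
  only females express z_DEE (it enters offspring z_O and, by default,
  female fitness). Males' latent z_dee = a_dee + e_dee is recorded for
  synthetic-study use and excluded from estimation by default.
- **Reproducibility.** One master seed; replicate generators are spawned via
  `numpy.random.SeedSequence(seed).spawn(n)`. Identical config + seed gives
  bit-identical output.
- **Asymptotic response.** Mean realized per-generation change over a
  post-transient window (default selection-phase generations 11–30). The
  only expected transient is β_DEE-driven: selecting mothers on their own
  DEE shifts the offspring environment once by the full phenotypic
  covariance, so the generation-1 growth response overshoots the asymptotic
  rate by `β_DEE·(½V_A(DEE) + V_E(DEE))`; under β_O-only selection the
  generation-1 maternal-input shift `β_O·(C + ½V_A(DEE))` already equals
  the asymptotic Δz̄_DEE rate and no transient appears in expectation. The
  test suite asserts both facts.

## Variance-component estimation

Moment estimators on the five statistics above, inverted in closed form:

    V_A(DEE) = 2·cov(z_DEE,dam; z_DEE,off)
    V_E(DEE) = var(z_DEE) − V_A(DEE)
    C        = 2·[cov(z_DEE,dam; z_O,off) − var(z_DEE)]
    V_AO     = 2·cov(z_O,sire; z_O,off) − C/2
    V_EO     = var(z_O) − V_AO − var(z_DEE) − C

Moment equations were preferred over REML/animal models because they are
transparent about *which* covariances carry the information, dependency-
light, and exactly invertible against the analytic forward map (the
forward–inverse identity is tested to 1e-10). The cost is efficiency; an
animal model would use the full pedigree. Estimation assumes neutral or
weakly selected data; no selection-bias correction is attempted.

Raw solutions may violate non-negativity or positive semidefiniteness in
finite samples; raw and truncated solutions are reported side by side with a
flag, never silently clipped. Standard errors come from a nonparametric
bootstrap over dams (each dam resampled with all her pairs and family
members; 500 resamples by default, seeded, vectorized via per-family
sufficient statistics). Response predictions from estimates propagate the
bootstrap draws through the (linear) response equations to percentile
intervals; statistics with fewer than 30 pairs are flagged low-confidence.

## Scenario grids

Grids toggle effects to 0/1 on the unit scale: the growth-response grid
holds V_AO = β_O = 1 and varies (V_A(DEE), β_DEE, C); the DEE-response grid
holds V_A(DEE) = 1 and varies (β_O, β_DEE, C, V_AO); a nested progression
runs univariate → multivariate → multivariate-plus-covariance for both
traits (the full unit-parameter model gives responses (4, 2)). Toggles with
a covariance but no corresponding variance violate positive
semidefiniteness and are omitted with a logged reason — "covariance
present" entails "variance present". The simulation engine scales gradients
by ε = 0.05 (unit gradients would break the weak-selection assumption and
clamp fitness at zero) and rescales responses by 1/ε; its residual
environmental variances are fixed at v_eo = v_edee = 1 (the analytic values
are independent of them; phenotypes should not be purely genetic).

## Problem sizes and numerical choices

Validation runs use n = 2000 per generation, 30 selected generations after
a 5-generation burn-in, 200 replicates, ε = 0.05, litter size 4; estimation
experiments use 5000 families with 500 bootstrap resamples. Analytic
identities are asserted at 1e-12 relative tolerance, stochastic agreements
at 3 Monte-Carlo (or bootstrap) SE. PSD validation allows 1e-9 absolute
slack for round-off. Singular genetic covariance matrices (e.g. perfectly
correlated breeding values) are handled by eigenvalue-clipped factorization
rather than Cholesky. Degenerate inputs — all-zero architectures, empty
scenario lists, constant phenotype tables — return exact zeros or empty
tables rather than errors; genuinely invalid inputs (negative variances,
PSD violations, unresolvable pedigrees, all-zero fitness) raise with the
offending quantity named.

## What the synthetic data does and does not emulate

The generator reproduces the model's own causal structure: additive
bivariate inheritance, one expressed maternal phenotype per dam applied
identically to all her offspring (one z_DEE per mother, not re-expressed
per litter), balanced sexes, equal litters, no mutation, no explicit
genome, no overlapping generations, no inbreeding avoidance beyond random
pairing. Passing tests therefore show internal consistency of model,
simulator and estimator — not that real pedigrees satisfy the assumptions.
Real data add measurement error, common-environment (litter) effects
confounded with e_DEE, paternal care, litter-size variation and selection
histories, none of which are modeled; a cross-fostering design would be
needed to separate common-environment from maternal-genetic variance.

## Known limitations

- Selection at a retained fraction as aggressive as truncation, or
  gradients large enough to clamp fitness noticeably, leave the
  weak-selection regime in which realized gradients equal nominal ones.
- The closed forms are first-order in β; even the variance-stationary
  simulator shows ~0.5% second-order deficits at ε = 0.05 grids.
- Moment estimation ignores males' latent DEE by default and is inefficient
  relative to an animal model; standard errors assume families are the
  independent resampling unit.
- Multigeneration time-lag dynamics are exhibited empirically but no
  lag equations are implemented; paternal effects and offspring→mother
  feedback are out of scope by the model's assumptions.
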