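# senet — multilevel social–ecological network analysis

`senet` is a Python toolkit for studying **social–ecological alignment** in
common-pool resource systems such as coral-reef fisheries. It asks a precise
structural question: do resource users who compete for the *same* resources
also form cooperative communication ties — and do places where they do show
better ecological conditions?

It is aimed at researchers working with multilevel network data: a social
network among resource users, an ecological network among resources, and
cross-level ties linking users to the resources they harvest.

## The model

A study site is a multilevel network with three tie sets:

* `A` — undirected binary communication ties among fishers,
* `B` — undirected trophic ties among target fish species, inferred from
  diet, relative body size, and habitat overlap,
* `X` — binary incidence linking each fisher to the species targeted by
  their primary gear.

Only `A` is modeled; `X` and `B` are exogenous. The social network follows
an exponential random graph model (ERGM)

```
P_theta(A | X) ∝ exp( theta · z(A, X) )
```

whose statistics `z` include the edge count, the alternating k-star (ASA)
and alternating triangle (ATA) with decay `lambda`, leader activity,
landing-site homophily and per-site activity controls, and the statistic
this package exists for — **social–ecological network closure**, the count
of closed cross-level triangles:

```
z_closure(A, X) = sum_{i<j} A_ij · | N_X(i) ∩ N_X(j) |
```

i.e. every pair of communicating fishers contributes the number of species
they both harvest. A positive, significant closure parameter means direct
resource competitors communicate more than chance, given the controls.

Estimation solves the method-of-moments condition `E_theta[z] = z_obs` (the
MLE condition for exponential families) by three-phase Robbins–Monro
stochastic approximation over a Metropolis–Hastings tie-toggle sampler,
with convergence t-ratios, simulation-based standard errors, goodness of
fit, and Mahalanobis model comparison.

Sites with a positive closure estimate exceeding twice its standard error
form the "closure" group; per-transect **reef-fish biomass** (length–weight
conversion, kg/ha) and **functional richness** (distinct trait
combinations) are then compared between groups with one-sided two-sample
t tests and Cohen's D, alongside two-sided tests for environmental
covariates (Welch/Satterthwaite where variances are unequal).

A fully synthetic study generator (`senet.synthetic`) emulates the field
design — five sites of 71–232 fishers, mean degree 1.5–3.5, 3–5 gear types
over 36 species, transect biomass below the 1200 kg/ha pristine reference —
with known ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from senet import gen_study, MultilevelERGM, ERGMSpec, compare_site_groups

study = gen_study(11)                      # 5 synthetic sites, seeded
site = study.sites[0]                      # site "A": 87 fishers
spec = ERGMSpec.from_names("edge_density,alt_triangle,se_closure")
res = MultilevelERGM(site.network, site.actors, spec).fit(
    seed=42, phase3_samples=800)
print(res.summary())
```

```
Multilevel ERGM (Robbins-Monro MCMC-MLE)
  actors: 87   dyads: 3741   converged: False
statistic               estimate       SE   conv t  sig
edge_density              -4.582    0.302   -0.025  *
alt_triangle              -0.125    0.228    0.122
se_closure                 0.147    0.034   -0.061  *
  * |estimate| > 2 SE (Wald P < 0.05)
```

The closure estimate (0.147, SE 0.034) is positive and significant — this
site was generated with a true closure effect of 0.15, which the fit
recovers. (The `converged` flag is strict: it requires every convergence
t-ratio below 0.1; here the alternating-triangle ratio is 0.12.)

```python
closure = {s.scenario.site_id for s in study.sites
           if s.scenario.has_closure_effect}
gc = compare_site_groups(study.transects_by_site(), closure,
                         "biomass", study.traits)
print(f"biomass: t({gc.df:.1f}) = {gc.t:.2f}, one-sided p = {gc.p:.3f}, "
      f"D = {gc.cohens_d:.2f}")
```

```
biomass: t(18.0) = 1.73, one-sided p = 0.050, D = 0.79
```

Closure-group transects carry higher fish biomass, with a large
standardized effect — the qualitative pattern the model family was built
to detect.

The same flow is available from the shell:

```shell
senet generate --seed 7 --out study/
senet fit --site study/A --seed 7 --out study/A/fit.json   # ... per site
senet compare --study study/ --out study/report.json
senet report --report study/report.json
```

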