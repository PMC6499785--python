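# Methods

## Model

The unit of analysis is a study site: a multilevel network with a social
level `A` (undirected, binary communication ties among `n` fishers), an
ecological level `B` (undirected trophic ties among target species), and a
cross-level incidence `X` (fisher–species ties induced by primary gear).
Only `A` is random. Conditional on `X`, the tie variables follow an
exponential family `P_theta(A) ∝ exp(theta · z(A, X))` with statistics:

| statistic | form | role |
|---|---|---|
| `edge_density` | number of ties | baseline density |
| `two_star` | `S2 = Σ_i C(d_i, 2)` | raw centralization (optional) |
| `alt_star(λ)` | `λ² Σ_i [(1−1/λ)^{d_i} − 1 + d_i/λ]` | geometrically damped degree dispersion (ASA) |
| `alt_triangle(λ)` | `λ Σ_{ties ij} [1 − (1−1/λ)^{P_ij}]` | transitive closure (ATA); `P_ij` = two-paths |
| `leader_activity` | `Σ_{ties} (L_i + L_j)` | leaders attract ties |
| `site_homophily` | ties with matching landing site | within-landing-site mixing |
| `site_activity(a)` | tie-ends on actors of landing site `a` | per-site activity control |
| `se_closure` | `Σ_{ties ij} |N_X(i) ∩ N_X(j)|` | closed cross-level triangles |

The degree form of the alternating star equals the alternating sum
`S2 − S3/λ + S4/λ² − …` (verified against brute-force enumeration in the
tests). `se_closure` is the plain (non-alternating) closed-triangle count:
each communicating pair contributes the number of species both harvest.
An alternating variant would damp the contribution of pairs sharing many
species; we use the plain count because the closure hypothesis is about
the presence of shared-resource ties, and the counts enter linearly into
the change statistics either way.

Assumptions: ties are undirected and binary (survey nominations are
symmetrized — by union by default, since name generators are
recall-limited; an intersection rule is available); `X` and `B` are fixed
and exogenous; all dyads are conditionally dependent only through the
modeled statistics. `λ = 2.0` by default for both alternating statistics,
the common choice in this model family; it is configurable per statistic
and is not estimated (no curved-family estimation).

## Estimation

`MultilevelERGM.fit` solves the moment condition `E_theta[z] = z_obs` by
three-phase Robbins–Monro stochastic approximation over a
Metropolis–Hastings sampler that proposes uniformly random dyad toggles
and accepts with probability `min(1, exp(theta · Δz))`; change statistics
are computed locally and verified against full recounts to machine
precision. Defaults (all configurable through `FitOptions`):

* initialization: edge parameter at `logit(observed density)`, others 0;
* phase 1: 100 thinned samples estimate the statistic variances `D` used
  to scale updates;
* phase 2: 5 subphases, gain 0.1 halved per subphase, iterations doubling
  from 100, update `theta ← theta − a·D⁻¹(z − z_obs)` clamped at 0.5 per
  component, with iterate averaging over the second half of each subphase;
  the chain advances `max(2n, dyads/4)` proposals between updates;
* phase 3: 1000 samples thinned at one sweep (= number of dyads) give the
  convergence t-ratios `(mean z_sim − z_obs)/sd(z_sim)`, the simulated
  covariance `Σ_z`, and `SE = sqrt(diag(Σ_z⁻¹))` (the exponential-family
  Fisher identity); a pseudo-inverse (tolerance 1e−10) is used and flagged
  when `Σ_z` is near-singular.

A fit is `converged` when every |t-ratio| < 0.1. Observed statistics at an
extreme bound (empty/complete network) and chains that collapse during
phase 2 raise `DegeneracyError` carrying the parameter trace. Goodness of
fit simulates at the estimate and reports t-ratios for the modeled
statistics plus auxiliaries (degree SD, global clustering, isolate count;
|t| < 2 labeled adequate) and the Mahalanobis distance of the observed
vector under the simulated covariance; model comparison prefers the
smaller distance. The residual screen flags landing sites whose tie
activity exceeds its simulated expectation by t > 2 for inclusion as
`site_activity` controls; sites covering all actors are skipped because
the statistic degenerates to twice the edge count.

The sampler and change statistics are numba-compiled; sampler state is
seeded explicitly and every stochastic operation is reproducible from its
seed (one root seed spawns all child seeds via `numpy.random.SeedSequence`).

## Group comparison

Sites are grouped by a pre-registered rule: closure sites are those whose
`se_closure` estimate is positive with |estimate| > 2·SE (Wald P < 0.05).
Per-transect biomass (`Σ count · a·L^b / area`, reported in kg/ha) and
functional richness (distinct tuples over diet, size class, and mobility)
are pooled within groups and compared with a one-sided two-sample t test
(alternative: closure group greater, the directional hypothesis).
Covariates are compared two-sided. When raw samples are available the
variant is chosen by a Levene pre-test at α = 0.05 (pooled when variances
are compatible, Welch/Satterthwaite otherwise); summary-statistic inputs
require an explicit variant. Cohen's D always uses the pooled
(n−1)-weighted SD, which is what reproduces the bundled published table;
its CI inverts the noncentral-t distribution (the published table's CI
method is unreported, so CI bounds are informative only). Mann–Whitney U
uses midranks, exact enumeration when `n1·n2 ≤ 400` without ties, and the
tie-corrected normal approximation otherwise.

Of the six bundled covariate rows, three (NPP, coral cover, fishing
pressure) recompute exactly at printed precision from their rounded group
summaries; sea-surface temperature and rugosity do not (rounding of the
inputs), and human gravity matches neither pooled nor Welch arithmetic.
The non-recomputable rows are retained in the dataset but flagged. Note
the source table's own footnote attributes Satterthwaite df to "NPP and
rugosity", yet the printed rugosity df (69) is the pooled value and the
coral-cover df (36.8) is fractional; the dataset follows the numbers, not
the footnote.

## Synthetic data

The generator reproduces the study conditions, not any particular dataset:

* five sites, fisher counts 87/71/103/76/95 (inside the 71–232 range; kept
  at the lower end so replicated estimation studies run quickly), mean
  degree targets 1.9–3.1 (inside 1.52–3.49), 2–3 landing sites, leader
  fraction 0.08;
* 36 species with unique (diet, size-class, mobility) combinations —
  sampled without replacement so a transect's functional richness equals
  its species count and declared richness targets are exact;
* five gear types over the species pool with overlap 0.5 (shared core plus
  gear-specific species; pairwise Jaccard similarity rises monotonically
  with the overlap parameter);
* trophic ties from the trait rules (diet permission matrix, size-ratio
  interval [1.5, 20], habitat overlap required). These defaults are
  deliberately coarse placeholders for taxon-specific feeding rules and
  are fully parameterized;
* social networks drawn from the ERGM itself at `theta*`: closure sites
  use `theta*_closure = 0.15` and alternating-triangle 0.2; null sites set
  the closure parameter to zero. The edge parameter is calibrated by
  single-parameter Robbins–Monro so the simulated mean degree hits the
  declared target; the calibration is unbiased across seeds, while any
  single draw fluctuates with the natural sampling variability;
* transects: 4 per site, 500 m²; per-transect species counts and biomass
  targets drawn from the declared normals (biomass truncated below the
  1200 kg/ha pristine reference), lognormal relative abundances, gamma
  lengths rescaled so realized biomass matches its target. Group-level
  targets (closure 610 ± 185 kg/ha, 24 ± 3.2 functional entities; null
  445 ± 185, 19 ± 3.2) reproduce standardized differences near 0.9
  (biomass) and 1.55 (richness), the magnitudes the pipeline is meant to
  detect.

What the generator does *not* emulate: spatial reef structure,
seasonality, observation error in visual censuses, directed or weighted
feeding relations, or fisher attributes correlated with network position
beyond the modeled effects. Passing tests therefore demonstrate that the
estimation and comparison machinery recovers known structure under the
declared design — not that field data of this kind are free of the
confounds the generator omits.

## Problem sizes and numerical choices

Replicated studies in the tests use 20 seeded replicates of the five-site
design fitted with the three-statistic closure model (phase-3 sample 400,
subphase iterations 60) — sizes chosen to make replication studies a
routine part of the test suite. Parameter recovery uses 60 actors and 15
species over 20 replicates. Tie-breaks and degenerate inputs: proposals
landing on the diagonal are discarded; zero-variance statistics yield
undefined (NaN) GOF t-ratios rather than errors; a t statistic with zero
pooled variance and equal means is reported as undefined with a note.

## Limitations

* Parameter magnitudes are not comparable across software implementing
  differently normalized alternating statistics; signs and significance
  are the portable quantities.
* The closure statistic counts shared species linearly; heavily
  overlapping gear catalogs make it correlate with the edge count, which
  inflates its standard error (the contrast across gear pairs is what
  identifies it).
* The estimator targets the method-of-moments solution; for near-degenerate
  specifications (strong positive closure on dense overlap structures) the
  chain can collapse — this is detected and raised, not silently absorbed.
* Cross-level and ecological ties are fixed: no inference about how social
  structure feeds back on harvesting behavior or the food web.
* The linear mixed-model robustness variant of the group comparisons
  (random effect for fishers belonging to two communities) is out of
  scope; the t-test and rank-test routes are implemented.
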