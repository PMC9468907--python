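# Methods

`grazeform` implements a trait-based analysis of frequently grazed grass
communities: from raw quadrat records it derives species trait indices,
classifies species into growth forms, models which kinds of species dominate
under which environmental conditions, and asks whether bare ground — the
standard field indicator of overgrazing — tracks grazing pressure. This note
records the statistical procedures, the choices made where the design was
genuinely open, and what the synthetic data generator does and does not
emulate.

## Data model

A survey is three tables. `quadrats.csv` holds one row per species-in-quadrat
record: % aerial cover, median leaf table height (mm; the visually assessed
~80th quantile of leaf biomass), culm orientation (six categories from
`lateral` to `upright`, including the hybrid codes `geniculate-lateral` and
`geniculate-upright`), stolon presence, rhizome class (`none`/`short`/`long`)
and a tufted-base flag. `quadrat_meta.csv` holds % bare ground and dung
presence per quadrat; `sites.csv` the four environment variables: mean annual
rainfall (mm yr⁻¹), % sand, cation exchange capacity (cmol(+) kg⁻¹) and pH.

Validation is total — every out-of-range value is reported with row and field,
nothing is coerced — and referential: every observation needs a quadrat-meta
row and a site-environment row. Summed species cover within a quadrat may
exceed 100% (overlapping canopies); only per-species cover is bounded.
Fewer than 15 quadrats at a site is a warning, not an error. Tufted base is
stored as an explicit field observation; short rhizomes are *not* folded into
it automatically, keeping the raw observation separable from any derivation a
user prefers.

## Trait indices

Four species-level indices summarise grazing-relevant architecture:

- **Culm orientation index** — mean of a per-record code: lateral = 1,
  geniculate-lateral = 2, geniculate or decumbent = 3, geniculate-upright = 4,
  upright = 5.
- **Lateral index** — proportion of records with stolons or long rhizomes.
- **Tuft index** — proportion of records with a tufted base.
- **Grazer use index** — per record, the ratio r of leaf table height to the
  site-level median height, reciprocated when r > 1 (ratios of exactly 1 are
  left as 1), then averaged over all the species' records pooled across sites
  (a flat mean over records, not a mean of site means). Species held near the
  local sward height score near 1; species much taller (avoided) or much
  shorter (inaccessible) score low.

The site median is the unweighted median over all species × quadrat records —
not cover-weighted and not per-species-first. That is the simplest faithful
reading of "site-level median leaf table height"; the flat-record convention
is a documented choice, as is pooling ratios across sites before averaging.
Two algebraic properties follow and are tested: the index is invariant to
rescaling all heights at a site, and records at ratios r and 1/r contribute
identically.

## Growth-form classification

Species occurring in more than 10 quadrats (strict inequality) enter the
formal classification; rarer species destabilise the clusters and are instead
assigned from a manual override table (provenance is recorded per species;
missing overrides yield an explicit `unassigned` label with a warning).

The pipeline is hierarchical clustering on principal components:

1. **Range standardisation** of the four indices to [0, 1] (min/max recorded).
2. **PCA**, centred and unit-variance scaled by default (correlation-matrix
   PCA, the default of the standard HCPC procedure; a flag switches to
   covariance PCA). Scaling uses the population SD so results are invariant
   to duplicating rows. The sign of each component is fixed by making its
   largest-magnitude loading positive. All four components are retained —
   with four traits, truncation would be an extra assumption.
3. **Ward clustering** of the PC scores: the minimum-variance criterion via
   the Lance–Williams recurrence on squared Euclidean distances, heights
   reported on the distance scale (height²/2 is the within-cluster
   sum-of-squares increase; "Ward.D2" behaviour). Exact ties are broken by
   the lexicographically smallest pair of cluster ids, making the tree fully
   deterministic. The implementation is validated in tests against both an
   exhaustive pair-scoring oracle (n ≤ 7) and `scipy.cluster.hierarchy`.
4. **Cut at k groups** (default k = 4; k is a parameter because the cut is an
   interpretability choice, not an automatic criterion), labels ordered by
   decreasing cluster size then dendrogram leaf order.
5. **v-tests** on the raw indices describe each cluster:
   v = (x̄_k − x̄) / sqrt((s²/n_k) · (N − n_k)/(N − 1)), with s² the
   population variance of all N values — the mean of a random size-n_k subset
   drawn without replacement has exactly this standard deviation, so v is a
   z-score for "this cluster is a random subset". Two-sided p-values use the
   standard normal; degenerate cases (s² = 0, or the cluster is the whole
   sample) report v = 0 with a flag.

Clusters are mapped to the four named growth forms from their v-test
signatures, claimed in a fixed precedence order: **lateral attractor** (high
lateral index), **resister** (high culm orientation, low grazer use),
**tufted attractor** (high tuft and grazer use), **avoider** (low grazer use
and tuft). Exact score ties are reported as ambiguous rather than silently
resolved. The optional k-means consolidation step some HCPC implementations
apply after the cut is deliberately not applied.

## Fourth-corner trait–environment model

For each site, species are ranked by site-mean cover (mean over all the
site's quadrats, absences counting zero) and the minimal prefix reaching 90%
of summed site cover is scored present — the 90% rule is relative to summed
cover, the only well-defined reading when summed cover ≠ 100. The resulting
sites × species presence matrix L, the standardized sites × environment
matrix R and the standardized species × trait matrix Q are linked by one
binomial GLM on the vectorised L:

logit P(s present at i) = α_s + Σ_e γ_e env_e(i) + Σ_{q,e} β_qe trait_q(s) env_e(i)

Species intercepts absorb trait main effects (traits are species-constant);
the β matrix is the fourth corner. Fitting is plain maximum likelihood by
iteratively reweighted least squares (Newton steps, deviance-change tolerance
1e-10, max 100 iterations), cross-checked against `statsmodels` GLM in tests.
No LASSO penalty is applied — AICc model selection presumes likelihood-based
fits. On separation/non-convergence the fit falls back to a small ridge
penalty with a logged warning; the reported deviance stays unpenalised.

All 15 non-empty environment subsets are fitted and ranked by
AICc = −2logL + 2p + 2p(p+1)/(n−p−1) with n the number of site × species
cells; the species-intercepts-only model is reported separately as a null
anchor (it cannot answer the trait–environment question, so it never
competes for best).

The overall interaction is tested by a site-block resampling ANOVA: the
statistic is the likelihood-ratio deviance between the model with and without
all trait × environment terms; each of the (default 999) iterations permutes
the environment rows en bloc against the community rows — preserving
within-site species co-occurrence — and refits both models;
p = (1 + #{null ≥ observed}) / (1 + iterations). Permutation (rather than
bootstrap resampling with replacement) was chosen because site
exchangeability under the null gives exact finite-sample type-I control,
which the acceptance suite verifies empirically (rejection rate at α = .05
within [0.03, 0.07] over 500 null replicates at 199 iterations). This is a
block-resampling test in the same spirit as PIT-trap residual resampling, but
equivalence to that specific algorithm is not claimed.

## Environmental ordination and cover surfaces

Sites are ordinated by centred, unit-variance PCA of the four environment
variables. Growth-form cover per site is the quadrat-mean of the summed
per-species cover of each form's species — all species at the site, not just
the dominant set, and absolute cover rather than relative composition (a 0%
floor interacts correctly with bare ground). Cover is interpolated over the
first two axes by piecewise-linear barycentric interpolation on a Delaunay
triangulation of the site scores: parameter-free, exact at the sites, bounded
by the observed covers, and never extrapolated outside the convex hull (cells
outside are missing by design — smooth-spline extrapolation artefacts are
deliberately avoided). Contour levels run in 10-percentage-point steps.

## Bare-ground analyses

Sites are split by which attractor form has greater cover (exact ties are
flagged and excluded); the two groups' mean bare ground is compared by a
one-way F test with df (1, n − 2). Within each group, % bare ground
(untransformed) is regressed on mean annual rainfall × % sand × dung
proportion (the proportion of quadrats with dung, a grazing-pressure proxy):
every sub-model of the three-way factorial that respects marginality
(interactions only alongside all their constituent main effects; 19 candidate
models including intercept-only) is fitted by OLS and ranked by Gaussian
AICc with the residual variance counted as a parameter — the convention of
the standard small-sample AICc for least squares. Candidates with fewer than
two residual degrees of freedom, or collinear designs, are skipped with a
warning. The best model's coefficients and overall regression F are reported.

A calibration note: under a pure-noise response with n = 20 sites, the
intercept-only model wins this 19-candidate AICc race roughly two-thirds of
the time — the AICc penalty gap to a one-predictor model is ≈ 2.8, which a
spurious predictor overcomes with probability ≈ 0.1, and the lattice offers
many chances. The test suite therefore checks the selection against an
independent all-subsets oracle replicate-by-replicate rather than asserting
a near-certain intercept-only win.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
every stage drawing from its own RNG stream spawned from one seed (so stages
can be regenerated independently and outputs are byte-reproducible):

- **Species pool** — four archetypes mirroring the growth forms; per species,
  latent trait values are truncated-normal draws around the archetype means
  (lateral/tuft in [0,1], culm code in [1,5]) plus a lognormal height ratio.
  Defaults: lateral attractors (lateral 0.85, tuft 0.15, culm 1.8, height
  ratio 1.0), tufted attractors (0.15, 0.80, 3.2, 1.0), resisters (0.10,
  0.90, 4.4, 2.8), avoiders (0.45, 0.15, 2.6, 0.33). An archetype whose SDs
  would truncate more than half its mass is rejected as degenerate.
- **Sites** — 33 sites by default, environment drawn uniformly over
  rainfall 336–987 mm yr⁻¹ and sand 44–93% (the gradients such surveys
  span), CEC 2–25 cmol(+) kg⁻¹ and pH 4.5–8.5 (field-plausible ranges).
- **Occurrence** — logit P(species at site) = α_s + traitsᵀ B env on
  standardized scales; the default B qualitatively mirrors the associations
  the analysis targets (tuft/lateral/culm increasing with rainfall, prostrate
  culms on sandy and high-CEC soils, tufted species on acid soils); B = 0
  gives the null generator.
- **Quadrats** — 30 per site (minimum 15 enforced); each present species
  gets a persistent Gamma-distributed site abundance weight that drives both
  its quadrat occupancy and its cover share, so a few species dominate every
  quadrat the way real swards do (default concentration 0.4 puts the
  minimal-90%-cover sets in the 2–12 species range); covers are weights ×
  lognormal noise normalised to a 50–95% total draw.
- **Heights** — record height = site sward scale (lognormal around 60 mm) ×
  species height ratio × lognormal record noise, so the grazer use index is
  exercised end-to-end as a derived statistic of heights rather than being
  set directly.
- **Field traits per record** — stolons/long rhizomes from the latent lateral
  probability, tufted base from the latent tuft probability, culm category
  from the latent code plus record jitter (code 3 renders as `geniculate` or
  `decumbent` with equal probability).
- **Dung and bare ground** — dung is Bernoulli per quadrat with a site-level
  grazing pressure drawn from U(0.2, 0.9); quadrat bare ground is
  20 + 15 × (site dung proportion) + N(0, 8), clipped to [0, 100].

Ground truth (archetype per species, latent traits, B, bare-ground
coefficients, site grazing pressures, expected per-form occupancy) is emitted
alongside the survey. What the generator does **not** emulate: spatial
structure among quadrats, temporal dynamics or grazer–sward feedbacks,
observer error in cover estimation, and phylogenetic correlation among
species. Passing recovery tests therefore demonstrates that the estimators
recover the generative structure they assume — not that field data satisfy
those assumptions.

## Problem sizes and numerics

Default analyses run at the survey's own scale (33 sites × 30 quadrats,
~48 species) in seconds. The Monte-Carlo studies in the test and acceptance
suites use 50 replicates at 40 sites for fourth-corner sign recovery, 500
null replicates at 199 permutation iterations (15 sites × 12 species
triplets) for type-I calibration, and 10⁴ vectorised replicates for the
bare-ground slope coverage — sizes chosen so each study's Monte-Carlo error
is small relative to the property it checks. IRLS tolerance is 1e-10 on the
relative deviance change; PCA reconstruction is exact to 1e-8; CSV output
uses shortest round-trip float formatting so writing is lossless and
byte-deterministic.

## Known limitations

- The growth-form names are assigned from v-test signatures by a fixed
  precedence rule; genuinely ambiguous clusterings (possible at small n or
  k ≠ 4) are flagged rather than resolved.
- The permutation ANOVA tests the joint trait–environment interaction only;
  per-coefficient inference is limited to the fitted values (no standard
  errors are reported for β entries).
- Bare-ground regressions are ordinary least squares on percentages; no
  beta-regression, mixed models or spatial autocorrelation handling.
- Presence/absence modelling discards abundance information by design; the
  dominant-set construction makes "presence" mean "dominant", and results
  should be read accordingly.
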