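# Methods

`trailside` implements a complete analysis chain for paired trail-side /
off-trail trampling surveys of subalpine vegetation: percent-cover
estimation from quadrat photographs, derivation of growth and
area-standardized reproduction traits, and hierarchical Bayesian models of
disturbance-by-elevation effects, together with a synthetic survey
generator that provides ground truth for every stage.

## Survey model and synthetic data

The survey layout is 14 transect pairs on three trails over a
1580–1980 m elevational gradient.  Each pair holds one trail-side
("disturbed") and one off-trail ("undisturbed") 10 m x 0.5 m transect at
the same location (shared elevation), divided into ten contiguous
1 m x 0.5 m quadrats.  Four focal taxa are simulated: the heath
*Phyllodoce empetriformis*, the heather *Cassiope mertensiana*, the
blueberry *Vaccinium ovalifolium*, and sedges (*Carex* spp., whose
phenophases cannot be distinguished in the field, so no reproduction
counts are generated for them).

Generative laws, per species:

* **Size traits** (maximum height and diameter, cm).  Integer cm sizes are
  zero-truncated negative binomial with log mean
  `b0 + bD*D + bE*E + bDE*D*E + u_pair`, `u_pair ~ N(0, sigma_pair^2)`,
  and shape `phi`.  Zero truncation reflects that a surveyed plant cannot
  have zero size (and keeps the trait-table invariant h, d > 0); at the
  default means the induced bias on the disturbance log-ratio is < 0.02.
  Stored sizes add sub-cm measurement jitter, uniform on
  (-0.499, 0.499) rounded to the mm, emulating mm-precision field
  measurements; nearest-integer rounding recovers the latent NB draw
  exactly.
* **Reproduction.**  Total buds+flowers+fruits are Poisson with rate
  `lambda_rep * height * diameter` (reproductive output proportional to
  plant area — the simplest law consistent with larger plants carrying
  more structures), split uniformly over the three phenophase columns.
* **Abundance.**  Candidate individuals per (quadrat, species) are
  Poisson(6), thinned by a per-species occupancy probability; the analysis
  stage then caps measurement at five randomly selected individuals per
  quadrat, mirroring the field protocol.  Occupancy defaults
  (0.40/0.35/0.50/0.17) put realized per-species sample sizes in the
  300–900 range typical of such surveys.
* **Cover.**  Quadrat cover fractions are Beta with logit-linear mean in
  disturbance x elevation plus a pair intercept and precision `phi_beta`.
  The quadrat image is painted with exactly `round(p*H*W)` green-dominant
  pixels (G > R and G > B strictly; greens drawn with G in [100, 255] and
  R, B strictly below G) and the remainder gray or red/brown-dominant, so
  the painted fraction is exact ground truth for the pixel classifier.

**Reference presets.**  `synthetic.reference_presets()` encodes
species-by-trait disturbance effects matching hierarchical-model estimates
from a BC Coast Mountains trampling survey (e.g., percent-cover
disturbance coefficient -8.38 on the logit scale; strong blueberry height
and diameter reductions; a null heather height response; a sedge height
response whose sign reverses along the gradient).  Published per-metre
elevation coefficients in that analysis print as 0.00 at two decimals
while the printed intercepts are only coherent with small nonzero values;
the presets therefore use elevation and interaction coefficients chosen
*within the printed rounding* so that mid-gradient mean sizes are
field-realistic (roughly 8–15 cm).  Dispersion and variance parameters are
not published and are survey-realism choices, fixed once: NB shape
`phi = 2`, `sigma_pair = 0.3`, Beta precision `phi_beta = 10` (typical for
quadrat vegetation-cover proportions), `lambda_rep = 0.05–0.08` per cm².

Not emulated: spatial autocorrelation within transects, interspecific
competition, weather/snowpack effects, observer error in species
identification.  Passing tests therefore demonstrate correctness of the
estimation machinery under the stated generative model, not robustness to
those field complications.

## Percent cover from quadrat photographs

Images are assumed pre-cropped to the quadrat frame.  The estimator (i)
boosts HSV saturation by a factor of 30 (`S' = min(1, 30 S)`), washing out
shading while preserving hue and value and therefore the channel rank
order of every non-gray pixel; (ii) classifies a pixel as vegetation when
its green digital number strictly exceeds both red and blue (ties and gray
pixels are non-green; moss counts as green, rocks and logs as non-green by
virtue of not being green-dominant); (iii) reports the exact fraction of
qualifying pixels.  Because the boost preserves channel order, the boosted
and unboosted paths agree exactly on images whose pixels have pairwise
distinct channels; both paths are exposed (`boost=False`), with the
boosted path the default.  RGB↔HSV conversion uses scikit-image; the test
suite checks it against an independent per-pixel `colorsys` oracle (exact
up to one 8-bit rounding step) and checks the classifier against a
nested-loop oracle exactly.

## Trait derivation

Plant area is the rectangular proxy height x diameter (cm²).
Area-standardized reproduction is (buds+flowers+fruits)/area; relative
reproduction divides by the species-wide maximum over all transects, so
each species' most reproductive individual scores exactly 1.  Rows with
non-positive sizes are excluded and logged.  Relativization happens before
the Beta-interval adjustment (0 -> 1e-4, 1 -> 1 - 1e-4), so interior data
are never perturbed.  Nearest-integer rounding for the NB family rounds
ties half away from zero (platform-independent).  A species whose every
individual has zero reproduction is non-informative for a proportional
model; its relative column is set to 0 and the species is flagged rather
than raising.

## Hierarchical models

Each model is `response ~ disturbance * elevation + (1 | transect pair)`
with disturbance coded on-trail = 1.  Families: negative binomial (log
mean link, log shape link; variance mu + mu²/phi) for rounded sizes; Beta
(mean mu, precision phi_beta; log precision link) for relative
reproduction and percent cover.  The Beta mean link defaults to **logit**:
a log mean link cannot produce means inside (0,1) at intercepts of the
magnitude the reference estimates carry (e.g. 6.58), so the log link —
implemented and selectable — rejects out-of-range means at -inf rather
than erroring.

Priors (configurable): Student-t(3, 0, 10) on each fixed effect — wide
enough for coefficients of magnitude ~20 on the raw scale —
half-Student-t(3, 0, 2.5) on `sigma_pair`, Normal(0, 2.5²) on the log
auxiliary parameter, `u_j ~ N(0, sigma_pair²)`.

**Sampler.**  Adaptive random-walk Metropolis-within-Gibbs: component-wise
updates of the fixed effects, a simultaneous per-group update of the
random intercepts (valid because the likelihood factorizes over pairs),
and scalar updates of `log sigma_pair` (prior-only conditional) and the
log auxiliary parameter.  Proposal scales adapt toward a 20–40% acceptance
window during warmup and are frozen afterwards.  Defaults are 3 chains of
5000 iterations with the first 1000 discarded as warmup (interpreted as
total iterations, 4000 retained per chain); this simple kernel needs more
iterations than a Hamiltonian sampler for the same effective sample size,
and the calibration experiments below use 3 x 1500 (500 warmup), which
yields bulk ESS of several hundred for the well-mixing parameters.

Two parameterization details matter for mixing and are exact (no
approximation in reported estimates):

* Internally the sampler works on a near-orthogonal design — centred
  disturbance, standardized elevation `z`, and their product — because the
  raw product column D*E is almost collinear with D when elevation varies
  little relative to its mean.  Draws are mapped back to the raw per-metre
  scale through the exact linear transform, and priors are evaluated on
  the raw-scale coefficients, so the reported posterior is exactly the
  documented model.
* Because elevation is constant within a pair, the intercept and the
  elevation coefficient are confounded with the random-intercept vector.
  The sampler adds likelihood-invariant "ridge" translation moves (shift a
  group-constant fixed effect, counter-shift all `u_j`), accepted on the
  prior ratio alone.  Without these moves those coefficients mix an order
  of magnitude more slowly.

Initialization is zero on the sampling scale for Beta-family models
(cover and reproduction) and data-informed (log mean response) for NB
models.  A constant disturbance column warns about unidentifiability and
fits anyway (the coefficient follows its prior); a non-finite posterior at
initialization raises with advice to rescale or re-seed.

**Inference rule.**  An effect is inferred when the equal-tailed 95%
credible interval of a coefficient excludes zero.  Note that with the
interaction fit on raw metres, the marginal coefficient `bD` is the
disturbance contrast extrapolated to elevation 0, and its posterior is
wide because it is entangled with the interaction term; the calibration
experiments in the test suite therefore evaluate the disturbance contrast
at the survey's mean elevation (`bD + bDE * mean(E)`), which is the
identified, scientifically meaningful effect and equals `bD` whenever the
true interaction is zero.  Reported tables keep the raw coefficients so
they are comparable to published per-metre estimates.

## Diagnostics

Split-R-hat uses the between/within chain-variance form on half-split
chains (constant draws return 1.0 with a degeneracy flag).  Bulk ESS uses
rank-normalized draws, FFT autocovariances, and Geyer's initial-monotone
positive-pair truncation; tail ESS is the minimum ESS of the 5%/95%
exceedance indicators.  The posterior predictive check simulates full
replicated response vectors from the fitted family and locates the
observed Fisher-Pearson skewness (`g1 = m3 / m2^{3/2}`, unadjusted) within
the replicate distribution (two-sided tail probability).  PSIS-LOO builds
per-observation importance ratios from pointwise log-likelihoods, fits a
generalized Pareto distribution to the largest ~20% of ratios by the
Zhang–Stephens profile-likelihood method (with the usual weak
regularization of k toward 0.5), replaces tail weights by expected GPD
order statistics truncated at the raw maximum, and reports `elpd_loo` and
per-observation Pareto-k values with counts above 0.5 and 0.7.  All
diagnostics are unit-tested against closed forms (iid and AR(1)
references) and cross-checked against arviz.

## Pipeline and problem sizes

`pipeline.run_pipeline` executes simulate-or-ingest -> cover -> traits ->
fits -> diagnostics with per-stage structured logging (row counts and
seeds, so exclusions are auditable) and writes per-model JSON plus a
combined CSV (species, trait, N, four coefficients with CIs and effect
flags).  Simulate mode writes the synthetic fixtures and then runs the
ingest path on them, making the simulate/ingest round-trip identity hold
by construction.  The default job manifest is the twelve models of the
field analysis (cover + 4 species x height/diameter + 3 shrub
reproduction models); reproduction jobs are auto-skipped for taxa without
counts.

The calibration experiments and the acceptance script run the sampler at
3 chains x 1500 iterations (500 warmup) and default survey size (14 pairs
x 10 quadrats; n ≈ 300–900 per model, 64 x 64-pixel quadrat images) —
sizes chosen so the full suite completes on a single CPU in a few minutes
while leaving bulk ESS in the hundreds.

## Known limitations

* The random-walk kernel mixes slowly for strongly correlated posteriors
  beyond the ridges handled explicitly; very small groups or separated
  likelihoods may need longer chains.
* The Beta model treats quadrat cover fractions as exchangeable given the
  pair intercept; pixel-count precision (n_green/n_total) is not
  propagated.
* The cover classifier is a channel-dominance rule, not segmentation:
  green-ish non-vegetation (e.g., lichens) would count as cover.
* Relative reproduction depends on a species-wide maximum estimated from
  the sample; with few individuals it is noisy, and the all-zero case is
  flagged rather than modeled.
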