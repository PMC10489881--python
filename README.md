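# trailside

Analysis toolkit for **paired trail-side / off-trail trampling surveys**
of subalpine and alpine vegetation, built for ecologists quantifying how
hiker trampling affects plant communities along elevational gradients.
It covers the full chain from raw field inputs to effect estimates:

1. **Percent cover from quadrat photographs** — boost HSV saturation by a
   factor of 30 to wash out shading (hue-preserving), classify each pixel
   as vegetation when its green digital number strictly exceeds both red
   and blue, and report the exact fraction of qualifying pixels.
2. **Trait derivation** — plant area as height x diameter, summed
   bud/flower/fruit counts, area-standardized reproduction, and relative
   reproduction (scaled by the species-wide maximum), plus the response
   preparation each model family needs (nearest-integer rounding for
   counts, open-interval adjustment for proportions).
3. **Hierarchical Bayesian models** — for percent cover and for each
   species-by-trait combination,

   ```
   response ~ disturbance * elevation + (1 | transect pair)
   ```

   with a negative binomial family (log link, shape phi) for sizes and a
   Beta family (logit mean link, precision phi) for proportions, fit by
   an adaptive Metropolis-within-Gibbs sampler written for this model
   class.  An effect is inferred when the 95% equal-tailed credible
   interval of a coefficient excludes zero.
4. **Diagnostics** — split-R-hat, rank-normalized bulk/tail ESS,
   Fisher-Pearson-skew posterior predictive checks, and PSIS-LOO with
   per-observation Pareto-k values.
5. **Synthetic surveys** — a generator that emulates the paired-transect
   design (14 pairs of 10 contiguous 1 m x 0.5 m quadrats, 1580–1980 m
   elevation, up to five randomly selected individuals per species per
   quadrat, four focal taxa with species-specific disturbance effects,
   painted quadrat images with exact known cover), so every stage is
   testable with no field data.

See `docs/methods.md` for the models, priors, sampler, and design
choices in detail.

## Worked example

Simulate a survey from the reference presets, estimate cover from the
painted quadrat images, and fit the percent-cover model:

```python
import numpy as np
from trailside import synthetic as syn, traits as tr, glmm, cover as cov

cfg = syn.SimConfig(seed=1)                      # 14 pairs x 10 quadrats
design = syn.make_design(cfg)
species, cover_params = syn.reference_presets()

imgs, truth = syn.simulate_cover_images(design, cover_params, cfg, seed=1)
fractions = np.array([cov.estimate_cover(im).green_fraction for im in imgs])
truth["percent_cover"] = tr.adjust_unit_interval(fractions)

spec = glmm.ModelSpec(response="percent_cover", family="beta")
data = glmm.build_model_data(truth, spec)
draws = glmm.sample_posterior(data, spec, chains=3, iterations=1500,
                              warmup=500, seed=1)
print(glmm.summarize_fit(draws, n_obs=data.n).table.loc[
    ["intercept", "b_disturbance", "b_elevation", "b_interaction"]].round(3))
```

which prints

```
                 mean    q2.5  q97.5   rhat  ess_bulk  ess_tail  effect
intercept       6.220   3.173  9.161  1.008   598.918   577.233    True
b_disturbance -10.653 -13.886 -7.625  1.003   511.343   525.443    True
b_elevation    -0.003  -0.004 -0.001  1.008   606.109   552.001    True
b_interaction   0.003   0.002  0.005  1.002   525.417   522.848    True
```

`b_disturbance` is the logit-scale trail-side contrast: strongly
negative with a credible interval far from zero (`effect = True`), i.e.
trampling sharply reduces green cover, while the per-metre elevation
terms are tiny.  The convergence columns (split-R-hat near 1, effective
sample sizes in the hundreds) say the chains mixed.

The same thing from the shell, end to end (simulation → images → cover →
traits → twelve model fits → combined report):

```sh
trailside pipeline --config examples/pipeline.yaml
trailside cover --input run/images --output cover.csv
trailside fit --data plants.csv --response height_cm --family nb --seed 1
```

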