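# trajmix

Latent trajectory-class analysis of longitudinal neurocognition, built for
studying "SuperAging" in older adults living with HIV — and for anyone who
needs a tested, pure-Python growth mixture model (GMM) pipeline with
full-information maximum likelihood (FIML) for visit dropout.

Cross-sectional work suggests a subgroup of older people with HIV performs
like healthy 25-year-olds.  Whether that youthful performance is *stable*
is a longitudinal question: follow a cohort over repeated visits, norm each
visit's test battery against young-adult ("peak-age") expectations, and ask
whether the trajectories sort into latent classes — and what baseline
biology and reserve predict class membership.  `trajmix` implements that
whole analysis on synthetic cohorts with known ground truth, so every stage
is verifiable:

* **`trajmix.synth`** — cohort generator: quadratic latent-class growth
  with shared random effects, covariates tied to class by a multinomial
  logit, monotone MAR dropout driven by education and enrollment date, and
  39 dichotomous health items.
* **`trajmix.norming`** — demographic regression norms, practice-effect
  correction, peak-age (age-25 substitution) and chronological T-scores:
  `T = 50 + 10 (raw − prediction)/residual SD`.
* **`trajmix.classify`** — baseline SuperAger / cognitively normal /
  impaired status via the peak-age −1 SD rule and the global deficit score.
* **`trajmix.reserve`** — a 39-criterion deficit-accumulation physiologic
  reserve index (normal count / available count ∈ [0, 1]).
* **`trajmix.gmm`** — the GMM engine: for class k,
  `y_i ~ N(Xα_k, ZΨZ' + Θ)` on each participant's observed visits, fitted
  by monotone multi-start EM; AIC/BIC/ssBIC, entropy, Lo–Mendell–Rubin
  test, bootstrap LRT, class-size adequacy, auxiliary missingness
  correlates, baseline-free secondary fits.
* **`trajmix.posthoc`** — the 3-step analysis: modal assignment first, then
  univariable screening and pruned multinomial logistic regression with
  per-SD odds ratios.
* **`trajmix.pipeline` / `trajmix` CLI** — end-to-end orchestration with
  seed-stamped, byte-reproducible output bundles.

## Worked example

Fit a 3-class quadratic growth mixture to a generated cohort:

```python
import numpy as np
from trajmix import synth, gmm

cfg = synth.GeneratorConfig(n_participants=4000, seed=11,
                            missingness_model=synth.MissingnessModel(enabled=False))
cohort = synth.generate(cfg)
panel = gmm.VisitPanel(cohort.panel())
fit = gmm.em_fit(panel, gmm.GrowthSpec(), K=3, n_starts=12, seed=7)

np.set_printoptions(suppress=True)
print("mixing proportions:", fit.pi.round(3))
print("growth means (intercept, linear, quadratic):")
print(fit.alpha.round(3))
print("entropy:", round(gmm.fit_indices(fit, panel.n)["entropy"], 3))
```

Output from this exact run:

```
mixing proportions: [0.168 0.546 0.286]
growth means (intercept, linear, quadratic):
[[49.795  0.074  0.036]
 [41.953 -0.438  0.068]
 [34.19  -1.008  0.117]]
entropy: 0.92
```

The three rows are the recovered classes in descending-intercept order —
a stable high-performing class near T = 50 (about 17% of the cohort), a
mid-level class starting near 42 with a shallow U-shaped course, and a low
class starting near 34 with a steeper U — recovering the generating means
(49.62, 0.04, 0.04), (41.91, −0.45, 0.07), (34.22, −1.04, 0.12) and shares
(16.8%, 54.3%, 28.8%) to within Monte-Carlo error, with crisp class
separation (entropy 0.92).

The same analysis end to end, from the shell:

```sh
trajmix run --seed 11 --kmax 4 --starts 20 --outdir myrun
```

writes the class-solution table, per-class trajectory means, baseline
status and reserve indices, concordance cross-tabs, the predictor
odds-ratio table, and a manifest with the seed and file hashes.

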