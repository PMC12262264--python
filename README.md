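# shade

Hierarchical Bayesian estimation of **directional, distance-resolved
spatial associations between cell types** in multiplexed tissue images.

Multiplexed imaging (mIF, CODEX and kin) yields point patterns of typed
cells across images nested in patients nested in cohorts. A recurring
question is whether one cell type arranges itself *around* another —
T cells near tumor cells, granulocytes near vessels — and at what
distances. Classical summaries (Ripley's K, G-cross) are symmetric or
image-by-image; this package instead models the **conditional intensity**
of a target type given the source patterns,

    log λ(v) = z(v)ᵀβ + Σ_k q_Ak(v)ᵀ δ_Ak,   q_Ak(v)_p = Σ_{x∈X_Ak} φ_p(‖v−x‖),

and summarizes each source's effect as a **spatial interaction curve**

    SIC_{Ak→B}(s) = Σ_p δ_Ak,p φ_p(s),

the log-intensity contribution of one source cell at distance s (positive
= attraction, negative = repulsion). Coefficients are pooled through a
three-level Gaussian hierarchy — cohort ψ → patient γ → image δ — so
sparse images borrow strength from their patient and cohort. The Poisson
point-process likelihood is fitted through the dummy-point logistic
approximation, and the posterior is sampled with a No-U-Turn sampler
with analytic gradients. The package also ships the synthetic-data
generator for multilevel patterns, a non-hierarchical ("flat") baseline,
G-cross envelope tests and a G-cross cohort screen, conditional-intensity
prediction maps with AUC evaluation, and posterior summaries (credible
bands, sign detection, cohort differences, MAD heterogeneity).

Intended users: computational biologists and biostatisticians analyzing
multiplexed tissue point patterns, and methodologists who need a
reproducible simulation/benchmark harness for multilevel spatial models.

## Worked example

```python
import numpy as np, shade

cfg = shade.SimulationConfig(patients_per_cohort=3, images_per_patient=2,
                             n_source=100, n_target=100, window_side=1000.0,
                             seed=7)
study = shade.simulate_study(cfg)                       # 12 images, 6 patients
designs = shade.study_designs_to_model_inputs(study, np.random.default_rng(8))
fit = shade.fit_shade(designs, study.design,
                      sampler=shade.SamplerConfig(chains=2, warmup=400,
                                                  draws=400, seed=9))
```

Running `python examples/simulate_and_fit.py` (the same code) prints:

```
simulated 12 images, 6 patients, 2 cohorts
divergences: 0, max split-Rhat: 1.015, min ESS: 121
cohort-level coefficients (short/medium/long-range kernels):
  C0: truth [1.5 1.  0.5] -> posterior mean [1.59 1.06 0.22]
  C1: truth [-1.5 -1.  -0.5] -> posterior mean [-1.45 -1.21 -0.31]
```

The two cohorts were simulated with opposite-sign interaction curves
(attraction vs repulsion of T cells around tumor cells at 20/40/60 μm);
the cohort-level posterior means recover the generating coefficients, and
the diagnostics line shows the sampler converged. From a fit you can then
reconstruct curves and their 95% bands, classify signs at probe distances,
difference two cohorts, or map predicted intensity:

```python
curve = shade.sic_curve(fit, cfg.basis, "cohort", "C0", "tumor",
                        np.arange(0.0, 101.0))
shade.sign_detection(curve, [20, 40, 60])   # ['positive', 'positive', 'positive']
```

The `examples/` directory has one short script per capability
(simulation+fit, SIC summaries, group differences and heterogeneity,
G-cross baselines, prediction maps). Real data enter as a CSV of
`x, y, cell_type, image_id, patient_id, group_id` (μm) plus an optional
per-image window CSV — see `shade.read_patterns_csv`. A thin CLI mirrors
the library: `shade simulate|fit|sic|gcross|predict|study1|study2`,
each writing a provenance record beside its outputs.

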