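"""Simulate a small multilevel study and fit the hierarchical model.

Two cohorts with opposite-sign spatial interaction curves (attraction vs
repulsion of T cells around tumor cells), three patients per cohort, two
images per patient. The fit recovers the cohort-level coefficients that
generated the data.
"""

import numpy as np

import shade

cfg = shade.SimulationConfig(patients_per_cohort=3, images_per_patient=2,
                             n_source=100, n_target=100, window_side=1000.0,
                             seed=7)
study = shade.simulate_study(cfg)
print(f"simulated {study.design.n_images} images, "
      f"{study.design.n_patients} patients, {study.design.n_cohorts} cohorts")

designs = shade.study_designs_to_model_inputs(study, np.random.default_rng(8))
fit = shade.fit_shade(designs, study.design,
                      sampler=shade.SamplerConfig(chains=2, warmup=400, draws=400,
                                                  seed=9))

print(f"divergences: {fit.diagnostics['divergences']}, "
      f"max split-Rhat: {fit.diagnostics['max_rhat']:.3f}, "
      f"min ESS: {fit.diagnostics['min_ess']:.0f}")

est = fit.psi.mean(axis=(0, 1))  # (cohorts, sources, basis)
print("\ncohort-level coefficients (short/medium/long-range kernels):")
for g, cid in enumerate(study.design.cohort_ids):
    print(f"  {cid}: truth {np.round(study.truth.psi[g, 0], 2)} "
          f"-> posterior mean {np.round(est[g, 0], 2)}")
print("\npositive coefficients mean attraction at that range, negative repulsion;")
print("posterior means close to truth show the cascade is identified.")
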