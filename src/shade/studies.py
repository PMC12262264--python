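"""Replicate simulation-study harnesses.

Two harnesses tie the simulator, the two model fits and the baselines
together:

* ``run_rmse_study`` — simulate a multilevel study, fit the hierarchical
  and the flat model to each replicate, and tabulate coefficient RMSE by
  spatial scale (the partial-pooling benefit study).
* ``run_detection_study`` — simulate responder/non-responder cohorts with
  opposite-sign interaction curves and score, per image and per test
  distance (20/40/60 μm), whether each method (hierarchical, flat,
  G-cross envelope) detects the correct interaction sign.

Replicate r derives its seed as ``base_seed + r`` so replicate sets can be
extended without reshuffling earlier ones. Replicates whose sampler run
fails are excluded and counted.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .gcross import csr_envelope
from .model import PriorConfig, SamplerConfig, fit_flat, fit_shade
from .sic import sic_curve, sign_detection
from .simulate import (SimulationConfig, rmse_eval, simulate_study,
                       study_designs_to_model_inputs)

log = logging.getLogger("shade")

TEST_DISTANCES = (20.0, 40.0, 60.0)


def _replicate_seed(base_seed: int, r: int) -> int:
    return int((base_seed + r) % (2 ** 31 - 1))


def run_rmse_study(config: SimulationConfig, replicates: int, base_seed: int = 0,
                   sampler: SamplerConfig = SamplerConfig(chains=2, warmup=400, draws=400),
                   priors: PriorConfig = PriorConfig()) -> pd.DataFrame:
    """Fit hierarchical and flat models to each replicate; tabulate RMSE by scale.

    Returns one row per (replicate, model) with aggregate and per-scale RMSE.
    Failed replicates are logged, excluded, and counted in the attribute
    ``df.attrs["n_failed"]``.
    """
    rows, n_failed = [], 0
    for r in range(replicates):
        seed = _replicate_seed(base_seed, r)
        try:
            study = simulate_study(replace(config, seed=seed))
            rng = np.random.default_rng(seed + 10_007)
            designs = study_designs_to_model_inputs(study, rng)
            fits = {
                "hierarchical": fit_shade(designs, study.design, priors=priors,
                                          sampler=replace(sampler, seed=seed)),
                "flat": fit_flat(designs, priors=priors,
                                 sampler=replace(sampler, seed=seed + 1)),
            }
            for name, fit in fits.items():
                res = rmse_eval(fit, study.truth, config.basis.scale_map,
                                design=study.design)
                rows.append({"replicate": r, "model": name,
                             "aggregate": res["aggregate"], "small": res["small"],
                             "medium": res["medium"], "large": res["large"]})
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            log.warning("replicate %d failed: %s", r, exc)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


def summarize_rmse(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and 2.5/97.5% replicate quantiles of RMSE per model and scale."""
    melted = df.melt(id_vars=["replicate", "model"],
                     value_vars=["aggregate", "small", "medium", "large"],
                     var_name="scale", value_name="rmse")
    return (melted.groupby(["model", "scale"])["rmse"]
            .agg(mean="mean", lo=lambda v: v.quantile(0.025),
                 hi=lambda v: v.quantile(0.975))
            .reset_index())


def _truth_sign(truth_delta_row: np.ndarray, spec, distance: float) -> str:
    from .basis import eval_basis
    val = float(truth_delta_row @ eval_basis(spec, [distance])[0])
    return "positive" if val > 0 else "negative" if val < 0 else "undetected"


def run_detection_study(config: SimulationConfig, replicates: int,
                        base_seed: int = 0,
                        sampler: SamplerConfig = SamplerConfig(chains=2, warmup=400,
                                                               draws=400),
                        priors: PriorConfig = PriorConfig(),
                        distances=TEST_DISTANCES,
                        n_sim_envelope: int = 39) -> pd.DataFrame:
    """Score sign-detection accuracy of SHADE, flat and G-cross per replicate.

    For each image and test distance, the realized image-level truth curve
    supplies the true sign; a method is correct when its detection label
    matches it. Returns one row per (replicate, method) with the proportion
    correct over images x distances.
    """
    rows, n_failed = [], 0
    spec = config.basis
    for r in range(replicates):
        seed = _replicate_seed(base_seed, r)
        try:
            study = simulate_study(replace(config, seed=seed))
            rng = np.random.default_rng(seed + 10_007)
            designs = study_designs_to_model_inputs(study, rng)
            hier = fit_shade(designs, study.design, priors=priors,
                             sampler=replace(sampler, seed=seed))
            flat = fit_flat(designs, priors=priors,
                            sampler=replace(sampler, seed=seed + 1))
            r_grid = np.linspace(0.0, max(distances) + 20.0, 81)
            grid = np.arange(0.0, spec.r_max + 1.0, 1.0)
            correct = {"shade": [], "flat": [], "gcross": []}
            env_rng = np.random.default_rng(seed + 20_011)
            for image_id in study.design.image_ids:
                m = study.design.image_index(image_id)
                truth_row = study.truth.delta[m, 0]
                truths = [_truth_sign(truth_row, spec, s) for s in distances]
                for name, fit in (("shade", hier), ("flat", flat)):
                    if image_id not in fit.image_ids:
                        correct[name].extend([False] * len(distances))
                        continue
                    curve = sic_curve(fit, spec, "image", image_id, fit.source_types[0],
                                      grid)
                    labels = sign_detection(curve, distances)
                    correct[name].extend(l == t for l, t in zip(labels, truths))
                entry = study.patterns[image_id]
                src = next(iter(entry["sources"].values()))
                tgt = entry["target"]
                if src.n == 0 or tgt.n == 0:
                    correct["gcross"].extend([False] * len(distances))
                else:
                    res = csr_envelope(src, tgt, r_grid, n_sim=n_sim_envelope,
                                       rng=env_rng, detection_distances=distances)
                    labels = [res.detections[float(s)] for s in distances]
                    correct["gcross"].extend(l == t for l, t in zip(labels, truths))
            for name, vals in correct.items():
                rows.append({"replicate": r, "method": name,
                             "n_source": config.n_source, "n_target": config.n_target,
                             "images_per_patient": config.images_per_patient,
                             "proportion_correct": float(np.mean(vals))})
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            log.warning("replicate %d failed: %s", r, exc)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


def run_detection_grid(base_config: SimulationConfig, densities=(15, 150),
                       images_per_patient=(1, 2, 3), replicates: int = 30,
                       base_seed: int = 0, **kwargs) -> pd.DataFrame:
    """Full detection-accuracy condition grid: density pairs x images-per-patient."""
    frames = []
    offset = 0
    for n_t in densities:
        for n_s in densities:
            for ipp in images_per_patient:
                cfg = replace(base_config, n_target=n_t, n_source=n_s,
                              images_per_patient=ipp)
                df = run_detection_study(cfg, replicates,
                                         base_seed=base_seed + offset, **kwargs)
                frames.append(df)
                offset += replicates
    return pd.concat(frames, ignore_index=True)
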