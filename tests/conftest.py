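import numpy as np
import pytest

import shade
from shade.model import PosteriorDraws
from shade.patterns import StudyDesign


def make_draws(delta, beta=None, psi=None, gamma=None, sigmas=None,
               source_types=("tumor",), image_ids=None, design=None,
               hierarchical=None) -> PosteriorDraws:
    """Build a PosteriorDraws object from raw coefficient arrays.

    ``delta`` has shape (S, M, K, P) (a single chain is added); psi/gamma
    similarly without the chain axis. Used to test posterior summaries with
    exactly known coefficient draws.
    """
    delta = np.asarray(delta, float)[None]  # add chain axis
    S, M = delta.shape[1], delta.shape[2]
    if beta is None:
        beta = np.zeros((1, S, M, 1))
    else:
        beta = np.asarray(beta, float)[None]
    if image_ids is None:
        image_ids = tuple(f"I{m}" for m in range(M))
    if hierarchical is None:
        hierarchical = psi is not None
    return PosteriorDraws(
        delta=delta, beta=beta,
        psi=None if psi is None else np.asarray(psi, float)[None],
        gamma=None if gamma is None else np.asarray(gamma, float)[None],
        sigmas=None if sigmas is None else np.asarray(sigmas, float)[None],
        source_types=tuple(source_types), image_ids=tuple(image_ids),
        design_meta=design, diagnostics={}, hierarchical=hierarchical)


def balanced_design(n_cohorts=2, patients_per_cohort=2, images_per_patient=2):
    cohorts = tuple(f"C{g}" for g in range(n_cohorts))
    patient_ids, pc, image_ids, ip = [], [], [], []
    n = 0
    for g in range(n_cohorts):
        for _ in range(patients_per_cohort):
            patient_ids.append(f"P{n}")
            pc.append(g)
            for j in range(images_per_patient):
                image_ids.append(f"I{n}_{j}")
                ip.append(n)
            n += 1
    return StudyDesign(tuple(image_ids), tuple(patient_ids), cohorts,
                       np.array(ip), np.array(pc))


@pytest.fixture(scope="session")
def rbf3():
    return shade.study_rbf_basis()


@pytest.fixture(scope="session")
def small_study():
    """A small but informative simulated study reused across fitting tests."""
    cfg = shade.SimulationConfig(patients_per_cohort=2, images_per_patient=2,
                                 n_source=80, n_target=80, window_side=1000.0,
                                 seed=11)
    return shade.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_designs(small_study):
    rng = np.random.default_rng(23)
    return shade.study_designs_to_model_inputs(small_study, rng)


@pytest.fixture(scope="session")
def small_hier_fit(small_study, small_designs):
    return shade.fit_shade(
        small_designs, small_study.design,
        sampler=shade.SamplerConfig(chains=1, warmup=300, draws=400, seed=3))


@pytest.fixture(scope="session")
def small_flat_fit(small_designs):
    return shade.fit_flat(
        small_designs,
        sampler=shade.SamplerConfig(chains=1, warmup=300, draws=400, seed=4))
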