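"""The hierarchical logistic posterior: closed forms, gradients, fitting behavior."""

import warnings

import numpy as np
import pytest
from scipy.special import log_expit

import shade
from conftest import balanced_design
from shade.basis import BasisSpec
from shade.design import DesignMatrix
from shade.model import (CoefficientTree, PriorConfig, SamplerConfig,
                         VarianceComponents, _HierModel, _stack_designs,
                         fit_flat, fit_shade, log_posterior)
from shade.patterns import PointPattern, StudyDesign, Window


def _tiny_design(y, Q, offset, spec, image_id="I0"):
    n = len(y)
    return DesignMatrix(y=np.asarray(y, float), Z=np.ones((n, 1)),
                        Q=np.asarray(Q, float), offset=float(offset),
                        coords=np.zeros((n, 2)), source_types=("tumor",),
                        spec=spec, lambda_dummy=float(np.exp(offset)),
                        image_id=image_id)


def _single_unit_meta():
    return StudyDesign(("I0",), ("P0",), ("C0",), np.array([0]), np.array([0]))


@pytest.fixture
def spec1():
    return BasisSpec.gaussian_rbf(centers=[30.0], widths=10.0, r_max=80.0)


def test_zero_coefficients_closed_form(spec1):
    # with every coefficient zero the logit is -log(lambda_dummy) on all rows
    offset = np.log(2.0)
    y = [1, 1, 0, 0, 0]
    Q = np.random.default_rng(0).random((5, 1))
    d = _tiny_design(y, Q, offset, spec1)
    meta = _single_unit_meta()
    tree = CoefficientTree(psi=np.zeros((1, 1, 1)), gamma=np.zeros((1, 1, 1)),
                           delta=np.zeros((1, 1, 1)), beta=np.zeros((1, 1)))
    vc = VarianceComponents(0.7, 0.8, 0.9)
    pr = PriorConfig()
    got = log_posterior(tree, vc, [d], meta, pr)
    lik = 2 * log_expit(-offset) + 3 * log_expit(offset)
    prior = (-np.log(0.7) - np.log(0.8) - np.log(0.9) - np.log(pr.beta_scale)
             - 0.5 * (0.7 ** 2 + 0.8 ** 2 + 0.9 ** 2))
    assert got == pytest.approx(lik + prior, rel=1e-12)


def test_hand_computed_three_row_posterior(spec1):
    # one image, three rows, hand-summed Bernoulli terms plus prior terms
    offset = 0.5
    Q = np.array([[0.2], [1.0], [0.0]])
    y = np.array([1.0, 0.0, 1.0])
    d = _tiny_design(y, Q, offset, spec1)
    meta = _single_unit_meta()
    psi, gamma, delta, b0 = 0.3, 0.5, 1.5, -0.2
    tree = CoefficientTree(psi=np.full((1, 1, 1), psi), gamma=np.full((1, 1, 1), gamma),
                           delta=np.full((1, 1, 1), delta), beta=np.full((1, 1), b0))
    vc = VarianceComponents(1.0, 0.5, 2.0)
    eta = b0 + Q[:, 0] * delta - offset
    lik = sum(e if yi == 1 else 0.0 for e, yi in zip(eta, y)) \
        - sum(np.log1p(np.exp(e)) for e in eta)
    prior = (-0.5 * psi ** 2 - np.log(1.0)
             - 0.5 * ((gamma - psi) / 0.5) ** 2 - np.log(0.5)
             - 0.5 * ((delta - gamma) / 2.0) ** 2 - np.log(2.0)
             - 0.5 * (b0 / 5.0) ** 2 - np.log(5.0)
             - 0.5 * (1.0 ** 2 + 0.5 ** 2 + 2.0 ** 2))
    got = log_posterior(tree, vc, [d], meta)
    assert got == pytest.approx(lik + prior, rel=1e-10)


def test_logit_shift_changes_likelihood_as_predicted(spec1):
    # raising the one-row logit by eps changes the Bernoulli term by
    # eps - [softplus(eta+eps) - softplus(eta)] for a label-1 row
    offset = 0.0
    d = _tiny_design([1.0], [[1.0]], offset, spec1)
    meta = _single_unit_meta()
    vc = VarianceComponents(1.0, 1.0, 1.0)

    def lp(delta, b0):
        tree = CoefficientTree(psi=np.zeros((1, 1, 1)), gamma=np.zeros((1, 1, 1)),
                               delta=np.full((1, 1, 1), delta),
                               beta=np.full((1, 1), b0))
        return log_posterior(tree, vc, [d], meta)

    eps = 0.37
    base_eta = 0.8
    got = lp(base_eta + eps, 0.0) - lp(base_eta, 0.0)
    predicted_lik = eps - (np.logaddexp(0, base_eta + eps) - np.logaddexp(0, base_eta))
    predicted_prior = -0.5 * (base_eta + eps) ** 2 + 0.5 * base_eta ** 2
    assert got == pytest.approx(predicted_lik + predicted_prior, rel=1e-10)
    # compensating the shift through beta restores the likelihood part exactly
    lik_only = (lp(base_eta + eps, -eps) - lp(base_eta, 0.0)) - predicted_prior \
        - (-0.5 * eps ** 2 / 25.0)
    assert lik_only == pytest.approx(0.0, abs=1e-10)


def test_non_finite_features_rejected(spec1):
    d = _tiny_design([1.0, 0.0], [[np.nan], [0.0]], 0.0, spec1)
    tree = CoefficientTree(psi=np.zeros((1, 1, 1)), gamma=np.zeros((1, 1, 1)),
                           delta=np.zeros((1, 1, 1)), beta=np.zeros((1, 1)))
    with pytest.raises(ValueError):
        log_posterior(tree, VarianceComponents(1, 1, 1), [d], _single_unit_meta())


def test_hierarchical_gradient_matches_finite_differences(small_designs, small_study):
    data = _stack_designs(small_designs)
    model = _HierModel(data, small_study.design, np.array(data.kept), PriorConfig())
    rng = np.random.default_rng(9)
    x = 0.3 * rng.standard_normal(model.dim)
    lp, grad = model.logp_grad(x)
    h = 1e-6
    for i in rng.choice(model.dim, size=12, replace=False):
        e = np.zeros(model.dim)
        e[i] = h
        num = (model.logp_grad(x + e)[0] - model.logp_grad(x - e)[0]) / (2 * h)
        assert num == pytest.approx(grad[i], rel=5e-4, abs=1e-5)


def test_fit_deterministic_given_seed(small_designs):
    s = SamplerConfig(chains=1, warmup=100, draws=100, seed=5)
    a = fit_flat(small_designs, sampler=s)
    b = fit_flat(small_designs, sampler=s)
    np.testing.assert_array_equal(a.delta, b.delta)


def test_identical_images_have_exchangeable_posteriors(spec1):
    # duplicate one image's design under two patients of one cohort
    rng = np.random.default_rng(3)
    w = Window.square(500.0)
    src = {"tumor": PointPattern.from_coords(w.sample_uniform(60, rng), w, "tumor")}
    tgt = PointPattern.from_coords(w.sample_uniform(60, rng), w, "tcell")
    d0 = shade.build_design(tgt, src, spec1, rng=np.random.default_rng(1), image_id="A")
    d1 = shade.build_design(tgt, src, spec1, rng=np.random.default_rng(1), image_id="B")
    meta = StudyDesign(("A", "B"), ("P0", "P1"), ("C0",),
                       np.array([0, 1]), np.array([0, 0]))
    fit = fit_shade([d0, d1], meta,
                    sampler=SamplerConfig(chains=1, warmup=300, draws=300, seed=2))
    m = fit.delta.mean(axis=(0, 1))
    mc_sd = fit.delta.std() / np.sqrt(fit.diagnostics["min_ess"])
    assert np.all(np.abs(m[0] - m[1]) < 6 * mc_sd + 0.05)


def test_tiny_image_scale_collapses_delta_to_gamma(small_designs, small_study):
    pr = PriorConfig(sigma_image_scale=1e-3)
    fit = fit_shade(small_designs, small_study.design, priors=pr,
                    sampler=SamplerConfig(chains=1, warmup=250, draws=250, seed=6))
    delta = fit.delta.mean(axis=(0, 1))  # (M, K, P)
    gamma = fit.gamma.mean(axis=(0, 1))  # (N, K, P)
    gaps = np.abs(delta - gamma[small_study.design.image_patient])
    assert gaps.max() < 0.02


def test_single_image_flat_and_hierarchical_agree(spec1):
    rng = np.random.default_rng(4)
    w = Window.square(600.0)
    src = {"tumor": PointPattern.from_coords(w.sample_uniform(80, rng), w, "tumor")}
    tgt = PointPattern.from_coords(w.sample_uniform(80, rng), w, "tcell")
    d = shade.build_design(tgt, src, spec1, rng=np.random.default_rng(2), image_id="I0")
    meta = _single_unit_meta()
    # weak hierarchy scales make the hierarchical single-image fit ~ flat
    pr = PriorConfig(sigma_cohort_scale=5.0, sigma_patient_scale=5.0,
                     sigma_image_scale=5.0)
    hier = fit_shade([d], meta, priors=pr,
                     sampler=SamplerConfig(chains=1, warmup=300, draws=300, seed=7,
                                           max_treedepth=8))
    flat = fit_flat([d], sampler=SamplerConfig(chains=1, warmup=300, draws=300, seed=8))
    mh = hier.delta.mean(axis=(0, 1)).ravel()
    mf = flat.delta.mean(axis=(0, 1)).ravel()
    sd = flat.delta.reshape(-1, flat.delta.shape[-1]).std(axis=0).ravel()
    assert np.all(np.abs(mh - mf) < 0.5 * sd + 0.1)


def test_prior_cascade_from_data_free_fit(spec1):
    # with features zeroed and a single uninformative row per image, the
    # coefficient draws must reproduce the Gaussian cascade
    meta = balanced_design(n_cohorts=1, patients_per_cohort=4, images_per_patient=2)
    designs = [_tiny_design([1.0], [[0.0]], 0.0, spec1, image_id=iid)
               for iid in meta.image_ids]
    fit = fit_shade(designs, meta,
                    sampler=SamplerConfig(chains=2, warmup=500, draws=1000, seed=9))
    gam = fit.gamma.reshape(-1, meta.n_patients)
    psi = fit.psi.reshape(-1, 1)
    sig = fit.sigmas.reshape(-1, 3)
    inn_p = (gam - psi)  # patient innovations, per draw
    # Var(gamma - psi) over draws x patients ~ E[sigma_patient^2]
    assert np.var(inn_p) == pytest.approx(np.mean(sig[:, 1] ** 2), rel=0.25)
    delta = fit.delta.reshape(-1, meta.n_images)
    inn_i = delta - gam[:, meta.image_patient]
    assert np.var(inn_i) == pytest.approx(np.mean(sig[:, 2] ** 2), rel=0.25)


def test_zero_target_image_dropped_with_warning(spec1):
    d_ok = _tiny_design([1.0, 0.0], [[0.1], [0.2]], 0.0, spec1, image_id="A")
    d_empty = _tiny_design([0.0, 0.0], [[0.1], [0.2]], 0.0, spec1, image_id="B")
    with pytest.warns(UserWarning, match="zero target cells"):
        fit = fit_flat([d_ok, d_empty],
                       sampler=SamplerConfig(chains=1, warmup=50, draws=50, seed=1))
    assert fit.image_ids == ("A",)
    with pytest.raises(ValueError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_flat([d_empty], sampler=SamplerConfig(chains=1, warmup=10, draws=10))


def test_partial_pooling_shrinks_image_estimates(small_study, small_hier_fit,
                                                 small_flat_fit):
    # hierarchical image coefficients sit closer to their patient means than
    # flat estimates do, on average
    meta = small_study.design
    hier_delta = small_hier_fit.delta.mean(axis=(0, 1))
    hier_gamma = small_hier_fit.gamma.mean(axis=(0, 1))
    flat_delta = small_flat_fit.delta.mean(axis=(0, 1))
    flat_patient_mean = np.stack([
        flat_delta[meta.image_patient == n].mean(axis=0)
        for n in range(meta.n_patients)])
    gap_hier = np.abs(hier_delta - hier_gamma[meta.image_patient]).mean()
    gap_flat = np.abs(flat_delta - flat_patient_mean[meta.image_patient]).mean()
    assert gap_hier < gap_flat
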