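"""Generator correctness: coefficient cascade, pattern laws, rejection sampler, RMSE."""

import numpy as np
import pytest
from scipy.stats import chisquare

import shade
from shade.model import CoefficientTree
from shade.patterns import Window
from shade.simulate import SimulationConfig


def test_zero_scatter_cascade_copies_cohort_truth():
    cfg = SimulationConfig(patients_per_cohort=3, images_per_patient=2,
                           sigma_patient=0.0, sigma_image=0.0)
    tree = shade.draw_coefficient_tree(cfg, 0)
    design = shade.simulate.make_design(cfg)
    np.testing.assert_array_equal(tree.gamma, cfg.true_psi[design.patient_cohort])
    np.testing.assert_array_equal(tree.delta, tree.gamma[design.image_patient])


def test_patient_scatter_matches_requested_variance():
    cfg = SimulationConfig(n_cohorts=1, patients_per_cohort=1000, images_per_patient=1,
                           true_psi=np.zeros((1, 1, 3)), sigma_patient=0.3)
    tree = shade.draw_coefficient_tree(cfg, 1)
    dev = tree.gamma - cfg.true_psi[0]
    # sample variance of N(0, 0.09) over 3000 values within 3 SE
    se = 0.09 * np.sqrt(2.0 / (dev.size - 1))
    assert abs(dev.var() - 0.09) < 3 * se


def test_opposite_sign_cohorts_inherit_sign_for_small_scatter():
    cfg = SimulationConfig(patients_per_cohort=4, images_per_patient=2,
                           sigma_patient=0.05, sigma_image=0.02)
    tree = shade.draw_coefficient_tree(cfg, 2)
    design = shade.simulate.make_design(cfg)
    cohort_of_image = design.patient_cohort[design.image_patient]
    assert np.all(tree.delta[cohort_of_image == 0] > 0)
    assert np.all(tree.delta[cohort_of_image == 1] < 0)


def test_fixed_count_mode_gives_exact_counts(rbf3):
    w = Window.square(800.0)
    sources, target = shade.simulate_image(np.array([[0.5, 0.2, 0.1]]), 150, 150,
                                           w, rbf3, np.random.default_rng(3))
    assert target.n == 150
    assert next(iter(sources.values())).n == 150


def test_poisson_count_mode_varies_counts(rbf3):
    w = Window.square(800.0)
    counts = []
    rng = np.random.default_rng(4)
    for _ in range(20):
        _, target = shade.simulate_image(np.zeros((1, 3)), 50, 50, w, rbf3, rng,
                                         count_mode="poisson", grid_n=32)
        counts.append(target.n)
    assert len(set(counts)) > 1
    assert abs(np.mean(counts) - 50) < 3 * np.sqrt(50 / 20)


def test_zero_interaction_targets_are_csr():
    # quadrat chi-square test rejects at ~ the nominal 5% rate
    rbf = shade.study_rbf_basis()
    w = Window.square(800.0)
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep, n_pts = 150, 128
    for _ in range(n_rep):
        _, target = shade.simulate_image(np.zeros((1, 3)), 20, n_pts, w, rbf, rng,
                                         grid_n=16)
        ix = np.minimum((target.coords[:, 0] / 200).astype(int), 3)
        iy = np.minimum((target.coords[:, 1] / 200).astype(int), 3)
        counts = np.bincount(ix * 4 + iy, minlength=16)
        rejections += chisquare(counts).pvalue < 0.05
    # binomial(150, 0.05) three-sigma band
    assert abs(rejections - 0.05 * n_rep) < 3 * np.sqrt(n_rep * 0.05 * 0.95) + 1


def test_positive_short_range_interaction_attracts_targets(rbf3):
    from scipy.spatial import cKDTree
    w = Window.square(800.0)
    rng = np.random.default_rng(6)
    closer = 0
    for _ in range(10):
        sources, target = shade.simulate_image(np.array([[2.0, 0.0, 0.0]]), 60, 80,
                                               w, rbf3, rng, grid_n=64)
        src = next(iter(sources.values()))
        tree = cKDTree(src.coords)
        d_t, _ = tree.query(target.coords)
        d_u, _ = tree.query(w.sample_uniform(80, rng))
        closer += d_t.mean() < d_u.mean()
    assert closer >= 9


def test_rejection_sampler_matches_analytic_radial_density():
    # single source at the window center, single RBF: the radial law is
    # p(r) ~ exp(c * phi(r)) * r on [0, R]
    spec = shade.BasisSpec.gaussian_rbf(centers=[60.0], widths=15.0, r_max=150.0)
    w = Window.square(400.0)
    c = 1.5
    rng = np.random.default_rng(7)
    from shade.patterns import PointPattern
    center = {"tumor": PointPattern.from_coords([[200.0, 200.0]], w, "tumor")}
    _, target = shade.simulate_image(np.array([[c]]), 1, 3000, w, spec, rng,
                                     grid_n=128, sources=center)
    r = np.hypot(target.coords[:, 0] - 200.0, target.coords[:, 1] - 200.0)
    # restrict to radii fully inside the window to keep the radial law exact
    r = r[r < 180.0]
    edges = np.linspace(0.0, 180.0, 13)
    obs, _ = np.histogram(r, bins=edges)
    rr = np.linspace(0.0, 180.0, 2001)
    phi = shade.eval_basis(spec, rr)[:, 0]
    dens = np.exp(c * phi) * rr
    probs = np.array([np.trapezoid(dens[(rr >= a) & (rr <= b)],
                                   rr[(rr >= a) & (rr <= b)]) for a, b in
                      zip(edges[:-1], edges[1:])])
    probs /= probs.sum()
    stat = chisquare(obs, probs * obs.sum())
    assert stat.pvalue > 0.001


def test_study_is_bit_reproducible():
    cfg = SimulationConfig(patients_per_cohort=2, images_per_patient=2,
                           n_source=30, n_target=30, window_side=600.0, seed=8)
    s1 = shade.simulate_study(cfg)
    s2 = shade.simulate_study(cfg)
    for iid in s1.design.image_ids:
        np.testing.assert_array_equal(s1.patterns[iid]["target"].coords,
                                      s2.patterns[iid]["target"].coords)
    np.testing.assert_array_equal(s1.truth.delta, s2.truth.delta)


def test_single_unit_study_reduces_to_one_image():
    cfg = SimulationConfig(n_cohorts=1, patients_per_cohort=1, images_per_patient=1,
                           n_source=20, n_target=20, window_side=500.0,
                           true_psi=np.zeros((1, 1, 3)), seed=9)
    study = shade.simulate_study(cfg)
    assert study.design.n_images == 1
    assert study.patterns[study.design.image_ids[0]]["target"].n == 20


def test_oversized_coefficients_abort_rejection():
    # a huge coefficient on a narrow kernel concentrates the density on a
    # vanishing ring; the sampler must refuse rather than loop forever
    from shade.patterns import PointPattern
    rbf = shade.study_rbf_basis()
    w = Window.square(2000.0)
    center = {"tumor": PointPattern.from_coords([[1000.0, 1000.0]], w, "tumor")}
    with pytest.raises(RuntimeError, match="acceptance rate"):
        shade.simulate_image(np.array([[80.0, 0.0, 0.0]]), 1, 50, w, rbf,
                             np.random.default_rng(10), grid_n=256, sources=center)


def test_rmse_zero_when_estimates_equal_truth(small_study, rbf3):
    from conftest import make_draws
    truth = small_study.truth
    draws = make_draws(truth.delta[None], design=small_study.design,
                       image_ids=small_study.design.image_ids)
    res = shade.rmse_eval(draws, truth, rbf3.scale_map, design=small_study.design)
    assert res["aggregate"] == 0.0


def test_rmse_hand_value_symmetric_errors(rbf3):
    from conftest import make_draws, balanced_design
    design = balanced_design(n_cohorts=1, patients_per_cohort=1, images_per_patient=2)
    truth = CoefficientTree(psi=np.zeros((1, 1, 3)), gamma=np.zeros((1, 1, 3)),
                            delta=np.zeros((2, 1, 3)), beta=np.zeros((2, 1)))
    est = np.zeros((1, 2, 1, 3))
    est[0, 0, 0, 0], est[0, 1, 0, 0] = 0.4, -0.4
    draws = make_draws(est, design=design, image_ids=design.image_ids)
    res = shade.rmse_eval(draws, truth, rbf3.scale_map, design=design)
    assert res["small"] == pytest.approx(0.4)
    assert res["medium"] == pytest.approx(0.0)
    assert res["aggregate"] == pytest.approx(0.4 / 3)


def test_rmse_shape_mismatch_errors(rbf3):
    from conftest import make_draws, balanced_design
    design = balanced_design(1, 1, 2)
    truth = CoefficientTree(psi=np.zeros((1, 1, 3)), gamma=np.zeros((1, 1, 3)),
                            delta=np.zeros((3, 1, 3)), beta=np.zeros((3, 1)))
    draws = make_draws(np.zeros((1, 2, 1, 2)), design=design,
                       image_ids=design.image_ids)
    with pytest.raises(ValueError):
        shade.rmse_eval(draws, truth, rbf3.scale_map, design=design)
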