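"""SIC reconstruction, credible bands, sign detection, group differences, MAD."""

import numpy as np
import pytest

import shade
from conftest import balanced_design, make_draws
from shade.sic import mad


@pytest.fixture
def grid():
    return np.arange(0.0, 101.0, 1.0)


def test_zero_coefficients_give_flat_zero_curve(rbf3, grid):
    draws = make_draws(np.zeros((50, 1, 1, 3)))
    c = shade.sic_curve(draws, rbf3, "image", "I0", "tumor", grid)
    assert np.all(c.draws == 0.0)
    assert np.all(c.median == 0.0)


def test_single_basis_coefficient_scales_one_kernel(rbf3, grid):
    delta = np.zeros((10, 1, 1, 3))
    delta[:, 0, 0, 1] = 2.5
    draws = make_draws(delta)
    c = shade.sic_curve(draws, rbf3, "image", "I0", "tumor", grid)
    expected = 2.5 * shade.eval_basis(rbf3, grid)[:, 1]
    np.testing.assert_allclose(c.draws[0], expected, atol=1e-12)


def test_curve_matrix_product_matches_per_draw_loop(rbf3, grid):
    rng = np.random.default_rng(0)
    delta = rng.standard_normal((100, 1, 1, 3))
    draws = make_draws(delta)
    c = shade.sic_curve(draws, rbf3, "image", "I0", "tumor", grid)
    phi = shade.eval_basis(rbf3, grid)
    for s in range(100):
        np.testing.assert_allclose(c.draws[s], phi @ delta[s, 0, 0], atol=1e-12)


def test_sic_linearity_in_coefficients(rbf3, grid):
    rng = np.random.default_rng(1)
    a = rng.standard_normal((20, 1, 1, 3))
    b = rng.standard_normal((20, 1, 1, 3))
    ca = shade.sic_curve(make_draws(a), rbf3, "image", "I0", "tumor", grid)
    cb = shade.sic_curve(make_draws(b), rbf3, "image", "I0", "tumor", grid)
    cab = shade.sic_curve(make_draws(a + b), rbf3, "image", "I0", "tumor", grid)
    np.testing.assert_allclose(cab.draws, ca.draws + cb.draws, atol=1e-12)


def test_median_lies_within_credible_band(rbf3, grid):
    rng = np.random.default_rng(2)
    draws = make_draws(rng.standard_normal((200, 1, 1, 3)))
    c = shade.sic_curve(draws, rbf3, "image", "I0", "tumor", grid)
    assert np.all(c.lower <= c.median + 1e-12)
    assert np.all(c.median <= c.upper + 1e-12)


def test_warning_beyond_twice_support(rbf3):
    draws = make_draws(np.zeros((5, 1, 1, 3)))
    with pytest.warns(UserWarning, match="2\\*r_max"):
        shade.sic_curve(draws, rbf3, "image", "I0", "tumor",
                        np.array([0.0, 2 * rbf3.r_max + 10.0]))


def test_sign_detection_interval_rules(rbf3, grid):
    # constant curves with known bands: [0.2, 0.8] -> positive; [-0.3, 0.4] -> undetected
    delta = np.zeros((1000, 1, 1, 3))
    q = np.quantile  # noqa: F841 - bands computed from uniform draw spread
    rng = np.random.default_rng(3)
    delta[:, 0, 0, 0] = rng.uniform(0.2, 0.8, size=1000)  # scaled by phi_0(20)=1
    draws = make_draws(delta)
    c = shade.sic_curve(draws, rbf3, "image", "I0", "tumor", grid)
    assert shade.sign_detection(c, [20.0]) == ["positive"]
    delta[:, 0, 0, 0] = rng.uniform(-0.3, 0.4, size=1000)
    c = shade.sic_curve(make_draws(delta), rbf3, "image", "I0", "tumor", grid)
    assert shade.sign_detection(c, [20.0]) == ["undetected"]
    delta[:, 0, 0, 0] = rng.uniform(-0.9, -0.1, size=1000)
    c = shade.sic_curve(make_draws(delta), rbf3, "image", "I0", "tumor", grid)
    assert shade.sign_detection(c, [20.0]) == ["negative"]
    with pytest.raises(ValueError):
        shade.sign_detection(c, [500.0])


def _hier_draws(rbf3, psi_values, n_draws=20, design=None):
    design = design or balanced_design()
    G, N, M = design.n_cohorts, design.n_patients, design.n_images
    psi = np.broadcast_to(np.asarray(psi_values)[None, :, None, :],
                          (n_draws, G, 1, 3)).copy()
    gamma = psi[:, design.patient_cohort]
    delta = gamma[:, design.image_patient]
    return make_draws(delta, psi=psi, gamma=gamma, design=design,
                      image_ids=design.image_ids)


def test_group_difference_zero_when_cohorts_identical(rbf3, grid):
    draws = _hier_draws(rbf3, np.array([[1.0, 0.5, 0.2], [1.0, 0.5, 0.2]]))
    diff = shade.group_difference(draws, rbf3, "C0", "C1", "tumor", grid)
    assert np.all(diff.draws == 0.0)
    assert not diff.flags.any()
    assert diff.flagged_ranges == []


def test_group_difference_reflects_basis_shift(rbf3, grid):
    a = np.array([[1.0, 0.5, 0.2], [1.0, 0.5, 0.2]])
    a[0, 1] += 0.7  # shift cohort C0 on the medium-range kernel
    draws = _hier_draws(rbf3, a)
    diff = shade.group_difference(draws, rbf3, "C0", "C1", "tumor", grid)
    expected = 0.7 * shade.eval_basis(rbf3, grid)[:, 1]
    np.testing.assert_allclose(diff.median, expected, atol=1e-12)
    assert diff.flags.any()
    with pytest.raises(ValueError):
        shade.group_difference(draws, rbf3, "C0", "nope", "tumor", grid)


def test_mad_hand_values():
    assert mad(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1.0)
    assert mad(np.array([3.0, 3.0, 3.0])) == pytest.approx(0.0)


def test_mad_shift_and_scale_invariances():
    rng = np.random.default_rng(4)
    x = rng.standard_normal((9, 50))
    np.testing.assert_allclose(mad(x + 5.0), mad(x), atol=1e-12)
    np.testing.assert_allclose(mad(3.0 * x), 3.0 * mad(x), atol=1e-12)


def test_heterogeneity_identical_patients_zero_mad(rbf3, grid):
    draws = _hier_draws(rbf3, np.array([[1.0, 0.5, 0.2], [1.0, 0.5, 0.2]]))
    het = shade.heterogeneity_mad(draws, rbf3, grid)["tumor"]
    np.testing.assert_allclose(het.between_patient, 0.0, atol=1e-12)
    np.testing.assert_allclose(het.between_image, 0.0, atol=1e-12)


def test_heterogeneity_grows_with_patient_scatter(rbf3, grid):
    # generator-level check: larger sigma_patient -> larger between-patient MAD
    design = balanced_design(n_cohorts=1, patients_per_cohort=6, images_per_patient=2)
    wins = 0
    for rep in range(10):
        curves = {}
        for sig in (0.5, 0.05):
            cfg = shade.SimulationConfig(
                n_cohorts=1, patients_per_cohort=6, images_per_patient=2,
                true_psi=np.array([[[1.0, 0.5, 0.2]]]), sigma_patient=sig,
                sigma_image=0.01, seed=100 + rep)
            tree = shade.draw_coefficient_tree(cfg, np.random.default_rng(100 + rep))
            draws = make_draws(tree.delta[None], psi=tree.psi[None],
                               gamma=tree.gamma[None], design=design,
                               image_ids=design.image_ids)
            het = shade.heterogeneity_mad(draws, rbf3, grid)["tumor"]
            curves[sig] = het.between_patient_mean
        wins += curves[0.5] > curves[0.05]
    assert wins >= 8


def test_heterogeneity_insufficient_units_raises(rbf3, grid):
    design = balanced_design(n_cohorts=1, patients_per_cohort=1, images_per_patient=2)
    psi = np.zeros((5, 1, 1, 3))
    draws = make_draws(np.zeros((5, 2, 1, 3)), psi=psi,
                       gamma=np.zeros((5, 1, 1, 3)), design=design,
                       image_ids=design.image_ids)
    with pytest.raises(ValueError, match="patient"):
        shade.heterogeneity_mad(draws, rbf3, grid)
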