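"""Synthetic multilevel point-pattern generator and coefficient-recovery metrics.

The generator mirrors the model's own data-generating story: cohort-level
SIC coefficients are fixed truth, patient- and image-level coefficients are
Gaussian perturbations of their parent level, source points are uniform in
the window, and target points are drawn from the inhomogeneous density
proportional to ``exp(sum_k q_k(v)' delta_k)`` by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSpec, scale_groups, study_rbf_basis
from .design import interaction_features
from .model import CoefficientTree, PosteriorDraws
from .patterns import PointPattern, StudyDesign, Window

DEFAULT_TRUE_PSI = np.array([[[1.5, 1.0, 0.5]],    # cohort "responder": attraction
                             [[-1.5, -1.0, -0.5]]])  # cohort "nonresponder": repulsion


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings.

    Defaults reproduce the hierarchical simulation design: two cohorts of
    20 patients with 4 images each, 150 points of each type per image in a
    1500x1500 μm window, dummy-to-real ratio 2, truth on three Gaussian
    RBFs (20/40/60 μm) with opposite-sign cohorts, and modest patient- and
    image-level coefficient scatter.
    """

    n_cohorts: int = 2
    patients_per_cohort: int = 20
    images_per_patient: int = 4
    n_source: int = 150
    n_target: int = 150
    window_side: float = 1500.0
    dummy_ratio: float = 2.0
    basis: BasisSpec = field(default_factory=study_rbf_basis)
    true_psi: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_PSI.copy())
    sigma_patient: float = 0.2
    sigma_image: float = 0.1
    count_mode: str = "fixed"        # "fixed" (binomial) or "poisson"
    source_type: str = "tumor"
    target_type: str = "tcell"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cohorts, self.patients_per_cohort, self.images_per_patient) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.sigma_patient < 0 or self.sigma_image < 0:
            raise ValueError("level scales must be nonnegative")
        if self.window_side <= 0:
            raise ValueError("window side must be positive")
        psi = np.asarray(self.true_psi, float)
        if psi.shape[0] != self.n_cohorts or psi.shape[2] != self.basis.P:
            raise ValueError("true_psi must have shape (n_cohorts, K, P)")
        object.__setattr__(self, "true_psi", psi)
        if self.count_mode not in ("fixed", "poisson"):
            raise ValueError("count_mode must be 'fixed' or 'poisson'")

    @property
    def n_source_types(self) -> int:
        return self.true_psi.shape[1]


@dataclass
class SimulatedStudy:
    """A realized study: per-image patterns, ground-truth coefficients, hierarchy."""

    patterns: dict                 # image_id -> {"target": PointPattern, "sources": {name: PointPattern}}
    truth: CoefficientTree
    design: StudyDesign
    config: SimulationConfig


def make_design(config: SimulationConfig) -> StudyDesign:
    """Balanced hierarchy labels: cohorts C0..; patients P000..; images I0000.."""
    cohort_ids = tuple(f"C{g}" for g in range(config.n_cohorts))
    patient_ids, patient_cohort = [], []
    image_ids, image_patient = [], []
    n = 0
    for g in range(config.n_cohorts):
        for _ in range(config.patients_per_cohort):
            patient_ids.append(f"P{n:03d}")
            patient_cohort.append(g)
            for j in range(config.images_per_patient):
                image_ids.append(f"I{n:03d}_{j}")
                image_patient.append(n)
            n += 1
    return StudyDesign(tuple(image_ids), tuple(patient_ids), cohort_ids,
                       np.array(image_patient), np.array(patient_cohort))


def draw_coefficient_tree(config: SimulationConfig,
                          rng: np.random.Generator | int) -> CoefficientTree:
    """Realize the Gaussian coefficient cascade below the fixed cohort truth.

    gamma(n) ~ Normal(psi(g(n)), sigma_patient^2) componentwise, and
    delta(m) ~ Normal(gamma(n(m)), sigma_image^2).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    design = make_design(config)
    K, P = config.n_source_types, config.basis.P
    psi = config.true_psi.copy()
    gamma = psi[design.patient_cohort] + config.sigma_patient * rng.standard_normal(
        (design.n_patients, K, P))
    delta = gamma[design.image_patient] + config.sigma_image * rng.standard_normal(
        (design.n_images, K, P))
    beta = np.zeros((design.n_images, 1))
    return CoefficientTree(psi=psi, gamma=gamma, delta=delta, beta=beta)


def simulate_image(delta: np.ndarray, n_source, n_target, window: Window,
                   spec: BasisSpec, rng: np.random.Generator | int,
                   source_type: str = "tumor", target_type: str = "tcell",
                   count_mode: str = "fixed", grid_n: int = 256,
                   max_inflation: float = 1.1, sources: dict | None = None):
    """Simulate one image: uniform sources, SIC-driven targets.

    ``delta`` has shape (K, P) — one coefficient row per source type; K
    independent uniform source patterns are generated (or taken from
    ``sources`` when supplied, e.g. to condition on a fixed configuration).
    Targets are drawn from the density proportional to
    ``exp(sum_k q_k(v)' delta_k)`` by rejection sampling against an upper
    bound taken as the maximum of the un-normalized density on a ``grid_n``
    x ``grid_n`` lattice, inflated by ``max_inflation`` for safety.

    Returns ``(sources, target)`` where sources maps type name -> pattern.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    delta = np.atleast_2d(np.asarray(delta, float))
    K = delta.shape[0]
    if K == 1:
        source_names = [source_type]
    else:
        source_names = [f"{source_type}{k}" for k in range(K)]
    if count_mode == "poisson":
        n_source = rng.poisson(n_source)
        n_target = rng.poisson(n_target)
    if sources is None:
        sources = {}
        for name in source_names:
            pts = window.sample_uniform(int(n_source), rng)
            sources[name] = PointPattern.from_coords(pts, window, name)
    else:
        source_names = list(sources)
        if len(source_names) != K:
            raise ValueError("sources must supply one pattern per coefficient row")

    def _log_density(coords):
        total = np.zeros(coords.shape[0])
        for k, name in enumerate(source_names):
            q = interaction_features(coords, sources[name], spec)
            total += q @ delta[k]
        return total

    n_target = int(n_target)
    if n_target == 0:
        target = PointPattern.from_coords(np.empty((0, 2)), window, target_type)
        return sources, target
    # upper bound for rejection from a lattice scan
    gx = np.linspace(window.x_min, window.x_max, grid_n)
    gy = np.linspace(window.y_min, window.y_max, grid_n)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    log_max = _log_density(grid).max() + np.log(max_inflation)
    accepted = []
    n_acc, n_prop = 0, 0
    while n_acc < n_target:
        batch = max(4 * (n_target - n_acc), 64)
        cand = window.sample_uniform(batch, rng)
        logd = _log_density(cand)
        keep = np.log(rng.random(batch)) < logd - log_max
        n_prop += batch
        n_acc += int(keep.sum())
        accepted.append(cand[keep])
        if n_prop >= 20_000 and n_acc / n_prop < 1e-4:
            raise RuntimeError(
                "rejection acceptance rate below 1e-4; the interaction "
                "coefficients are too large for this window — reduce them")
    pts = np.vstack(accepted)[:n_target]
    target = PointPattern.from_coords(pts, window, target_type)
    return sources, target


def simulate_study(config: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Compose the coefficient cascade and per-image simulation over the design."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    design = make_design(config)
    truth = draw_coefficient_tree(config, rng)
    window = Window.square(config.window_side)
    patterns = {}
    for m, image_id in enumerate(design.image_ids):
        sources, target = simulate_image(
            truth.delta[m], config.n_source, config.n_target, window,
            config.basis, rng, source_type=config.source_type,
            target_type=config.target_type, count_mode=config.count_mode)
        patterns[image_id] = {"target": target, "sources": sources}
    return SimulatedStudy(patterns=patterns, truth=truth, design=design, config=config)


# ------------------------------------------------------------------ evaluation

def rmse_eval(draws: PosteriorDraws, truth: CoefficientTree,
              scale_map: dict[int, str], design: StudyDesign | None = None) -> dict:
    """RMSE of posterior-mean image coefficients against simulation truth.

    Per basis index p, the RMSE is taken over images (and source types);
    scale-level summaries average the per-index RMSEs within each scale
    group; the aggregate averages over all basis indices. ``design`` maps
    the fit's image ids onto truth rows; it defaults to the hierarchy
    stored with the draws (flat fits must pass it explicitly when images
    were dropped or reordered).
    """
    est = draws.posterior_mean_delta()  # (M, K, P)
    meta = design if design is not None else draws.design_meta
    if meta is not None:
        idx = np.array([meta.image_index(iid) for iid in draws.image_ids])
        tru = truth.delta[idx]
    else:
        tru = truth.delta
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: estimates {est.shape} vs truth {tru.shape}")
    sq = (est - tru) ** 2
    per_p = np.sqrt(sq.mean(axis=(0, 1)))  # (P,)
    groups = {s: [p for p, lab in scale_map.items() if lab == s]
              for s in ("small", "medium", "large")}
    out = {"aggregate": float(per_p.mean()), "per_basis": per_p}
    for s, ps in groups.items():
        out[s] = float(per_p[ps].mean()) if ps else float("nan")
    return out


def study_designs_to_model_inputs(study: SimulatedStudy, rng,
                                  lambda_dummy: float | None = None):
    """Build per-image DesignMatrix objects from a simulated study."""
    from .design import build_design
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    designs = []
    for image_id in study.design.image_ids:
        entry = study.patterns[image_id]
        designs.append(build_design(entry["target"], entry["sources"],
                                    study.config.basis,
                                    lambda_dummy=lambda_dummy,
                                    dummy_ratio=study.config.dummy_ratio,
                                    rng=rng, image_id=image_id))
    return designs


def rmse_by_scale(draws: PosteriorDraws, study: SimulatedStudy) -> dict:
    """Convenience wrapper: rmse_eval with the study's basis scale map."""
    return rmse_eval(draws, study.truth, study.config.basis.scale_map,
                     design=study.design)


def scale_members(spec: BasisSpec) -> dict:
    return scale_groups(spec)
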