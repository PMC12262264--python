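"""Hierarchical Bayesian logistic model for conditional spatial intensity.

The target type's conditional intensity is log-linear in covariates and in
basis-weighted interaction features of the source types. The Poisson
point-process likelihood is approximated by a logistic regression over
observed target cells (label 1) and dummy points (label 0), with offset
``-log(lambda_dummy)``.

Interaction coefficients are pooled through a three-level Gaussian
hierarchy — cohort (psi), patient (gamma), image (delta):

    psi_kp(g)   ~ Normal(0, sigma_cohort^2)
    gamma_kp(n) ~ Normal(psi_kp(g(n)), sigma_patient^2)
    delta_kp(m) ~ Normal(gamma_kp(n(m)), sigma_image^2)

with half-Normal hyperpriors on the three scales and Normal(0, 5^2)
priors on the per-image covariate coefficients beta. Sampling uses NUTS on
a non-centered reparameterization (standard-normal innovations scaled by
the level scales), which leaves the posterior unchanged while removing the
funnel geometry that frustrates HMC in centered hierarchies.

``fit_flat`` is the no-pooling baseline: each image's delta gets an
independent weakly informative Normal prior and there are no patient or
cohort levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._kernels import logistic_ll_grad
from .design import DesignMatrix
from .nuts import sample_nuts
from .patterns import StudyDesign

__all__ = ["PriorConfig", "SamplerConfig", "CoefficientTree", "VarianceComponents",
           "PosteriorDraws", "log_posterior", "fit_shade", "fit_flat"]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the hierarchical prior (log-intensity scale)."""

    sigma_cohort_scale: float = 1.0   # half-Normal scale for sigma_cohort
    sigma_patient_scale: float = 1.0
    sigma_image_scale: float = 1.0
    beta_scale: float = 5.0           # Normal sd for covariate coefficients
    flat_delta_scale: float = 5.0     # Normal sd for the flat model's deltas
    pool_intercept: bool = False      # per-image beta by default


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    max_treedepth: int = 10
    # "auto": dense mass matrix only for moderate dimension, where the warmup
    # covariance estimate is reliable and cross-level posterior correlations
    # make it pay off; diagonal otherwise
    dense_mass: bool | str = "auto"


@dataclass
class CoefficientTree:
    """Point values of all coefficients at the three hierarchy levels.

    Shapes: psi (G, K, P), gamma (N, K, P), delta (M, K, P), beta (M, J).
    """

    psi: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    beta: np.ndarray

    def validate(self, design_meta: StudyDesign) -> None:
        if self.psi.shape[0] != design_meta.n_cohorts:
            raise ValueError("psi rows != number of cohorts")
        if self.gamma.shape[0] != design_meta.n_patients:
            raise ValueError("gamma rows != number of patients")
        if self.delta.shape[0] != design_meta.n_images:
            raise ValueError("delta rows != number of images")


@dataclass
class VarianceComponents:
    sigma_cohort: float
    sigma_patient: float
    sigma_image: float

    def __post_init__(self):
        if min(self.sigma_cohort, self.sigma_patient, self.sigma_image) <= 0:
            raise ValueError("variance-component scales must be strictly positive")


# --------------------------------------------------------------------- data prep

@dataclass
class _StackedData:
    y: np.ndarray
    Z: np.ndarray
    Q: np.ndarray
    X: np.ndarray             # [Z | Q], the per-row regressors in one block
    offset: np.ndarray        # per row
    row_starts: np.ndarray    # first row of each image block
    image_of_row: np.ndarray
    n_images: int
    K: int
    P: int
    J: int
    source_types: tuple
    kept: list                # indices of retained designs in the input order


def _stack_designs(designs: list[DesignMatrix], drop_empty: bool = True) -> _StackedData:
    kept = []
    for i, d in enumerate(designs):
        if d.n_real == 0:
            if drop_empty:
                warnings.warn(f"image {d.image_id!r} has zero target cells; dropped",
                              stacklevel=3)
                continue
        kept.append(i)
    if not kept:
        raise ValueError("no image with at least one observed target cell")
    ref = designs[kept[0]]
    for i in kept[1:]:
        if designs[i].source_types != ref.source_types:
            raise ValueError("designs disagree on source types")
        if designs[i].Z.shape[1] != ref.Z.shape[1]:
            raise ValueError("designs disagree on covariate dimension")
    y = np.concatenate([designs[i].y for i in kept])
    Z = np.vstack([designs[i].Z for i in kept])
    Q = np.vstack([designs[i].Q for i in kept])
    offset = np.concatenate([np.full(designs[i].n_rows, designs[i].offset) for i in kept])
    sizes = np.array([designs[i].n_rows for i in kept])
    row_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    image_of_row = np.repeat(np.arange(len(kept)), sizes)
    K = ref.n_sources
    P = ref.spec.P
    return _StackedData(y=y, Z=Z, Q=Q, X=np.ascontiguousarray(np.hstack([Z, Q])),
                        offset=offset, row_starts=row_starts,
                        image_of_row=image_of_row, n_images=len(kept), K=K, P=P,
                        J=ref.Z.shape[1], source_types=ref.source_types, kept=kept)


# ----------------------------------------------------------------- log posterior

def _loglik_terms(data: _StackedData, delta_flat: np.ndarray, beta: np.ndarray):
    """Bernoulli log-likelihood and per-row residual for given image coefficients."""
    eta = (np.einsum("ij,ij->i", data.Z, beta[data.image_of_row])
           + np.einsum("ij,ij->i", data.Q, delta_flat[data.image_of_row])
           - data.offset)
    ll = float(np.sum(data.y * eta) - np.sum(np.logaddexp(0.0, eta)))
    return ll, eta


def log_posterior(tree: CoefficientTree, vc: VarianceComponents,
                  designs: list[DesignMatrix], design_meta: StudyDesign,
                  priors: PriorConfig = PriorConfig()) -> float:
    """Log posterior density (up to an additive constant) at given coefficients.

    Sums the Bernoulli log-likelihood over all rows of all images with logit
    ``z'beta + sum_k q_k' delta_k(m) - log(lambda_dummy)``, the Gaussian
    hierarchical log-densities of the three coefficient levels, the
    half-Normal hyperprior terms on the scales, and the Normal prior on beta.
    """
    tree.validate(design_meta)
    data = _stack_designs(designs, drop_empty=False)
    if not np.all(np.isfinite(data.Q)):
        raise ValueError("non-finite interaction features")
    KP = data.K * data.P
    delta_flat = tree.delta.reshape(design_meta.n_images, KP)[np.array(data.kept)]
    beta = tree.beta[np.array(data.kept)]
    ll, _ = _loglik_terms(data, delta_flat, beta)

    def _normal_lp(x, mean, sd):
        return float(np.sum(-0.5 * ((x - mean) / sd) ** 2 - np.log(sd)))

    lp = ll
    lp += _normal_lp(tree.psi, 0.0, vc.sigma_cohort)
    lp += _normal_lp(tree.gamma, tree.psi[design_meta.patient_cohort], vc.sigma_patient)
    lp += _normal_lp(tree.delta, tree.gamma[design_meta.image_patient], vc.sigma_image)
    lp += _normal_lp(tree.beta, 0.0, priors.beta_scale)
    for s, scale in ((vc.sigma_cohort, priors.sigma_cohort_scale),
                     (vc.sigma_patient, priors.sigma_patient_scale),
                     (vc.sigma_image, priors.sigma_image_scale)):
        lp += -0.5 * (s / scale) ** 2
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the supplied coefficients")
    return lp


# ------------------------------------------------------------- hierarchical fit

class _HierModel:
    """Packed-parameter log posterior + gradient, non-centered parameterization.

    Parameter vector layout:
      psi_raw (G*KP) | gamma_raw (N*KP) | delta_raw (M*KP) | beta (M*J) | log_sigma (3)
    """

    def __init__(self, data: _StackedData, design_meta: StudyDesign,
                 kept_images: np.ndarray, priors: PriorConfig):
        self.data = data
        self.priors = priors
        self.ip = design_meta.image_patient[kept_images]
        self.pc = design_meta.patient_cohort
        self.G = design_meta.n_cohorts
        self.N = design_meta.n_patients
        self.M = data.n_images
        self.KP = data.K * data.P
        self.J = data.J
        s = 0
        self.sl_psi = slice(s, s + self.G * self.KP); s = self.sl_psi.stop
        self.sl_gam = slice(s, s + self.N * self.KP); s = self.sl_gam.stop
        self.sl_del = slice(s, s + self.M * self.KP); s = self.sl_del.stop
        self.sl_beta = slice(s, s + self.M * self.J); s = self.sl_beta.stop
        self.sl_ls = slice(s, s + 3)
        self.dim = s + 3

    def unpack(self, x):
        psi_raw = x[self.sl_psi].reshape(self.G, self.KP)
        gam_raw = x[self.sl_gam].reshape(self.N, self.KP)
        del_raw = x[self.sl_del].reshape(self.M, self.KP)
        beta = x[self.sl_beta].reshape(self.M, self.J)
        ls = x[self.sl_ls]
        return psi_raw, gam_raw, del_raw, beta, ls

    def centered(self, x):
        """Map raw parameters to (psi, gamma, delta, beta, sigmas)."""
        psi_raw, gam_raw, del_raw, beta, ls = self.unpack(x)
        sc, sp, si = np.exp(ls)
        psi = sc * psi_raw
        gamma = psi[self.pc] + sp * gam_raw
        delta = gamma[self.ip] + si * del_raw
        return psi, gamma, delta, beta, (sc, sp, si)

    def logp_grad(self, x):
        pr = self.priors
        psi_raw, gam_raw, del_raw, beta, ls = self.unpack(x)
        sc, sp, si = np.exp(np.clip(ls, -30, 30))
        psi = sc * psi_raw
        gamma = psi[self.pc] + sp * gam_raw
        delta = gamma[self.ip] + si * del_raw
        data = self.data
        coef = np.hstack([beta, delta])
        ll, g_coef = logistic_ll_grad(data.X, data.y, data.offset, coef,
                                      data.image_of_row)
        g_beta_lik = g_coef[:, : self.J]
        g_delta = np.ascontiguousarray(g_coef[:, self.J:])
        # flow up the hierarchy
        g_gamma = np.zeros((self.N, self.KP))
        np.add.at(g_gamma, self.ip, g_delta)
        g_psi = np.zeros((self.G, self.KP))
        np.add.at(g_psi, self.pc, g_gamma)

        raw = x[: self.sl_del.stop]
        lp = (ll
              - 0.5 * float(raw @ raw)
              - 0.5 * float((beta * beta).sum()) / pr.beta_scale ** 2
              - 0.5 * (sc / pr.sigma_cohort_scale) ** 2
              - 0.5 * (sp / pr.sigma_patient_scale) ** 2
              - 0.5 * (si / pr.sigma_image_scale) ** 2
              + float(ls.sum()))  # Jacobian of sigma = exp(log_sigma)

        grad = np.empty_like(x)
        grad[self.sl_psi] = (g_psi * sc).ravel()
        grad[self.sl_gam] = (g_gamma * sp).ravel()
        grad[self.sl_del] = (g_delta * si).ravel()
        grad[: self.sl_del.stop] -= raw
        grad[self.sl_beta] = (g_beta_lik - beta / pr.beta_scale ** 2).ravel()
        grad[self.sl_ls] = [
            sc * float((g_psi * psi_raw).sum()) - (sc / pr.sigma_cohort_scale) ** 2 + 1.0,
            sp * float((g_gamma * gam_raw).sum()) - (sp / pr.sigma_patient_scale) ** 2 + 1.0,
            si * float((g_delta * del_raw).sum()) - (si / pr.sigma_image_scale) ** 2 + 1.0,
        ]
        return lp, grad


class _FlatModel:
    """Independent per-image coefficients with weakly informative priors."""

    def __init__(self, data: _StackedData, priors: PriorConfig):
        self.data = data
        self.priors = priors
        self.M = data.n_images
        self.KP = data.K * data.P
        self.J = data.J
        self.sl_del = slice(0, self.M * self.KP)
        self.sl_beta = slice(self.sl_del.stop, self.sl_del.stop + self.M * self.J)
        self.dim = self.sl_beta.stop

    def unpack(self, x):
        delta = x[self.sl_del].reshape(self.M, self.KP)
        beta = x[self.sl_beta].reshape(self.M, self.J)
        return delta, beta

    def logp_grad(self, x):
        pr = self.priors
        delta, beta = self.unpack(x)
        data = self.data
        coef = np.hstack([beta, delta])
        eta = np.einsum("ij,ij->i", data.X, coef[data.image_of_row]) - data.offset
        ll = float(np.sum(data.y * eta) - np.sum(np.logaddexp(0.0, eta)))
        r = data.y - expit(eta)
        g_coef = np.add.reduceat(data.X * r[:, None], data.row_starts, axis=0)
        g_beta = g_coef[:, : self.J]
        g_delta = np.ascontiguousarray(g_coef[:, self.J:])
        lp = (ll - 0.5 * float(np.sum(delta ** 2)) / pr.flat_delta_scale ** 2
              - 0.5 * float(np.sum(beta ** 2)) / pr.beta_scale ** 2)
        grad = np.empty_like(x)
        grad[self.sl_del] = (g_delta - delta / pr.flat_delta_scale ** 2).ravel()
        grad[self.sl_beta] = (g_beta - beta / pr.beta_scale ** 2).ravel()
        return lp, grad


# ------------------------------------------------------------- posterior draws

@dataclass
class PosteriorDraws:
    """Posterior draws of the coefficient tree, with sampler diagnostics.

    Arrays have a leading (chains, draws) pair of axes. ``psi``, ``gamma``
    and ``sigmas`` are None for the flat model. ``image_ids`` lists the
    images actually fitted (zero-target images are dropped).
    """

    delta: np.ndarray                      # (C, S, M, K, P)
    beta: np.ndarray                       # (C, S, M, J)
    psi: np.ndarray | None                 # (C, S, G, K, P)
    gamma: np.ndarray | None               # (C, S, N, K, P)
    sigmas: np.ndarray | None              # (C, S, 3): cohort, patient, image
    source_types: tuple
    image_ids: tuple
    design_meta: StudyDesign | None
    diagnostics: dict = field(default_factory=dict)
    hierarchical: bool = True

    @property
    def n_draws_total(self) -> int:
        return self.delta.shape[0] * self.delta.shape[1]

    def _flat(self, arr):
        return arr.reshape((-1,) + arr.shape[2:])

    def coefficients(self, level: str, unit_id, source: str) -> np.ndarray:
        """(S_total, P) draws of the SIC coefficients for one unit and source."""
        k = self.source_types.index(source)
        if level == "image":
            m = self.image_ids.index(unit_id)
            return self._flat(self.delta)[:, m, k, :]
        if not self.hierarchical:
            raise ValueError("flat fits only carry image-level coefficients")
        if level == "patient":
            n = self.design_meta.patient_index(unit_id)
            return self._flat(self.gamma)[:, n, k, :]
        if level == "cohort":
            g = self.design_meta.cohort_index(unit_id)
            return self._flat(self.psi)[:, g, k, :]
        raise ValueError(f"unknown level {level!r}")

    def posterior_mean_delta(self) -> np.ndarray:
        """(M, K, P) posterior means of the image-level coefficients."""
        return self.delta.mean(axis=(0, 1))

    def units(self, level: str) -> tuple:
        if level == "image":
            return self.image_ids
        if level == "patient":
            return self.design_meta.patient_ids
        if level == "cohort":
            return self.design_meta.cohort_ids
        raise ValueError(f"unknown level {level!r}")

    def to_frame(self):
        """Long-format draws table (parameter, chain, draw, value)."""
        import pandas as pd
        rows = []
        C, S = self.delta.shape[:2]
        for c in range(C):
            for s in range(S):
                for m, iid in enumerate(self.image_ids):
                    for k, st in enumerate(self.source_types):
                        for p in range(self.delta.shape[-1]):
                            rows.append((f"delta[{iid},{st},{p}]", c, s,
                                         self.delta[c, s, m, k, p]))
        return pd.DataFrame(rows, columns=["parameter", "chain", "draw", "value"])


def _diagnostics(param_arrays: dict, stats_list) -> dict:
    import arviz as az
    ds = az.convert_to_dataset({k: v for k, v in param_arrays.items()})
    single_chain = next(iter(param_arrays.values())).shape[0] < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rhat = None if single_chain else az.rhat(ds)  # split-Rhat needs >= 2 chains
        ess = az.ess(ds)
    out = {
        "divergences": int(sum(int(s.divergent.sum()) for s in stats_list)),
        "divergent_warmup": int(sum(s.n_divergent_warmup for s in stats_list)),
        "step_sizes": [float(s.step_size) for s in stats_list],
        "max_rhat": (float("nan") if rhat is None else
                     float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))),
        "min_ess": float(min(np.nanmin(ess[v].values) for v in ess.data_vars)),
        "rhat": ({} if rhat is None else
                 {v: np.asarray(rhat[v].values).tolist() for v in rhat.data_vars}),
        "ess": {v: np.asarray(ess[v].values).tolist() for v in ess.data_vars},
    }
    return out


def _run_chains(model, sampler: SamplerConfig, init_scale: float = 0.1):
    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    dense = sampler.dense_mass
    if dense == "auto":
        dense = model.dim <= 150
    draws_list, stats_list = [], []
    for c in range(sampler.chains):
        rng = np.random.default_rng(seeds[c])
        x0 = init_scale * rng.standard_normal(model.dim)
        draws, stats = sample_nuts(model.logp_grad, x0, sampler.warmup, sampler.draws,
                                   rng, target_accept=sampler.target_accept,
                                   max_treedepth=sampler.max_treedepth,
                                   dense_mass=dense)
        draws_list.append(draws)
        stats_list.append(stats)
    all_draws = np.stack(draws_list)  # (C, S, dim)
    n_div = sum(int(s.divergent.sum()) for s in stats_list)
    if n_div >= sampler.chains * sampler.draws:
        raise RuntimeError(
            "sampler failed: every post-warmup transition diverged; "
            f"diagnostics: step_sizes={[float(s.step_size) for s in stats_list]}")
    return all_draws, stats_list


def fit_shade(designs: list[DesignMatrix], design_meta: StudyDesign,
              priors: PriorConfig = PriorConfig(),
              sampler: SamplerConfig = SamplerConfig()) -> PosteriorDraws:
    """Fit the three-level hierarchical model by NUTS.

    Images with zero observed target cells are dropped with a warning (their
    rows would carry no label-1 outcomes and inform only the intercept).
    """
    data = _stack_designs(designs)
    kept = np.array(data.kept)
    model = _HierModel(data, design_meta, kept, priors)
    all_draws, stats_list = _run_chains(model, sampler)
    C, S = all_draws.shape[:2]
    K, P = data.K, data.P
    psi = np.empty((C, S, model.G, K, P))
    gamma = np.empty((C, S, model.N, K, P))
    delta = np.empty((C, S, model.M, K, P))
    beta = np.empty((C, S, model.M, model.J))
    sigmas = np.empty((C, S, 3))
    for c in range(C):
        for s in range(S):
            ps, gm, dl, bt, (sc, sp, si) = model.centered(all_draws[c, s])
            psi[c, s] = ps.reshape(model.G, K, P)
            gamma[c, s] = gm.reshape(model.N, K, P)
            delta[c, s] = dl.reshape(model.M, K, P)
            beta[c, s] = bt
            sigmas[c, s] = (sc, sp, si)
    diag = _diagnostics({"psi": psi.reshape(C, S, -1),
                         "sigma": sigmas,
                         "delta": delta.reshape(C, S, -1)}, stats_list)
    image_ids = tuple(designs[i].image_id for i in data.kept)
    return PosteriorDraws(delta=delta, beta=beta, psi=psi, gamma=gamma,
                          sigmas=sigmas, source_types=data.source_types,
                          image_ids=image_ids, design_meta=design_meta,
                          diagnostics=diag, hierarchical=True)


def fit_flat(designs: list[DesignMatrix],
             priors: PriorConfig = PriorConfig(),
             sampler: SamplerConfig = SamplerConfig()) -> PosteriorDraws:
    """Fit the non-hierarchical baseline: independent image-level coefficients."""
    data = _stack_designs(designs)
    model = _FlatModel(data, priors)
    all_draws, stats_list = _run_chains(model, sampler)
    C, S = all_draws.shape[:2]
    K, P = data.K, data.P
    delta = np.empty((C, S, model.M, K, P))
    beta = np.empty((C, S, model.M, model.J))
    for c in range(C):
        for s in range(S):
            dl, bt = model.unpack(all_draws[c, s])
            delta[c, s] = dl.reshape(model.M, K, P)
            beta[c, s] = bt
    diag = _diagnostics({"delta": delta.reshape(C, S, -1)}, stats_list)
    image_ids = tuple(designs[i].image_id for i in data.kept)
    return PosteriorDraws(delta=delta, beta=beta, psi=None, gamma=None,
                          sigmas=None, source_types=data.source_types,
                          image_ids=image_ids, design_meta=None,
                          diagnostics=diag, hierarchical=False)
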