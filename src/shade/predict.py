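"""Conditional-intensity prediction maps and discrimination AUC.

Given posterior draws for an image, the fitted conditional intensity at
any location v is ``exp(z(v)'beta + sum_k q_k(v)' delta_k)``; evaluating
its posterior mean on a lattice yields a predicted density map for the
target type. Discrimination is summarized by the AUC of the fitted
real-vs-dummy probability ``lambda / (lambda + lambda_dummy)`` over a
fresh set of dummy points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .basis import BasisSpec
from .design import generate_dummy_points, interaction_features
from .model import PosteriorDraws
from .patterns import PointPattern


@dataclass
class IntensityMap:
    """Posterior-mean predicted intensity on a regular lattice (cell centers)."""

    x: np.ndarray            # (nx,) cell-center x coordinates
    y: np.ndarray            # (ny,)
    values: np.ndarray       # (nx, ny) intensity per μm²
    spacing: float
    image_id: object
    target_type: str = "target"

    def at(self, coords: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup of the map at arbitrary locations."""
        c = np.atleast_2d(coords)
        ix = np.abs(self.x[None, :] - c[:, [0]]).argmin(axis=1)
        iy = np.abs(self.y[None, :] - c[:, [1]]).argmin(axis=1)
        return self.values[ix, iy]

    @property
    def integral(self) -> float:
        """Quadrature integral of the map over the window (expected count)."""
        return float(self.values.sum() * self.spacing ** 2)

    def to_ascii_grid(self) -> str:
        """ESRI-ASCII-style text raster (rows from north to south)."""
        header = (f"ncols {self.x.size}\nnrows {self.y.size}\n"
                  f"xllcorner {self.x[0] - self.spacing / 2}\n"
                  f"yllcorner {self.y[0] - self.spacing / 2}\n"
                  f"cellsize {self.spacing}\nNODATA_value -9999\n")
        body = "\n".join(" ".join(f"{v:.6g}" for v in self.values[:, j])
                         for j in range(self.y.size - 1, -1, -1))
        return header + body


def _image_linear_predictor_draws(draws: PosteriorDraws, image_id, Q, Z):
    """(S_total, n) draws of the log-intensity at feature rows (Q, Z)."""
    m = draws.image_ids.index(image_id)
    S_delta = draws.delta.reshape((-1,) + draws.delta.shape[2:])[:, m]  # (S, K, P)
    S_beta = draws.beta.reshape((-1,) + draws.beta.shape[2:])[:, m]     # (S, J)
    KP = S_delta.shape[1] * S_delta.shape[2]
    return S_beta @ Z.T + S_delta.reshape(-1, KP) @ Q.T


def intensity_map(draws: PosteriorDraws, image_id, sources: dict,
                  spec: BasisSpec, grid_spacing: float = 5.0,
                  covariates=None) -> IntensityMap:
    """Posterior-mean conditional-intensity map for one image.

    ``sources`` maps source-type name -> PointPattern (the same types, in
    the same order, used when fitting). Node values are posterior means of
    ``exp(z'beta + sum_k q_k' delta_k)`` at lattice cell centers.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if image_id not in draws.image_ids:
        raise ValueError(f"image {image_id!r} not present in the fit")
    window = next(iter(sources.values())).window
    x = np.arange(window.x_min + grid_spacing / 2, window.x_max, grid_spacing)
    y = np.arange(window.y_min + grid_spacing / 2, window.y_max, grid_spacing)
    GX, GY = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([GX.ravel(), GY.ravel()])
    Q = np.hstack([interaction_features(nodes, sources[name], spec)
                   for name in draws.source_types])
    Z = np.ones((nodes.shape[0], draws.beta.shape[-1]))
    if covariates is not None:
        Z[:, 1:] = np.asarray(covariates(nodes), float).reshape(nodes.shape[0], -1)
    eta = _image_linear_predictor_draws(draws, image_id, Q, Z)
    values = np.exp(eta).mean(axis=0).reshape(x.size, y.size)
    return IntensityMap(x=x, y=y, values=values, spacing=grid_spacing,
                        image_id=image_id)


def predict_auc(draws: PosteriorDraws, image_id, target: PointPattern,
                sources: dict, spec: BasisSpec, lambda_dummy: float | None = None,
                dummy_ratio: float = 2.0, rng: np.random.Generator | int = 12345,
                covariates=None) -> float:
    """AUC of the fitted real-vs-dummy probability for one image.

    Scores are posterior means of ``P(real) = sigmoid(log lambda(v) -
    log lambda_dummy)`` over the observed target cells (label 1) and a
    freshly generated dummy set (label 0). The evaluation dummies use their
    own RNG so scoring rows differ from the fitting rows.
    """
    if target.n == 0:
        raise ValueError("image has no observed target cells")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    window = target.window
    if lambda_dummy is None:
        lambda_dummy = dummy_ratio * target.n / window.area
    dummies = generate_dummy_points(window, lambda_dummy, rng)
    if dummies.shape[0] == 0:
        raise ValueError("no dummy points generated; increase lambda_dummy")
    coords = np.vstack([target.coords, dummies])
    y = np.zeros(coords.shape[0])
    y[: target.n] = 1.0
    Q = np.hstack([interaction_features(coords, sources[name], spec)
                   for name in draws.source_types])
    Z = np.ones((coords.shape[0], draws.beta.shape[-1]))
    if covariates is not None:
        Z[:, 1:] = np.asarray(covariates(coords), float).reshape(coords.shape[0], -1)
    eta = _image_linear_predictor_draws(draws, image_id, Q, Z) - np.log(lambda_dummy)
    scores = expit(eta).mean(axis=0)
    return float(roc_auc_score(y, scores))
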