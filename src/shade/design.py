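"""Interaction features, dummy points and design-matrix assembly.

The conditional-intensity model is fitted through a logistic approximation:
observed target cells (label 1) are pooled with "dummy" points from a
homogeneous Poisson process of known intensity ``lambda_dummy`` (label 0),
and the log odds of a point being real equals the log conditional intensity
minus ``log(lambda_dummy)``. Each row of the design matrix carries the
covariates z(v), the per-source-type interaction features q_Ak(v) (basis
functions summed over source points within the support radius), and the
offset log(lambda_dummy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .basis import BasisSpec, eval_basis
from .patterns import PointPattern, Window


def interaction_features(targets, source: PointPattern, spec: BasisSpec,
                         window: Window | None = None) -> np.ndarray:
    """Per-location interaction features q(v) for one source pattern.

    Row v is ``sum_{x in source} phi(dist(v, x))``; only source points within
    ``spec.r_max`` of v contribute (a KD-tree prunes the pair search).

    ``targets`` may be an (n, 2) coordinate array or a PointPattern; when both
    target and source are patterns their windows must match.
    """
    if isinstance(targets, PointPattern):
        if targets.window != source.window:
            raise ValueError("target and source patterns must share a window")
        t_coords = targets.coords
    else:
        t_coords = np.asarray(targets, dtype=float).reshape(-1, 2)
        if window is not None and window != source.window:
            raise ValueError("window mismatch between targets and source")
    n = t_coords.shape[0]
    out = np.zeros((n, spec.P))
    if n == 0 or source.n == 0:
        return out
    t_tree = cKDTree(t_coords)
    s_tree = cKDTree(source.coords)
    pairs = t_tree.sparse_distance_matrix(s_tree, spec.r_max, output_type="ndarray")
    if pairs.size == 0:
        return out
    phi = eval_basis(spec, pairs["v"])
    rows = pairs["i"]
    for p in range(spec.P):
        out[:, p] = np.bincount(rows, weights=phi[:, p], minlength=n)
    return out


def generate_dummy_points(window: Window, lambda_dummy: float,
                          rng: np.random.Generator | int) -> np.ndarray:
    """Homogeneous Poisson dummy points with intensity lambda_dummy (per μm²).

    Count ~ Poisson(lambda_dummy * |W|); locations i.i.d. uniform on W.
    """
    if lambda_dummy <= 0:
        raise ValueError("lambda_dummy must be positive")
    if window.area <= 0:
        raise ValueError("window must have positive area")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = rng.poisson(lambda_dummy * window.area)
    return window.sample_uniform(n, rng)


@dataclass
class DesignMatrix:
    """Stacked rows for one image: observed target cells then dummy points.

    Attributes
    ----------
    y : (n,) 0/1 labels (1 = observed target cell).
    Z : (n, J) covariates; first column is the intercept (all ones).
    Q : (n, K*P) interaction features, source types in ``source_types`` order,
        each contributing a contiguous block of P columns.
    offset : log(lambda_dummy), constant within the image.
    coords : (n, 2) row locations (μm).
    """

    y: np.ndarray
    Z: np.ndarray
    Q: np.ndarray
    offset: float
    coords: np.ndarray
    source_types: tuple[str, ...]
    spec: BasisSpec
    lambda_dummy: float
    image_id: object = None

    @property
    def n_rows(self) -> int:
        return self.y.size

    @property
    def n_real(self) -> int:
        return int(self.y.sum())

    @property
    def n_sources(self) -> int:
        return len(self.source_types)


def build_design(target: PointPattern, sources: dict[str, PointPattern],
                 spec: BasisSpec, lambda_dummy: float | None = None,
                 covariates=None, rng: np.random.Generator | int = 0,
                 dummy_ratio: float = 2.0, image_id=None) -> DesignMatrix:
    """Assemble the logistic design matrix for one image.

    Parameters
    ----------
    target : observed pattern of the target type.
    sources : map source-type name -> PointPattern (same window as target).
    lambda_dummy : dummy intensity per μm²; defaults to
        ``dummy_ratio * n_target / |W|`` (expected dummy count =
        dummy_ratio x observed target count).
    covariates : optional callable coords -> (n, J-1) array of extra
        covariate columns appended after the intercept.
    """
    window = target.window
    for name, src in sources.items():
        if src.window != window:
            raise ValueError(f"source {name!r} window differs from target window")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if lambda_dummy is None:
        if target.n == 0:
            raise ValueError("cannot infer lambda_dummy from an empty target pattern")
        lambda_dummy = dummy_ratio * target.n / window.area
    dummies = generate_dummy_points(window, lambda_dummy, rng)
    coords = np.vstack([target.coords, dummies]) if target.n else dummies.copy()
    n = coords.shape[0]
    y = np.zeros(n)
    y[: target.n] = 1.0
    Z = np.ones((n, 1))
    if covariates is not None:
        extra = np.asarray(covariates(coords), dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        Z = np.hstack([Z, extra])
    names = tuple(sources)
    Q = np.zeros((n, len(names) * spec.P))
    for k, name in enumerate(names):
        Q[:, k * spec.P:(k + 1) * spec.P] = interaction_features(
            coords, sources[name], spec, window=window)
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite interaction features")
    return DesignMatrix(y=y, Z=Z, Q=Q, offset=float(np.log(lambda_dummy)),
                        coords=coords, source_types=names, spec=spec,
                        lambda_dummy=float(lambda_dummy), image_id=image_id)
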