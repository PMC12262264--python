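"""Distance basis functions for spatial interaction curves.

A spatial interaction curve (SIC) is represented as a linear combination
``SIC(s) = sum_p c_p * phi_p(s)`` of nonnegative basis functions of
distance ``s`` (in micrometres), compactly supported on ``[0, r_max]``.
Two families are provided:

* ``bspline`` — a clamped cubic B-spline basis with equally spaced knots
  on ``[0, r_max]``; smooth, local, and a partition of unity.
* ``gaussian_rbf`` — Gaussian bumps at fixed centers, truncated to zero
  beyond ``r_max``; convenient when interactions are expected at a few
  known ranges (e.g. short/medium/long).

Each basis index is assigned a spatial *scale* label (small / medium /
large) used when aggregating coefficient errors by range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

SCALES = ("small", "medium", "large")


def _default_scale_map(centers: np.ndarray, r_max: float) -> dict[int, str]:
    """Assign each basis index to a scale by the third of [0, r_max] its center falls in."""
    out = {}
    for p, c in enumerate(centers):
        third = min(int(3 * c / r_max), 2)
        out[p] = SCALES[third]
    return out


@dataclass(frozen=True)
class BasisSpec:
    """Specification of the distance basis {phi_p}_{p=1..P}.

    Attributes
    ----------
    family : {"bspline", "gaussian_rbf"}
    P : number of basis functions.
    r_max : support radius (μm); phi_p(s) = 0 for s > r_max.
    knots : full clamped knot vector (bspline family).
    centers, widths : RBF centers and Gaussian widths (gaussian_rbf family).
    degree : spline degree (bspline family).
    scale_map : maps basis index p (0-based) to "small"/"medium"/"large".
    """

    family: str
    P: int
    r_max: float
    knots: np.ndarray | None = None
    centers: np.ndarray | None = None
    widths: np.ndarray | None = None
    degree: int = 3
    scale_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.family not in ("bspline", "gaussian_rbf"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if set(self.scale_map) != set(range(self.P)):
            raise ValueError("scale_map must cover every basis index exactly once")

    # ---------------------------------------------------------------- constructors
    @staticmethod
    def bspline(P: int = 6, r_max: float = 150.0, degree: int = 3,
                scale_map: dict[int, str] | None = None) -> "BasisSpec":
        """Clamped B-spline basis with equally spaced interior knots on [0, r_max]."""
        if P < degree + 1:
            raise ValueError(f"need P >= degree+1 ({degree + 1}) for a clamped basis")
        n_inner = P - degree + 1
        inner = np.linspace(0.0, r_max, n_inner)
        knots = np.concatenate([np.full(degree, 0.0), inner, np.full(degree, r_max)])
        # Greville abscissae locate each basis function's effective center.
        greville = np.array([knots[p + 1: p + degree + 1].mean() for p in range(P)])
        if scale_map is None:
            scale_map = _default_scale_map(greville, r_max)
        return BasisSpec(family="bspline", P=P, r_max=r_max, knots=knots,
                         degree=degree, scale_map=scale_map)

    @staticmethod
    def gaussian_rbf(centers, widths, r_max: float | None = None,
                     scale_map: dict[int, str] | None = None) -> "BasisSpec":
        """Gaussian bumps exp(-(s-c)^2 / (2 w^2)), truncated to zero beyond r_max."""
        centers = np.asarray(centers, dtype=float)
        widths = np.broadcast_to(np.asarray(widths, dtype=float), centers.shape).copy()
        if np.any(widths <= 0):
            raise ValueError("widths must be positive")
        if r_max is not None and r_max <= 0:
            raise ValueError("r_max must be positive")
        if r_max is None:
            r_max = float(np.max(centers + 4 * widths))
        if scale_map is None:
            order = np.argsort(centers)
            if len(centers) == 3:
                scale_map = {int(order[i]): SCALES[i] for i in range(3)}
            else:
                scale_map = _default_scale_map(centers, r_max)
        return BasisSpec(family="gaussian_rbf", P=len(centers), r_max=r_max,
                         centers=centers, widths=widths, scale_map=scale_map)


def default_basis() -> BasisSpec:
    """Package default: cubic B-splines, P=6, r_max=150 μm."""
    return BasisSpec.bspline(P=6, r_max=150.0)


def study_rbf_basis() -> BasisSpec:
    """Three Gaussian RBFs at 20/40/60 μm (width 10 μm), the simulation-study basis.

    Centers align with the short-, medium- and long-range scales probed at
    the 20/40/60 μm test distances; r_max = 100 μm.
    """
    return BasisSpec.gaussian_rbf(centers=[20.0, 40.0, 60.0], widths=10.0, r_max=100.0)


def eval_basis(spec: BasisSpec, distances) -> np.ndarray:
    """Evaluate all P basis functions at the given distances.

    Parameters
    ----------
    spec : BasisSpec
    distances : array-like of nonnegative distances (μm).

    Returns
    -------
    (n, P) array with entry (i, p) = phi_p(distances[i]); rows are zero
    for distances beyond ``spec.r_max``.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1:
        d = d.ravel()
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = np.zeros((d.size, spec.P))
    inside = d <= spec.r_max
    if not np.any(inside):
        return out
    di = d[inside]
    if spec.family == "bspline":
        dm = BSpline.design_matrix(di, spec.knots, spec.degree, extrapolate=False)
        out[inside] = dm.toarray()
    else:
        z = (di[:, None] - spec.centers[None, :]) / spec.widths[None, :]
        out[inside] = np.exp(-0.5 * z * z)
    return out


def scale_groups(spec: BasisSpec) -> dict[str, list[int]]:
    """Invert the scale map: scale label -> list of basis indices."""
    groups: dict[str, list[int]] = {s: [] for s in SCALES}
    for p in range(spec.P):
        groups[spec.scale_map[p]].append(p)
    return groups
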