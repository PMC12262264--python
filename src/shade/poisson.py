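"""Independent maximum-likelihood fit of the inhomogeneous Poisson model.

Maximizes the exact Poisson point-process log-likelihood

    sum_{y in targets} log lambda(y) - int_W lambda(v) dv,
    log lambda(v) = beta0 + sum_k q_k(v)' delta_k,

with the window integral evaluated by midpoint quadrature on a fine
lattice. This is a direct numerical fit of the model the logistic
dummy-point construction approximates, and serves as its cross-check: as
the dummy intensity grows, logistic posterior means converge to this fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .basis import BasisSpec
from .design import interaction_features
from .patterns import PointPattern


def fit_poisson_ml(target: PointPattern, sources: dict, spec: BasisSpec,
                   grid_n: int = 192) -> dict:
    """Quadrature maximum-likelihood fit; returns beta0 and delta (K*P,).

    ``grid_n`` controls the quadrature lattice (grid_n x grid_n midpoint
    cells over the window).
    """
    window = target.window
    names = tuple(sources)
    Qd = np.hstack([interaction_features(target.coords, sources[n], spec)
                    for n in names])
    xs = np.linspace(window.x_min, window.x_max, grid_n + 1)
    ys = np.linspace(window.y_min, window.y_max, grid_n + 1)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    GX, GY = np.meshgrid(cx, cy, indexing="ij")
    nodes = np.column_stack([GX.ravel(), GY.ravel()])
    w = (xs[1] - xs[0]) * (ys[1] - ys[0])
    Qg = np.hstack([interaction_features(nodes, sources[n], spec) for n in names])

    KP = Qd.shape[1]

    def nll_grad(theta):
        b0, delta = theta[0], theta[1:]
        eta_d = b0 + Qd @ delta
        eta_g = b0 + Qg @ delta
        lam_g = np.exp(eta_g)
        integral = w * lam_g.sum()
        nll = -(eta_d.sum() - integral)
        g_b0 = -(Qd.shape[0] - integral)
        g_delta = -(Qd.sum(axis=0) - w * (lam_g @ Qg))
        return nll, np.concatenate([[g_b0], g_delta])

    theta0 = np.zeros(1 + KP)
    theta0[0] = np.log(max(target.n, 1) / window.area)
    res = minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    if not res.success and res.status != 1:
        raise RuntimeError(f"Poisson ML fit failed: {res.message}")
    return {"beta0": float(res.x[0]), "delta": res.x[1:],
            "source_types": names, "nll": float(res.fun)}
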