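"""Fused likelihood/gradient kernel for the logistic point-process models.

One pass over the stacked design rows computes the Bernoulli log-likelihood
and the per-image coefficient gradient. A numba-compiled kernel is used
when available; a vectorized numpy fallback gives identical results.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _core(X, y, offset, coef, img_idx):  # pragma: no cover - compiled
        n, D = X.shape
        M = coef.shape[0]
        ll = 0.0
        g = np.zeros((M, D))
        for i in range(n):
            m = img_idx[i]
            eta = -offset[i]
            for j in range(D):
                eta += X[i, j] * coef[m, j]
            if eta > 0.0:
                sp = eta + np.log1p(np.exp(-eta))
                p = 1.0 / (1.0 + np.exp(-eta))
            else:
                e = np.exp(eta)
                sp = np.log1p(e)
                p = e / (1.0 + e)
            ll += y[i] * eta - sp
            r = y[i] - p
            for j in range(D):
                g[m, j] += X[i, j] * r
        return ll, g

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in practice
    HAVE_NUMBA = False


def _core_numpy(X, y, offset, coef, img_idx):
    from scipy.special import expit
    eta = np.einsum("ij,ij->i", X, coef[img_idx]) - offset
    ll = float((y * eta).sum() - np.logaddexp(0.0, eta).sum())
    r = y - expit(eta)
    g = np.zeros_like(coef)
    np.add.at(g, img_idx, X * r[:, None])
    return ll, g


def logistic_ll_grad(X, y, offset, coef, img_idx):
    """Log-likelihood and (M, D) gradient of per-image coefficients."""
    if HAVE_NUMBA:
        return _core(X, y, offset, coef, img_idx)
    return _core_numpy(X, y, offset, coef, img_idx)
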