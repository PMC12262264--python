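"""A self-contained No-U-Turn sampler with dual-averaging adaptation.

Implements multinomial NUTS (tree doubling with progressive multinomial
sampling from the trajectory), a diagonal or dense mass matrix adapted
from warmup draws in Stan-style expanding windows, and dual-averaging
step-size adaptation toward a target acceptance statistic. The target
density is supplied as a single callable returning
``(log p(x), grad log p(x))``.

This is a general-purpose sampler over unconstrained real vectors; the
model modules hand it analytically differentiated log posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NUTSStats"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error treated as a divergent transition


@dataclass
class NUTSStats:
    """Per-draw sampler statistics for one chain."""

    divergent: np.ndarray        # bool per kept draw
    accept_stat: np.ndarray      # mean Metropolis acceptance over the trajectory
    tree_depth: np.ndarray
    energy: np.ndarray
    step_size: float
    inv_mass: np.ndarray
    n_divergent_warmup: int = 0


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "g_prop", "logp_prop", "log_weight", "sum_p",
                 "divergent", "turning", "sum_accept", "n_steps")


class _Metric:
    """Euclidean metric: diagonal or dense inverse mass matrix."""

    def __init__(self, inv_mass):
        self.inv_mass = inv_mass
        self.dense = inv_mass.ndim == 2
        if self.dense:
            # momenta ~ N(0, M) with M = inv_mass^{-1}; if inv_mass = L L^T
            # then p = L^{-T} z has the right covariance
            self._chol = np.linalg.cholesky(inv_mass)

    def velocity(self, p):
        return self.inv_mass @ p if self.dense else self.inv_mass * p

    def kinetic(self, p):
        return 0.5 * float(np.dot(p, self.velocity(p)))

    def sample_momentum(self, rng):
        z = rng.standard_normal(self.inv_mass.shape[0])
        if self.dense:
            from scipy.linalg import solve_triangular
            return solve_triangular(self._chol.T, z, lower=False)
        return z / np.sqrt(self.inv_mass)


def _leapfrog(logp_grad, x, p, g, eps, metric):
    p_half = p + 0.5 * eps * g
    x_new = x + eps * metric.velocity(p_half)
    logp_new, g_new = logp_grad(x_new)
    p_new = p_half + 0.5 * eps * g_new
    return x_new, p_new, g_new, logp_new


def _hamiltonian(logp, p, metric):
    return logp - metric.kinetic(p)


def _build_leaf(logp_grad, x, p, g, v, eps, metric, h0, rng):
    x1, p1, g1, logp1 = _leapfrog(logp_grad, x, p, g, v * eps, metric)
    t = _Tree()
    t.x_minus = t.x_plus = t.x_prop = x1
    t.p_minus = t.p_plus = p1
    t.g_minus = t.g_plus = t.g_prop = g1
    t.logp_prop = logp1
    h1 = _hamiltonian(logp1, p1, metric) if np.isfinite(logp1) else -np.inf
    delta_h = h1 - h0
    t.log_weight = delta_h if np.isfinite(delta_h) else -np.inf
    t.divergent = (not np.isfinite(delta_h)) or (delta_h < -_DIVERGENCE_THRESHOLD)
    t.turning = False
    t.sum_accept = float(np.exp(min(delta_h, 0.0))) if np.isfinite(delta_h) else 0.0
    t.n_steps = 1
    t.sum_p = p1.copy()
    return t


def _merge(rng, left: _Tree, right: _Tree, going_right: bool) -> _Tree:
    out = _Tree()
    if going_right:
        out.x_minus, out.p_minus, out.g_minus = left.x_minus, left.p_minus, left.g_minus
        out.x_plus, out.p_plus, out.g_plus = right.x_plus, right.p_plus, right.g_plus
    else:
        out.x_minus, out.p_minus, out.g_minus = right.x_minus, right.p_minus, right.g_minus
        out.x_plus, out.p_plus, out.g_plus = left.x_plus, left.p_plus, left.g_plus
    total = np.logaddexp(left.log_weight, right.log_weight)
    # progressive multinomial sampling between subtrees
    if np.isfinite(total) and np.log(rng.random()) < right.log_weight - total:
        out.x_prop, out.g_prop, out.logp_prop = right.x_prop, right.g_prop, right.logp_prop
    else:
        out.x_prop, out.g_prop, out.logp_prop = left.x_prop, left.g_prop, left.logp_prop
    out.log_weight = total
    out.sum_p = left.sum_p + right.sum_p
    out.divergent = left.divergent or right.divergent
    out.turning = left.turning or right.turning
    out.sum_accept = left.sum_accept + right.sum_accept
    out.n_steps = left.n_steps + right.n_steps
    return out


def _build_tree(logp_grad, x, p, g, v, depth, eps, metric, h0, rng) -> _Tree:
    if depth == 0:
        return _build_leaf(logp_grad, x, p, g, v, eps, metric, h0, rng)
    first = _build_tree(logp_grad, x, p, g, v, depth - 1, eps, metric, h0, rng)
    if first.divergent or first.turning:
        return first
    if v > 0:
        second = _build_tree(logp_grad, first.x_plus, first.p_plus, first.g_plus,
                             v, depth - 1, eps, metric, h0, rng)
    else:
        second = _build_tree(logp_grad, first.x_minus, first.p_minus, first.g_minus,
                             v, depth - 1, eps, metric, h0, rng)
    merged = _merge(rng, first, second, going_right=v > 0)
    if not (merged.divergent or merged.turning):
        merged.turning = _uturn(merged, metric)
    return merged


def _uturn(t: _Tree, metric) -> bool:
    # u-turn when either end's velocity points back across the subtree span
    span = t.x_plus - t.x_minus
    return (np.dot(span, metric.velocity(t.p_minus)) < 0) \
        or (np.dot(span, metric.velocity(t.p_plus)) < 0)


def _find_reasonable_eps(logp_grad, x, g, logp, metric, rng):
    eps = 1.0
    p = metric.sample_momentum(rng)
    h0 = _hamiltonian(logp, p, metric)
    _, p1, _, logp1 = _leapfrog(logp_grad, x, p, g, eps, metric)
    h1 = _hamiltonian(logp1, p1, metric) if np.isfinite(logp1) else -np.inf
    delta = h1 - h0
    direction = 1.0 if delta > np.log(0.8) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, p1, _, logp1 = _leapfrog(logp_grad, x, p, g, eps, metric)
        h1 = _hamiltonian(logp1, p1, metric) if np.isfinite(logp1) else -np.inf
        delta = h1 - h0
        crossed = (delta > np.log(0.8)) if direction < 0 else (delta < np.log(0.8))
        if crossed:
            break
    return max(eps, 1e-8)


def _transition(logp_grad, x, g, logp, eps, metric, max_treedepth, rng):
    p0 = metric.sample_momentum(rng)
    h0 = _hamiltonian(logp, p0, metric)
    tree = _Tree()
    tree.x_minus = tree.x_plus = tree.x_prop = x
    tree.p_minus = tree.p_plus = p0
    tree.g_minus = tree.g_plus = tree.g_prop = g
    tree.logp_prop = logp
    tree.log_weight = 0.0
    tree.sum_p = p0.copy()
    tree.divergent = False
    tree.turning = False
    tree.sum_accept = 0.0
    tree.n_steps = 0
    depth = 0
    divergent = False
    while depth < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v > 0:
            sub = _build_tree(logp_grad, tree.x_plus, tree.p_plus, tree.g_plus,
                              v, depth, eps, metric, h0, rng)
        else:
            sub = _build_tree(logp_grad, tree.x_minus, tree.p_minus, tree.g_minus,
                              v, depth, eps, metric, h0, rng)
        if sub.divergent or sub.turning:
            divergent = divergent or sub.divergent
            tree.sum_accept += sub.sum_accept
            tree.n_steps += sub.n_steps
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.random()) < sub.log_weight - tree.log_weight:
            tree.x_prop, tree.g_prop, tree.logp_prop = sub.x_prop, sub.g_prop, sub.logp_prop
        tree = _merge_top(tree, sub, v > 0)
        depth += 1
        if _uturn(tree, metric):
            break
    accept_stat = tree.sum_accept / max(tree.n_steps, 1)
    return tree.x_prop, tree.g_prop, tree.logp_prop, accept_stat, divergent, depth, h0


def _merge_top(tree: _Tree, sub: _Tree, going_right: bool) -> _Tree:
    if going_right:
        tree.x_plus, tree.p_plus, tree.g_plus = sub.x_plus, sub.p_plus, sub.g_plus
    else:
        tree.x_minus, tree.p_minus, tree.g_minus = sub.x_minus, sub.p_minus, sub.g_minus
    tree.log_weight = np.logaddexp(tree.log_weight, sub.log_weight)
    tree.sum_p = tree.sum_p + sub.sum_p
    tree.sum_accept += sub.sum_accept
    tree.n_steps += sub.n_steps
    return tree


def sample_nuts(logp_grad, x0, n_warmup: int, n_draws: int,
                rng: np.random.Generator | int, target_accept: float = 0.9,
                max_treedepth: int = 10, dense_mass: bool = False):
    """Run one NUTS chain.

    Parameters
    ----------
    logp_grad : callable x -> (logp, grad), both finite at x0.
    x0 : initial position (unconstrained).
    n_warmup, n_draws : warmup (adaptation) and kept-draw counts.
    rng : numpy Generator or seed.
    target_accept : dual-averaging target for the acceptance statistic.
    dense_mass : adapt a dense (full-covariance) mass matrix instead of a
        diagonal one; pays off when the posterior has strong linear
        correlations, e.g. between hierarchy levels.

    Returns
    -------
    draws : (n_draws, d) array of kept positions.
    stats : NUTSStats
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.array(x0, dtype=float)
    d = x.size
    logp, g = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("log posterior not finite at the initial point")
    metric = _Metric(np.ones(d))
    eps = _find_reasonable_eps(logp_grad, x, g, logp, metric, rng)

    # dual averaging state
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # Stan-style windows: initial fast window, expanding slow windows for the
    # mass matrix, final fast window for the step size.
    init_buf = min(75, max(1, n_warmup // 5))
    term_buf = min(50, max(1, n_warmup // 10))
    slow_start = init_buf
    slow_end = max(slow_start, n_warmup - term_buf)
    window_ends = []
    w = 25
    pos = slow_start
    while pos < slow_end:
        end = min(pos + w, slow_end)
        if slow_end - end < w:  # absorb the remainder into the last window
            end = slow_end
        window_ends.append(end)
        pos = end
        w *= 2

    # Dense covariance is only estimable in the last (largest) slow window;
    # earlier windows adapt a diagonal metric even in dense mode.
    welford_n = 0
    welford_mean = np.zeros(d)
    welford_m2 = np.zeros((d, d)) if dense_mass else np.zeros(d)
    n_div_warmup = 0

    draws = np.empty((n_draws, d))
    stats = NUTSStats(divergent=np.zeros(n_draws, bool),
                      accept_stat=np.zeros(n_draws),
                      tree_depth=np.zeros(n_draws, int),
                      energy=np.zeros(n_draws),
                      step_size=eps, inv_mass=metric.inv_mass)

    total = n_warmup + n_draws
    wi = 0
    for it in range(total):
        x, g, logp, a_stat, divergent, depth, h0 = _transition(
            logp_grad, x, g, logp, eps, metric, max_treedepth, rng)
        warming = it < n_warmup
        if warming:
            n_div_warmup += int(divergent)
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (target_accept - a_stat) / (da_count + t0)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w_da = da_count ** (-kappa)
            log_eps_bar = w_da * log_eps + (1 - w_da) * log_eps_bar
            eps = np.exp(log_eps)
            if slow_start <= it < slow_end:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                if dense_mass:
                    welford_m2 += np.outer(delta, x - welford_mean)
                else:
                    welford_m2 += delta * (x - welford_mean)
            if wi < len(window_ends) and it + 1 == window_ends[wi]:
                if welford_n > 4:
                    var = welford_m2 / (welford_n - 1)
                    shrink = welford_n / (welford_n + 5.0)
                    last_window = wi == len(window_ends) - 1
                    if dense_mass and last_window and welford_n >= d + 25:
                        # shrink off-diagonals toward the diagonal so the
                        # metric stays well conditioned
                        diag = np.maximum(np.diag(var).copy(), 1e-10)
                        var = shrink * var
                        var[np.diag_indices(d)] = diag
                        var += 1e-8 * np.eye(d)
                    else:
                        diag = np.diag(var) if dense_mass else var
                        diag = shrink * diag + (1 - shrink) * 1e-3
                        var = np.maximum(diag, 1e-10)
                    metric = _Metric(var)
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps = _find_reasonable_eps(logp_grad, x, g, logp, metric, rng)
                mu = np.log(10 * eps)
                log_eps_bar, h_bar, da_count = np.log(eps), 0.0, 0
                wi += 1
            if it + 1 == n_warmup:
                eps = np.exp(log_eps_bar)
        else:
            k = it - n_warmup
            draws[k] = x
            stats.divergent[k] = divergent
            stats.accept_stat[k] = a_stat
            stats.tree_depth[k] = depth
            stats.energy[k] = -h0
    stats.step_size = float(eps)
    stats.inv_mass = metric.inv_mass
    stats.n_divergent_warmup = n_div_warmup
    return draws, stats
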