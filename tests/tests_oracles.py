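"""Independent oracles shared by tests: brute-force pair sums and de Boor."""

import numpy as np

import shade


def bruteforce_features(t_coords, s_coords, spec):
    """Double-loop pairwise feature sum, no neighbor pruning."""
    out = np.zeros((len(t_coords), spec.P))
    for i, t in enumerate(t_coords):
        for s in s_coords:
            d = float(np.hypot(t[0] - s[0], t[1] - s[1]))
            out[i] += shade.eval_basis(spec, [d])[0]
    return out


def de_boor_row(x, knots, degree):
    """Cox-de Boor recursion for all basis values at one point."""
    t = np.asarray(knots, float)
    n_basis = len(t) - degree - 1
    B = np.zeros(len(t) - 1)
    for i in range(len(t) - 1):
        if t[i] <= x < t[i + 1]:
            B[i] = 1.0
    if x == t[-1]:
        nz = np.nonzero(t < t[-1])[0]
        if nz.size:
            B[nz[-1]] = 1.0
    for k in range(1, degree + 1):
        B_next = np.zeros(len(t) - 1 - k)
        for i in range(len(B_next)):
            left = 0.0
            if t[i + k] > t[i]:
                left = (x - t[i]) / (t[i + k] - t[i]) * B[i]
            right = 0.0
            if t[i + k + 1] > t[i + 1]:
                right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * B[i + 1]
            B_next[i] = left + right
        B = B_next
    return B[:n_basis]
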