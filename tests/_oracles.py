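"""Independent brute-force oracles shared across test modules."""

import numpy as np


def grid_min_objective(X, y, step=0.001):
    """Coarse-to-fine enumeration of min ||y - Xp||^2 over the grid
    {p >= 0, sum(p) <= 1} with the given final step.

    The objective is convex, so the full-box coarse scan localizes the
    minimizer and refinement around it reaches the global grid minimum.
    """

    def enumerate_box(center, half, s):
        d = X.shape[1]
        axes = []
        for c in center:
            lo = max(0.0, c - half)
            hi = min(1.0, c + half)
            axes.append(np.arange(lo, hi + s / 2, s))
        P = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
        P = P[P.sum(axis=1) <= 1.0 + 1e-12]
        R = P @ X.T - y
        obj = (R * R).sum(axis=1)
        k = int(np.argmin(obj))
        return P[k], float(obj[k])

    d = X.shape[1]
    p, _ = enumerate_box(np.full(d, 0.5), 0.5, 0.05)
    for s in (0.01, step):
        p, best = enumerate_box(p, 5 * s, s)
    return best
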