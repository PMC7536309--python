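"""Independent reference implementations used to cross-check the package."""

import numpy as np


def brute_force_greedy(X, y, nvar):
    """Greedy covariance selection, re-implemented from the definition:
    explicit covariance scan over columns plus explicit projection-based
    deflation at every step.  Deliberately naive and independent of the
    package's vectorized implementation."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n = len(y)
    chosen = []
    for _ in range(nvar):
        best_j, best_crit = None, -1.0
        for j in range(X.shape[1]):
            if j in chosen or np.allclose(X[:, j], 0):
                continue
            c = (X[:, j] @ y / (n - 1)) ** 2
            if c > best_crit + 1e-15:
                best_crit, best_j = c, j
        v = X[:, best_j].copy()
        chosen.append(best_j)
        proj = np.outer(v, v) / (v @ v)
        X = X - proj @ X
        y = y - proj @ y
    return chosen
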