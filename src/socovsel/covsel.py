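"""CovSel greedy covariance selection and sequential orthogonalization.

CovSel picks, at each step, the predictor column with maximal squared
covariance with the response, then deflates both the predictors and the
response by projecting out the picked column.  Deflation is what makes
the procedure parsimonious: a column highly correlated with an earlier
pick carries little residual covariance and will not be picked again.

The orthogonalization helpers implement the multi-block extension: before
a later block is searched, the subspace already explained by earlier
selected variables is removed from both that block and the response, so
each block can only contribute new information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CovSelSelection",
    "covsel_select",
    "orthogonalize_block",
    "orthogonalize_response",
]

# Relative singular-value cutoff for the pseudo-inverse in the projector
# (I - S (S^T S)^+ S^T); with ~20 samples collinear selections are likely.
PINV_RCOND = 1e-12

# A deflated column whose remaining squared norm is below this fraction of
# its original squared norm is numerically in the span of earlier picks.
_RANK_TOL = 1e-20


@dataclass(frozen=True)
class CovSelSelection:
    """Ordered selection: original column indices and per-step criterion values."""

    indices: tuple[int, ...]
    criteria: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.indices) != len(set(self.indices)):
            raise ValueError("selected indices must be unique")
        if len(self.criteria) != len(self.indices):
            raise ValueError("one criterion value per selected index")


def covsel_select(
    X: np.ndarray, y: np.ndarray, nvar: int, *, strict: bool = True
) -> CovSelSelection:
    """Greedy covariance selection with deflation.

    Parameters
    ----------
    X:
        Centred (typically autoscaled) predictor matrix, samples x columns.
    y:
        Centred response, one column.
    nvar:
        Number of variables to select.
    strict:
        If True, raise when fewer than ``nvar`` linearly independent
        columns are available; if False, stop early and return a shorter
        selection (used by grid searches on tiny folds).

    Returns
    -------
    CovSelSelection
        Indices refer to the *original* column positions; the criterion is
        the squared sample covariance of the deflated column with the
        deflated response at the moment of selection.  Ties break toward
        the lowest column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)}")
    if nvar < 1:
        raise ValueError("nvar must be a positive integer")
    if nvar > p:
        raise ValueError(f"nvar = {nvar} exceeds the {p} available columns")
    indices, criteria = _covsel_core(X, y, nvar, strict)
    return CovSelSelection(tuple(indices), tuple(criteria))


def _covsel_core(
    X: np.ndarray, y: np.ndarray, nvar: int, strict: bool
) -> tuple[list[int], list[float]]:
    """Validation-free greedy core shared with the cross-validation hot path."""
    n = X.shape[0]
    Xd = X.copy()
    yd = y.copy()
    norms0 = np.einsum("ij,ij->j", X, X)
    dead = norms0 == 0.0  # zero-variance columns never enter
    indices: list[int] = []
    criteria: list[float] = []
    denom = max(n - 1, 1)
    for _ in range(nvar):
        cov = Xd.T @ yd / denom
        crit = cov * cov
        normsd = np.einsum("ij,ij->j", Xd, Xd)
        exhausted = dead | (normsd <= _RANK_TOL * np.where(norms0 > 0, norms0, 1.0))
        crit[exhausted] = -1.0  # never pick a spent column, even over zero covariance
        if indices:
            crit[np.asarray(indices)] = -1.0
        j = int(np.argmax(crit))  # argmax takes the first (lowest) index on ties
        if crit[j] < 0.0:
            if strict:
                raise ValueError(
                    f"requested {nvar} variables but the column space is exhausted "
                    f"after {len(indices)} picks"
                )
            break
        indices.append(j)
        criteria.append(float(crit[j]))
        v = Xd[:, j]
        vv = float(v @ v)
        # deflate X and y by the projector I - v v^T / (v^T v)
        coef_x = (v @ Xd) / vv
        Xd = Xd - np.outer(v, coef_x)
        yd = yd - v * (float(v @ yd) / vv)
        Xd[:, j] = 0.0
    return indices, criteria


def _projection_weights(X_sel: np.ndarray, target: np.ndarray) -> np.ndarray:
    """W = (X_sel^T X_sel)^+ X_sel^T target, with a rank-tolerant pseudo-inverse."""
    gram = X_sel.T @ X_sel
    return np.linalg.pinv(gram, rcond=PINV_RCOND) @ (X_sel.T @ target)


def orthogonalize_block(
    X_next: np.ndarray, X_sel: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Project a later block onto the orthogonal complement of selected columns.

    Returns ``(X_orth, W)`` with ``X_orth = X_next - X_sel @ W``; the
    weights ``W`` (one row per selected column, one column per corrected
    column) are reused verbatim at prediction time, so new samples are
    corrected with training-set geometry.
    """
    X_next = np.asarray(X_next, dtype=float)
    if X_sel is None or X_sel.shape[1] == 0:
        return X_next.copy(), np.zeros((0, X_next.shape[1]))
    X_sel = np.asarray(X_sel, dtype=float)
    if X_sel.shape[0] != X_next.shape[0]:
        raise ValueError(
            f"row-count mismatch: selected columns have {X_sel.shape[0]} rows, "
            f"block has {X_next.shape[0]}"
        )
    W = _projection_weights(X_sel, X_next)
    return X_next - X_sel @ W, W


def orthogonalize_response(y: np.ndarray, X_sel: np.ndarray | None) -> np.ndarray:
    """Project the response onto the orthogonal complement of selected columns."""
    y = np.asarray(y, dtype=float).reshape(-1)
    if X_sel is None or X_sel.shape[1] == 0:
        return y.copy()
    X_sel = np.asarray(X_sel, dtype=float)
    if X_sel.shape[0] != len(y):
        raise ValueError(
            f"row-count mismatch: selected columns have {X_sel.shape[0]} rows, "
            f"response has {len(y)}"
        )
    w = _projection_weights(X_sel, y)
    return y - X_sel @ w
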