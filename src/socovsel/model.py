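"""The sequential orthogonalized covariance-selection classifier.

Fitting proceeds block by block in a chosen order.  From the first block,
CovSel picks the columns with maximal squared covariance with the centred
binary response.  Every later block — and the response — is first
orthogonalized against *all* columns selected so far, so the block can
only contribute information the earlier blocks do not already carry; the
per-stage regression coefficients are then ordinary least squares of the
orthogonalized response on the stage's orthogonalized picks.  The final
prediction is the additive combination of the stage contributions

    yhat = X_1,sel B_1 + X_2,sel B_2 + ... + intercept

and a one-dimensional Gaussian LDA on yhat turns the continuous
prediction into class labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .covsel import covsel_select, orthogonalize_block, orthogonalize_response
from .preprocessing import BlockScaler

__all__ = ["LdaRule", "OrthoStage", "SoCovSelModel", "fit_lda", "fit_so_covsel"]


@dataclass
class LdaRule:
    """One-dimensional Gaussian LDA on the predicted response.

    ``threshold`` is the yhat value where the two class discriminant
    scores are equal; with equal priors it is the midpoint of the class
    means.  A sample exactly at the threshold is assigned to class 1.
    """

    mean0: float
    mean1: float
    pooled_var: float
    prior0: float
    prior1: float
    threshold: float

    def predict(self, yhat: np.ndarray) -> np.ndarray:
        yhat = np.asarray(yhat, dtype=float)
        if self.mean1 >= self.mean0:
            return (yhat >= self.threshold).astype(int)
        return (yhat <= self.threshold).astype(int)


def fit_lda(yhat_train: np.ndarray, labels: np.ndarray, priors: str | tuple = "empirical") -> LdaRule:
    """Fit the 1-D LDA rule: class means, pooled (n-2) variance, priors, threshold.

    ``priors`` may be ``"empirical"`` (class frequencies), ``"equal"``, or an
    explicit ``(prior0, prior1)`` pair.
    """
    yhat_train = np.asarray(yhat_train, dtype=float).reshape(-1)
    labels = np.asarray(labels, dtype=int).reshape(-1)
    g1 = yhat_train[labels == 1]
    g0 = yhat_train[labels == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both classes must be present to fit the LDA rule")
    n = len(yhat_train)
    m1, m0 = float(g1.mean()), float(g0.mean())
    ss = float(((g1 - m1) ** 2).sum() + ((g0 - m0) ** 2).sum())
    pooled = ss / (n - 2) if n > 2 else 0.0
    if pooled <= 0.0:
        raise ValueError("zero pooled variance: predicted responses are degenerate")
    if priors == "empirical":
        p1, p0 = len(g1) / n, len(g0) / n
    elif priors == "equal":
        p1 = p0 = 0.5
    else:
        p0, p1 = float(priors[0]), float(priors[1])
        total = p0 + p1
        p0, p1 = p0 / total, p1 / total
    if m1 == m0:
        threshold = m1  # degenerate separation; >= tie rule still applies
    else:
        threshold = 0.5 * (m0 + m1) + pooled * np.log(p0 / p1) / (m1 - m0)
    return LdaRule(m0, m1, pooled, p0, p1, float(threshold))


@dataclass
class OrthoStage:
    """One fitted stage: which block, which columns, and how to correct them.

    ``W`` has one row per previously selected column (accumulated across
    earlier stages, in selection order) and one column per this stage's
    selected columns; at prediction time the new sample's selected values
    are corrected as ``x_orth = x_sel - s_prev @ W`` before applying ``B``.
    """

    block_name: str
    block_index: int
    selected_indices: tuple[int, ...]
    selected_names: tuple[str, ...]
    W: np.ndarray
    B: np.ndarray
    criteria: tuple[float, ...]


@dataclass
class SoCovSelModel:
    block_order: tuple[str, ...]
    block_widths: tuple[int, ...]
    stages: list[OrthoStage]
    intercept: float
    lda: LdaRule
    scaler: BlockScaler | None = None
    analyte_names: tuple[tuple[str, ...], ...] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected_names(self) -> list[str]:
        return [a for st in self.stages for a in st.selected_names]

    @property
    def complexities(self) -> tuple[int, ...]:
        by_block = {st.block_index: len(st.selected_indices) for st in self.stages}
        return tuple(by_block.get(k, 0) for k in range(len(self.block_order)))

    # -- prediction ------------------------------------------------------

    def predict_response(self, blocks_new: Sequence[np.ndarray]) -> np.ndarray:
        """Continuous prediction yhat for new samples (already autoscaled blocks).

        Blocks must be supplied in the model's block order with the
        training (post-filter, pre-selection) widths.
        """
        blocks_new = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks_new]
        if len(blocks_new) != len(self.block_order):
            raise ValueError(
                f"expected {len(self.block_order)} blocks, got {len(blocks_new)}"
            )
        for b, w, name in zip(blocks_new, self.block_widths, self.block_order):
            if b.shape[1] != w:
                raise ValueError(f"block {name!r} has width {b.shape[1]}, expected {w}")
        n = blocks_new[0].shape[0]
        if any(b.shape[0] != n for b in blocks_new):
            raise ValueError("blocks must share the same number of rows")
        yhat = np.full(n, self.intercept, dtype=float)
        S_new = np.empty((n, 0))
        for st in self.stages:
            x_sel = blocks_new[st.block_index][:, list(st.selected_indices)]
            x_orth = x_sel - S_new @ st.W if S_new.shape[1] else x_sel
            yhat += x_orth @ st.B
            S_new = np.hstack([S_new, x_sel])
        return yhat

    def classify(self, blocks_new: Sequence[np.ndarray]) -> np.ndarray:
        """Predicted labels in {1, 0} (ties at the LDA threshold go to class 1)."""
        return self.lda.predict(self.predict_response(blocks_new))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "block_order": list(self.block_order),
            "block_widths": list(self.block_widths),
            "intercept": self.intercept,
            "lda": vars(self.lda).copy(),
            "stages": [
                {
                    "block_name": st.block_name,
                    "block_index": st.block_index,
                    "selected_indices": list(st.selected_indices),
                    "selected_names": list(st.selected_names),
                    "W": st.W.tolist(),
                    "B": st.B.tolist(),
                    "criteria": list(st.criteria),
                }
                for st in self.stages
            ],
            "analyte_names": [list(a) for a in self.analyte_names]
            if self.analyte_names is not None
            else None,
            "meta": self.meta,
        }
        if self.scaler is not None:
            d["scaler"] = {
                "block_names": self.scaler.block_names,
                "means": [m.tolist() for m in self.scaler.means],
                "sds": [s.tolist() for s in self.scaler.sds],
                "n_fit": self.scaler.n_fit,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SoCovSelModel":
        scaler = None
        if "scaler" in d:
            sc = d["scaler"]
            scaler = BlockScaler(
                list(sc["block_names"]),
                [np.asarray(m, dtype=float) for m in sc["means"]],
                [np.asarray(s, dtype=float) for s in sc["sds"]],
                int(sc["n_fit"]),
            )
        return cls(
            block_order=tuple(d["block_order"]),
            block_widths=tuple(d["block_widths"]),
            stages=[
                OrthoStage(
                    st["block_name"],
                    int(st["block_index"]),
                    tuple(st["selected_indices"]),
                    tuple(st["selected_names"]),
                    np.asarray(st["W"], dtype=float).reshape(-1, len(st["B"])),
                    np.asarray(st["B"], dtype=float),
                    tuple(st["criteria"]),
                )
                for st in d["stages"]
            ],
            intercept=float(d["intercept"]),
            lda=LdaRule(**d["lda"]),
            scaler=scaler,
            analyte_names=tuple(tuple(a) for a in d["analyte_names"])
            if d.get("analyte_names")
            else None,
            meta=d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SoCovSelModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_so_covsel(
    blocks_ordered: Sequence[np.ndarray],
    y: np.ndarray,
    complexities: Sequence[int],
    *,
    block_names: Sequence[str] | None = None,
    analyte_names: Sequence[Sequence[str]] | None = None,
    priors: str | tuple = "empirical",
    scaler: BlockScaler | None = None,
) -> SoCovSelModel:
    """Fit the sequential model on (already autoscaled) block matrices.

    ``complexities[k]`` is the number of variables to select from the k-th
    block in the given order; a 0 skips the block entirely.  At least one
    entry must be positive and ``y`` must contain both classes.
    """
    blocks = [np.asarray(b, dtype=float) for b in blocks_ordered]
    y = np.asarray(y, dtype=float).reshape(-1)
    complexities = [int(c) for c in complexities]
    if len(complexities) != len(blocks):
        raise ValueError("one complexity per block is required")
    if all(c == 0 for c in complexities):
        raise ValueError("at least one block must contribute a variable")
    if not set(np.unique(y)).issubset({0.0, 1.0}) or len(np.unique(y)) < 2:
        raise ValueError("y must be binary 0/1 with both classes present")
    n = len(y)
    for k, (b, c) in enumerate(zip(blocks, complexities)):
        if b.shape[0] != n:
            raise ValueError(f"block {k} has {b.shape[0]} rows, expected {n}")
        if c < 0 or c > b.shape[1]:
            raise ValueError(
                f"block {k}: requested {c} variables from {b.shape[1]} columns"
            )
    if block_names is None:
        block_names = [f"block{k + 1}" for k in range(len(blocks))]
    if analyte_names is None:
        analyte_names = [
            [f"{bn}_v{j + 1}" for j in range(b.shape[1])]
            for bn, b in zip(block_names, blocks)
        ]

    y_c = y - y.mean()
    S = np.empty((n, 0))
    contrib = np.zeros(n)
    stages: list[OrthoStage] = []
    for k, (X, c) in enumerate(zip(blocks, complexities)):
        if c == 0:
            continue
        X_orth, W_full = orthogonalize_block(X, S)
        y_orth = orthogonalize_response(y_c, S)
        sel = covsel_select(X_orth, y_orth, c, strict=False)
        idx = list(sel.indices)
        criteria = list(sel.criteria)
        if len(idx) < c:
            # Column space exhausted: the remaining requested picks carry no
            # new information.  Fill with the lowest-index unused columns
            # (criterion 0); least squares leaves their coefficients ~0.
            for j in range(X.shape[1]):
                if len(idx) == c:
                    break
                if j not in idx:
                    idx.append(j)
                    criteria.append(0.0)
        Xsel_orth = X_orth[:, idx]
        # columns annihilated by orthogonalization carry no information and
        # must not receive explosive least-squares coefficients
        orig_norm = np.linalg.norm(X[:, idx], axis=0)
        live = np.linalg.norm(Xsel_orth, axis=0) > 1e-10 * np.where(orig_norm > 0, orig_norm, 1.0)
        B = np.zeros(len(idx))
        if live.any():
            B[live], *_ = np.linalg.lstsq(Xsel_orth[:, live], y_orth, rcond=None)
        contrib += Xsel_orth @ B
        stages.append(
            OrthoStage(
                block_name=str(block_names[k]),
                block_index=k,
                selected_indices=tuple(idx),
                selected_names=tuple(analyte_names[k][j] for j in idx),
                W=W_full[:, idx] if W_full.shape[0] else np.zeros((0, len(idx))),
                B=B,
                criteria=tuple(criteria),
            )
        )
        S = np.hstack([S, X[:, idx]])

    intercept = float(y.mean() - contrib.mean())
    yhat_train = contrib + intercept
    lda = fit_lda(yhat_train, y.astype(int), priors)
    return SoCovSelModel(
        block_order=tuple(block_names),
        block_widths=tuple(b.shape[1] for b in blocks),
        stages=stages,
        intercept=intercept,
        lda=lda,
        scaler=scaler,
        analyte_names=tuple(tuple(a) for a in analyte_names),
    )
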