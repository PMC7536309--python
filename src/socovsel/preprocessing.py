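"""Detection-limit filtering and per-block autoscaling.

Autoscaling (mean-centre, divide by the n-1 standard deviation) is the
standard chemometric pretreatment: it puts analytes measured on very
different concentration scales (pg/mL cytokines vs µM amino acids) on a
common footing so that covariance-based selection compares information,
not units.  The scaler can be fitted on any row subset, which is what
makes leakage-free, train-fold-only scaling inside cross-validation
possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Block, MultiBlockDataset

__all__ = ["BlockScaler", "filter_below_lod", "fit_scaler", "apply_scaler"]


@dataclass
class BlockScaler:
    """Per-block column means and standard deviations (concentration units)."""

    block_names: list[str]
    means: list[np.ndarray]
    sds: list[np.ndarray]
    n_fit: int

    def __post_init__(self) -> None:
        for name, m, s in zip(self.block_names, self.means, self.sds):
            if len(m) != len(s):
                raise ValueError(f"block {name!r}: mean/SD length mismatch")
            if np.any(s <= 0):
                raise ValueError(f"block {name!r}: non-positive standard deviation")


def filter_below_lod(
    ds: MultiBlockDataset, min_detected_fraction: float = 1.0
) -> tuple[MultiBlockDataset, list[str]]:
    """Drop analytes whose detected fraction falls below a threshold.

    With the default ``min_detected_fraction = 1.0`` an analyte is removed
    as soon as any sample is censored — the strictest policy, which
    reproduces removing fully-censored assays.  The removed list follows
    panel order (block order, then column order).  Block structure is
    preserved; a block emptied entirely is an error rather than a silent
    disappearance.
    """
    if not 0.0 <= min_detected_fraction <= 1.0:
        raise ValueError("min_detected_fraction must lie in [0, 1]")
    removed: list[str] = []
    new_blocks: list[Block] = []
    for b in ds.blocks:
        detected = 1.0 - b.censored.to_numpy().mean(axis=0)
        keep = [a for a, f in zip(b.analytes, detected) if f >= min_detected_fraction]
        removed.extend(a for a, f in zip(b.analytes, detected) if f < min_detected_fraction)
        if not keep:
            raise ValueError(f"block {b.name!r} would be emptied by detection-limit filtering")
        new_blocks.append(Block(b.name, b.data[keep].copy(), b.censored[keep].copy()))
    out = MultiBlockDataset(list(ds.sample_ids), new_blocks, ds.y.copy(), dict(ds.meta))
    return out, removed


def fit_scaler(ds: MultiBlockDataset, rows: Sequence[int] | None = None) -> BlockScaler:
    """Fit per-column autoscaling parameters on a row subset (default: all rows)."""
    idx = list(range(ds.n_samples)) if rows is None else list(rows)
    if len(idx) < 2:
        raise ValueError("autoscaling needs at least two rows")
    means, sds = [], []
    for b in ds.blocks:
        sub = b.values[idx]
        cens = b.censored.to_numpy()[idx]
        if np.isnan(sub).any():
            j = int(np.argwhere(np.isnan(sub))[0][1])
            kind = "censored" if cens[np.isnan(sub[:, j]), j].any() else "missing"
            raise ValueError(
                f"analyte {b.analytes[j]!r} has {kind} values in the scaling rows; "
                "filter or handle them before autoscaling"
            )
        m = sub.mean(axis=0)
        s = sub.std(axis=0, ddof=1)
        if np.any(s == 0):
            j = int(np.argmax(s == 0))
            raise ValueError(f"analyte {b.analytes[j]!r} is constant over the scaling rows")
        means.append(m)
        sds.append(s)
    return BlockScaler(ds.block_names, means, sds, len(idx))


def apply_scaler(sc: BlockScaler, ds: MultiBlockDataset) -> MultiBlockDataset:
    """Autoscale every block with the scaler's (possibly out-of-sample) parameters."""
    if sc.block_names != ds.block_names:
        raise ValueError(f"scaler blocks {sc.block_names} != dataset blocks {ds.block_names}")
    new_blocks = []
    for b, m, s in zip(ds.blocks, sc.means, sc.sds):
        if b.data.shape[1] != len(m):
            raise ValueError(
                f"block {b.name!r} width {b.data.shape[1]} does not match scaler width {len(m)}"
            )
        scaled = (b.values - m) / s
        new_blocks.append(
            Block(
                b.name,
                pd.DataFrame(scaled, columns=b.analytes, index=b.data.index),
                b.censored.copy(),
            )
        )
    return MultiBlockDataset(list(ds.sample_ids), new_blocks, ds.y.copy(), dict(ds.meta))


def scale_matrices(
    train: list[np.ndarray], test: list[np.ndarray] | None = None
) -> tuple[list[np.ndarray], list[np.ndarray] | None]:
    """Autoscale raw block matrices on the training rows only.

    Array-level twin of :func:`fit_scaler`/:func:`apply_scaler` used in the
    cross-validation hot path, where constructing DataFrames per fold would
    dominate the runtime.
    """
    out_tr, out_te = [], []
    for k, X in enumerate(train):
        m = X.mean(axis=0)
        s = X.std(axis=0, ddof=1)
        if np.any(s == 0):
            raise ValueError(f"constant column in block index {k} over the training rows")
        out_tr.append((X - m) / s)
        if test is not None:
            out_te.append((test[k] - m) / s)
    return out_tr, (out_te if test is not None else None)
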