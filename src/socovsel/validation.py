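"""Repeated double cross-validation, selection frequencies, permutation test.

Double cross-validation (DCV) nests two loops: the *inner* loop picks the
block order and the per-block number of selected variables by k-fold
cross-validated misclassification count on the outer-training samples;
the *outer* loop refits with the winning settings and predicts samples
that never touched model building.  Repeating the whole procedure over
many random partitions (rDCV) yields spread estimates for the figures of
merit and, because each repetition x outer-segment pair fits its own
model, a selection-frequency tally that measures how robustly each
analyte is picked.

The permutation test re-runs the same machinery on label-permuted data to
build the null distribution of accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Sequence

import numpy as np

from .covsel import _RANK_TOL
from .data_model import MultiBlockDataset
from .model import SoCovSelModel, fit_so_covsel
from .preprocessing import scale_matrices

__all__ = [
    "RdcvConfig",
    "DcvRunResult",
    "RdcvSummary",
    "PermutationResult",
    "make_partition",
    "inner_select",
    "run_dcv",
    "run_rdcv",
    "permutation_test",
]

_SEED_MOD = 2**31 - 1


@dataclass
class RdcvConfig:
    """Settings for repeated double cross-validation.

    Defaults mirror the study design this pipeline targets: 50
    repetitions, leave-one-out outer loop on 21 samples, 5 inner
    cancelation groups, per-block complexity 0..4 with the all-zero tuple
    excluded, and all block orders as candidates.
    """

    n_repetitions: int = 50
    n_outer_groups: int = 21
    n_inner_groups: int = 5
    complexity_min: int = 0
    complexity_max: int = 4
    candidate_orders: tuple[tuple[int, ...], ...] | None = None  # None = all permutations
    scaling: str = "fold"  # "fold" (leakage-free) or "global" (pretreat once)
    priors: str = "empirical"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.scaling not in ("fold", "global"):
            raise ValueError("scaling must be 'fold' or 'global'")
        if self.complexity_min < 0 or self.complexity_max < max(1, self.complexity_min):
            raise ValueError("complexity range must allow at least one positive entry")
        if self.n_repetitions < 1 or self.n_outer_groups < 2 or self.n_inner_groups < 2:
            raise ValueError("repetition and group counts must be positive (groups >= 2)")

    def orders(self, n_blocks: int) -> tuple[tuple[int, ...], ...]:
        if self.candidate_orders is not None:
            for o in self.candidate_orders:
                if sorted(o) != list(range(n_blocks)):
                    raise ValueError(f"candidate order {o} is not a permutation of blocks")
            return tuple(tuple(o) for o in self.candidate_orders)
        return tuple(permutations(range(n_blocks)))


@dataclass
class DcvRunResult:
    """One DCV run: per-outer-segment choices and the pooled outer predictions."""

    orders: list[tuple[int, ...]]  # chosen block order per outer segment
    complexities: list[tuple[int, ...]]  # chosen counts, aligned to the chosen order
    selected: list[tuple[str, ...]]  # selected analyte names per outer model
    y_true: np.ndarray
    y_pred: np.ndarray  # every sample predicted exactly once
    outer_assignment: np.ndarray | None = None  # sample -> outer segment index

    @property
    def rate_class1(self) -> float:
        mask = self.y_true == 1
        return float((self.y_pred[mask] == 1).mean())

    @property
    def rate_class0(self) -> float:
        mask = self.y_true == 0
        return float((self.y_pred[mask] == 0).mean())

    @property
    def accuracy(self) -> float:
        return float((self.y_pred == self.y_true).mean())


@dataclass
class RdcvSummary:
    n_repetitions: int
    n_outer_groups: int
    total_models: int
    rates_class1: np.ndarray  # per-run correct-classification rate, cases
    rates_class0: np.ndarray
    accuracies: np.ndarray
    selection_frequency: dict[str, int]
    modal_order: tuple[str, ...]
    modal_complexity: tuple[int, ...]  # aligned to the modal order
    per_model: list[dict] = field(default_factory=list)
    config: RdcvConfig | None = None

    def _stats(self, v: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }

    @property
    def figures_of_merit(self) -> dict:
        return {
            "class1_rate": self._stats(self.rates_class1),
            "class0_rate": self._stats(self.rates_class0),
            "accuracy": self._stats(self.accuracies),
        }


@dataclass
class PermutationResult:
    n_randomizations: int
    observed: float
    null: np.ndarray
    p_value: float
    note: str = ""


def make_partition(
    n: int, k: int, labels: np.ndarray | None, rng: np.random.Generator
) -> np.ndarray:
    """Random stratified partition of ``n`` samples into ``k`` near-equal groups.

    Group sizes differ by at most one overall; within each class the
    assignment is round-robin over a shuffled group order, so class
    balance per group is as even as arithmetic permits.  ``k == n``
    degenerates to leave-one-out.
    """
    if not 2 <= k <= n:
        raise ValueError(f"group count k={k} must satisfy 2 <= k <= n={n}")
    group_order = rng.permutation(k)
    assign = np.empty(n, dtype=int)
    ptr = 0
    if labels is None:
        labels = np.zeros(n, dtype=int)
    labels = np.asarray(labels)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            assign[i] = group_order[ptr % k]
            ptr += 1
    return assign


# ---------------------------------------------------------------------------
# Inner-loop grid search
# ---------------------------------------------------------------------------
#
# The grid is (candidate order) x (per-block complexity tuple).  Because
# CovSel is greedy with deflation, the selection for complexity c is the
# length-c prefix of the selection for any larger complexity *given the
# same upstream selections*; the search therefore walks a tree branching
# on each block's complexity, running CovSel once per node instead of once
# per grid point.  Every node uses the same orthogonalization primitives
# as `fit_so_covsel`, so the result is identical to evaluating the grid
# point-by-point (asserted by a test).


def _tree_errors(
    blocks_tr: list[np.ndarray],
    y_tr: np.ndarray,
    blocks_te: list[np.ndarray],
    y_te: np.ndarray,
    cmaxs: Sequence[int],
    cmin: int,
    priors: str,
    out: dict[tuple[int, ...], int],
    fold_counts: dict[tuple[int, ...], int],
) -> None:
    """Accumulate per-complexity-tuple misclassification counts for one fold.

    Leaves are collected and classified in one vectorized pass: the 1-D
    LDA (class means, pooled n-2 variance, priors, equal-discriminant
    threshold, ties to class 1) is evaluated for all leaves at once with
    exactly the arithmetic of :func:`socovsel.model.fit_lda`.
    """
    n_tr, n_te = len(y_tr), len(y_te)
    ybar = y_tr.mean()
    y_c = y_tr - ybar
    n_blocks = len(blocks_tr)
    prefixes: list[tuple[int, ...]] = []
    rows_tr: list[np.ndarray] = []
    rows_te: list[np.ndarray] = []

    # Walking one stage fuses CovSel, orthogonalization, and the stage
    # regression: each greedy pick's deflation vector v is the Gram-Schmidt
    # residual of the picked column against everything selected so far, so
    # the stage contribution to yhat grows by the rank-1 projection
    # alpha * v (training) / alpha * v_te (test, with the training
    # coefficients), and later blocks are orthogonalized by the same rank-1
    # updates.  This reproduces, pick for pick, what `fit_so_covsel` +
    # `orthogonalize_block` compute on every grid point.

    def rec(
        k: int,
        rem_tr: list[np.ndarray],  # blocks k.. already orthogonalized vs selections
        rem_te: list[np.ndarray],
        y_cur: np.ndarray,  # response deflated against all selections so far
        contrib_tr: np.ndarray,
        contrib_te: np.ndarray,
        prefix: tuple[int, ...],
    ) -> None:
        if k == n_blocks:
            if sum(prefix) > 0:
                prefixes.append(prefix)
                rows_tr.append(contrib_tr)
                rows_te.append(contrib_te)
            return
        if cmin == 0:
            rec(k + 1, rem_tr[1:], rem_te[1:], y_cur, contrib_tr, contrib_te, prefix + (0,))
        X_tr = rem_tr[0]
        cmax = min(cmaxs[k], X_tr.shape[1], n_tr - 1)
        if cmax < max(cmin, 1):
            return
        X_tr = X_tr.copy()
        X_te = rem_te[0].copy()
        tail_tr = [b.copy() for b in rem_tr[1:]]
        tail_te = [b.copy() for b in rem_te[1:]]
        norms0 = np.einsum("ij,ij->j", X_tr, X_tr)
        norms = norms0.copy()
        floor = _RANK_TOL * np.where(norms0 > 0, norms0, 1.0)
        for step in range(1, cmax + 1):
            cov = X_tr.T @ y_cur
            crit = cov * cov
            crit[norms <= floor] = -1.0
            j = int(np.argmax(crit))
            if crit[j] < 0.0:
                break  # column space exhausted
            v = X_tr[:, j].copy()
            v_te = X_te[:, j].copy()
            vv = float(v @ v)
            alpha = float(v @ y_cur) / vv
            y_cur = y_cur - alpha * v
            contrib_tr = contrib_tr + alpha * v
            contrib_te = contrib_te + alpha * v_te
            coef = (v @ X_tr) / vv
            X_tr -= v[:, None] * coef
            X_te -= v_te[:, None] * coef
            norms -= coef * coef * vv
            norms[j] = 0.0
            for t in range(len(tail_tr)):
                coef_t = (v @ tail_tr[t]) / vv
                tail_tr[t] -= v[:, None] * coef_t
                tail_te[t] -= v_te[:, None] * coef_t
            if step >= max(cmin, 1):
                rec(k + 1, tail_tr, tail_te, y_cur, contrib_tr, contrib_te, prefix + (step,))

    rec(0, list(blocks_tr), list(blocks_te), y_c, np.zeros(n_tr), np.zeros(n_te), ())
    if not prefixes:
        return

    Ytr = np.vstack(rows_tr) + ybar  # leaves x n_tr
    Yte = np.vstack(rows_te) + ybar
    mask1 = y_tr == 1
    mask0 = ~mask1
    n1, n0 = int(mask1.sum()), int(mask0.sum())
    m1 = Ytr[:, mask1].mean(axis=1)
    m0 = Ytr[:, mask0].mean(axis=1)
    ss = ((Ytr[:, mask1] - m1[:, None]) ** 2).sum(axis=1) + (
        (Ytr[:, mask0] - m0[:, None]) ** 2
    ).sum(axis=1)
    pooled = ss / (n_tr - 2) if n_tr > 2 else np.zeros_like(ss)
    if priors == "empirical":
        p1, p0 = n1 / n_tr, n0 / n_tr
    elif priors == "equal":
        p1 = p0 = 0.5
    else:
        p0, p1 = float(priors[0]), float(priors[1])
        p0, p1 = p0 / (p0 + p1), p1 / (p0 + p1)
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        thr = 0.5 * (m0 + m1) + pooled * np.log(p0 / p1) / diff
    thr = np.where(diff == 0.0, m1, thr)
    pred1 = np.where(diff[:, None] >= 0.0, Yte >= thr[:, None], Yte <= thr[:, None])
    errors = (pred1 != (y_te == 1)[None, :]).sum(axis=1)
    errors[pooled <= 0.0] = n_te  # degenerate predictions score worst
    for prefix, e in zip(prefixes, errors):
        out[prefix] = out.get(prefix, 0) + int(e)
        fold_counts[prefix] = fold_counts.get(prefix, 0) + 1


def _grid_search(
    blocks: list[np.ndarray],
    y: np.ndarray,
    cfg: RdcvConfig,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Pick (block order, complexity tuple) minimizing inner-CV misclassifications.

    Ties break toward fewer total variables, then toward the earlier
    candidate order, then lexicographically on the complexity tuple.
    """
    n = len(y)
    k = min(cfg.n_inner_groups, n)
    assign = make_partition(n, k, y, rng)
    orders = cfg.orders(len(blocks))

    folds = []
    for g in range(k):
        te = np.flatnonzero(assign == g)
        tr = np.flatnonzero(assign != g)
        if len(np.unique(y[tr])) < 2:
            continue  # a fold whose training part is single-class cannot score
        if cfg.scaling == "fold":
            btr, bte = scale_matrices([b[tr] for b in blocks], [b[te] for b in blocks])
        else:
            btr, bte = [b[tr] for b in blocks], [b[te] for b in blocks]
        folds.append((btr, y[tr], bte, y[te]))
    if not folds:
        raise ValueError("no usable inner fold: training parts lost a class")

    best_key = None
    best = None
    for oi, order in enumerate(orders):
        errs: dict[tuple[int, ...], int] = {}
        fold_counts: dict[tuple[int, ...], int] = {}
        cmaxs = [cfg.complexity_max] * len(blocks)
        for btr, ytr, bte, yte in folds:
            _tree_errors(
                [btr[i] for i in order],
                ytr,
                [bte[i] for i in order],
                yte,
                cmaxs,
                cfg.complexity_min,
                cfg.priors,
                errs,
                fold_counts,
            )
        widths = [blocks[i].shape[1] for i in order]
        ranges = [range(cfg.complexity_min, min(cfg.complexity_max, w) + 1) for w in widths]
        for comp in product(*ranges):
            if sum(comp) == 0:
                continue
            if fold_counts.get(comp, 0) != len(folds):
                continue  # rank-exhausted on at least one fold: not comparable
            key = (errs[comp], sum(comp), oi, comp)
            if best_key is None or key < best_key:
                best_key = key
                best = (order, comp)
    if best is None:
        raise ValueError("empty model-selection grid")
    return best


def inner_select(
    train: MultiBlockDataset, cfg: RdcvConfig, rng: np.random.Generator
) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Dataset-level inner-loop model selection; returns block names + counts."""
    order, comp = _grid_search(train.matrices(), train.y.astype(float), cfg, rng)
    names = train.block_names
    return tuple(names[i] for i in order), comp


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------


def _fit_outer(
    blocks: list[np.ndarray],
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    order: tuple[int, ...],
    comp: tuple[int, ...],
    cfg: RdcvConfig,
    block_names: Sequence[str],
    analyte_names: Sequence[Sequence[str]],
) -> tuple[SoCovSelModel, np.ndarray]:
    if cfg.scaling == "fold":
        btr, bte = scale_matrices([b[tr] for b in blocks], [b[te] for b in blocks])
    else:
        btr, bte = [b[tr] for b in blocks], [b[te] for b in blocks]
    model = fit_so_covsel(
        [btr[i] for i in order],
        y[tr],
        comp,
        block_names=[block_names[i] for i in order],
        analyte_names=[analyte_names[i] for i in order],
        priors=cfg.priors,
    )
    pred = model.classify([bte[i] for i in order])
    return model, pred


def _run_dcv_arrays(
    blocks: list[np.ndarray],
    y: np.ndarray,
    block_names: Sequence[str],
    analyte_names: Sequence[Sequence[str]],
    cfg: RdcvConfig,
    rng: np.random.Generator,
) -> DcvRunResult:
    n = len(y)
    k = min(cfg.n_outer_groups, n)
    assign = None
    for _ in range(100):
        cand = make_partition(n, k, y, rng)
        ok = all(len(np.unique(y[np.flatnonzero(cand != g)])) == 2 for g in range(k))
        if ok:
            assign = cand
            break
    if assign is None:
        raise ValueError("could not build an outer partition keeping both classes in training")

    orders: list[tuple[int, ...]] = []
    comps: list[tuple[int, ...]] = []
    selected: list[tuple[str, ...]] = []
    y_pred = np.empty(n, dtype=int)
    for g in range(k):
        te = np.flatnonzero(assign == g)
        tr = np.flatnonzero(assign != g)
        order, comp = _grid_search([b[tr] for b in blocks], y[tr], cfg, rng)
        model, pred = _fit_outer(
            blocks, y, tr, te, order, comp, cfg, block_names, analyte_names
        )
        y_pred[te] = pred
        orders.append(order)
        comps.append(comp)
        selected.append(tuple(model.selected_names))
    return DcvRunResult(orders, comps, selected, y.astype(int).copy(), y_pred, assign)


def run_dcv(ds: MultiBlockDataset, cfg: RdcvConfig, rng: np.random.Generator) -> DcvRunResult:
    """One double cross-validation run over the dataset."""
    blocks = ds.matrices()
    if cfg.scaling == "global":
        blocks, _ = scale_matrices(blocks)
    analyte_names = [b.analytes for b in ds.blocks]
    return _run_dcv_arrays(blocks, ds.y.astype(float), ds.block_names, analyte_names, cfg, rng)


def run_rdcv(ds: MultiBlockDataset, cfg: RdcvConfig) -> RdcvSummary:
    """Repeated DCV: aggregate figures of merit, selection frequencies, modes.

    Run ``r`` uses the derived seed ``(base_seed + r) mod (2^31 - 1)``; the
    whole summary is bit-reproducible from the config alone.
    """
    blocks = ds.matrices()
    y = ds.y.astype(float)
    block_names = ds.block_names
    analyte_names = [b.analytes for b in ds.blocks]
    if cfg.scaling == "global":
        blocks, _ = scale_matrices(blocks)

    rates1, rates0, accs = [], [], []
    freq: Counter[str] = Counter()
    order_votes: Counter[tuple[int, ...]] = Counter()
    per_model: list[dict] = []
    for r in range(cfg.n_repetitions):
        rng = np.random.default_rng((cfg.base_seed + r) % _SEED_MOD)
        run = _run_dcv_arrays(blocks, y, block_names, analyte_names, cfg, rng)
        rates1.append(run.rate_class1)
        rates0.append(run.rate_class0)
        accs.append(run.accuracy)
        for seg, (order, comp, sel) in enumerate(zip(run.orders, run.complexities, run.selected)):
            freq.update(sel)
            order_votes[order] += 1
            per_model.append(
                {
                    "run": r,
                    "segment": seg,
                    "order": tuple(block_names[i] for i in order),
                    "complexity": comp,
                    "selected": sel,
                }
            )

    modal_order_idx = max(order_votes, key=lambda o: (order_votes[o], [-i for i in o]))
    comp_votes = Counter(
        m["complexity"] for m in per_model if m["order"] == tuple(block_names[i] for i in modal_order_idx)
    )
    modal_comp = max(comp_votes, key=lambda c: (comp_votes[c], [-v for v in c]))
    return RdcvSummary(
        n_repetitions=cfg.n_repetitions,
        n_outer_groups=min(cfg.n_outer_groups, ds.n_samples),
        total_models=len(per_model),
        rates_class1=np.array(rates1),
        rates_class0=np.array(rates0),
        accuracies=np.array(accs),
        selection_frequency=dict(freq),
        modal_order=tuple(block_names[i] for i in modal_order_idx),
        modal_complexity=modal_comp,
        per_model=per_model,
        config=cfg,
    )


def permutation_test(
    ds: MultiBlockDataset,
    cfg: RdcvConfig,
    n_randomizations: int,
    rng: np.random.Generator,
    *,
    observed: float | None = None,
) -> PermutationResult:
    """Label-permutation null for the rDCV overall accuracy.

    The observed statistic is the mean rDCV accuracy at ``cfg`` (or a
    caller-supplied value from a larger run); each randomization permutes
    the labels and recomputes the statistic from a single DCV run, a
    granularity recorded in the result.  The p-value uses the add-one
    rule, so it is bounded below by 1/(B+1).
    """
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    if observed is None:
        observed = float(np.mean(run_rdcv(ds, cfg).accuracies))
    blocks = ds.matrices()
    if cfg.scaling == "global":
        blocks, _ = scale_matrices(blocks)
    analyte_names = [b.analytes for b in ds.blocks]
    null = np.empty(n_randomizations)
    for b in range(n_randomizations):
        y_perm = rng.permutation(ds.y.astype(float))
        run = _run_dcv_arrays(blocks, y_perm, ds.block_names, analyte_names, cfg, rng)
        null[b] = run.accuracy
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_randomizations + 1)
    return PermutationResult(
        n_randomizations=n_randomizations,
        observed=observed,
        null=null,
        p_value=float(p),
        note="null statistic: overall accuracy from a single DCV run per randomization",
    )
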