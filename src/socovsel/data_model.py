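"""Multi-block data model and delimited-table I/O.

A multi-block dataset holds one concentration matrix per analytical
platform ("block") over a shared set of samples, together with a binary
class label (1 = case, 0 = control).  Blocks are ordered; the order in
which they enter the sequential model is a modelling choice made later.

Censored values (below the assay detection limit) are encoded on disk by
a sentinel token (default ``"<LOD"``) and in memory by ``NaN`` plus a
boolean censoring mask, so they are distinguishable from values missing
at random (empty cells, ``NaN`` with mask ``False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalytePanel",
    "Block",
    "MultiBlockDataset",
    "read_multiblock",
    "write_multiblock",
    "validate_dataset",
]

DEFAULT_LOD_SENTINEL = "<LOD"


@dataclass(frozen=True)
class AnalytePanel:
    """Assignment of analytes to named, ordered blocks.

    Parameters
    ----------
    block_names:
        Unique block identifiers in their declared order.
    membership:
        Mapping analyte name -> block name.  Every analyte belongs to
        exactly one block; insertion order within a block is preserved.
    """

    block_names: tuple[str, ...]
    membership: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.block_names:
            raise ValueError("panel must declare at least one block")
        if len(set(self.block_names)) != len(self.block_names):
            raise ValueError("block names must be unique")
        unknown = {b for b in self.membership.values() if b not in self.block_names}
        if unknown:
            raise ValueError(f"membership refers to undeclared blocks: {sorted(unknown)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnalytePanel":
        """Build a panel from (analyte, block) pairs; block order follows first appearance."""
        membership: dict[str, str] = {}
        block_names: list[str] = []
        for analyte, block in pairs:
            if analyte in membership:
                raise ValueError(f"analyte {analyte!r} listed more than once in panel")
            if block not in block_names:
                block_names.append(block)
            membership[analyte] = block
        return cls(tuple(block_names), membership)

    def analytes(self, block: str) -> list[str]:
        return [a for a, b in self.membership.items() if b == block]

    @property
    def assayed_count(self) -> dict[str, int]:
        return {b: len(self.analytes(b)) for b in self.block_names}

    @classmethod
    def read_csv(cls, path: str | Path) -> "AnalytePanel":
        df = pd.read_csv(path, dtype=str)
        if not {"analyte", "block"}.issubset(df.columns):
            raise ValueError("panel file must have columns 'analyte' and 'block'")
        return cls.from_pairs(zip(df["analyte"], df["block"]))

    def write_csv(self, path: str | Path) -> None:
        rows = [(a, b) for b in self.block_names for a in self.analytes(b)]
        pd.DataFrame(rows, columns=["analyte", "block"]).to_csv(path, index=False)


@dataclass
class Block:
    """One platform's concentration matrix (samples x analytes).

    ``data`` holds floats with NaN where no number is available;
    ``censored`` is True exactly where the NaN is a below-LOD censoring
    rather than a value missing at random.
    """

    name: str
    data: pd.DataFrame
    censored: pd.DataFrame

    @property
    def analytes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "Block":
        return Block(self.name, self.data.copy(), self.censored.copy())


@dataclass
class MultiBlockDataset:
    sample_ids: list[str]
    blocks: list[Block]
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    @property
    def analyte_names(self) -> list[str]:
        return [a for b in self.blocks for a in b.analytes]

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def matrices(self, order: Sequence[str] | None = None) -> list[np.ndarray]:
        """Block value matrices, optionally in a caller-supplied block order."""
        names = list(order) if order is not None else self.block_names
        return [self.block(n).values for n in names]

    def subset(self, rows: Sequence[int]) -> "MultiBlockDataset":
        rows = list(rows)
        return MultiBlockDataset(
            sample_ids=[self.sample_ids[i] for i in rows],
            blocks=[
                Block(b.name, b.data.iloc[rows].copy(), b.censored.iloc[rows].copy())
                for b in self.blocks
            ],
            y=self.y[rows].copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "MultiBlockDataset":
        return MultiBlockDataset(
            list(self.sample_ids), [b.copy() for b in self.blocks], self.y.copy(), dict(self.meta)
        )

    def panel(self) -> AnalytePanel:
        return AnalytePanel.from_pairs((a, b.name) for b in self.blocks for a in b.analytes)


def validate_dataset(ds: MultiBlockDataset) -> list[str]:
    """Check MultiBlockDataset invariants; return human-readable violations.

    Returns an empty list iff the dataset is well formed.  Never mutates
    or raises — callers that need hard failure wrap this themselves.
    """
    violations: list[str] = []
    n = len(ds.sample_ids)
    if len(ds.y) != n:
        violations.append(f"label vector length {len(ds.y)} != sample count {n}")
    for b in ds.blocks:
        if len(b.data) != n:
            violations.append(f"block {b.name!r} has {len(b.data)} rows, expected {n}")
        if b.data.shape != b.censored.shape:
            violations.append(f"block {b.name!r} censoring mask shape mismatch")
    seen: dict[str, str] = {}
    for b in ds.blocks:
        for a in b.analytes:
            if a in seen:
                violations.append(
                    f"analyte {a!r} appears in both block {seen[a]!r} and block {b.name!r}"
                )
            seen[a] = b.name
    yvals = set(np.unique(ds.y).tolist())
    if not yvals.issubset({0, 1}):
        violations.append(f"labels must be 0/1, found {sorted(yvals)}")
    elif len(yvals) < 2:
        violations.append("single class present")
    if len(set(ds.sample_ids)) != n:
        violations.append("sample ids not unique")
    return violations


def _parse_cell(token: str, sentinel: str) -> tuple[float, bool]:
    token = token.strip()
    if token == sentinel:
        return np.nan, True
    if token == "":
        return np.nan, False
    try:
        return float(token), False
    except ValueError as exc:
        raise ValueError(f"cannot parse value {token!r} as a number") from exc


def read_multiblock(
    data_path: str | Path,
    panel_path: str | Path,
    label_column: str,
    *,
    lod_sentinel: str = DEFAULT_LOD_SENTINEL,
    positive_label: str = "PF&S",
    negative_label: str = "nonPF&S",
    sample_id_column: str | None = "sample_id",
) -> MultiBlockDataset:
    """Read a samples-by-analytes CSV plus a panel CSV into a dataset.

    The data file must be rectangular with a header row; every non-label
    (and non-id) column must be mapped to a block by the panel.  The label
    column may contain the literal codes ``0``/``1`` or the configured
    class labels (default ``PF&S`` / ``nonPF&S``).
    """
    try:
        raw = pd.read_csv(data_path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed data table {data_path}: {exc}") from exc
    if raw.empty:
        raise ValueError(f"data table {data_path} has no data rows")
    if label_column not in raw.columns:
        raise ValueError(f"label column {label_column!r} not found in {data_path}")

    panel = AnalytePanel.read_csv(panel_path)

    if sample_id_column is not None and sample_id_column in raw.columns:
        sample_ids = raw[sample_id_column].astype(str).tolist()
    else:
        sample_id_column = None
        sample_ids = [f"S{i + 1:02d}" for i in range(len(raw))]

    skip = {label_column, sample_id_column} - {None}
    data_columns = [c for c in raw.columns if c not in skip]
    unmapped = [c for c in data_columns if c not in panel.membership]
    if unmapped:
        raise ValueError(f"column {unmapped[0]!r} is not mapped to any block by the panel")
    missing = [a for a in panel.membership if a not in raw.columns]
    if missing:
        raise ValueError(f"panel analyte {missing[0]!r} is absent from the data table header")

    y = np.empty(len(raw), dtype=int)
    for i, token in enumerate(raw[label_column]):
        token = str(token).strip()
        if token in ("1", positive_label):
            y[i] = 1
        elif token in ("0", negative_label):
            y[i] = 0
        else:
            raise ValueError(
                f"label column contains {token!r}; expected "
                f"{positive_label!r}/{negative_label!r} or 1/0"
            )

    blocks: list[Block] = []
    for bname in panel.block_names:
        cols = panel.analytes(bname)
        vals = np.empty((len(raw), len(cols)))
        cens = np.zeros((len(raw), len(cols)), dtype=bool)
        for j, col in enumerate(cols):
            for i, token in enumerate(raw[col]):
                vals[i, j], cens[i, j] = _parse_cell(str(token), lod_sentinel)
        blocks.append(
            Block(
                bname,
                pd.DataFrame(vals, columns=cols, index=sample_ids),
                pd.DataFrame(cens, columns=cols, index=sample_ids),
            )
        )
    return MultiBlockDataset(sample_ids, blocks, y, meta={"source": str(data_path)})


def write_multiblock(
    ds: MultiBlockDataset,
    data_path: str | Path,
    panel_path: str | Path,
    *,
    label_column: str = "group",
    lod_sentinel: str = DEFAULT_LOD_SENTINEL,
) -> None:
    """Write dataset + panel CSVs that round-trip through :func:`read_multiblock`."""
    columns: dict[str, list[str]] = {"sample_id": list(ds.sample_ids)}
    for b in ds.blocks:
        vals = b.values
        cens = b.censored.to_numpy()
        for j, a in enumerate(b.analytes):
            col = []
            for i in range(ds.n_samples):
                if cens[i, j]:
                    col.append(lod_sentinel)
                elif np.isnan(vals[i, j]):
                    col.append("")
                else:
                    col.append(repr(float(vals[i, j])))
            columns[a] = col
    columns[label_column] = [str(int(v)) for v in ds.y]
    pd.DataFrame(columns).to_csv(data_path, index=False)
    ds.panel().write_csv(panel_path)
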