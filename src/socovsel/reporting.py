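"""Result serialization, the selection-frequency chart, and the text report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .validation import PermutationResult, RdcvSummary

__all__ = [
    "summary_to_json",
    "selections_to_csv",
    "frequency_to_csv",
    "frequency_chart",
    "render_report",
    "write_manifest",
]


def summary_to_json(summary: RdcvSummary, path: str | Path) -> None:
    fom = summary.figures_of_merit
    payload = {
        "n_repetitions": summary.n_repetitions,
        "n_outer_groups": summary.n_outer_groups,
        "total_models": summary.total_models,
        "figures_of_merit": fom,
        "modal_order": list(summary.modal_order),
        "modal_complexity": list(summary.modal_complexity),
        "selection_frequency": summary.selection_frequency,
    }
    Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False))


def selections_to_csv(summary: RdcvSummary, path: str | Path) -> None:
    rows = [
        {
            "run": m["run"],
            "segment": m["segment"],
            "order": ">".join(m["order"]),
            "complexity": "-".join(str(c) for c in m["complexity"]),
            "selected": ";".join(m["selected"]),
        }
        for m in summary.per_model
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def frequency_to_csv(summary: RdcvSummary, path: str | Path, block_of: dict[str, str] | None = None) -> None:
    rows = [
        {"analyte": a, "block": (block_of or {}).get(a, ""), "count": c}
        for a, c in sorted(summary.selection_frequency.items(), key=lambda kv: -kv[1])
    ]
    pd.DataFrame(rows, columns=["analyte", "block", "count"]).to_csv(path, index=False)


def frequency_chart(
    summary: RdcvSummary,
    path: str | Path,
    block_of: dict[str, str] | None = None,
    block_order: list[str] | None = None,
) -> None:
    """One panel per block, bars = number of outer models selecting each analyte."""
    if block_of is None:
        blocks = {"all": sorted(summary.selection_frequency)}
    else:
        order = block_order or list(dict.fromkeys(block_of.values()))
        blocks = {b: [a for a, bb in block_of.items() if bb == b] for b in order}
    fig, axes = plt.subplots(
        len(blocks), 1, figsize=(10, 2.6 * len(blocks)), squeeze=False
    )
    for ax, (bname, analytes) in zip(axes.ravel(), blocks.items()):
        counts = [summary.selection_frequency.get(a, 0) for a in analytes]
        ax.bar(range(len(analytes)), counts, color="#4878a8")
        ax.set_xticks(range(len(analytes)))
        ax.set_xticklabels(analytes, rotation=90, fontsize=6)
        ax.set_ylabel("models")
        ax.set_title(f"{bname} (of {summary.total_models} models)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _pct(stats: dict) -> str:
    return f"{100 * stats['mean']:.1f} ± {100 * stats['sd']:.1f}%"


def render_report(
    summary: RdcvSummary,
    path: str | Path,
    *,
    permutation: PermutationResult | None = None,
    removed: list[str] | None = None,
    retained: int | None = None,
    top_n: int = 5,
) -> str:
    """Markdown report of the discrimination analysis; returns the text."""
    fom = summary.figures_of_merit
    lines = ["# Multi-block discrimination report", ""]
    if retained is not None or removed:
        lines += ["## Panel", ""]
        if retained is not None:
            lines.append(f"- Retained analytes: {retained}")
        if removed:
            lines.append(f"- Removed below detection limit ({len(removed)}): {', '.join(removed)}")
        lines.append("")
    lines += [
        "## Validated figures of merit",
        "",
        f"- Models fitted: {summary.total_models} "
        f"({summary.n_repetitions} repetitions × {summary.n_outer_groups} outer segments)",
        f"- Case correct-classification rate: {_pct(fom['class1_rate'])}",
        f"- Control correct-classification rate: {_pct(fom['class0_rate'])}",
        f"- Overall accuracy: {_pct(fom['accuracy'])}",
        f"- Modal block order: {' > '.join(summary.modal_order)}",
        f"- Modal complexity: {'-'.join(str(c) for c in summary.modal_complexity)}",
        "",
        "## Most frequently selected analytes",
        "",
    ]
    top = sorted(summary.selection_frequency.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    for a, c in top:
        lines.append(f"- {a}: {c}/{summary.total_models} models")
    if permutation is not None:
        lines += [
            "",
            "## Permutation test",
            "",
            f"- Randomizations: {permutation.n_randomizations}",
            f"- Observed accuracy: {100 * permutation.observed:.1f}%",
            f"- p-value: {permutation.p_value:.4g}",
            f"- {permutation.note}",
        ]
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


def write_manifest(path: str | Path, config: object, inputs: list[str | Path], seed: int) -> None:
    """Record everything needed to re-execute a run bit-identically."""
    from . import __version__

    digests = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "base_seed": seed,
        "config": asdict(config) if hasattr(config, "__dataclass_fields__") else config,
        "input_digests": digests,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
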