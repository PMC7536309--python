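#!/usr/bin/env python
"""Assemble the final Markdown report from the rDCV and permutation outputs."""

import json
from pathlib import Path

import numpy as np

from socovsel import RdcvConfig, filter_below_lod, read_multiblock, run_rdcv
from socovsel.reporting import render_report
from socovsel.validation import PermutationResult

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

if __name__ == "__main__":
    data = ROOT / "data"
    ds = read_multiblock(data / "concentrations.csv", data / "panel.csv", "group")
    ds, removed = filter_below_lod(ds)
    summary = run_rdcv(ds, RdcvConfig(base_seed=SEED))

    perm = None
    perm_file = ROOT / "permutation.json"
    if perm_file.exists():
        d = json.loads(perm_file.read_text())
        perm = PermutationResult(
            d["n_randomizations"], d["observed_accuracy"],
            np.array([]), d["p_value"], d["note"],
        )
    text = render_report(
        summary, ROOT / "report.md",
        permutation=perm, removed=removed, retained=len(ds.analyte_names),
    )
    print(text)
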