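#!/usr/bin/env python
"""Generate the synthetic study cohort and write it to results/data/.

Emulates the serum-panel design: 21 participants (11 cases, 10 controls),
75 assayed analytes across three platform blocks, 16 of them fully below
the detection limit, and five planted discriminant markers (2 amino
acids, 2 inflammatory mediators, 1 MDV cargo protein).
"""

import json
from pathlib import Path

from socovsel import SyntheticConfig, generate_assayed, write_multiblock

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    ds, truth = generate_assayed(cfg)
    write_multiblock(ds, OUT / "concentrations.csv", OUT / "panel.csv")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "planted": {b: list(v) for b, v in truth.planted.items()},
                "effect_sizes": truth.effect_sizes,
                "rho": truth.rho,
            },
            indent=1,
            ensure_ascii=False,
        )
    )
    n = sum(len(b.analytes) for b in ds.blocks)
    print(f"wrote {ds.n_samples}-sample cohort, {n} assayed analytes -> {OUT}")
    print(f"planted markers: {truth.planted}")
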