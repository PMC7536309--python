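"""Synthetic multi-block serum panels with planted ground truth.

The generator emulates a small case-control biomarker study: 21 samples
(11 cases, 10 controls), three platform blocks — amino acids and
derivatives, inflammatory mediators, and mitochondrial-derived-vesicle
(MDV) cargo proteins — with a handful of planted discriminant analytes, a
shared latent factor inducing inter-block correlation, and optional
below-detection-limit censoring that reproduces a 75-assayed /
59-retained panel.

Every variable is built on a standardized scale, x = rho*z + sqrt(1-rho^2)*eps,
with z a per-sample latent factor shared across blocks, so each variable
has unit marginal variance and the planted effect delta *is* the
standardized mean shift between classes.  For the lognormal family the
standardized variable is mapped to concentrations by exp(mu_j + sigma*x),
placing the effect before exponentiation so delta keeps the same meaning
in both families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Block, MultiBlockDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "censor_panel",
    "AMINO_ACIDS",
    "INFLAMMATION",
    "MDV",
    "BELOW_LOD",
]

# Full assayed vocabulary, by platform block.
AMINO_ACIDS = (
    "1-methylhistidine", "3-methylhistidine", "4-hydroxyproline",
    "α-aminobutyric acid", "β-alanine", "β-aminobutyric acid",
    "γ-aminobutyric acid", "alanine", "aminoadipic acid", "anserine",
    "arginine", "asparagine", "aspartic acid", "carnosine", "citrulline",
    "cystathionine", "cystine", "ethanolamine", "glutamic acid", "glycine",
    "histidine", "isoleucine", "leucine", "lysine", "methionine",
    "ornithine", "phenylalanine", "phosphoethanolamine", "phosphoserine",
    "proline", "sarcosine", "serine", "taurine", "threonine", "tryptophan",
    "tyrosine", "valine",
)
INFLAMMATION = (
    "BDNF", "CRP", "IL1-β", "IL1-ra", "IL2", "IL4", "IL5", "IL6", "IL7",
    "IL8", "IL9", "IL10", "IL12", "IL13", "IL15", "IL17", "FGF basic",
    "FGF21", "G-CSF", "GM-CSF", "IFN-γ", "MCP-1", "MIP-1α", "MIP-1β",
    "CCL5", "CCL11", "IP-10", "MPO", "PDGF-BB", "TNF-α", "VEGF",
)
MDV = ("ATP5A", "CD63", "MTCOI", "NDUFB8", "NDUFS3", "SDHB", "UQCRC2")

# Analytes whose serum concentrations fall below the assay detection limit
# in the emulated study (5 amino acids, 8 inflammatory mediators, 3 MDV
# proteins; 75 assayed -> 59 retained).
BELOW_LOD = {
    "amino_acids": (
        "anserine", "carnosine", "cystathionine", "γ-aminobutyric acid",
        "phosphoserine",
    ),
    "inflammation": ("IL2", "IL5", "IL7", "IL10", "IL13", "IL15", "G-CSF", "VEGF"),
    "mdv": ("MTCOI", "NDUFB8", "UQCRC2"),
}

_BLOCK_VOCAB = {"amino_acids": AMINO_ACIDS, "inflammation": INFLAMMATION, "mdv": MDV}
_DEFAULT_RETAINED = (32, 23, 4)
_DEFAULT_ASSAYED = (37, 31, 7)
# Default planted discriminant analytes per block (2, 2, 1).
_DEFAULT_PLANTED = {
    "amino_acids": ("phosphoethanolamine", "tryptophan"),
    "inflammation": ("IL1-ra", "MIP-1β"),
    "mdv": ("NDUFS3",),
}
# Plausible concentration medians per platform (µM, pg/mL, arbitrary units).
_SCALE_RANGES = {"amino_acids": (10.0, 300.0), "inflammation": (2.0, 400.0), "mdv": (0.2, 3.0)}


@dataclass
class SyntheticConfig:
    n_case: int = 11
    n_control: int = 10
    block_names: tuple[str, ...] = ("amino_acids", "inflammation", "mdv")
    block_widths: tuple[int, ...] = _DEFAULT_RETAINED
    planted_counts: tuple[int, ...] = (2, 2, 1)
    effect_size: float = 1.5  # standardized mean shift added to cases
    rho: float = 0.3  # shared latent-factor loading (inter-block redundancy)
    family: str = "lognormal"  # or "gaussian"
    log_sigma: float = 0.4  # lognormal spread on the log scale
    censor_counts: tuple[int, ...] = (5, 8, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be positive")
        if len(self.block_widths) != len(self.block_names):
            raise ValueError("block_widths must match block_names")
        if len(self.planted_counts) != len(self.block_names):
            raise ValueError("planted_counts must match block_names")
        for c, w in zip(self.planted_counts, self.block_widths):
            if c < 0 or c > w:
                raise ValueError("planted_counts must lie within block widths")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.family not in ("gaussian", "lognormal"):
            raise ValueError("family must be 'gaussian' or 'lognormal'")


@dataclass
class SyntheticTruth:
    planted: dict[str, tuple[str, ...]]  # block -> planted analyte names
    effect_sizes: dict[str, float] = field(default_factory=dict)  # analyte -> delta
    rho: float = 0.0


def _block_analytes(cfg: SyntheticConfig, k: int) -> list[str]:
    """Analyte names for block k: the study vocabulary at default widths,
    systematic names otherwise."""
    name = cfg.block_names[k]
    width = cfg.block_widths[k]
    vocab = _BLOCK_VOCAB.get(name)
    if vocab is not None:
        if width == len(vocab):  # assayed widths: full vocabulary
            return list(vocab)
        censored = set(BELOW_LOD.get(name, ()))
        retained = [a for a in vocab if a not in censored]
        if width == len(retained):
            return retained
    return [f"{name}_v{j + 1}" for j in range(width)]


def _planted_names(cfg: SyntheticConfig, k: int, analytes: list[str]) -> list[str]:
    name = cfg.block_names[k]
    count = cfg.planted_counts[k]
    defaults = _DEFAULT_PLANTED.get(name, ())
    if count <= len(defaults) and all(a in analytes for a in defaults[:count]):
        return list(defaults[:count])
    return analytes[:count]


def generate(cfg: SyntheticConfig) -> tuple[MultiBlockDataset, SyntheticTruth]:
    """Draw one dataset plus its ground truth; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_control
    y = np.array([1] * cfg.n_case + [0] * cfg.n_control)
    sample_ids = [f"{'PFS' if c else 'CTL'}{i + 1:02d}" for i, c in enumerate(y)]

    z = rng.standard_normal(n)  # shared latent factor
    blocks: list[Block] = []
    truth = SyntheticTruth(planted={}, rho=cfg.rho)
    for k, bname in enumerate(cfg.block_names):
        width = cfg.block_widths[k]
        analytes = _block_analytes(cfg, k)
        eps = rng.standard_normal((n, width))
        x = cfg.rho * z[:, None] + np.sqrt(1.0 - cfg.rho**2) * eps
        planted = _planted_names(cfg, k, analytes)
        for a in planted:
            x[:, analytes.index(a)] += cfg.effect_size * y
            truth.effect_sizes[a] = cfg.effect_size
        truth.planted[bname] = tuple(planted)
        lo, hi = _SCALE_RANGES.get(bname, (1.0, 100.0))
        median = np.exp(rng.uniform(np.log(lo), np.log(hi), size=width))
        if cfg.family == "lognormal":
            conc = np.exp(np.log(median) + cfg.log_sigma * x)
        else:
            conc = median * (1.0 + 0.15 * x)
        blocks.append(
            Block(
                bname,
                pd.DataFrame(conc, columns=analytes, index=sample_ids),
                pd.DataFrame(False, columns=analytes, index=sample_ids),
            )
        )
    ds = MultiBlockDataset(sample_ids, blocks, y, meta={"synthetic": True, "seed": cfg.seed})
    return ds, truth


def censor_panel(ds: MultiBlockDataset, cfg: SyntheticConfig) -> MultiBlockDataset:
    """Mark the designated analytes fully below-LOD in an assayed-width dataset.

    With the default assayed widths (37, 31, 7) the censor lists are the
    named study analytes; detection-limit filtering of the result recovers
    the retained 32/23/4 panel.
    """
    out = ds.copy()
    for k, b in enumerate(out.blocks):
        name = b.name
        if name in BELOW_LOD and len(b.analytes) == len(_BLOCK_VOCAB.get(name, ())):
            targets = BELOW_LOD[name]
        else:
            count = cfg.censor_counts[k] if k < len(cfg.censor_counts) else 0
            targets = tuple(b.analytes[:count])
        for a in targets:
            if a not in b.analytes:
                raise ValueError(f"censor list names absent analyte {a!r} in block {name!r}")
            b.data[a] = np.nan
            b.censored[a] = True
    return out


def generate_assayed(cfg: SyntheticConfig | None = None) -> tuple[MultiBlockDataset, SyntheticTruth]:
    """Convenience: full 75-analyte panel with the 16 study analytes censored."""
    base = cfg or SyntheticConfig()
    assayed = SyntheticConfig(
        n_case=base.n_case,
        n_control=base.n_control,
        block_names=base.block_names,
        block_widths=_DEFAULT_ASSAYED,
        planted_counts=base.planted_counts,
        effect_size=base.effect_size,
        rho=base.rho,
        family=base.family,
        log_sigma=base.log_sigma,
        censor_counts=base.censor_counts,
        seed=base.seed,
    )
    ds, truth = generate(assayed)
    return censor_panel(ds, assayed), truth
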