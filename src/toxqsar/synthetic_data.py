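"""Synthetic fixtures: numeric descriptor tables and toxicophore-labeled SMILES.

Two generators stand in for real screening data during development and
testing. The numeric generator emits a Gaussian class-conditional feature
table: ``n_informative`` columns have their class means separated by
``effect`` standard deviations, the rest are independent standard-normal
noise. Column names record which columns carry signal (``inf_*`` vs
``noise_*``) so recovery tests can score a selector without peeking at the
generator internals at run time.

The SMILES generator assembles substituted benzenes from a small fragment
vocabulary. Activity is structural: a molecule is active iff it carries the
planted toxicophore substructure (default: an aromatic nitro group, a
classic mutagenicity alert), optionally XOR-ed with label noise. Every
emitted SMILES is valid by construction and re-validated on emission.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_features import CompoundSet, DescriptorMatrix, LabeledCompound, validate_smiles


# ---------------------------------------------------------------------------
# numeric generator
# ---------------------------------------------------------------------------

@dataclass
class NumericSynthConfig:
    """Study conditions for the numeric fixture.

    Defaults: 500 samples, 20 features of which 5 are informative with a
    2-SD class separation, 30% active prevalence (screening data are
    imbalanced toward inactives).
    """

    n: int = 500
    p: int = 20
    n_informative: int = 5
    effect: float = 2.0
    prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4 or self.p < 1:
            raise ValueError("need n >= 4 and p >= 1")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("n_informative must lie in [0, p]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be non-negative")


def generate_numeric(cfg: NumericSynthConfig) -> tuple[DescriptorMatrix, np.ndarray]:
    """Generate a labeled numeric feature table; reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    n_active = int(round(cfg.n * cfg.prevalence))
    n_active = min(max(n_active, 2), cfg.n - 2)
    labels = np.zeros(cfg.n, dtype=int)
    labels[rng.choice(cfg.n, size=n_active, replace=False)] = 1

    values = rng.standard_normal((cfg.n, cfg.p))
    values[:, : cfg.n_informative] += cfg.effect * labels[:, None]
    names = [f"inf_{j:02d}" for j in range(cfg.n_informative)] + [
        f"noise_{j:02d}" for j in range(cfg.p - cfg.n_informative)
    ]
    ids = [f"c{i:04d}" for i in range(cfg.n)]
    return DescriptorMatrix(values, names, ids, "synthetic_numeric"), labels


# ---------------------------------------------------------------------------
# SMILES generator
# ---------------------------------------------------------------------------

#: benign substituents; none of them matches the default toxicophore
DEFAULT_FRAGMENTS = (
    "C", "CC", "CCC", "CCCC", "C(C)C",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br",
    "C(=O)N", "C(=O)O", "C(=O)OC", "C#N",
    "S", "SC", "C(F)(F)F", "CO",
)

#: substituent carrying the planted alert
_NITRO_SUBSTITUENT = "[N+](=O)[O-]"


@dataclass
class SmilesSynthConfig:
    """Study conditions for the chemistry fixture.

    300 substituted benzenes; ~40% carry an aromatic nitro group (the
    toxicophore) and are labeled active; no label noise by default so the
    structural signal is exact.
    """

    n: int = 300
    toxicophore: str = "c[N+](=O)[O-]"
    label_noise: float = 0.0
    fragment_vocabulary: tuple[str, ...] = DEFAULT_FRAGMENTS
    toxic_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 compounds")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if Chem.MolFromSmarts(self.toxicophore) is None:
            raise ValueError(f"toxicophore SMARTS does not parse: {self.toxicophore!r}")
        if not 0.0 < self.toxic_fraction < 1.0:
            raise ValueError("toxic_fraction must lie strictly in (0, 1)")


def _assemble(substituents: list[str]) -> str:
    """Benzene core with 1-3 substituents at fixed ring positions."""
    subs = list(substituents) + [""] * (3 - len(substituents))
    a, b, c = subs[:3]
    smiles = "c1cc" + (f"({a})" if a else "") + "cc" + (f"({b})" if b else "") + "c1" + c
    return smiles


def generate_smiles(cfg: SmilesSynthConfig) -> CompoundSet:
    """Generate a toxicophore-labeled compound set; reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    pattern = Chem.MolFromSmarts(cfg.toxicophore)
    vocab = list(cfg.fragment_vocabulary)
    for frag in vocab:
        if Chem.MolFromSmiles("C" + frag if frag in ("Cl", "Br", "F") else frag) is None:
            raise ValueError(f"fragment does not parse: {frag!r}")

    compounds: list[LabeledCompound] = []
    n_matches = 0
    for i in range(cfg.n):
        n_subs = int(rng.integers(1, 4))
        subs = [vocab[int(k)] for k in rng.integers(0, len(vocab), size=n_subs)]
        if rng.random() < cfg.toxic_fraction:
            subs[int(rng.integers(0, n_subs))] = _NITRO_SUBSTITUENT
        smiles = validate_smiles(_assemble(subs))
        mol = Chem.MolFromSmiles(smiles)
        matches = mol.HasSubstructMatch(pattern)
        n_matches += int(matches)
        label = int(matches) ^ int(rng.random() < cfg.label_noise)
        compounds.append(LabeledCompound(f"m{i:04d}", smiles, label))

    match_rate = n_matches / cfg.n
    if not 0.2 < match_rate < 0.8:
        raise ValueError(
            f"vocabulary produced a toxicophore match rate of {match_rate:.2f}, "
            "outside (0.2, 0.8); both classes must be well represented"
        )
    return CompoundSet(endpoint="synthetic", compounds=compounds)
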