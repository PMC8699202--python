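"""Synthetic tryptic-like peptides with a known ground-truth CCS function.

The generator emulates the make-up of a timsTOF tryptic data set: peptide
lengths of 7-45 residues drawn with realistic amino-acid frequencies, a
strong C-terminal K/R bias, charge states 2-4 assigned by a length-dependent
rule, occasional Met oxidation and N-terminal acetylation.

The ground-truth CCS is a documented stand-in, NOT a physical model: a
per-charge affine function of (neutral mass)^(2/3) — the surface scaling of
a roughly globular ion — plus small per-residue offsets and a positional
term that moves CCS when designated residues (proline, histidine by default)
sit closer to the C-terminus.  The positional term is what makes the
ground truth sequence-position dependent, so feature sets that encode
position can beat those that do not.  Gaussian noise of configurable sigma
(default 5 A^2, roughly the experimental scatter scale) is added on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemistry import (
    OXIDIZED_MET,
    Peptide,
    Residue,
    peptide_mass,
)

#: rough proteome-wide amino-acid frequencies used for residue sampling
AA_FREQUENCIES = {
    "A": 7.0, "C": 2.3, "D": 4.7, "E": 7.1, "F": 3.7, "G": 6.6, "H": 2.6,
    "I": 4.3, "K": 5.7, "L": 9.9, "M": 2.1, "N": 3.6, "P": 6.3, "Q": 4.8,
    "R": 5.6, "S": 8.3, "T": 5.3, "V": 6.0, "W": 1.2, "Y": 2.7,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_peptides: int = 1000
    length_range: tuple[int, int] = (7, 45)
    c_term_kr_prob: float = 0.9
    met_ox_prob: float = 0.1
    acetyl_prob: float = 0.05
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid length range")
        for p in (self.c_term_kr_prob, self.met_ox_prob, self.acetyl_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthParams:
    """Parameters of the constructed CCS function (see module docstring)."""

    intercepts: dict[int, float] = field(
        default_factory=lambda: {2: 80.0, 3: 100.0, 4: 120.0}
    )
    slopes: dict[int, float] = field(
        default_factory=lambda: {2: 2.4, 3: 2.9, 4: 3.0}
    )
    residue_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "G": -4.0, "A": -2.0, "S": -3.0, "P": 0.0, "V": 1.0, "T": -1.0,
            "C": 0.0, "L": 3.0, "I": 3.0, "N": -1.0, "D": -2.0, "Q": 0.0,
            "K": 4.0, "E": -1.0, "M": 1.0, "H": 2.0, "F": 4.0, "R": 5.0,
            "Y": 3.0, "W": 6.0, OXIDIZED_MET: -2.0,
        }
    )
    positional_residues: tuple[str, ...] = ("P", "H")
    positional_weight: float = 15.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.slopes.values()):
            raise ValueError("slopes must be positive")


def _charge_probs(n: int) -> tuple[float, float, float]:
    """Length-dependent charge assignment: longer peptides carry more protons."""
    if n <= 12:
        return (0.80, 0.18, 0.02)
    if n <= 22:
        return (0.55, 0.40, 0.05)
    if n <= 32:
        return (0.25, 0.55, 0.20)
    return (0.10, 0.50, 0.40)


def generate_peptides(cfg: GeneratorConfig) -> list[Peptide]:
    """Draw tryptic-like peptides; fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    symbols = np.array(list(AA_FREQUENCIES))
    weights = np.array(list(AA_FREQUENCIES.values()))
    weights = weights / weights.sum()
    lo, hi = cfg.length_range
    peptides: list[Peptide] = []
    for _ in range(cfg.n_peptides):
        n = int(rng.integers(lo, hi + 1))
        letters = list(rng.choice(symbols, size=n, p=weights))
        if rng.random() < cfg.c_term_kr_prob:
            letters[-1] = "K" if rng.random() < 0.5 else "R"
        residues = []
        for ch in letters:
            if ch == "M" and rng.random() < cfg.met_ox_prob:
                residues.append(Residue(OXIDIZED_MET, is_oxidized_met=True))
            else:
                residues.append(Residue(ch))
        acetyl = bool(rng.random() < cfg.acetyl_prob)
        z = int(rng.choice((2, 3, 4), p=_charge_probs(n)))
        peptides.append(Peptide(tuple(residues), n_term_acetylated=acetyl, charge=z))
    return peptides


def ground_truth_ccs(
    p: Peptide,
    params: GroundTruthParams | None = None,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Noiseless (sigma=0) or noisy ground-truth CCS in Angstrom^2."""
    params = params or GroundTruthParams()
    n = len(p)
    M = peptide_mass(p)
    ccs = params.intercepts[p.charge] + params.slopes[p.charge] * M ** (2.0 / 3.0)
    for j, r in enumerate(p.residues):
        ccs += params.residue_offsets[r.symbol]
        if r.symbol in params.positional_residues:
            rel = j / (n - 1) if n > 1 else 0.0
            ccs += params.positional_weight * rel
    if sigma > 0:
        if rng is None:
            raise ValueError("a random generator is required when sigma > 0")
        ccs += float(rng.normal(0.0, sigma))
    return float(ccs)


@dataclass
class LabeledSet:
    peptides: list[Peptide]
    ccs: np.ndarray

    def __len__(self) -> int:
        return len(self.peptides)


@dataclass
class DatasetSplits:
    train: LabeledSet
    val: LabeledSet
    test: LabeledSet


def make_dataset(
    cfg: GeneratorConfig, params: GroundTruthParams | None = None
) -> DatasetSplits:
    """Generate, label, deduplicate, shuffle and split 85/5/10.

    Duplicate modified-sequence strings are removed before splitting, so no
    peptide string occurs in more than one split.
    """
    if cfg.n_peptides < 20:
        raise ValueError("need at least 20 peptides to split 85/5/10")
    params = params or GroundTruthParams()
    rng = np.random.default_rng(cfg.seed + 104729)  # label noise + shuffle stream
    peptides = generate_peptides(cfg)
    seen: set[str] = set()
    unique: list[Peptide] = []
    for p in peptides:
        if p.sequence not in seen:
            seen.add(p.sequence)
            unique.append(p)
    ccs = np.array(
        [ground_truth_ccs(p, params, cfg.noise_sigma, rng) for p in unique]
    )
    n = len(unique)
    order = rng.permutation(n)
    n_train = int(round(0.85 * n))
    n_val = int(round(0.05 * n))
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    def subset(idx: np.ndarray) -> LabeledSet:
        return LabeledSet([unique[i] for i in idx], ccs[idx])

    return DatasetSplits(subset(idx_train), subset(idx_val), subset(idx_test))
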