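"""Peptide parsing, residue chemistry and mass computation.

A peptide is an ordered list of residues with a charge state (2-4) and an
optional N-terminal acetylation flag.  Two modifications are supported, the
only ones present in the timsTOF tryptic data this tool targets: N-terminal
acetylation and oxidation of methionine to methionine sulfoxide.  Oxidized
methionine is carried as a dedicated 21st residue symbol (lowercase ``m``).

Canonical sequence dialect
--------------------------
``[*]<residues>`` where ``*`` marks an acetylated N-terminus and each residue
is an uppercase one-letter code, with lowercase ``m`` for oxidized Met, e.g.
``*AAmK``.  The parser additionally accepts the bracketed dialect used by
common search-engine exports: a leading ``(ac)`` and ``(ox)`` following an
``M``, e.g. ``_(ac)AAM(ox)K_`` (surrounding underscores are ignored).

Residue chemistry (element counts, side-chain class flags, descriptor scales,
monoisotopic masses) is loaded from a versioned CSV shipped with the package
(``data/residue_chemistry_v1.csv``) and can be replaced by a user table with
the same columns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import InvalidChargeError, InvalidSequenceError, UnsupportedModificationError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
OXIDIZED_MET = "m"
ALPHABET = STANDARD_AA + OXIDIZED_MET
SUPPORTED_CHARGES = (2, 3, 4)

PROTON_MASS = 1.00727646688
#: monoisotopic atomic masses, Da
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

_DEFAULT_TABLE = "residue_chemistry_v1.csv"

#: class-flag column names, in the feature order of the residue descriptor set
CLASS_FLAG_COLUMNS = (
    "acidic",
    "modified",
    "amide",
    "nonpolar",
    "small",
    "uncharged_polar",
    "aliphatic_nonpolar",
    "aromatic",
    "positive",
    "hydroxyl",
)
DYAD_COLUMNS = ("dyad_ND", "dyad_EQ")
DESCRIPTOR_COLUMNS = (
    "hydropathy",
    "bulkiness",
    "polarity",
    "volume",
    "isoelectric_point",
    "helix_propensity",
)


@dataclass(frozen=True)
class ElementCounts:
    """Counts of H, C, N, O, S atoms."""

    H: int = 0
    C: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ("H", "C", "N", "O", "S"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(
            self.H + other.H,
            self.C + other.C,
            self.N + other.N,
            self.O + other.O,
            self.S + other.S,
        )

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        return ElementCounts(
            self.H - other.H,
            self.C - other.C,
            self.N - other.N,
            self.O - other.O,
            self.S - other.S,
        )

    def mass(self) -> float:
        """Monoisotopic mass of this composition in Da."""
        return sum(getattr(self, el) * m for el, m in ATOMIC_MASS.items())

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.H, self.C, self.N, self.O, self.S)


WATER = ElementCounts(H=2, O=1)
ACETYL = ElementCounts(H=2, C=2, O=1)  # net addition of an acetyl group


@dataclass(frozen=True)
class Residue:
    symbol: str
    is_oxidized_met: bool = False

    def __post_init__(self) -> None:
        if self.symbol not in ALPHABET:
            raise InvalidSequenceError(f"unknown residue symbol {self.symbol!r}")
        if self.is_oxidized_met != (self.symbol == OXIDIZED_MET):
            raise InvalidSequenceError(
                "is_oxidized_met must be true exactly for the oxidized-Met symbol"
            )


@dataclass(frozen=True)
class Peptide:
    residues: tuple[Residue, ...]
    n_term_acetylated: bool = False
    charge: int = 2

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidSequenceError("peptide must contain at least one residue")
        if self.charge not in SUPPORTED_CHARGES:
            raise InvalidChargeError(f"charge {self.charge} not in {SUPPORTED_CHARGES}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """Canonical modified-sequence string (without charge)."""
        prefix = "*" if self.n_term_acetylated else ""
        return prefix + "".join(r.symbol for r in self.residues)


@dataclass(frozen=True)
class ResidueChemistry:
    """Chemistry record for one residue symbol."""

    symbol: str
    one_hot_index: int
    composition: ElementCounts
    class_flags: tuple[int, ...]  # 10 side-chain class flags
    dyad_flags: tuple[int, int]  # {N,D} and {E,Q}
    descriptors: tuple[float, ...]  # 6 literature scales
    mono_mass: float


class ResidueChemistryTable:
    """The 21-entry residue chemistry table backing featurization and masses.

    Loaded from a CSV with one row per residue symbol; see the packaged
    ``residue_chemistry_v1.csv`` for the column contract.
    """

    def __init__(self, entries: dict[str, ResidueChemistry], source: str = "<memory>"):
        if set(entries) != set(ALPHABET):
            raise ValueError("chemistry table must cover exactly the 21-symbol alphabet")
        indices = sorted(e.one_hot_index for e in entries.values())
        if indices != list(range(21)):
            raise ValueError("one-hot indices must be a bijection onto 0-20")
        for e in entries.values():
            if len(e.descriptors) != 6:
                raise ValueError("descriptor vectors must have length 6")
        self._entries = entries
        self.source = source

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResidueChemistryTable":
        with open(path, newline="") as fh:
            return cls._parse(csv.DictReader(fh), source=str(path))

    @classmethod
    def default(cls) -> "ResidueChemistryTable":
        ref = resources.files("pepccs.data").joinpath(_DEFAULT_TABLE)
        with ref.open(newline="") as fh:
            return cls._parse(csv.DictReader(fh), source=_DEFAULT_TABLE)

    @classmethod
    def _parse(cls, reader: csv.DictReader, source: str) -> "ResidueChemistryTable":
        entries = {}
        for row in reader:
            sym = row["symbol"]
            entries[sym] = ResidueChemistry(
                symbol=sym,
                one_hot_index=int(row["one_hot_index"]),
                composition=ElementCounts(
                    *(int(row[el]) for el in ("H", "C", "N", "O", "S"))
                ),
                class_flags=tuple(int(row[c]) for c in CLASS_FLAG_COLUMNS),
                dyad_flags=tuple(int(row[c]) for c in DYAD_COLUMNS),
                descriptors=tuple(float(row[c]) for c in DESCRIPTOR_COLUMNS),
                mono_mass=float(row["mono_mass"]),
            )
        return cls(entries, source=source)

    def __getitem__(self, symbol: str) -> ResidueChemistry:
        return self._entries[symbol]

    def symbols(self) -> tuple[str, ...]:
        return tuple(sorted(self._entries, key=lambda s: self._entries[s].one_hot_index))

    def content_key(self) -> str:
        """Stable string over the table contents, used in featurization hashes."""
        parts = []
        for sym in self.symbols():
            e = self._entries[sym]
            parts.append(
                f"{sym}:{e.one_hot_index}:{e.composition.as_tuple()}:"
                f"{e.class_flags}:{e.dyad_flags}:{e.descriptors}:{e.mono_mass}"
            )
        return "|".join(parts)


_default_table: ResidueChemistryTable | None = None


def default_chemistry() -> ResidueChemistryTable:
    """The packaged residue chemistry table (cached)."""
    global _default_table
    if _default_table is None:
        _default_table = ResidueChemistryTable.default()
    return _default_table


def parse_peptide(text: str, charge: int) -> Peptide:
    """Parse a modified-sequence string into a :class:`Peptide`.

    Accepts the canonical dialect (``*`` acetylation prefix, lowercase ``m``
    for oxidized Met) and the bracketed dialect (``(ac)`` prefix, ``(ox)``
    after ``M``); surrounding underscores are stripped.
    """
    if charge not in SUPPORTED_CHARGES:
        raise InvalidChargeError(f"charge {charge} not in {SUPPORTED_CHARGES}")
    s = text.strip().strip("_")
    acetylated = False
    if s.startswith("(ac)"):
        acetylated = True
        s = s[4:]
    elif s.startswith("*"):
        acetylated = True
        s = s[1:]
    residues: list[Residue] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            end = s.find(")", i)
            if end < 0:
                raise InvalidSequenceError(f"unterminated modification mark in {text!r}")
            mark = s[i : end + 1]
            if mark == "(ox)":
                if not residues or residues[-1].symbol != "M":
                    raise UnsupportedModificationError(
                        "(ox) must directly follow an M residue"
                    )
                residues[-1] = Residue(OXIDIZED_MET, is_oxidized_met=True)
            else:
                raise UnsupportedModificationError(f"unsupported modification {mark!r}")
            i = end + 1
            continue
        if ch == OXIDIZED_MET:
            residues.append(Residue(OXIDIZED_MET, is_oxidized_met=True))
        elif ch in STANDARD_AA:
            residues.append(Residue(ch))
        else:
            raise InvalidSequenceError(f"unknown residue letter {ch!r} in {text!r}")
        i += 1
    if not residues:
        raise InvalidSequenceError("empty sequence")
    return Peptide(tuple(residues), n_term_acetylated=acetylated, charge=charge)


def format_peptide(p: Peptide) -> str:
    """Canonical string form; inverse of :func:`parse_peptide` on that dialect."""
    return p.sequence


def residue_composition(
    r: Residue, chem: ResidueChemistryTable | None = None
) -> ElementCounts:
    """Elemental composition of the residue (free amino acid minus water)."""
    chem = chem or default_chemistry()
    return chem[r.symbol].composition


def peptide_formula(p: Peptide, chem: ResidueChemistryTable | None = None) -> ElementCounts:
    """Molecular formula of the neutral peptide (residues + H2O, + acetyl)."""
    chem = chem or default_chemistry()
    total = WATER
    for r in p.residues:
        total = total + chem[r.symbol].composition
    if p.n_term_acetylated:
        total = total + ACETYL
    return total


def peptide_mass(p: Peptide, chem: ResidueChemistryTable | None = None) -> float:
    """Neutral monoisotopic mass in Da."""
    chem = chem or default_chemistry()
    mass = sum(chem[r.symbol].mono_mass for r in p.residues) + WATER.mass()
    if p.n_term_acetylated:
        mass += ACETYL.mass()
    return mass


def ion_mass(p: Peptide, chem: ResidueChemistryTable | None = None) -> float:
    """Monoisotopic mass of the protonated ion: neutral mass + z protons."""
    return peptide_mass(p, chem) + p.charge * PROTON_MASS
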