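"""Molecular-formula bookkeeping for a fragment library.

High-resolution mass spectra of small molecules are conventionally reported
as the protonated ion [M+H]+, so compound tables often carry the *ion*
formula (one H more than the neutral molecule).  This module parses such
formula strings, converts ion <-> neutral, counts heavy (non-hydrogen)
atoms -- the denominator of ligand efficiency -- and computes monoisotopic
m/z values for the [M+H]+ adduct.

The element set is deliberately small: the twelve elements that cover
essentially all fragment-sized drug-like chemistry.  Anything else is a
parse error, which doubles as a typo guard on hand-transcribed tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "Compound",
    "parse_formula",
    "neutral_from_protonated",
    "heavy_atom_count",
    "monoisotopic_mass",
    "monoisotopic_mz",
    "read_compound_table",
]

#: IUPAC monoisotopic atomic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType({
    "H": 1.00782503207,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
})

#: Mass of a proton (Da); [M+H]+ adds a proton, i.e. an H atom minus one electron.
PROTON_MASS = 1.007276466

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill convention: C first, then H, then the rest alphabetically.
# Without carbon, everything (H included) is alphabetical.
def _hill_order(symbols: set[str]) -> list[str]:
    if "C" in symbols:
        rest = sorted(symbols - {"C", "H"})
        return ["C"] + (["H"] if "H" in symbols else []) + rest
    return sorted(symbols)


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula operations."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral molecule or an adduct ion.

    Counts are strictly positive; an element with count zero is simply
    absent.  Instances are immutable and hashable.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
            clean[sym] = n
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return MolecularFormula(merged)

    def format(self) -> str:
        """Hill-ordered formula string, e.g. ``C9H10N4O`` (count 1 omitted)."""
        parts = []
        for sym in _hill_order(set(self.counts)):
            n = self.counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.format()


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count formula string like ``"C9H11N4O"``.

    An element symbol may be followed by an optional integer count
    (default 1); repeated symbols accumulate.  Parentheses, hydrates and
    isotope labels are not supported.

    Raises
    ------
    FormulaError
        On an empty string, an unknown element symbol, an explicit zero
        count, or any text that is not part of a valid token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"unparseable token at {text[pos:]!r} in {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def neutral_from_protonated(ion: MolecularFormula) -> MolecularFormula:
    """Neutral formula of the molecule whose [M+H]+ ion formula is *ion*.

    HRMS lines print the ion formula; the neutral molecule has one H fewer.
    Raises :class:`FormulaError` if the ion contains no hydrogen.
    """
    h = ion["H"]
    if h < 1:
        raise FormulaError("not a valid [M+H]+ ion formula: no hydrogen to remove")
    counts = {sym: n for sym, n in ion.counts.items() if sym != "H"}
    if h > 1:
        counts["H"] = h - 1
    # a bare proton leaves the empty formula
    if not counts:
        return _EMPTY
    return MolecularFormula(counts)


# MolecularFormula requires counts >= 1, so the empty formula is the
# one legitimate zero-element value; construct it once, bypassing validation.
_EMPTY = object.__new__(MolecularFormula)
object.__setattr__(_EMPTY, "counts", MappingProxyType({}))


def heavy_atom_count(f: MolecularFormula) -> int:
    """Number of non-hydrogen atoms (the HAC of ligand efficiency)."""
    return sum(n for sym, n in f.counts.items() if sym != "H")


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic (most-abundant-isotope) mass of the neutral formula, Da."""
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in f.counts.items())


def monoisotopic_mz(neutral: MolecularFormula, adduct: str = "+H", charge: int = 1) -> float:
    """m/z of an adduct ion of the neutral molecule.

    Only the ``"+H"`` (protonation, z = +1) adduct is supported: the ion
    mass is the neutral monoisotopic mass plus the proton mass 1.007276 Da
    (equivalently, plus one H atom minus one electron).  Rounding to the
    4 dp printed in HRMS reports is left to the caller.
    """
    if adduct != "+H" or charge != 1:
        raise FormulaError(f"unsupported adduct spec: {adduct!r} (charge {charge})")
    return monoisotopic_mass(neutral) + PROTON_MASS


@dataclass
class Compound:
    """A library member: id, name, and neutral formula and/or heavy-atom count.

    At least one of ``neutral_formula`` / ``heavy_atom_count`` must be given;
    when both are present they must agree.
    """

    id: str
    name: str = ""
    neutral_formula: MolecularFormula | None = None
    heavy_atom_count: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.neutral_formula is None and self.heavy_atom_count is None:
            raise ValueError(f"compound {self.id!r}: need a formula or a heavy-atom count")
        if self.neutral_formula is not None:
            hac = heavy_atom_count(self.neutral_formula)
            if self.heavy_atom_count is None:
                self.heavy_atom_count = hac
            elif self.heavy_atom_count != hac:
                raise ValueError(
                    f"compound {self.id!r}: stated heavy-atom count "
                    f"{self.heavy_atom_count} disagrees with formula ({hac})"
                )
        if self.heavy_atom_count is not None and self.heavy_atom_count < 1:
            raise ValueError(f"compound {self.id!r}: heavy-atom count must be >= 1")


def read_compound_table(path) -> dict[str, Compound]:
    """Read a compound table from delimited text.

    Columns: ``compound_id,name,ion_formula,neutral_formula,heavy_atoms``.
    Exactly one of the last three must be non-empty per row; ``#`` lines
    are comments.  Returns a dict keyed by compound id.
    """
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    required = {"compound_id", "name", "ion_formula", "neutral_formula", "heavy_atoms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    out: dict[str, Compound] = {}
    for _, row in df.iterrows():
        cid = row["compound_id"].strip()
        provided = [c for c in ("ion_formula", "neutral_formula", "heavy_atoms")
                    if row[c].strip()]
        if len(provided) != 1:
            raise ValueError(
                f"compound {cid!r}: exactly one of ion_formula/neutral_formula/"
                f"heavy_atoms must be given, got {provided or 'none'}"
            )
        col = provided[0]
        if col == "ion_formula":
            neutral = neutral_from_protonated(parse_formula(row[col]))
            cpd = Compound(cid, row["name"], neutral_formula=neutral)
        elif col == "neutral_formula":
            cpd = Compound(cid, row["name"], neutral_formula=parse_formula(row[col]))
        else:
            cpd = Compound(cid, row["name"], heavy_atom_count=int(row[col]))
        if cid in out:
            raise ValueError(f"duplicate compound id {cid!r}")
        out[cid] = cpd
    return out
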