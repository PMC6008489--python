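"""Protein-ligand contact geometry from PDB coordinate files.

ATP-site kinase inhibitors anchor to the hinge backbone through one or two
hydrogen bonds (for MPS1: the E603 carbonyl and the G605 amide NH), often
with an extra polar contact to the catalytic lysine and hydrophobic packing
against pocket residues.  This module reads a coordinate file, selects the
ligand and protein environments, and reports:

* hydrogen-bond candidates — N/O ... N/O pairs within a distance cutoff
  (default 3.5 Å).  X-ray structures at typical kinase resolutions carry no
  hydrogen positions, so the criterion is distance-only and donor/acceptor
  roles are assigned heuristically from atom identity, with "undetermined"
  when the chemistry is ambiguous;
* hydrophobic contacts — carbon-carbon pairs within 4.5 Å, grouped by
  protein residue;
* pocket-residue comparisons between two structures under a user-supplied
  residue-number correspondence map (e.g. gatekeeper M602 of MPS1 vs L210
  of Aurora A).

Parsing is delegated to gemmi; alternate locations are collapsed to the
highest-occupancy conformer (ties prefer altloc 'A').
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import gemmi
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AtomRecord", "HBondContact", "HydrophobicContact", "StructureModel",
           "read_structure", "read_structure_text", "measure_distance",
           "find_hbonds", "find_hydrophobic_contacts", "compare_pocket_residues"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue context and Cartesian coordinates (Å)."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    x: float
    y: float
    z: float
    is_hetero: bool

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")


def measure_distance(a: AtomRecord, b: AtomRecord) -> float:
    """Euclidean distance between two atoms in Å."""
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


@dataclass(frozen=True)
class HBondContact:
    """A donor-acceptor candidate pair.  ``role`` records which side donates:
    'ligand-donor', 'protein-donor' or 'undetermined'."""

    donor: AtomRecord
    acceptor: AtomRecord
    distance: float
    role: str = "undetermined"


@dataclass(frozen=True)
class HydrophobicContact:
    ligand_atom: AtomRecord
    protein_atom: AtomRecord
    distance: float


Selector = Callable[[AtomRecord], bool] | dict | Sequence[AtomRecord]


class StructureModel:
    """A flat list of atoms with selection helpers."""

    def __init__(self, atoms: Sequence[AtomRecord], name: str = ""):
        if not atoms:
            raise ValueError("structure contains no atoms")
        self.atoms = list(atoms)
        self.name = name

    def __len__(self) -> int:
        return len(self.atoms)

    def select(self, *, residue_name: str | None = None, chain: str | None = None,
               residue_numbers: Iterable[int] | None = None,
               elements: Iterable[str] | None = None,
               hetero: bool | None = None) -> list[AtomRecord]:
        nums = set(residue_numbers) if residue_numbers is not None else None
        els = {e.upper() for e in elements} if elements is not None else None
        out = []
        for a in self.atoms:
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if chain is not None and a.chain != chain:
                continue
            if nums is not None and a.residue_number not in nums:
                continue
            if els is not None and a.element.upper() not in els:
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            out.append(a)
        return out

    def resolve(self, selector: Selector) -> list[AtomRecord]:
        """Materialise a selector (atom list, select-kwargs dict or predicate)."""
        if isinstance(selector, dict):
            return self.select(**selector)
        if callable(selector):
            return [a for a in self.atoms if selector(a)]
        return list(selector)

    def residues(self, chain: str | None = None) -> dict[tuple[str, int], str]:
        """(chain, residue_number) -> residue_name map."""
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            out.setdefault((a.chain, a.residue_number), a.residue_name)
        return out


_WATER = {"HOH", "WAT", "DOD"}


def _pick_altloc(group: list) -> gemmi.Atom:
    """Highest occupancy wins; on a tie, the alphabetically first altloc
    (so 'A' beats 'B')."""
    return min(group, key=lambda at: (-at.occ, at.altloc or "A"))


def _from_gemmi(st: gemmi.Structure, include_waters: bool) -> StructureModel:
    st.setup_entities()
    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if not include_waters and residue.name in _WATER:
                continue
            is_het = residue.het_flag == "H"
            by_name: dict[str, list] = {}
            for at in residue:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = _pick_altloc(group) if len(group) > 1 else group[0]
                element = at.element.name if at.element.name != "X" else ""
                if not element:
                    # fall back on the leading letter of the atom name
                    element = "".join(c for c in at.name if c.isalpha())[:1]
                if element.upper() in ("H", "D"):
                    continue
                atoms.append(AtomRecord(
                    serial=at.serial, atom_name=name, element=element,
                    residue_name=residue.name, residue_number=residue.seqid.num,
                    chain=chain.name, x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    is_hetero=is_het,
                ))
    if not atoms:
        raise ValueError("no atoms parsed from structure")
    return StructureModel(atoms, name=st.name)


def read_structure(path, include_waters: bool = False) -> StructureModel:
    """Read a PDB-format coordinate file into a :class:`StructureModel`.

    Hydrogens are dropped (the contact criteria are heavy-atom based);
    waters are excluded unless requested.  Malformed lines are skipped by
    the parser with a warning.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    return _from_gemmi(st, include_waters)


def read_structure_text(text: str, include_waters: bool = False) -> StructureModel:
    """Parse PDB-format text (used heavily by fixtures and tests)."""
    st = gemmi.read_pdb_string(text)
    return _from_gemmi(st, include_waters)


# Donor/acceptor chemistry of protein polar atoms.  Backbone O and
# side-chain carbonyl/carboxylate oxygens can only accept; backbone N and
# saturated side-chain nitrogens (with H attached) can only donate;
# hydroxyls and histidine ring nitrogens can do either.
_PROTEIN_ACCEPTOR_ONLY = {
    ("*", "O"), ("*", "OXT"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}
_PROTEIN_DONOR_ONLY = {
    ("*", "N"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("TRP", "NE1"),
}


def _protein_polarity(a: AtomRecord) -> str:
    key_any = ("*", a.atom_name)
    key_res = (a.residue_name, a.atom_name)
    if key_any in _PROTEIN_ACCEPTOR_ONLY or key_res in _PROTEIN_ACCEPTOR_ONLY:
        return "acceptor"
    if key_any in _PROTEIN_DONOR_ONLY or key_res in _PROTEIN_DONOR_ONLY:
        return "donor"
    return "ambiguous"


def _assign_roles(lig: AtomRecord, prot: AtomRecord) -> tuple[AtomRecord, AtomRecord, str]:
    """Label donor/acceptor for a ligand-protein polar pair.

    Protein atoms have well-defined chemistry; ligand atoms are unknown, so
    the protein side decides: a protein acceptor implies the ligand donates
    and vice versa.  Pairs where the protein atom is itself ambiguous
    (hydroxyls, His ring N) stay 'undetermined', reported ligand-first.
    """
    pol = _protein_polarity(prot)
    if pol == "acceptor":
        return lig, prot, "ligand-donor"
    if pol == "donor":
        return prot, lig, "protein-donor"
    return lig, prot, "undetermined"


def find_hbonds(model: StructureModel, ligand_selector: Selector,
                protein_selector: Selector, max_dist: float = 3.5) -> list[HBondContact]:
    """All ligand N/O x protein N/O pairs within *max_dist* Å, nearest first.

    Distance-only criterion; see module docstring for the rationale.
    """
    lig = [a for a in model.resolve(ligand_selector) if a.element.upper() in ("N", "O")]
    prot = [a for a in model.resolve(protein_selector) if a.element.upper() in ("N", "O")]
    if not lig or not prot:
        raise ValueError("empty ligand or protein selection (no N/O atoms)")
    contacts = []
    for la in lig:
        for pa in prot:
            d = measure_distance(la, pa)
            if d <= max_dist:
                donor, acceptor, role = _assign_roles(la, pa)
                contacts.append(HBondContact(donor, acceptor, d, role))
    contacts.sort(key=lambda c: (c.distance, c.donor.serial, c.acceptor.serial))
    return contacts


def find_hydrophobic_contacts(model: StructureModel, ligand_selector: Selector,
                              protein_selector: Selector,
                              max_dist: float = 4.5) -> list[HydrophobicContact]:
    """Carbon-carbon ligand-protein pairs within *max_dist* Å, nearest first."""
    lig = [a for a in model.resolve(ligand_selector) if a.element.upper() == "C"]
    prot = [a for a in model.resolve(protein_selector) if a.element.upper() == "C"]
    if not lig or not prot:
        raise ValueError("empty ligand or protein selection (no carbon atoms)")
    contacts = []
    for la in lig:
        for pa in prot:
            d = measure_distance(la, pa)
            if d <= max_dist:
                contacts.append(HydrophobicContact(la, pa, d))
    contacts.sort(key=lambda c: (c.distance, c.ligand_atom.serial, c.protein_atom.serial))
    return contacts


def contact_residues(contacts: Iterable[HydrophobicContact]) -> dict[tuple[str, int, str], int]:
    """Group hydrophobic contacts by protein residue -> pair count."""
    out: dict[tuple[str, int, str], int] = {}
    for c in contacts:
        key = (c.protein_atom.chain, c.protein_atom.residue_number,
               c.protein_atom.residue_name)
        out[key] = out.get(key, 0) + 1
    return out


def compare_pocket_residues(model_a: StructureModel, model_b: StructureModel,
                            alignment_map: dict[int, int],
                            chain_a: str | None = None,
                            chain_b: str | None = None) -> pd.DataFrame:
    """Compare mapped residue positions between two structures.

    *alignment_map* gives residue-number correspondences (a -> b), supplied
    by the user from a sequence or structural alignment.  Returns a table
    with columns ``residue_number_a,residue_name_a,residue_number_b,
    residue_name_b,same_amino_acid``; unmapped numbers are reported with
    blank names and a null flag rather than raised.
    """
    res_a = {num: name for (ch, num), name in model_a.residues(chain_a).items()}
    res_b = {num: name for (ch, num), name in model_b.residues(chain_b).items()}
    rows = []
    for na, nb in sorted(alignment_map.items()):
        name_a, name_b = res_a.get(na), res_b.get(nb)
        if name_a is None or name_b is None:
            logger.warning("unmapped residue pair %s -> %s", na, nb)
            rows.append({"residue_number_a": na, "residue_name_a": name_a or "",
                         "residue_number_b": nb, "residue_name_b": name_b or "",
                         "same_amino_acid": None})
        else:
            rows.append({"residue_number_a": na, "residue_name_a": name_a,
                         "residue_number_b": nb, "residue_name_b": name_b,
                         "same_amino_acid": name_a == name_b})
    return pd.DataFrame(rows, columns=["residue_number_a", "residue_name_a",
                                       "residue_number_b", "residue_name_b",
                                       "same_amino_acid"])


def contacts_frame(hbonds: Iterable[HBondContact],
                   hydrophobics: Iterable[HydrophobicContact]) -> pd.DataFrame:
    """Flatten contacts into the report table
    ``contact_type,ligand_atom,protein_chain,protein_residue,protein_atom,distance_A``."""
    rows = []
    for c in hbonds:
        lig, prot = (c.donor, c.acceptor) if c.role != "protein-donor" else (c.acceptor, c.donor)
        rows.append({
            "contact_type": f"hbond({c.role})",
            "ligand_atom": lig.atom_name,
            "protein_chain": prot.chain,
            "protein_residue": f"{prot.residue_name}{prot.residue_number}",
            "protein_atom": prot.atom_name,
            "distance_A": round(c.distance, 2),
        })
    for c in hydrophobics:
        rows.append({
            "contact_type": "hydrophobic",
            "ligand_atom": c.ligand_atom.atom_name,
            "protein_chain": c.protein_atom.chain,
            "protein_residue": f"{c.protein_atom.residue_name}{c.protein_atom.residue_number}",
            "protein_atom": c.protein_atom.atom_name,
            "distance_A": round(c.distance, 2),
        })
    return pd.DataFrame(rows, columns=["contact_type", "ligand_atom", "protein_chain",
                                       "protein_residue", "protein_atom", "distance_A"])
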