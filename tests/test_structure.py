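"""PDB reading and protein-ligand contact geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fragpanel.structure import (
    AtomRecord,
    compare_pocket_residues,
    contact_residues,
    find_hbonds,
    find_hydrophobic_contacts,
    measure_distance,
    read_structure,
    read_structure_text,
)

LIG = {"residue_name": "LIG"}
PROT = {"hetero": False}


def atom(x, y, z, name="X", element="C", serial=1, resname="GLY", resnum=1, chain="A",
         het=False):
    return AtomRecord(serial, name, element, resname, resnum, chain,
                      float(x), float(y), float(z), het)


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00 10.00           C
ATOM      3  O   ALA A   1       1.500   2.000   0.000  1.00 10.00           O
END
"""


def test_read_toy_structure_exact_coordinates():
    m = read_structure_text(TOY_PDB)
    assert len(m) == 3
    ca = next(a for a in m.atoms if a.atom_name == "CA")
    assert (ca.x, ca.y, ca.z) == (1.5, 0.0, 0.0)
    assert ca.element == "C" and not ca.is_hetero


def test_read_structure_from_file(tmp_path, hinge_pdb_text):
    p = tmp_path / "hinge.pdb"
    p.write_text(hinge_pdb_text)
    m = read_structure(p)
    assert {(a.residue_name, a.residue_number) for a in m.atoms if not a.is_hetero} == {
        ("GLU", 603), ("GLY", 605), ("VAL", 539)}


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C
ATOM      3  CB AALA A   1       1.000   1.000   0.000  0.50 10.00           C
ATOM      4  CB BALA A   1       6.000   1.000   0.000  0.50 10.00           C
END
"""


def test_altloc_highest_occupancy_then_a():
    m = read_structure_text(ALTLOC_PDB)
    assert len(m) == 2
    ca = next(a for a in m.atoms if a.atom_name == "CA")
    cb = next(a for a in m.atoms if a.atom_name == "CB")
    assert ca.x == 5.0  # B has higher occupancy
    assert cb.x == 1.0  # tie -> altloc A


def test_empty_structure_rejected():
    with pytest.raises((ValueError, RuntimeError)):
        read_structure_text("END\n")


@pytest.mark.parametrize(
    "a, b, d",
    [
        (atom(0, 0, 0), atom(0, 0, 2.8), 2.8),
        (atom(1, 2, 2), atom(0, 0, 0), 3.0),
        (atom(4, 5, 6), atom(4, 5, 6), 0.0),
    ],
)
def test_measure_distance(a, b, d):
    assert measure_distance(a, b) == pytest.approx(d)


coords = st.floats(min_value=-500, max_value=500, allow_nan=False)
points = st.tuples(coords, coords, coords)


@given(points, points, points)
def test_distance_is_a_metric(p, q, r):
    a, b, c = (atom(*t) for t in (p, q, r))
    dab, dba = measure_distance(a, b), measure_distance(b, a)
    assert dab == dba >= 0
    assert (dab == 0) == (p == q)
    assert measure_distance(a, c) <= dab + measure_distance(b, c) + 1e-9


def test_hinge_hbonds(hinge_model):
    contacts = find_hbonds(hinge_model, LIG, PROT)
    pairs = {(c.donor.atom_name, c.acceptor.atom_name, round(c.distance, 2), c.role)
             for c in contacts}
    # ligand NH donates to the GLU backbone carbonyl; the GLY backbone NH
    # donates to the ligand carbonyl oxygen
    assert ("N1", "O", 2.8, "ligand-donor") in pairs
    assert ("N", "O1", 2.7, "protein-donor") in pairs
    assert [c.distance for c in contacts] == sorted(c.distance for c in contacts)


def test_hbonds_respect_cutoff(hinge_model):
    assert find_hbonds(hinge_model, LIG, PROT, max_dist=2.0) == []


def test_hbonds_empty_selection_raises(hinge_model):
    with pytest.raises(ValueError):
        find_hbonds(hinge_model, {"residue_name": "NOPE"}, PROT)


def brute_force_hbonds(model, max_dist=3.5):
    """Independent all-pairs oracle for ligand/protein N-O contacts."""
    lig = [a for a in model.atoms if a.is_hetero and a.element in "NO"]
    prot = [a for a in model.atoms if not a.is_hetero and a.element in "NO"]
    out = []
    for a in lig:
        for b in prot:
            d = math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
            if d <= max_dist:
                out.append((a.serial, b.serial, round(d, 6)))
    return sorted(out)


def random_model(rng, n_prot=60, n_lig=12):
    """Random synthetic complex in a 12 A box, mixed elements."""
    atoms = []
    serial = 1
    for i in range(n_prot):
        el = rng.choice(["N", "O", "C"])
        atoms.append(atom(*rng.uniform(0, 12, 3), name=el, element=el,
                          serial=serial, resname="GLY", resnum=i + 1))
        serial += 1
    for i in range(n_lig):
        el = rng.choice(["N", "O", "C"])
        atoms.append(atom(*rng.uniform(0, 12, 3), name=f"{el}{i}", element=el,
                          serial=serial, resname="LIG", resnum=900, het=True))
        serial += 1
    from fragpanel.structure import StructureModel
    return StructureModel(atoms)


def test_hbonds_match_brute_force_on_random_complexes():
    rng = np.random.default_rng(12345)
    for _ in range(25):
        m = random_model(rng)
        got = sorted((c.donor.serial, c.acceptor.serial, round(c.distance, 6))
                     if c.role != "protein-donor" else
                     (c.acceptor.serial, c.donor.serial, round(c.distance, 6))
                     for c in find_hbonds(m, {"hetero": True}, {"hetero": False}))
        assert got == brute_force_hbonds(m)


def test_hbonds_independent_of_atom_order():
    rng = np.random.default_rng(99)
    m = random_model(rng)
    from fragpanel.structure import StructureModel
    shuffled = StructureModel(list(rng.permutation(np.array(m.atoms, dtype=object))))
    a = [(c.distance, c.donor.serial) for c in find_hbonds(m, {"hetero": True}, PROT)]
    b = [(c.distance, c.donor.serial) for c in find_hbonds(shuffled, {"hetero": True}, PROT)]
    assert a == b


def test_hydrophobic_contacts(hinge_model):
    contacts = find_hydrophobic_contacts(hinge_model, LIG, PROT)
    residues = contact_residues(contacts)
    assert ("A", 539, "VAL") in residues
    # ring carbon C2 packs against the valine side chain within 4.5 A
    assert any(c.ligand_atom.atom_name == "C2" and
               c.protein_atom.residue_name == "VAL" for c in contacts)


def test_hydrophobic_contacts_empty_beyond_cutoff(hinge_model):
    assert find_hydrophobic_contacts(hinge_model, LIG, PROT, max_dist=0.5) == []


GATEKEEPER_A = """\
ATOM      1  CA  MET A 602       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  ILE A 663       5.000   0.000   0.000  1.00 10.00           C
END
"""
GATEKEEPER_B = """\
ATOM      1  CA  LEU A 210       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  ALA A 273       5.000   0.000   0.000  1.00 10.00           C
END
"""


def test_compare_pocket_residues_gatekeeper():
    """The MPS1 gatekeeper (M602) and back-pocket I663 map to L210 and A273
    of Aurora A: both positions differ."""
    a = read_structure_text(GATEKEEPER_A)
    b = read_structure_text(GATEKEEPER_B)
    tab = compare_pocket_residues(a, b, {602: 210, 663: 273})
    assert tab["residue_name_a"].tolist() == ["MET", "ILE"]
    assert tab["residue_name_b"].tolist() == ["LEU", "ALA"]
    assert tab["same_amino_acid"].tolist() == [False, False]


def test_compare_pocket_residues_identity():
    a = read_structure_text(GATEKEEPER_A)
    tab = compare_pocket_residues(a, a, {602: 602, 663: 663})
    assert tab["same_amino_acid"].all()


def test_compare_pocket_residues_reports_unmapped():
    a = read_structure_text(GATEKEEPER_A)
    tab = compare_pocket_residues(a, a, {602: 602, 999: 999})
    row = tab[tab["residue_number_a"] == 999].iloc[0]
    assert row["residue_name_a"] == "" and row["same_amino_acid"] is None
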