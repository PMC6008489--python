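import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


# A minimal kinase hinge environment with a bound ligand: the ligand amine
# N1 sits 2.8 A from the GLU backbone carbonyl O, the GLY backbone NH sits
# 2.7 A from the ligand carbonyl O1, and a ligand ring carbon packs against
# a valine side chain.  Geometry is synthetic (hand-placed coordinates).
HINGE_PDB = """\
ATOM      1  N   GLU A 603      10.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  GLU A 603      11.400  10.000  10.000  1.00 20.00           C
ATOM      3  C   GLU A 603      12.000  11.300  10.000  1.00 20.00           C
ATOM      4  O   GLU A 603      13.200  11.500  10.000  1.00 20.00           O
ATOM      5  N   GLY A 605      12.000  14.000  10.000  1.00 20.00           N
ATOM      6  CA  GLY A 605      13.000  15.000  10.000  1.00 20.00           C
ATOM      7  CB  VAL A 539      16.000  12.000  12.000  1.00 20.00           C
ATOM      8  CG1 VAL A 539      16.500  12.500  13.000  1.00 20.00           C
HETATM    9  N1  LIG A 900      13.200  11.500  12.800  1.00 20.00           N
HETATM   10  O1  LIG A 900      12.000  14.000  12.700  1.00 20.00           O
HETATM   11  C1  LIG A 900      14.000  12.000  13.500  1.00 20.00           C
HETATM   12  C2  LIG A 900      15.000  13.000  13.500  1.00 20.00           C
END
"""


@pytest.fixture
def hinge_pdb_text():
    return HINGE_PDB


@pytest.fixture
def hinge_model():
    from fragpanel.structure import read_structure_text

    return read_structure_text(HINGE_PDB)


def random_profile(rng: np.random.Generator, max_c: int = 8, max_k: int = 8,
                   missing_prob: float = 0.15):
    """Small random panel profile with missing cells for oracle tests."""
    import pandas as pd
    from fragpanel.selectivity import PanelProfile

    n_c = int(rng.integers(1, max_c + 1))
    n_k = int(rng.integers(1, max_k + 1))
    vals = rng.uniform(-20, 120, (n_c, n_k))
    mask = rng.random((n_c, n_k)) < missing_prob
    # never blank out an entire row (profile invariant)
    for i in range(n_c):
        if mask[i].all():
            mask[i, int(rng.integers(0, n_k))] = False
    vals = np.where(mask, np.nan, vals)
    mat = pd.DataFrame(vals, index=[f"c{i}" for i in range(n_c)],
                       columns=[f"k{j}" for j in range(n_k)])
    conc = pd.Series(100.0, index=mat.index)
    return PanelProfile(mat, conc)
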