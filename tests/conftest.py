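import numpy as np
import pytest

from complexlens import Structure, parse_structure
from complexlens.structure_io import Atom

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
"""

ALTLOC_PDB = """\
ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BGLY A   1       1.000   0.000   0.000  0.40  0.00           C
"""

ION_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2 CL    CL A 101       5.000   0.000   0.000  1.00  0.00          CL
HETATM    3  O   HOH A 201       8.000   0.000   0.000  1.00  0.00           O
"""


@pytest.fixture
def minimal_structure() -> Structure:
    return parse_structure(MINIMAL_PDB, format="pdb")


@pytest.fixture
def ion_structure() -> Structure:
    return parse_structure(ION_PDB, format="pdb")


def make_atom(
    serial=1, name="CA", element="C", resname="GLY", resseq=1, chain="A",
    coords=(0.0, 0.0, 0.0), mass=12.011, vdw=1.70, is_ion=False,
) -> Atom:
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_seq=resseq, chain_id=chain, altloc="",
        coords=np.asarray(coords, dtype=float), occupancy=1.0,
        mass=mass, vdw_radius=vdw, is_ion=is_ion, is_water=False,
    )


def chain_of_cas(chain_id: str, coords, start_resseq: int = 1) -> list[Atom]:
    """One CA atom per residue at the given coordinates."""
    return [
        make_atom(serial=i + 1, resseq=start_resseq + i, chain=chain_id, coords=c)
        for i, c in enumerate(coords)
    ]
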