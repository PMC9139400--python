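import numpy as np
import pytest
import trimesh

import molprint as mp

TET_VERTS = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@pytest.fixture
def tetrahedron() -> mp.TriMesh:
    """Closed right-corner tetrahedron, volume 1/6, outward winding."""
    return mp.TriMesh(TET_VERTS.copy(), TET_FACES.copy())


@pytest.fixture
def box():
    """Factory for axis-aligned closed boxes (trimesh primitive)."""

    def make(extents=(10.0, 10.0, 10.0), unit=mp.ANGSTROM, center=(0, 0, 0)):
        tm = trimesh.creation.box(extents=extents)
        m = mp.TriMesh.from_trimesh(tm, unit)
        return m.transformed(translation=center)

    return make


@pytest.fixture
def icosphere():
    def make(radius=1.0, subdivisions=3, unit=mp.ANGSTROM):
        return mp.TriMesh.from_trimesh(
            trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius), unit
        )

    return make


@pytest.fixture
def cylinder():
    def make(radius=1.0, height=10.0, sections=64, unit=mp.ANGSTROM):
        return mp.TriMesh.from_trimesh(
            trimesh.creation.cylinder(radius=radius, height=height, sections=sections),
            unit,
        )

    return make


@pytest.fixture
def single_atom() -> mp.MolecularStructure:
    return mp.MolecularStructure(
        [mp.AtomRecord(serial=1, name="C", element="C", coords=(0, 0, 0), radius=1.7)]
    )


@pytest.fixture
def alpha_helix() -> mp.MolecularStructure:
    """12-residue idealized alpha helix (phi -57, psi -47)."""
    return mp.build_peptide_chain(12, mp.TorsionSpec.uniform(12, -57.0, -47.0))


PDB_SAMPLE = """\
REMARK sample structure
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CA AALA A   2       3.332   1.536   0.000  1.00  0.00           C
ATOM      6  CA BALA A   2       3.400   1.600   0.100  1.00  0.00           C
ATOM      7  CA  SER B   1       5.000   0.000   0.000  1.00  0.00           C
HETATM    8 ZN    ZN B   2       8.000   0.000   0.000  1.00  0.00          ZN
HETATM    9  O   HOH B   3       9.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def pdb_sample() -> str:
    return PDB_SAMPLE
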