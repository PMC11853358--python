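import numpy as np
import pytest

from ppidyn.structio import AtomRecord, StructureModel, TrajectoryEnsemble


def bead(name, resnum, chain, xyz, resname="GLY", element=None, **kw):
    el = element if element is not None else name[0]
    return AtomRecord(name, el, resname, resnum, chain, np.asarray(xyz, float), **kw)


@pytest.fixture
def toy_peptide():
    """Two-residue, five-atom single-chain model."""
    atoms = [
        bead("N", 1, "A", [0.0, 0.0, 0.0], "ALA"),
        bead("CA", 1, "A", [1.5, 0.0, 0.0], "ALA"),
        bead("C", 1, "A", [2.2, 1.2, 0.0], "ALA"),
        bead("CA", 2, "A", [3.8, 1.2, 0.0], "GLY"),
        bead("HA", 2, "A", [4.2, 2.0, 0.5], "GLY", element="H"),
    ]
    return StructureModel(atoms)


@pytest.fixture
def toy_complex():
    """Two chains of Cα beads 100 Å apart (no interface)."""
    atoms = []
    for i in range(4):
        atoms.append(bead("CA", i + 1, "A", [3.8 * i, 0.0, 0.0]))
    for i in range(4):
        atoms.append(bead("CA", i + 1, "B", [3.8 * i, 100.0, 0.0]))
    return StructureModel(atoms)


def static_trajectory(model: StructureModel, n_frames: int = 5) -> TrajectoryEnsemble:
    xyz = model.coordinates
    return TrajectoryEnsemble(model, np.repeat(xyz[None], n_frames, axis=0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.200   1.200   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  GLY B  10       0.000   8.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY B  11       3.800   8.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""
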