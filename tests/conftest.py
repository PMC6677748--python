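import numpy as np
import pytest

from ionflux.structures_io import AtomRecord, Frame, Trajectory


def make_trajectory(atoms, frames_xyz, times=None):
    """Build a Trajectory from (name, resname, resnum, chain, element)
    tuples and a list of (n_atoms, 3) coordinate arrays."""
    topology = [
        AtomRecord(
            serial=i + 1, name=a[0], residue_name=a[1], residue_number=a[2],
            chain_id=a[3], element=a[4], position_index=i,
        )
        for i, a in enumerate(atoms)
    ]
    if times is None:
        times = list(range(len(frames_xyz)))
    frames = [Frame(np.asarray(xyz, dtype=float), float(t))
              for xyz, t in zip(frames_xyz, times)]
    return Trajectory(topology, frames)


@pytest.fixture
def water_trio_traj():
    """Three waters (O + 2 H each), one frame."""
    atoms = []
    coords = []
    for w in range(3):
        x = 5.0 * w
        atoms += [
            ("O", "HOH", w + 1, "W", "O"),
            ("H1", "HOH", w + 1, "W", "H"),
            ("H2", "HOH", w + 1, "W", "H"),
        ]
        coords += [(x, 0.0, 0.0), (x + 0.95, 0.0, 0.0), (x, 0.95, 0.0)]
    return make_trajectory(atoms, [coords])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


MINIMAL_PDB = """\
ATOM      1  N   ASP B  24      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP B  24      12.560   6.351  -6.509  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ASP B  24      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP B  24      12.560   6.351  -6.509  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ASP B  24      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP B  24      12.560   6.351  -6.509  1.00  0.00           C
ENDMDL
END
"""

MISSING_ATOM_PDB = """\
MODEL        1
ATOM      1  N   ASP B  24      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP B  24      12.560   6.351  -6.509  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ASP B  24      11.104   6.134  -6.504  1.00  0.00           N
ENDMDL
END
"""
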