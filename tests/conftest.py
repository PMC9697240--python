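"""Shared fixtures: generated structures and small hand-written PDB texts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandkit import FiberSpec, build_fiber, build_unstacked

# hand-written single-cytosine PDB (base heavy atoms only, standard geometry)
SINGLE_C_PDB = """\
ATOM      1  N1   DC A   1      -1.285   4.542   0.000  1.00  0.00           N
ATOM      2  C2   DC A   1      -1.472   3.158   0.000  1.00  0.00           C
ATOM      3  O2   DC A   1      -2.628   2.709   0.001  1.00  0.00           O
ATOM      4  N3   DC A   1      -0.391   2.344   0.000  1.00  0.00           N
ATOM      5  C4   DC A   1       0.837   2.868   0.000  1.00  0.00           C
ATOM      6  N4   DC A   1       1.875   2.027   0.001  1.00  0.00           N
ATOM      7  C5   DC A   1       1.056   4.275   0.000  1.00  0.00           C
ATOM      8  C6   DC A   1      -0.023   5.068   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def b_fiber_c6():
    return build_fiber(FiberSpec("CCCCCC", form="B"))


@pytest.fixture(scope="session")
def a_fiber_a6():
    return build_fiber(FiberSpec("AAAAAA", form="A"))


@pytest.fixture(scope="session")
def b_duplex_g4():
    return build_fiber(FiberSpec("GGGG", form="B", duplex=True))


@pytest.fixture(scope="session")
def b_duplex_12():
    return build_fiber(FiberSpec("CGCGAATTCGCG", form="B", duplex=True))


@pytest.fixture(scope="session")
def a_duplex_12():
    return build_fiber(FiberSpec("CGCGAATTCGCG", form="A", duplex=True))


@pytest.fixture(scope="session")
def unstacked_c6():
    return build_unstacked("CCCCCC")


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-20.0, 20.0, 3)
    return R.as_matrix(), t


def apply_rigid_motion(structure, R, t):
    """Copy of a single-model structure with all atoms moved by (R, t)."""
    moved = structure.model(0)
    coords = moved.coordinates()
    moved.set_coordinates((R @ coords.T).T + t)
    return moved
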