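"""Base reference frames.

Each nucleobase gets a right-handed orthonormal triad + origin by least-squares
superposition of the standard base geometry (shipped in the parameter file)
onto the observed ring atoms.  The frame's z-axis is the base normal used by
the stacking criteria; pair frames average the two frames of a Watson-Crick
pair after flipping the second strand's frame into the first strand's
convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from ._geom import kabsch, unit
from ._params import standard_base_coords
from .nucleic_io import ATOMIC_MASS, NucleotideResidue

__all__ = ["BaseFrame", "fit_base_frame", "base_normal", "base_center", "pair_frame"]


@dataclasses.dataclass
class BaseFrame:
    """Orthonormal triad (columns x, y, z of `axes`) + origin fitted to a base."""

    origin: np.ndarray
    axes: np.ndarray
    fit_rmsd: float = 0.0
    residue_ref: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be 3x3")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must form a right-handed (det +1) triad")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def flipped(self) -> "BaseFrame":
        """Same frame in the complementary-strand convention (y, z negated)."""
        ax = self.axes.copy()
        ax[:, 1] *= -1.0
        ax[:, 2] *= -1.0
        return BaseFrame(self.origin.copy(), ax, self.fit_rmsd, self.residue_ref)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "BaseFrame":
        return BaseFrame(R @ self.origin + np.asarray(t, float), R @ self.axes,
                         self.fit_rmsd, self.residue_ref)


def fit_base_frame(residue: NucleotideResidue) -> BaseFrame:
    """Least-squares fit of the standard base onto the observed ring atoms.

    The standard base carries its reference frame implicitly (its coordinates
    are expressed in that frame), so the optimal proper rotation/translation
    of the standard ring atoms onto the observed ones *is* the base frame.
    """
    names, coords = standard_base_coords(residue.base)
    ring = residue.ring_atom_names()
    std = []
    obs = []
    for n in ring:
        if not residue.has_atom(n):
            raise ValueError(f"residue {residue.label()}: ring atom {n!r} missing")
        std.append(coords[names.index(n)])
        obs.append(residue.atom(n).position)
    R, t, rmsd = kabsch(np.array(std), np.array(obs))
    return BaseFrame(origin=t, axes=R, fit_rmsd=rmsd, residue_ref=residue.label())


def base_normal(residue: NucleotideResidue) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring heavy atoms.

    The sign is chosen to agree with the fitted frame's z-axis, so normals of
    sequential bases in a regular helix point the same way.
    """
    pts = np.array([residue.atom(n).position for n in residue.ring_atom_names()])
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred)
    if s[1] < 1e-8:  # rank < 2: collinear/degenerate ring
        raise ValueError(f"residue {residue.label()}: ring atoms are degenerate")
    n = vt[2]
    z = fit_base_frame(residue).z
    if np.dot(n, z) < 0:
        n = -n
    return unit(n)


def base_center(residue: NucleotideResidue, mass_weighted: bool = True,
                include_hydrogens: bool = True) -> np.ndarray:
    """(Mass-weighted) mean position of the nucleobase atoms.

    Sugar and phosphate atoms are excluded; hydrogens enter when present and
    `include_hydrogens` is true.
    """
    atoms = residue.base_atoms(include_hydrogens=include_hydrogens)
    if not atoms:
        raise ValueError(f"residue {residue.label()}: no base atoms present")
    pos = np.array([a.position for a in atoms])
    if mass_weighted:
        w = np.array([ATOMIC_MASS[a.element] for a in atoms])
    else:
        w = np.ones(len(atoms))
    return (w[:, None] * pos).sum(axis=0) / w.sum()


def pair_frame(frame_i: BaseFrame, frame_j: BaseFrame) -> BaseFrame:
    """Watson-Crick base-pair frame: flip frame_j to the strand-I convention,
    then take the rigid mean (average origin; rotation halfway along the
    geodesic between the two orientations)."""
    fj = frame_j.flipped()
    if np.dot(frame_i.z, fj.z) < 0.0:
        raise ValueError("frames do not form a valid pair: z-axes subtend more "
                         "than 90 degrees after flipping")
    rel = Rotation.from_matrix(frame_i.axes.T @ fj.axes)
    half = Rotation.from_rotvec(0.5 * rel.as_rotvec())
    axes = frame_i.axes @ half.as_matrix()
    origin = 0.5 * (frame_i.origin + fj.origin)
    return BaseFrame(origin=origin, axes=axes,
                     fit_rmsd=0.5 * (frame_i.fit_rmsd + frame_j.fit_rmsd),
                     residue_ref=f"{frame_i.residue_ref}:{frame_j.residue_ref}")
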