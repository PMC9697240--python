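"""Base-frame fitting, normals, centres of mass and pair frames."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandkit import (AtomRecord, NucleotideResidue, base_center, base_normal,
                       fit_base_frame, pair_frame)
from strandkit._params import standard_base_coords
from strandkit.base_frames import BaseFrame
from strandkit.nucleic_io import ATOMIC_MASS, element_from_name

from conftest import apply_rigid_motion, random_rigid_motion


def residue_from_standard(base, R=np.eye(3), t=np.zeros(3)):
    names, coords = standard_base_coords(base)
    moved = (R @ coords.T).T + t
    atoms = [AtomRecord(n, element_from_name(n), p) for n, p in zip(names, moved)]
    return NucleotideResidue(base, "A", 1, atoms)


@pytest.mark.parametrize("base", "ACGT")
def test_standard_base_fits_identity(base):
    f = fit_base_frame(residue_from_standard(base))
    assert np.allclose(f.axes, np.eye(3), atol=1e-9)
    assert np.allclose(f.origin, 0.0, atol=1e-9)
    assert f.fit_rmsd < 1e-9


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_known_rigid_motion_is_recovered(seed):
    rng = np.random.default_rng(seed)
    R0, t0 = random_rigid_motion(rng)
    f = fit_base_frame(residue_from_standard("G", R0, t0))
    assert np.allclose(f.axes, R0, atol=1e-9)
    assert np.allclose(f.origin, t0, atol=1e-9)
    assert f.fit_rmsd < 1e-9


def test_mirror_input_still_yields_proper_rotation():
    """A mirrored non-planar ring cannot be superposed by any proper rotation,
    so the fit must keep det = +1 and report a real residual.  (The ring is
    puckered first: a mirrored *planar* set is reachable by flipping it over.)"""
    names, coords = standard_base_coords("A")
    ring = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
    bent = coords.copy()
    for i, n in enumerate(names):
        if n in ring:
            bent[i, 2] += 0.3 * (-1.0) ** ring.index(n)
    mirrored = bent * np.array([-1.0, 1.0, 1.0])
    atoms = [AtomRecord(n, element_from_name(n), p)
             for n, p in zip(names, mirrored)]
    f = fit_base_frame(NucleotideResidue("A", "A", 1, atoms))
    assert np.linalg.det(f.axes) > 0
    assert f.fit_rmsd > 0.05


def test_missing_ring_atom_is_named():
    res = residue_from_standard("C")
    res.atoms = [a for a in res.atoms if a.name != "N3"]
    with pytest.raises(ValueError, match="N3"):
        fit_base_frame(res)


def test_normal_of_planar_ring_is_z():
    n = base_normal(residue_from_standard("T"))
    assert np.allclose(np.abs(n), [0.0, 0.0, 1.0], atol=1e-9)
    # sign convention: matches the fitted frame z-axis
    assert np.dot(n, fit_base_frame(residue_from_standard("T")).z) > 0


def test_normal_covariance_under_rotation():
    rng = np.random.default_rng(3)
    R0, _ = random_rigid_motion(rng)
    n0 = base_normal(residue_from_standard("C"))
    n1 = base_normal(residue_from_standard("C", R0))
    assert np.allclose(n1, R0 @ n0, atol=1e-9)


def test_normal_of_slightly_puckered_ring_stays_close():
    names, coords = standard_base_coords("C")
    bumped = coords.copy()
    ring = ("N1", "C2", "N3", "C4", "C5", "C6")
    for i, n in enumerate(names):
        if n in ring:
            bumped[i, 2] += 0.05 * (-1.0) ** ring.index(n)
    atoms = [AtomRecord(n, element_from_name(n), p) for n, p in zip(names, bumped)]
    n_vec = base_normal(NucleotideResidue("C", "A", 1, atoms))
    angle = np.degrees(np.arccos(abs(np.clip(n_vec[2], -1, 1))))
    assert angle < 2.0


def test_base_center_degenerate_and_brute_force():
    one = NucleotideResidue("C", "A", 1, [AtomRecord("N1", "N", [1.0, 2.0, 3.0])])
    assert np.allclose(base_center(one), [1.0, 2.0, 3.0])
    two = NucleotideResidue("C", "A", 1, [AtomRecord("N1", "N", [2.0, 0.0, 0.0]),
                                          AtomRecord("N3", "N", [-2.0, 0.0, 0.0])])
    assert np.allclose(base_center(two), 0.0, atol=1e-12)
    # full cytosine vs an independent hand computation of sum(m r) / sum(m)
    res = residue_from_standard("C")
    num = np.zeros(3)
    den = 0.0
    for a in res.atoms:
        if a.name == "C1'":
            continue  # sugar atom: not part of the nucleobase
        m = ATOMIC_MASS[a.element]
        num += m * a.position
        den += m
    assert np.allclose(base_center(res), num / den, atol=1e-12)
    # unweighted flag gives the plain centroid
    cent = np.mean([a.position for a in res.atoms if a.name != "C1'"], axis=0)
    assert np.allclose(base_center(res, mass_weighted=False), cent, atol=1e-12)


def _flip(frame):
    ax = frame.axes.copy()
    ax[:, 1] *= -1
    ax[:, 2] *= -1
    return BaseFrame(frame.origin, ax)


def test_pair_frame_of_ideal_pair_is_the_shared_frame():
    rng = np.random.default_rng(7)
    R0, t0 = random_rigid_motion(rng)
    fi = BaseFrame(t0, R0)
    fj = _flip(fi)  # perfect Watson-Crick partner: same frame, flipped
    fp = pair_frame(fi, fj)
    assert np.allclose(fp.axes, fi.axes, atol=1e-12)
    assert np.allclose(fp.origin, fi.origin, atol=1e-12)


@pytest.mark.parametrize("theta", [5.0, 15.0, 30.0])
def test_pair_frame_bisects_a_propeller(theta):
    base = BaseFrame(np.zeros(3), np.eye(3))
    rot = Rotation.from_rotvec(np.radians(theta / 2) * np.array([1.0, 0, 0]))
    fi = BaseFrame(base.origin, base.axes @ rot.as_matrix())
    fj_unflipped = BaseFrame(base.origin, base.axes @ rot.inv().as_matrix())
    fp = pair_frame(fi, _flip(fj_unflipped))
    assert np.allclose(fp.axes, base.axes, atol=1e-9)


def test_pair_frame_rejects_anti_aligned_pairs():
    fi = BaseFrame(np.zeros(3), np.eye(3))
    # partner NOT flipped: after the internal flip its z opposes fi.z
    with pytest.raises(ValueError, match="90"):
        pair_frame(fi, BaseFrame(np.zeros(3), np.eye(3)))


def test_fiber_pair_origins_sit_on_the_helix_axis(b_duplex_g4):
    """The generated duplex is a uniform screw about the global z-axis, so
    every pair-frame origin must lie on it."""
    s1, s2 = b_duplex_g4.strands
    n = len(s1)
    for k in range(n):
        fp = pair_frame(fit_base_frame(s1.residues[k]),
                        fit_base_frame(s2.residues[n - 1 - k]))
        assert np.hypot(fp.origin[0], fp.origin[1]) < 0.1


def test_frames_normals_centers_are_rigid_motion_covariant(b_fiber_c6):
    rng = np.random.default_rng(11)
    R0, t0 = random_rigid_motion(rng)
    moved = apply_rigid_motion(b_fiber_c6, R0, t0)
    for r_old, r_new in zip(b_fiber_c6.all_residues(), moved.all_residues()):
        f_old, f_new = fit_base_frame(r_old), fit_base_frame(r_new)
        assert np.allclose(f_new.axes, R0 @ f_old.axes, atol=1e-9)
        assert np.allclose(f_new.origin, R0 @ f_old.origin + t0, atol=1e-9)
        assert np.allclose(base_normal(r_new), R0 @ base_normal(r_old), atol=1e-9)
        assert np.allclose(base_center(r_new),
                           R0 @ base_center(r_old) + t0, atol=1e-9)


def test_refit_of_reemitted_standard_base_is_idempotent():
    rng = np.random.default_rng(13)
    R0, t0 = random_rigid_motion(rng)
    f1 = fit_base_frame(residue_from_standard("T", R0, t0))
    again = residue_from_standard("T", f1.axes, f1.origin)
    f2 = fit_base_frame(again)
    assert np.allclose(f1.axes, f2.axes, atol=1e-12)
    assert np.allclose(f1.origin, f2.origin, atol=1e-12)
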