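"""Stacking criteria, hydrogen-bond criteria and trajectory statistics."""

import itertools

import numpy as np
import pytest

from strandkit import (AtomRecord, FiberSpec, HBondThresholds,
                       NucleicStructure, NucleotideResidue,
                       StackingThresholds, Strand, TrajectorySpec, build_fiber,
                       find_hbonds, is_stacked, make_mock_trajectory,
                       trajectory_stats)
from strandkit._geom import angle_between

from conftest import apply_rigid_motion, random_rigid_motion


def shifted(residue, delta):
    atoms = [AtomRecord(a.name, a.element, a.position + np.asarray(delta))
             for a in residue.atoms]
    return NucleotideResidue(residue.base, residue.chain_id,
                             residue.seq_index, atoms)


def test_adjacent_fiber_pair_is_stacked(b_fiber_c6):
    r1, r2 = b_fiber_c6.strands[0].residues[:2]
    rec = is_stacked(r1, r2)
    assert rec.stacked
    assert rec.min_heavy_distance < 4.0
    assert rec.center_distance < 5.0
    assert rec.normal_angle < 45.0 or rec.normal_angle > 135.0


def test_distant_pair_fails_distance_criteria(b_fiber_c6):
    r1, r2 = b_fiber_c6.strands[0].residues[:2]
    rec = is_stacked(r1, shifted(r2, [20.0, 0.0, 0.0]))
    assert not rec.stacked
    assert rec.min_heavy_distance > 4.0
    assert rec.center_distance > 5.0


def test_coplanar_side_by_side_pair_is_not_stacked(b_fiber_c6):
    """Parallel normals alone do not make a stack: centres >= 5 A fail (ii)."""
    r1 = b_fiber_c6.strands[0].residues[0]
    r2 = shifted(r1, [6.0, 0.0, 0.0])  # same plane, 6 A apart
    rec = is_stacked(r1, r2)
    assert rec.normal_angle < 1.0
    assert rec.center_distance > 5.0
    assert not rec.stacked


def test_stacking_is_symmetric(b_fiber_c6):
    r1, r2 = b_fiber_c6.strands[0].residues[1:3]
    a = is_stacked(r1, r2)
    b = is_stacked(r2, r1)
    assert a.stacked == b.stacked
    assert a.min_heavy_distance == pytest.approx(b.min_heavy_distance)
    assert a.center_distance == pytest.approx(b.center_distance)
    assert a.normal_angle == pytest.approx(b.normal_angle)


def test_threshold_monotonicity(b_fiber_c6, unstacked_c6):
    """Enlarging any threshold never turns a stacked pair unstacked."""
    wide = StackingThresholds(max_heavy_distance=8.0, max_center_distance=10.0,
                              max_normal_angle=80.0)
    for structure in (b_fiber_c6, unstacked_c6):
        residues = structure.strands[0].residues
        for i in range(len(residues) - 1):
            rec = is_stacked(residues[i], residues[i + 1])
            rec_wide = is_stacked(residues[i], residues[i + 1], wide)
            assert not (rec.stacked and not rec_wide.stacked)


def test_detections_are_rigid_motion_invariant(b_duplex_g4):
    rng = np.random.default_rng(21)
    R0, t0 = random_rigid_motion(rng)
    moved = apply_rigid_motion(b_duplex_g4, R0, t0)
    res0 = b_duplex_g4.all_residues()
    res1 = moved.all_residues()
    for i, j in itertools.combinations(range(len(res0)), 2):
        a = is_stacked(res0[i], res0[j])
        b = is_stacked(res1[i], res1[j])
        assert a.stacked == b.stacked
        assert a.min_heavy_distance == pytest.approx(b.min_heavy_distance,
                                                     abs=1e-9)
        assert a.normal_angle == pytest.approx(b.normal_angle, abs=1e-7)
    h0 = {(b.donor, b.hydrogen, b.acceptor) for b in find_hbonds(b_duplex_g4.model(0))}
    h1 = {(b.donor, b.hydrogen, b.acceptor) for b in find_hbonds(moved)}
    assert h0 == h1


def test_watson_crick_gc_pair_gives_three_hbonds():
    pair = build_fiber(FiberSpec("G", form="B", duplex=True))
    bonds = find_hbonds(pair.model(0))
    assert len(bonds) == 3
    donors = {b.donor.split(":")[1] for b in bonds}
    assert donors == {"N1", "N2", "N4"}  # G:N1-H...N3, G:N2-H...O2, C:N4-H...O6
    pair_at = build_fiber(FiberSpec("A", form="B", duplex=True))
    assert len(find_hbonds(pair_at.model(0))) == 2  # A.T pairs donate twice


def _minimal_hbond_system(distance_xy, hydrogen_pos):
    """Acceptor O2 at the origin; donor N4-H along +x at a chosen geometry."""
    acc = NucleotideResidue("C", "A", 1, [AtomRecord("O2", "O", [0.0, 0.0, 0.0])])
    don = NucleotideResidue("C", "A", 3, [
        AtomRecord("N4", "N", [distance_xy, 0.0, 0.0]),
        AtomRecord("H41", "H", hydrogen_pos)])
    return NucleicStructure([Strand([acc, don])], allow_mismatch=True)


def test_hbond_distance_criterion_is_strict():
    # perfect 180-degree alignment but X...Y = 3.5 A: no bond
    s = _minimal_hbond_system(3.5, [3.5 - 1.01, 0.0, 0.0])
    assert find_hbonds(s) == []
    # same geometry at 2.9 A: one bond
    s = _minimal_hbond_system(2.9, [2.9 - 1.01, 0.0, 0.0])
    bonds = find_hbonds(s)
    assert len(bonds) == 1
    assert bonds[0].distance_xy == pytest.approx(2.9)
    assert bonds[0].angle_xhy == pytest.approx(180.0)


def test_hbond_angle_criterion_rejects_bent_contacts():
    """X-H-Y bent to 140 degrees fails even at short X...Y distance."""
    h = np.zeros(3)
    y = np.array([1.01, 0.0, 0.0])
    x = 1.9 * np.array([np.cos(np.radians(140.0)), np.sin(np.radians(140.0)), 0.0])
    assert angle_between(x - h, y - h) == pytest.approx(140.0)
    d_xy = np.linalg.norm(x - y)
    assert d_xy < 3.3  # the distance criterion alone would pass
    acc = NucleotideResidue("C", "A", 1, [AtomRecord("O2", "O", x)])
    don = NucleotideResidue("C", "A", 3, [AtomRecord("N4", "N", y),
                                          AtomRecord("H41", "H", h)])
    s = NucleicStructure([Strand([acc, don])], allow_mismatch=True)
    assert find_hbonds(s) == []


def test_find_hbonds_requires_hydrogens(b_fiber_c6):
    bare = b_fiber_c6.model(0)
    for r in bare.all_residues():
        r.atoms = [a for a in r.atoms if a.element != "H"]
    with pytest.raises(ValueError, match="idealize_h"):
        find_hbonds(NucleicStructure(bare.strands, allow_mismatch=True))
    bonds = find_hbonds(NucleicStructure(bare.strands, allow_mismatch=True),
                        idealize_h=True)
    assert isinstance(bonds, list)


def test_trajectory_of_identical_fiber_snapshots(b_fiber_c6):
    coords = b_fiber_c6.coordinates()
    traj = NucleicStructure(b_fiber_c6.strands, np.stack([coords] * 4))
    stats = trajectory_stats(traj)
    assert all(v == 1.0 for v in stats.adjacent_fractions.values())
    assert all(v == 0 for v in stats.nonadjacent_counts.values())


def test_mock_trajectory_fractions_recover_ground_truth(b_fiber_c6):
    p = [0.6, 0.6, 0.6, 0.02, 0.0]
    n = 1500
    traj, truth = make_mock_trajectory(
        b_fiber_c6, TrajectorySpec(n_snapshots=n, stack_probability=p,
                                   sigma=0.05, seed=101))
    stats = trajectory_stats(traj, include_hbonds=False)
    detected = np.array(list(stats.adjacent_fractions.values()))
    assert np.allclose(detected, truth.stacking_fractions())
    for pi, fi in zip(p, detected):
        bound = 3.0 * np.sqrt(pi * (1.0 - pi) / n) if 0 < pi < 1 else 0.0
        assert abs(fi - pi) <= max(bound, 1e-12)
    assert sum(stats.nonadjacent_counts.values()) == 0


def test_mock_trajectory_hbond_rate_and_persistence(b_fiber_c6):
    n = 1200
    rate = 104.0 / 5e4
    traj, truth = make_mock_trajectory(
        b_fiber_c6, TrajectorySpec(n_snapshots=n, stack_probability=0.5,
                                   sigma=0.05, hbond_rate=rate, seed=202))
    stats = trajectory_stats(traj)
    assert stats.total_hbonds == len(truth.hbond_events)
    assert abs(stats.total_hbonds - rate * n) <= 3.0 * np.sqrt(rate * n)
    assert stats.persistent_hbonds == 0


def test_fast_path_matches_brute_force_reference(b_fiber_c6):
    """On small structures the trajectory aggregator must agree exactly with
    the exhaustive double-loop single-pair detectors."""
    traj, _ = make_mock_trajectory(
        b_fiber_c6, TrajectorySpec(n_snapshots=25, stack_probability=0.5,
                                   sigma=0.08, hbond_rate=0.2, seed=33))
    stats = trajectory_stats(traj)
    n = len(traj.all_residues())
    ref_adj = {}
    ref_non = {}
    ref_counts = []
    for m in traj.iter_models():
        rs = m.all_residues()
        for i, j in itertools.combinations(range(n), 2):
            key = (f"A.{rs[i].label()}", f"A.{rs[j].label()}")
            hit = int(is_stacked(rs[i], rs[j]).stacked)
            if j == i + 1:
                ref_adj[key] = ref_adj.get(key, 0) + hit
            else:
                ref_non[key] = ref_non.get(key, 0) + hit
        ref_counts.append(len(find_hbonds(m)))
    for key, frac in stats.adjacent_fractions.items():
        assert frac == pytest.approx(ref_adj.get(key, 0) / traj.n_models)
    for key, count in stats.nonadjacent_counts.items():
        assert count == ref_non.get(key, 0)
    assert stats.hbond_counts == ref_counts


def test_trajectory_stats_threshold_override(b_fiber_c6):
    coords = b_fiber_c6.coordinates()
    traj = NucleicStructure(b_fiber_c6.strands, coords[None])
    tight = StackingThresholds(max_heavy_distance=1.0)
    stats = trajectory_stats(traj, stack_thresholds=tight, include_hbonds=False)
    assert all(v == 0.0 for v in stats.adjacent_fractions.values())
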