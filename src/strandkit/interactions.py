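"""Geometric detection of base stacking and inter-base hydrogen bonds.

Two nucleobases count as stacked when all three criteria hold: (i) some pair
of base heavy atoms lies closer than 4 A, (ii) the base centres of mass are
closer than 5 A, and (iii) the angle between the base-plane normals falls in
[0, 45] or [135, 180] degrees.  An X...H-Y hydrogen bond (X, Y base
heteroatoms of different nucleobases, H covalently bound to Y) requires the
X-Y distance below 3.3 A and the X-H-Y angle within 150-180 degrees.
Boundary values are excluded (strict "lower than", as the criteria are
stated).  All thresholds are configurable.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from ._geom import angle_between
from .base_frames import base_center, base_normal
from .hydrogens import with_base_hydrogens
from .nucleic_io import (ATOMIC_MASS, BASE_HEAVY_ATOMS, NucleicStructure,
                         NucleotideResidue)

__all__ = [
    "StackingThresholds",
    "HBondThresholds",
    "StackRecord",
    "HBondRecord",
    "TrajectoryStats",
    "is_stacked",
    "find_hbonds",
    "trajectory_stats",
]


@dataclasses.dataclass(frozen=True)
class StackingThresholds:
    """Stacking criteria thresholds (defaults: 4 A, 5 A, 45/135 degrees)."""

    max_heavy_distance: float = 4.0
    max_center_distance: float = 5.0
    max_normal_angle: float = 45.0  # allowed windows [0, a) and (180 - a, 180]

    def normal_angle_ok(self, angle: float) -> bool:
        return angle < self.max_normal_angle or angle > 180.0 - self.max_normal_angle


@dataclasses.dataclass(frozen=True)
class HBondThresholds:
    """Hydrogen-bond criteria thresholds (defaults: 3.3 A, 150 degrees)."""

    max_donor_acceptor_distance: float = 3.3
    min_xhy_angle: float = 150.0
    covalent_h_cutoff: float = 1.2


@dataclasses.dataclass
class StackRecord:
    """Stacking verdict plus the three diagnostics it was based on."""

    pair: Tuple[str, str]
    stacked: bool
    min_heavy_distance: float
    center_distance: float
    normal_angle: float


@dataclasses.dataclass(frozen=True)
class HBondRecord:
    """One X...H-Y hydrogen bond between different nucleobases."""

    donor: str      # "residue:atom" of the heteroatom Y carrying H
    hydrogen: str
    acceptor: str   # "residue:atom" of X
    distance_xy: float
    angle_xhy: float

    def identity(self) -> Tuple[str, str, str]:
        return (self.acceptor, self.hydrogen, self.donor)


def _base_heavy_positions(residue: NucleotideResidue) -> np.ndarray:
    names = BASE_HEAVY_ATOMS[residue.base]
    return np.array([residue.atom(n).position for n in names if residue.has_atom(n)])


def is_stacked(res_i: NucleotideResidue, res_j: NucleotideResidue,
               thresholds: Optional[StackingThresholds] = None,
               mass_weighted: bool = True) -> StackRecord:
    """Evaluate the three stacking criteria for one base pair.

    Symmetric in its arguments; all diagnostics are reported even when the
    verdict is negative.
    """
    thr = thresholds or StackingThresholds()
    pi = _base_heavy_positions(res_i)
    pj = _base_heavy_positions(res_j)
    min_heavy = float(cdist(pi, pj).min())
    center_d = float(np.linalg.norm(
        base_center(res_i, mass_weighted=mass_weighted)
        - base_center(res_j, mass_weighted=mass_weighted)))
    ang = angle_between(base_normal(res_i), base_normal(res_j))
    stacked = (min_heavy < thr.max_heavy_distance
               and center_d < thr.max_center_distance
               and thr.normal_angle_ok(ang))
    return StackRecord(pair=(res_i.label(), res_j.label()), stacked=stacked,
                       min_heavy_distance=min_heavy, center_distance=center_d,
                       normal_angle=ang)


def _heteroatoms(residue: NucleotideResidue):
    """Base heteroatoms (N/O) of one residue."""
    out = []
    for name in BASE_HEAVY_ATOMS[residue.base]:
        if name[0] in "NO" and residue.has_atom(name):
            out.append(residue.atom(name))
    return out


def _donor_pairs(residue: NucleotideResidue, cutoff: float):
    """(heteroatom Y, hydrogen H) pairs with an explicit covalent H-Y bond."""
    hetero = _heteroatoms(residue)
    hydrogens = [a for a in residue.base_atoms() if a.element == "H"]
    pairs = []
    for h in hydrogens:
        for y in hetero:
            if np.linalg.norm(h.position - y.position) < cutoff:
                pairs.append((y, h))
    return pairs


def find_hbonds(snapshot: NucleicStructure,
                thresholds: Optional[HBondThresholds] = None,
                idealize_h: bool = False) -> List[HBondRecord]:
    """All inter-base hydrogen bonds in one model, each reported once.

    Requires explicit hydrogens; with ``idealize_h`` base hydrogens are placed
    at idealised sp2 positions first.
    """
    thr = thresholds or HBondThresholds()
    if snapshot.n_models != 1:
        raise ValueError("find_hbonds expects a single-model snapshot; "
                         "use trajectory_stats for trajectories")
    residues = snapshot.all_residues()
    have_h = any(a.element == "H" for r in residues for a in r.base_atoms())
    if not have_h:
        if not idealize_h:
            raise ValueError(
                "no hydrogens present: hydrogen-bond detection needs explicit "
                "hydrogens; pass idealize_h=True to place idealised base "
                "hydrogens")
        snapshot = with_base_hydrogens(snapshot)
        residues = snapshot.all_residues()

    records: List[HBondRecord] = []
    seen = set()
    for ri, rj in itertools.permutations(residues, 2):
        # rj donates (Y-H), ri accepts (X)
        donors = _donor_pairs(rj, thr.covalent_h_cutoff)
        if not donors:
            continue
        for x in _heteroatoms(ri):
            for y, h in donors:
                d_xy = float(np.linalg.norm(x.position - y.position))
                if d_xy >= thr.max_donor_acceptor_distance:
                    continue
                ang = angle_between(x.position - h.position, y.position - h.position)
                if ang < thr.min_xhy_angle:
                    continue
                key = (f"{ri.chain_id}.{ri.label()}:{x.name}",
                       f"{rj.chain_id}.{rj.label()}:{h.name}",
                       f"{rj.chain_id}.{rj.label()}:{y.name}")
                if key in seen:
                    continue
                seen.add(key)
                records.append(HBondRecord(donor=key[2], hydrogen=key[1],
                                           acceptor=key[0], distance_xy=d_xy,
                                           angle_xhy=float(ang)))
    return records


@dataclasses.dataclass
class TrajectoryStats:
    """Per-pair stacking statistics and per-snapshot hydrogen-bond records."""

    n_snapshots: int
    #: adjacent intra-strand pairs: label -> fraction of snapshots stacked
    adjacent_fractions: Dict[Tuple[str, str], float]
    #: non-adjacent pairs: label -> count of snapshots stacked
    nonadjacent_counts: Dict[Tuple[str, str], int]
    #: number of hydrogen bonds in each snapshot
    hbond_counts: List[int]
    #: bonds (same X, H, Y) present in >= 2 consecutive snapshots
    persistent_hbonds: int

    @property
    def total_hbonds(self) -> int:
        return int(sum(self.hbond_counts))


def trajectory_stats(traj: NucleicStructure,
                     stack_thresholds: Optional[StackingThresholds] = None,
                     hbond_thresholds: Optional[HBondThresholds] = None,
                     idealize_h: bool = False,
                     include_hbonds: bool = True) -> TrajectoryStats:
    """Aggregate stacking and hydrogen-bond statistics over all models.

    Stacking is evaluated for every residue pair in every snapshot; fractions
    are reported for adjacent intra-strand pairs and occurrence counts for all
    other pairs.  Hydrogen-bond persistence counts bonds with identical
    (X, H, Y) atoms detected in consecutive snapshots.

    The per-snapshot math is identical to :func:`is_stacked` and
    :func:`find_hbonds` but runs on precomputed atom indices so long
    trajectories stay fast.
    """
    sthr = stack_thresholds or StackingThresholds()
    hthr = hbond_thresholds or HBondThresholds()
    if include_hbonds:
        have_h = any(a.element == "H" for r in traj.all_residues()
                     for a in r.base_atoms())
        if not have_h:
            if not idealize_h:
                raise ValueError(
                    "no hydrogens present: hydrogen-bond detection needs "
                    "explicit hydrogens; pass idealize_h=True to place "
                    "idealised base hydrogens")
            traj = with_base_hydrogens(traj)

    residues0 = traj.all_residues()
    n = len(residues0)
    atoms0 = traj.all_atoms()
    # flat-array index bookkeeping per residue
    res_atom_slices = []
    k = 0
    for r in residues0:
        res_atom_slices.append((k, k + len(r.atoms)))
        k += len(r.atoms)

    heavy_idx: List[np.ndarray] = []
    ring_idx: List[np.ndarray] = []
    mass_w: List[np.ndarray] = []
    hetero_idx: List[np.ndarray] = []
    hydro_idx: List[np.ndarray] = []
    base_idx: List[np.ndarray] = []
    for r, (lo, _hi) in zip(residues0, res_atom_slices):
        heavy_names = set(BASE_HEAVY_ATOMS[r.base])
        ring_names = set(r.ring_atom_names())
        base_atom_names = {a.name for a in r.base_atoms()}
        hv, rg, het, hyd, bs, w = [], [], [], [], [], []
        for i, a in enumerate(r.atoms):
            gi = lo + i
            is_base_h = a.element == "H" and a.name in base_atom_names
            if a.name in heavy_names:
                hv.append(gi)
                if a.name[0] in "NO":
                    het.append(gi)
            if a.name in ring_names:
                rg.append(gi)
            if is_base_h:
                hyd.append(gi)
            if a.name in heavy_names or is_base_h:
                bs.append(gi)
                w.append(ATOMIC_MASS[a.element])
        heavy_idx.append(np.array(hv))
        ring_idx.append(np.array(rg))
        hetero_idx.append(np.array(het))
        hydro_idx.append(np.array(hyd))
        base_idx.append(np.array(bs))
        mass_w.append(np.array(w))

    strand_of = np.empty(n, dtype=int)
    pos_in_strand = np.empty(n, dtype=int)
    k = 0
    for si, strand in enumerate(traj.strands):
        for pos in range(len(strand)):
            strand_of[k] = si
            pos_in_strand[k] = pos
            k += 1
    adjacent = [(i, j) for i, j in itertools.combinations(range(n), 2)
                if strand_of[i] == strand_of[j]
                and abs(pos_in_strand[i] - pos_in_strand[j]) == 1]
    adjacent_set = set(adjacent)
    others = [(i, j) for i, j in itertools.combinations(range(n), 2)
              if (i, j) not in adjacent_set]

    adj_hits = {p: 0 for p in adjacent}
    other_hits = {p: 0 for p in others}
    hbond_counts: List[int] = []
    persistent = 0
    prev_bonds: set = set()

    for coords in traj.models:
        centers = np.array([
            np.average(coords[base_idx[i]], axis=0, weights=mass_w[i])
            for i in range(n)])
        normals = []
        for i in range(n):
            pts = coords[ring_idx[i]]
            c = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(c, full_matrices=False)
            normals.append(vt[2])
        center_d = cdist(centers, centers)

        for pairs, hits in ((adjacent, adj_hits), (others, other_hits)):
            for (i, j) in pairs:
                if center_d[i, j] >= sthr.max_center_distance:
                    continue
                cosang = abs(float(np.clip(np.dot(normals[i], normals[j]),
                                           -1.0, 1.0)))
                ang = np.degrees(np.arccos(cosang))  # folded to [0, 90]
                if not (ang < sthr.max_normal_angle
                        or ang > 180.0 - sthr.max_normal_angle):
                    continue
                dmin = cdist(coords[heavy_idx[i]], coords[heavy_idx[j]]).min()
                if dmin < sthr.max_heavy_distance:
                    hits[(i, j)] += 1

        if include_hbonds:
            bonds = set()
            for i, j in itertools.permutations(range(n), 2):
                if hetero_idx[i].size == 0 or hydro_idx[j].size == 0:
                    continue
                # donors on j: hydrogen covalently bound to a heteroatom
                hy = cdist(coords[hydro_idx[j]], coords[hetero_idx[j]])
                dh, dy = np.nonzero(hy < hthr.covalent_h_cutoff)
                if dh.size == 0:
                    continue
                xy = cdist(coords[hetero_idx[i]],
                           coords[hetero_idx[j][dy]])
                for xi, di in zip(*np.nonzero(
                        xy < hthr.max_donor_acceptor_distance)):
                    x = coords[hetero_idx[i][xi]]
                    h = coords[hydro_idx[j][dh[di]]]
                    y = coords[hetero_idx[j][dy[di]]]
                    ang = angle_between(x - h, y - h)
                    if ang >= hthr.min_xhy_angle:
                        bonds.add((int(hetero_idx[i][xi]),
                                   int(hydro_idx[j][dh[di]]),
                                   int(hetero_idx[j][dy[di]])))
            hbond_counts.append(len(bonds))
            persistent += len(bonds & prev_bonds)
            prev_bonds = bonds
        else:
            hbond_counts.append(0)

    n_models = traj.n_models
    # chain-qualified labels so duplex strands cannot collide
    labels = [f"{r.chain_id}.{r.label()}" for r in residues0]

    def lab(p):
        return (labels[p[0]], labels[p[1]])

    return TrajectoryStats(
        n_snapshots=n_models,
        adjacent_fractions={lab(p): adj_hits[p] / n_models for p in adjacent},
        nonadjacent_counts={lab(p): other_hits[p] for p in others},
        hbond_counts=hbond_counts,
        persistent_hbonds=persistent,
    )
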