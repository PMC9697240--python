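"""Ideal fiber-model DNA generator and synthetic conformer/trajectory factory.

Structures are assembled by chaining per-step rigid transforms built from the
form's canonical fiber step parameters (B: twist 36 degrees, rise 3.38 A and
vanishing slide/roll, the calf-thymus fiber standard; A: smaller twist,
negative slide, positive roll) and stamping a per-base nucleotide template
into each frame.  The templates combine the standard-reference-frame base
geometries with a deoxyribose built from the form's pucker (B: C2'-endo
family, A: C3'-endo) and backbone torsions; all of these live in the shipped
parameter file, not in code.

Besides ideal helices the module produces deliberately unstacked elongated
conformers, rigid-body perturbations of existing structures, and mock
multi-snapshot trajectories whose per-step stacking probabilities and
hydrogen-bond event rates are programmed, so detector statistics can be
checked against known ground truth.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from ._geom import dihedral, place_atom, rotation_about_axis, unit
from ._params import fiber_step_params, load_params, standard_base_coords
from .base_frames import BaseFrame, fit_base_frame
from .hydrogens import add_base_hydrogens
from .nucleic_io import (AtomRecord, NucleicStructure, NucleotideResidue, Strand,
                         element_from_name, reverse_complement)
from .step_geometry import StepParameters, build_step, step_parameters

__all__ = [
    "FiberSpec",
    "TrajectorySpec",
    "MockTrajectoryTruth",
    "build_fiber",
    "build_unstacked",
    "perturb_steps",
    "make_mock_trajectory",
    "nucleotide_template",
]

_FLIP = np.diag([1.0, -1.0, -1.0])  # strand-II (complementary) frame convention

#: acceptor/donor atoms used when a mock-trajectory hydrogen-bond event is
#: realised between two bases (edge-contact, coplanar geometry)
_EVENT_ACCEPTOR = {"A": "N3", "G": "O6", "C": "O2", "T": "O2"}
_EVENT_DONOR = {"A": ("N6", "H61"), "G": ("N2", "H21"),
                "C": ("N4", "H41"), "T": ("N3", "H3")}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FiberSpec:
    """What to build: sequence (5'->3'), helix form, single or duplex, and
    optional per-step parameter overrides (1-based step index)."""

    sequence: str
    form: str = "B"
    duplex: bool = False
    step_overrides: Optional[Dict[int, Dict[str, float]]] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        if self.form not in ("A", "B"):
            raise ValueError(f"unknown helix form {self.form!r}")
        n_steps = len(self.sequence) - 1
        for idx in (self.step_overrides or {}):
            if not 1 <= idx <= n_steps:
                raise ValueError(f"step override index {idx} outside [1, {n_steps}]")


@dataclasses.dataclass
class TrajectorySpec:
    """Programmed statistics for a mock trajectory.

    `stack_probability` is a scalar or one value per adjacent step; unstacked
    steps get an elongated offset geometry (`unstack_rise`, alternating-sign
    `unstack_roll`).  `hbond_rate` is the expected number of inserted
    inter-base hydrogen-bond events per snapshot; `sigma` is isotropic
    Gaussian coordinate noise in Angstrom.
    """

    n_snapshots: int
    stack_probability: Union[float, Sequence[float]] = 1.0
    sigma: float = 0.0
    hbond_rate: float = 0.0
    unstack_rise: float = 7.0
    unstack_roll: float = 60.0
    seed: int = 0

    def probabilities(self, n_steps: int) -> np.ndarray:
        p = np.atleast_1d(np.asarray(self.stack_probability, dtype=float))
        if p.size == 1:
            p = np.full(n_steps, p[0])
        if p.size != n_steps:
            raise ValueError(f"expected {n_steps} stacking probabilities, got {p.size}")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("stacking probabilities must lie in [0, 1]")
        return p

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.hbond_rate < 0:
            raise ValueError("hbond_rate must be >= 0")


@dataclasses.dataclass
class MockTrajectoryTruth:
    """Ground-truth labels of a generated mock trajectory."""

    stacked: np.ndarray               # (n_snapshots, n_steps) bool
    hbond_events: List[Tuple[int, int]]  # (snapshot index, step index)

    def stacking_fractions(self) -> np.ndarray:
        return self.stacked.mean(axis=0)


# ---------------------------------------------------------------------------
# nucleotide templates
# ---------------------------------------------------------------------------

def _ring_coordinates(P: float, tau_m: float) -> Dict[str, np.ndarray]:
    """Furanose ring atoms satisfying the pseudorotation torsions.

    The ring is chain-built from bond lengths/angles and the target torsions,
    then refined by least squares so all five bonds and all five torsions are
    met simultaneously.
    """
    params = load_params()
    b = params["bonds"]
    a = params["angles"]
    # Altona-Sundaralingam convention: nu2 = tau_m cos P
    nu = np.array([tau_m * np.cos(np.radians(P + 144.0 * (j - 2))) for j in range(5)])

    o4 = np.zeros(3)
    c1 = np.array([b["C1p_O4p"], 0.0, 0.0])
    c2 = place_atom([0.0, 1.0, 0.0], o4, c1, b["C1p_C2p"], a["ring_C1p"], 0.0)
    c3 = place_atom(o4, c1, c2, b["C2p_C3p"], a["ring_C2p"], nu[1])
    c4 = place_atom(c1, c2, c3, b["C3p_C4p"], a["ring_C3p"], nu[2])

    order = ["O4'", "C1'", "C2'", "C3'", "C4'"]
    bonds = [("O4'", "C1'", b["C1p_O4p"]), ("C1'", "C2'", b["C1p_C2p"]),
             ("C2'", "C3'", b["C2p_C3p"]), ("C3'", "C4'", b["C3p_C4p"]),
             ("C4'", "O4'", b["C4p_O4p"])]
    torsion_quads = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
                     ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
                     ("C3'", "C4'", "O4'", "C1'")]

    x0 = np.concatenate([o4, c1, c2, c3, c4])

    def residuals(x):
        pos = {n: x[3 * i:3 * i + 3] for i, n in enumerate(order)}
        res = []
        for p, q, length in bonds:
            res.append(10.0 * (np.linalg.norm(pos[p] - pos[q]) - length))
        for j, quad in enumerate(torsion_quads):
            d = dihedral(*[pos[n] for n in quad])
            diff = (d - nu[j] + 180.0) % 360.0 - 180.0
            res.append(np.radians(diff) * 3.0)
        return np.array(res)

    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return {n: sol.x[3 * i:3 * i + 3].copy() for i, n in enumerate(order)}


def _direction_two_angles(origin, a1, theta1, a2, theta2, side) -> np.ndarray:
    """Unit direction from `origin` making theta1 with origin->a1 and theta2
    with origin->a2; the out-of-plane component takes the sign of `side`."""
    u1 = unit(np.asarray(a1) - origin)
    u2 = unit(np.asarray(a2) - origin)
    c12 = float(np.dot(u1, u2))
    rhs = np.array([np.cos(np.radians(theta1)), np.cos(np.radians(theta2))])
    alpha, beta = np.linalg.solve(np.array([[1.0, c12], [c12, 1.0]]), rhs)
    in_plane = alpha * u1 + beta * u2
    w = unit(np.cross(u1, u2))
    gamma_sq = max(0.0, 1.0 - float(np.dot(in_plane, in_plane)))
    gamma = np.sqrt(gamma_sq)
    if np.dot(w, side) < 0:
        gamma = -gamma
    return unit(in_plane + gamma * w)


def _ring_normal(pos: Dict[str, np.ndarray]) -> np.ndarray:
    """Ring plane normal oriented by the O4'->C1'->C2'->C3'->C4' circulation."""
    order = ["O4'", "C1'", "C2'", "C3'", "C4'"]
    pts = np.array([pos[n] for n in order])
    centre = pts.mean(axis=0)
    n = np.zeros(3)
    for i in range(5):
        n += np.cross(pts[i] - centre, pts[(i + 1) % 5] - centre)
    return unit(n)


@lru_cache(maxsize=16)
def nucleotide_template(base: str, form: str) -> Tuple[Tuple[str, ...], np.ndarray]:
    """(atom names, coordinates) of a full nucleotide in the standard base
    frame of `base`, with the sugar/backbone of helix `form` and idealised
    base hydrogens."""
    params = load_params()
    b = params["bonds"]
    a = params["angles"]
    sugar = params["sugar"][form]

    names_b, coords_b = standard_base_coords(base)
    std = {n: coords_b[i] for i, n in enumerate(names_b)}
    n_att = "N9" if base in "AG" else "N1"
    chi_ref = "C4" if base in "AG" else "C2"

    ring = _ring_coordinates(sugar["P"], sugar["tau_m"])
    normal = _ring_normal(ring)

    # glycosidic nitrogen relative to the ring: the beta-D side (chirality at
    # C1'/C3'/C4' follows the D-deoxyribose reference geometry)
    n_dir = _direction_two_angles(ring["C1'"], ring["O4'"], a["N_C1p_O4p"],
                                  ring["C2'"], a["N_C1p_C2p"], -normal)
    glyco_len = float(np.linalg.norm(std[n_att] - std["C1'"]))
    n_local = ring["C1'"] + glyco_len * n_dir

    # rigid-map the sugar onto the standard-frame C1'/N anchor ...
    u_loc = unit(n_local - ring["C1'"])
    u_std = unit(std[n_att] - std["C1'"])
    axis = np.cross(u_loc, u_std)
    if np.linalg.norm(axis) < 1e-12:
        R1 = np.eye(3) if np.dot(u_loc, u_std) > 0 else rotation_about_axis(
            unit(np.cross(u_loc, [1.0, 0.0, 0.0])), 180.0)
    else:
        ang = np.degrees(np.arctan2(np.linalg.norm(axis), np.dot(u_loc, u_std)))
        R1 = rotation_about_axis(axis, ang)

    def mapped(R, rot_extra=None):
        out = {}
        for k, v in ring.items():
            p = R @ (v - ring["C1'"])
            if rot_extra is not None:
                p = rot_extra @ p
            out[k] = p + std["C1'"]
        return out

    placed = mapped(R1)
    # ... then set the glycosidic torsion chi by rotating about the C1'->N bond
    chi_now = dihedral(placed["O4'"], std["C1'"], std[n_att], std[chi_ref])
    delta = sugar["chi"] - chi_now
    R2 = rotation_about_axis(u_std, delta)
    placed = mapped(R1, rot_extra=R2)
    chi_check = dihedral(placed["O4'"], std["C1'"], std[n_att], std[chi_ref])
    if abs((chi_check - sugar["chi"] + 180.0) % 360.0 - 180.0) > 1e-6:
        R2 = rotation_about_axis(u_std, -delta)
        placed = mapped(R1, rot_extra=R2)

    ring_n = _ring_normal(placed)
    # exocyclic substituents: C5' on the base side of the sugar, O3' opposite
    c5_dir = _direction_two_angles(placed["C4'"], placed["C3'"], a["C3p_C4p_C5p"],
                                   placed["O4'"], a["O4p_C4p_C5p"], -ring_n)
    placed["C5'"] = placed["C4'"] + b["C4p_C5p"] * c5_dir
    o3_dir = _direction_two_angles(placed["C3'"], placed["C4'"], a["C4p_C3p_O3p"],
                                   placed["C2'"], a["C2p_C3p_O3p"], ring_n)
    placed["O3'"] = placed["C3'"] + b["C3p_O3p"] * o3_dir
    placed["O5'"] = place_atom(placed["C3'"], placed["C4'"], placed["C5'"],
                               b["C5p_O5p"], a["C4p_C5p_O5p"], sugar["gamma"])
    placed["P"] = place_atom(placed["C4'"], placed["C5'"], placed["O5'"],
                             b["O5p_P"], a["C5p_O5p_P"], sugar["beta"])
    for i, tor in enumerate(sugar["op_torsions"], start=1):
        placed[f"OP{i}"] = place_atom(placed["C5'"], placed["O5'"], placed["P"],
                                      b["P_OP"], a["O5p_P_OP"],
                                      sugar["alpha_p"] + tor)

    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
             "C1'"] + [n for n in names_b if n != "C1'"]
    coords = {**placed, **{n: std[n] for n in names_b if n != "C1'"}}

    # idealised base hydrogens via a temporary residue
    tmp = NucleotideResidue(base, "A", 1, [
        AtomRecord(n, element_from_name(n), coords[n]) for n in order])
    add_base_hydrogens(tmp)
    names = tuple(atm.name for atm in tmp.atoms)
    arr = np.array([atm.position for atm in tmp.atoms])
    return names, arr


def _make_residue(base: str, form: str, chain_id: str, seq_index: int,
                  frame: BaseFrame) -> NucleotideResidue:
    names, coords = nucleotide_template(base, form)
    pos = (frame.axes @ coords.T).T + frame.origin
    atoms = [AtomRecord(n, element_from_name(n), p) for n, p in zip(names, pos)]
    return NucleotideResidue(base, chain_id, seq_index, atoms)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _chain_frames(n: int, step_list: List[StepParameters],
                  start: Optional[BaseFrame] = None) -> List[BaseFrame]:
    frames = [start or BaseFrame(np.zeros(3), np.eye(3))]
    for i in range(n - 1):
        frames.append(build_step(frames[-1], step_list[i]))
    return frames


def build_fiber(spec: FiberSpec) -> NucleicStructure:
    """Ideal fiber-model helix for the given spec (single strand or duplex)."""
    seq = spec.sequence
    n = len(seq)
    base_params = fiber_step_params(spec.form)
    steps = []
    for i in range(1, n):
        d = dict(base_params)
        if spec.step_overrides and i in spec.step_overrides:
            d.update(spec.step_overrides[i])
        steps.append(StepParameters(**d))
    frames = _chain_frames(n, steps)

    strand1 = Strand([_make_residue(seq[k], spec.form, "A", k + 1, frames[k])
                      for k in range(n)])
    if not spec.duplex:
        return NucleicStructure([strand1])

    comp = reverse_complement(seq)
    residues2 = []
    for j in range(n):  # strand II 5'->3'; residue j pairs with strand-I n-1-j
        frame = frames[n - 1 - j]
        flipped = BaseFrame(frame.origin, frame.axes @ _FLIP)
        residues2.append(_make_residue(comp[j], spec.form, "B", j + 1, flipped))
    return NucleicStructure([strand1, Strand(residues2)])


def build_unstacked(sequence: str, form: str = "B") -> NucleicStructure:
    """Elongated single-strand conformer in which no adjacent pair satisfies
    the stacking criteria (large rise, large alternating roll)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    spec = FiberSpec(sequence, form=form)
    n = len(sequence)
    steps = [StepParameters(rise=7.0, roll=60.0 * (-1.0) ** i, twist=36.0)
             for i in range(n - 1)]
    frames = _chain_frames(n, steps)
    strand = Strand([_make_residue(spec.sequence[k], form, "A", k + 1, frames[k])
                     for k in range(n)])
    return NucleicStructure([strand])


def _strand_frames(strand: Strand) -> List[BaseFrame]:
    return [fit_base_frame(r) for r in strand]


def perturb_steps(structure: NucleicStructure, deltas=None,
                  sigma: Optional[float] = None, seed: int = 0) -> NucleicStructure:
    """Rebuild a single-model structure with per-step offsets added to its
    measured step coordinates.

    `deltas` is an (n_steps, 6) array (shift, slide, rise, tilt, roll, twist)
    or a dict {1-based step index: 6-vector or {name: value}}; with `sigma`
    set, Gaussian offsets drawn from the given seed are added instead.
    Duplexes are perturbed on their base-pair steps, single strands on base
    steps; each residue (or pair) moves rigidly with its frame.
    """
    if structure.n_models != 1:
        raise ValueError("perturb_steps expects a single-model structure")
    from .base_frames import pair_frame  # local import to avoid cycle at init

    duplex = structure.is_duplex
    s1 = structure.strands[0]
    n = len(s1)
    n_steps = n - 1
    if n_steps < 1 and deltas:
        raise ValueError("structure has no steps to perturb")

    d = np.zeros((n_steps, 6))
    if deltas is not None:
        if isinstance(deltas, dict):
            for idx, v in deltas.items():
                if not 1 <= idx <= n_steps:
                    raise ValueError(f"step index {idx} outside [1, {n_steps}]")
                if isinstance(v, dict):
                    vec = np.zeros(6)
                    namepos = {"shift": 0, "slide": 1, "rise": 2,
                               "tilt": 3, "roll": 4, "twist": 5}
                    for k2, val in v.items():
                        vec[namepos[k2]] = val
                else:
                    vec = np.asarray(v, dtype=float)
                d[idx - 1] = vec
        else:
            d = np.asarray(deltas, dtype=float).reshape(n_steps, 6)
    if sigma is not None:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, sigma, size=(n_steps, 6))
    if not np.all(np.isfinite(d)):
        raise ValueError("deltas must be finite")

    if duplex:
        s2 = structure.strands[1]
        frames = [pair_frame(fit_base_frame(s1.residues[k]),
                             fit_base_frame(s2.residues[n - 1 - k]))
                  for k in range(n)]
    else:
        frames = _strand_frames(s1)

    new_frames = [frames[0]]
    for i in range(n_steps):
        p = step_parameters(frames[i], frames[i + 1])
        arr = p.as_array() + d[i]
        new_frames.append(build_step(new_frames[-1], StepParameters(*arr)))

    def moved(residue, old: BaseFrame, new: BaseFrame) -> NucleotideResidue:
        R = new.axes @ old.axes.T
        atoms = [AtomRecord(atm.name, atm.element,
                            R @ (atm.position - old.origin) + new.origin,
                            atm.occupancy, atm.b_factor)
                 for atm in residue.atoms]
        return NucleotideResidue(residue.base, residue.chain_id,
                                 residue.seq_index, atoms)

    new_s1 = Strand([moved(s1.residues[k], frames[k], new_frames[k])
                     for k in range(n)])
    if not duplex:
        return NucleicStructure([new_s1])
    s2 = structure.strands[1]
    new_s2 = Strand([moved(s2.residues[j], frames[n - 1 - j], new_frames[n - 1 - j])
                     for j in range(n)])
    return NucleicStructure([new_s1, new_s2], allow_mismatch=True)


# ---------------------------------------------------------------------------
# mock trajectories
# ---------------------------------------------------------------------------

def _hbond_step_frame(frame_i: BaseFrame, base_i: str, base_j: str,
                      form: str) -> BaseFrame:
    """Frame for residue j such that bases i and j sit coplanar, edge-on, with
    one X...H-Y contact satisfying the hydrogen-bond criteria.

    The edge-contact geometry keeps the base centres > 5 A apart, so the pair
    still fails stacking criterion (ii) and the programmed "unstacked" label
    stays truthful.
    """
    names_i, coords_i = nucleotide_template(base_i, form)
    names_j, coords_j = nucleotide_template(base_j, form)
    ti = {n: c for n, c in zip(names_i, coords_i)}
    tj = {n: c for n, c in zip(names_j, coords_j)}

    x = ti[_EVENT_ACCEPTOR[base_i]]
    centre_i = np.mean([ti[n] for n in
                        ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)
    u = x - centre_i
    u[2] = 0.0
    u = unit(u)

    yn, hn = _EVENT_DONOR[base_j]
    y, h = tj[yn], tj[hn]
    v = h - y
    v[2] = 0.0
    v = unit(v)
    # rotate base j about z so its Y->H direction points back at X, then
    # translate so H lies on the X...Y line at hydrogen-bond distance
    ang = np.degrees(np.arctan2(np.cross(v, -u)[2], np.dot(v, -u)))
    Rz = rotation_about_axis([0.0, 0.0, 1.0], ang)
    y_target = x + 2.9 * u
    t = y_target - Rz @ y
    axes_j = frame_i.axes @ Rz
    origin_j = frame_i.origin + frame_i.axes @ t
    return BaseFrame(origin_j, axes_j)


def make_mock_trajectory(base: NucleicStructure, spec: TrajectorySpec,
                         form: str = "B"):
    """Multi-model structure with programmed per-step stacking and hydrogen
    bonding; returns ``(trajectory, truth)``.

    Each snapshot samples every adjacent step independently: stacked steps
    get the fiber step geometry, unstacked steps an elongated offset geometry,
    and hydrogen-bond events (expected `hbond_rate` per snapshot) replace one
    unstacked step by a coplanar edge-contact geometry.  Isotropic Gaussian
    coordinate noise `sigma` is added last.  Everything is driven by
    ``spec.seed``, so outputs are byte-identical across runs.
    """
    if base.n_models != 1 or base.is_duplex:
        raise ValueError("mock trajectories start from a single-model single strand")
    seq = base.strands[0].sequence()
    n = len(seq)
    n_steps = n - 1
    p = spec.probabilities(n_steps)
    rng = np.random.default_rng(spec.seed)

    fiber = StepParameters(**fiber_step_params(form))
    start = fit_base_frame(base.strands[0].residues[0])

    templates = [nucleotide_template(b, form) for b in seq]
    n_atoms = sum(len(t[0]) for t in templates)
    models = np.empty((spec.n_snapshots, n_atoms, 3))
    stacked_truth = np.zeros((spec.n_snapshots, n_steps), dtype=bool)
    events: List[Tuple[int, int]] = []

    for s in range(spec.n_snapshots):
        stacked = rng.random(n_steps) < p
        stacked_truth[s] = stacked
        hb_steps: List[int] = []
        if spec.hbond_rate > 0:
            n_events = rng.poisson(spec.hbond_rate)
            unstacked_idx = np.flatnonzero(~stacked)
            if n_events > 0 and unstacked_idx.size > 0:
                chosen = rng.choice(unstacked_idx,
                                    size=min(n_events, unstacked_idx.size),
                                    replace=False)
                # keep event steps pairwise non-adjacent so each inserted
                # contact stays a single, countable hydrogen bond
                for c in chosen:
                    if all(abs(int(c) - k) >= 2 for k in hb_steps):
                        hb_steps.append(int(c))
                events.extend((s, c) for c in hb_steps)

        frames = [start]
        for i in range(n_steps):
            if stacked[i]:
                frames.append(build_step(frames[-1], fiber))
            elif i in hb_steps:
                frames.append(_hbond_step_frame(frames[-1], seq[i], seq[i + 1],
                                                form))
            else:
                frames.append(build_step(frames[-1], StepParameters(
                    rise=spec.unstack_rise,
                    roll=spec.unstack_roll * (-1.0) ** i,
                    twist=fiber.twist)))
        k = 0
        for idx, (names, coords) in enumerate(templates):
            f = frames[idx]
            models[s, k:k + len(names)] = (f.axes @ coords.T).T + f.origin
            k += len(names)
        if spec.sigma > 0:
            models[s] += rng.normal(0.0, spec.sigma, size=(n_atoms, 3))

    residues = []
    k = 0
    for idx, (names, coords) in enumerate(templates):
        atoms = [AtomRecord(nm, element_from_name(nm), models[0, k + i])
                 for i, nm in enumerate(names)]
        k += len(names)
        residues.append(NucleotideResidue(seq[idx], "A", idx + 1, atoms))
    traj = NucleicStructure([Strand(residues)], models)
    return traj, MockTrajectoryTruth(stacked=stacked_truth, hbond_events=events)
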