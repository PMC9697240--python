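"""Furanose ring pucker and backbone torsions.

The five ring torsions nu0..nu4 of the deoxyribose are condensed into the
pseudorotation phase P and amplitude tau_m (Altona-Sundaralingam), and P is
mapped onto the named conformer wheel (C3'-endo at 18 degrees, C2'-endo at
162, ...).  B-DNA sugars populate the C1'-exo/C2'-endo sectors; A-DNA sugars
the C3'-endo sector.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Tuple

import numpy as np

from ._geom import dihedral
from .nucleic_io import NucleotideResidue, Strand

__all__ = [
    "PuckerResult",
    "BackboneTorsions",
    "ring_torsions",
    "pseudorotation",
    "classify_pucker",
    "pucker_result",
    "backbone_torsions",
]

#: atom quadruples defining nu0..nu4 (prime convention)
RING_TORSION_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)

#: primary conformer names, sector centres at 18 + 36k degrees
PUCKER_WHEEL = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

_AS_DENOM = 2.0 * (np.sin(np.radians(36.0)) + np.sin(np.radians(72.0)))


@dataclasses.dataclass
class PuckerResult:
    """Ring torsions, pseudorotation coordinates and named conformer."""

    nu: Tuple[float, float, float, float, float]
    P: float
    tau_m: float
    label: str
    residue_ref: str = ""


@dataclasses.dataclass
class BackboneTorsions:
    """Backbone torsions alpha..zeta and glycosidic chi; None at chain termini."""

    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    delta: Optional[float] = None
    epsilon: Optional[float] = None
    zeta: Optional[float] = None
    chi: Optional[float] = None
    residue_ref: str = ""


def ring_torsions(residue: NucleotideResidue) -> Tuple[float, ...]:
    """The five signed ring torsions nu0..nu4 in degrees, (-180, 180]."""
    out = []
    for quad in RING_TORSION_ATOMS:
        pts = []
        for name in quad:
            if not residue.has_atom(name):
                raise ValueError(f"residue {residue.label()}: sugar atom "
                                 f"{name!r} missing")
            pts.append(residue.atom(name).position)
        out.append(dihedral(*pts))
    return tuple(out)


def pseudorotation(nu) -> Tuple[float, float]:
    """Pseudorotation phase P (degrees, [0, 360)) and amplitude tau_m (>= 0).

    Uses tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)) with
    the quadrant fixed by the sign of nu2; tau_m = nu2 / cos P.
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (5,):
        raise ValueError("expected five ring torsions")
    if np.allclose(nu, 0.0, atol=1e-9):
        raise ValueError("planar ring: pseudorotation phase is undefined")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = nu[2] * _AS_DENOM
    P = np.degrees(np.arctan2(num, den)) % 360.0
    tau_m = nu[2] / np.cos(np.radians(P))
    return float(P), float(tau_m)


def classify_pucker(P: float, fine: bool = False) -> str:
    """Named conformer for phase P.

    Default: the ten primary 36-degree sectors centred at 18 + 36k degrees
    (half-open [centre-18, centre+18)).  With ``fine=True``, twenty 18-degree
    sectors; intermediate (twist) sectors are named by their two flanking
    envelopes, e.g. "C3'-endo/C4'-exo".
    """
    P = float(P) % 360.0
    if not fine:
        # primary sector centred at 18 + 36k covers [36k, 36k + 36)
        return PUCKER_WHEEL[int(P // 36.0) % 10]
    m = int((P + 9.0) // 18.0) % 20
    if m % 2 == 1:  # centred on a primary envelope sector
        return PUCKER_WHEEL[m // 2]
    prev_name = PUCKER_WHEEL[(m // 2 - 1) % 10]
    next_name = PUCKER_WHEEL[m // 2]
    return f"{prev_name}/{next_name}"


def pucker_result(residue: NucleotideResidue, fine: bool = False) -> PuckerResult:
    """Full pucker analysis of one residue."""
    nu = ring_torsions(residue)
    P, tau_m = pseudorotation(nu)
    return PuckerResult(nu=nu, P=P, tau_m=tau_m,
                        label=classify_pucker(P, fine=fine),
                        residue_ref=residue.label())


def _maybe_dihedral(atoms) -> Optional[float]:
    if any(a is None for a in atoms):
        return None
    return dihedral(*[a.position for a in atoms])


def _get(residue, name):
    return residue.atom(name) if residue is not None and residue.has_atom(name) else None


def backbone_torsions(strand: Strand) -> List[BackboneTorsions]:
    """Backbone torsions alpha..zeta and chi per residue.

    Chain termini (and any missing atoms) yield None entries with a warning
    rather than an error.
    """
    out = []
    residues = strand.residues
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        t = BackboneTorsions(residue_ref=res.label())
        t.alpha = _maybe_dihedral([_get(prev_res, "O3'"), _get(res, "P"),
                                   _get(res, "O5'"), _get(res, "C5'")])
        t.beta = _maybe_dihedral([_get(res, "P"), _get(res, "O5'"),
                                  _get(res, "C5'"), _get(res, "C4'")])
        t.gamma = _maybe_dihedral([_get(res, "O5'"), _get(res, "C5'"),
                                   _get(res, "C4'"), _get(res, "C3'")])
        t.delta = _maybe_dihedral([_get(res, "C5'"), _get(res, "C4'"),
                                   _get(res, "C3'"), _get(res, "O3'")])
        t.epsilon = _maybe_dihedral([_get(res, "C4'"), _get(res, "C3'"),
                                     _get(res, "O3'"), _get(next_res, "P")])
        t.zeta = _maybe_dihedral([_get(res, "C3'"), _get(res, "O3'"),
                                  _get(next_res, "P"), _get(next_res, "O5'")])
        if res.is_purine:
            chi_atoms = [_get(res, "O4'"), _get(res, "C1'"),
                         _get(res, "N9"), _get(res, "C4")]
        else:
            chi_atoms = [_get(res, "O4'"), _get(res, "C1'"),
                         _get(res, "N1"), _get(res, "C2")]
        t.chi = _maybe_dihedral(chi_atoms)
        interior = 0 < i < len(residues) - 1
        expected = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi") \
            if interior else ("beta", "gamma", "delta", "chi")
        missing = [n for n in expected if getattr(t, n) is None]
        if missing:
            warnings.warn(f"residue {res.label()}: missing atoms leave torsions "
                          f"{missing} undefined", stacklevel=2)
        out.append(t)
    return out
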