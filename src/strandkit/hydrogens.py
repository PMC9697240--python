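"""Idealised base hydrogens.

MD snapshots carry explicit hydrogens; crystallographic and generated
structures often do not.  This module places base hydrogens at idealised sp2
positions (N-H 1.01 A, C-H 1.08 A, in the base plane) so that the geometric
hydrogen-bond criteria can be evaluated on hydrogen-free inputs.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from ._geom import rotation_about_axis, unit
from .nucleic_io import AtomRecord, NucleicStructure, NucleotideResidue, Strand

__all__ = ["add_base_hydrogens", "with_base_hydrogens"]

N_H = 1.01
C_H = 1.08

#: hydrogen name -> (parent atom, heavy neighbours of the parent within the base)
_H_GEOMETRY: Dict[str, Dict[str, Tuple[str, Tuple[str, ...]]]] = {
    "A": {"H2": ("C2", ("N1", "N3")), "H8": ("C8", ("N7", "N9")),
          "H61": ("N6", ("C6",)), "H62": ("N6", ("C6",))},
    "G": {"H1": ("N1", ("C2", "C6")), "H8": ("C8", ("N7", "N9")),
          "H21": ("N2", ("C2",)), "H22": ("N2", ("C2",))},
    "C": {"H5": ("C5", ("C4", "C6")), "H6": ("C6", ("C5", "N1")),
          "H41": ("N4", ("C4",)), "H42": ("N4", ("C4",))},
    "T": {"H3": ("N3", ("C2", "C4")), "H6": ("C6", ("C5", "N1"))},
}


def _plane_normal(residue: NucleotideResidue) -> np.ndarray:
    pts = np.array([residue.atom(n).position for n in residue.ring_atom_names()])
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


def add_base_hydrogens(residue: NucleotideResidue, overwrite: bool = False) -> int:
    """Add idealised base hydrogens to one residue in place.

    Returns the number of hydrogens added.  Existing hydrogens are kept
    unless `overwrite` is set.
    """
    normal = _plane_normal(residue)
    added = 0
    spec = _H_GEOMETRY[residue.base]
    for hname, (parent_name, neighbours) in spec.items():
        if residue.has_atom(hname):
            if not overwrite:
                continue
            residue.atoms.remove(residue.atom(hname))
        parent = residue.atom(parent_name).position
        if len(neighbours) == 2:
            # ring position: H along the exterior bisector, in plane
            u1 = unit(residue.atom(neighbours[0]).position - parent)
            u2 = unit(residue.atom(neighbours[1]).position - parent)
            direction = -unit(u1 + u2)
            length = N_H if parent_name.startswith("N") else C_H
        else:
            # amino group: two H at +/-120 degrees from the N->C bond, in plane
            v = unit(residue.atom(neighbours[0]).position - parent)
            sign = 1.0 if hname.endswith("1") else -1.0
            direction = rotation_about_axis(normal, sign * 120.0) @ v
            length = N_H
        pos = parent + length * direction
        residue.atoms.append(AtomRecord(hname, "H", pos))
        added += 1
    return added


def with_base_hydrogens(structure: NucleicStructure) -> NucleicStructure:
    """Copy of the structure with idealised base hydrogens on every residue,
    consistently across all models."""
    per_model = []
    topo = None
    for mi in range(structure.n_models):
        m = structure.model(mi)
        for res in m.all_residues():
            add_base_hydrogens(res)
        per_model.append(m.coordinates())
        if topo is None:
            topo = m
    assert topo is not None
    return NucleicStructure(topo.strands, np.stack(per_model), allow_mismatch=True)
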