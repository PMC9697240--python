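"""Structural data model and PDB input/output for DNA oligomers.

The in-memory model is deliberately small: a :class:`NucleicStructure` holds
one or two :class:`Strand` objects (5'->3' residue order) plus, for NMR
ensembles and trajectories, a stack of coordinate models sharing one topology.
File parsing and writing are delegated to gemmi; this module normalises the
legacy PDB dialects (asterisk primes, O1P/O2P, C5M) into one convention.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterator, List, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "NucleotideResidue",
    "Strand",
    "NucleicStructure",
    "read_structure",
    "write_structure",
    "parse_sequence_spec",
    "reverse_complement",
]

#: canonical residue-name spellings accepted for the four deoxynucleotides
RESIDUE_NAME_MAP = {}
for _base in "ACGT":
    for _name in (_base, "D" + _base, "D" + _base + "5", "D" + _base + "3",
                  _base + "5", _base + "3"):
        RESIDUE_NAME_MAP[_name] = _base
RESIDUE_NAME_MAP.update({"ADE": "A", "CYT": "C", "GUA": "G", "THY": "T"})

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: purine/pyrimidine ring atom names (the frame-fitting sets)
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: all heavy atoms belonging to the nucleobase (ring + exocyclic substituents)
BASE_HEAVY_ATOMS = {
    "A": PURINE_RING + ("N6",),
    "G": PURINE_RING + ("O6", "N2"),
    "C": PYRIMIDINE_RING + ("O2", "N4"),
    "T": PYRIMIDINE_RING + ("O2", "O4", "C7"),
}

#: hydrogens attached to base heavy atoms (idealised naming)
BASE_HYDROGENS = {
    "A": {"H2": "C2", "H8": "C8", "H61": "N6", "H62": "N6"},
    "G": {"H1": "N1", "H8": "C8", "H21": "N2", "H22": "N2"},
    "C": {"H5": "C5", "H6": "C6", "H41": "N4", "H42": "N4"},
    "T": {"H3": "N3", "H6": "C6"},
}

ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}

_NAME_FIXES = {"O1P": "OP1", "O2P": "OP2", "C5M": "C7", "O1'": "O4'"}


def normalize_atom_name(name: str) -> str:
    """Unify PDB atom-name dialects: asterisk primes, O1P/O2P, C5M, 1H2'."""
    name = name.strip().replace("*", "'")
    if name and name[0].isdigit():  # e.g. 1H2' -> H2'1
        name = name[1:] + name[0]
    return _NAME_FIXES.get(name, name)


def element_from_name(name: str) -> str:
    """Element symbol inferred from a (normalised) nucleic-acid atom name."""
    for ch in name:
        if ch.isalpha():
            el = ch.upper()
            if el in ATOMIC_MASS:
                return el
            break
    raise ValueError(f"cannot infer element for atom name {name!r}")


@dataclasses.dataclass
class AtomRecord:
    """One atom: PDB-convention name, element symbol and position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclasses.dataclass
class NucleotideResidue:
    """A deoxynucleotide: base identity, chain/sequence bookkeeping and atoms."""

    base: str
    chain_id: str
    seq_index: int
    atoms: List[AtomRecord] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.base not in "ACGT":
            raise ValueError(f"unknown base {self.base!r}")

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label()}: atom {name!r} not found")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def label(self) -> str:
        return f"{self.base}({self.seq_index})"

    @property
    def is_purine(self) -> bool:
        return self.base in "AG"

    def ring_atom_names(self) -> Sequence[str]:
        return PURINE_RING if self.is_purine else PYRIMIDINE_RING

    def base_atoms(self, include_hydrogens: bool = True) -> List[AtomRecord]:
        """Atoms belonging to the nucleobase (no sugar/phosphate)."""
        heavy = set(BASE_HEAVY_ATOMS[self.base])
        hyd = set(BASE_HYDROGENS[self.base]) | {"H7", "H71", "H72", "H73"}
        out = []
        for a in self.atoms:
            if a.name in heavy or (include_hydrogens and a.name in hyd):
                out.append(a)
        return out


@dataclasses.dataclass
class Strand:
    """Ordered 5'->3' list of residues forming one DNA strand."""

    residues: List[NucleotideResidue]

    def __post_init__(self):
        if not self.residues:
            raise ValueError("a strand needs at least one residue")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue seq_index must be strictly increasing 5'->3'")

    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[NucleotideResidue]:
        return iter(self.residues)


class NucleicStructure:
    """One or two strands plus >= 1 coordinate models sharing the topology.

    The residue/atom objects always carry the coordinates of the *current*
    model (model 1 after reading a file); the full model stack is available
    through :meth:`model` and :meth:`iter_models`.
    """

    def __init__(self, strands: List[Strand], models: Optional[np.ndarray] = None,
                 allow_mismatch: bool = False):
        if not strands or len(strands) > 2:
            raise ValueError("a structure holds 1 or 2 strands")
        self.strands = strands
        if len(strands) == 2 and not allow_mismatch:
            s1, s2 = strands
            if len(s1) != len(s2):
                raise ValueError("duplex strands must have equal length")
            if reverse_complement(s1.sequence()) != s2.sequence():
                raise ValueError(
                    "duplex strands are not antiparallel-complementary "
                    f"({s1.sequence()} vs {s2.sequence()}); pass allow_mismatch=True "
                    "to override")
        coords = self.coordinates()
        if models is None:
            models = coords[None, :, :]
        models = np.asarray(models, dtype=float)
        if models.ndim != 3 or models.shape[1:] != (coords.shape[0], 3):
            raise ValueError("models must be (n_models, n_atoms, 3) matching topology")
        self.models = models

    # -- topology/coordinate plumbing ------------------------------------
    def all_atoms(self) -> List[AtomRecord]:
        return [a for s in self.strands for r in s for a in r.atoms]

    def all_residues(self) -> List[NucleotideResidue]:
        return [r for s in self.strands for r in s]

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.all_atoms()], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        atoms = self.all_atoms()
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array does not match topology")
        for a, p in zip(atoms, coords):
            a.position = np.array(p, dtype=float)

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def is_duplex(self) -> bool:
        return len(self.strands) == 2

    def model(self, index: int) -> "NucleicStructure":
        """Return a single-model copy of this structure at model `index` (0-based)."""
        coords = self.models[index]
        new_strands = []
        k = 0
        for s in self.strands:
            residues = []
            for r in s:
                atoms = [AtomRecord(a.name, a.element, coords[k + i],
                                    a.occupancy, a.b_factor)
                         for i, a in enumerate(r.atoms)]
                k += len(r.atoms)
                residues.append(NucleotideResidue(r.base, r.chain_id, r.seq_index, atoms))
            new_strands.append(Strand(residues))
        return NucleicStructure(new_strands, allow_mismatch=True)

    def iter_models(self) -> Iterator["NucleicStructure"]:
        for i in range(self.n_models):
            yield self.model(i)


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# sequence-spec mini-language
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"([ACGT])(\d*)")


def parse_sequence_spec(spec: str) -> str:
    """Expand compact sequence notation: digits repeat the preceding base.

    ``"A2C2A2" -> "AACCAA"``, ``"CTG4ACT3C2AG2" -> "CTGGGGACTTTCCAGG"``.
    """
    spec = spec.strip().upper()
    out = []
    pos = 0
    while pos < len(spec):
        m = _TOKEN.match(spec, pos)
        if not m:
            raise ValueError(f"malformed sequence spec {spec!r} at position {pos}: "
                             f"unexpected {spec[pos]!r}")
        base, count = m.group(1), m.group(2)
        if count == "":
            n = 1
        else:
            n = int(count)
            if n <= 0:
                raise ValueError(f"malformed sequence spec {spec!r} at position "
                                 f"{pos}: repeat count must be positive")
        out.append(base * n)
        pos = m.end()
    if not out:
        raise ValueError("empty sequence spec")
    return "".join(out)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _residue_base(resname: str) -> str:
    name = resname.strip().upper()
    if name not in RESIDUE_NAME_MAP:
        raise ValueError(f"unknown residue name {name!r}: only canonical "
                         "deoxynucleotides (A/C/G/T, DA/DC/DG/DT, ...) are supported")
    return RESIDUE_NAME_MAP[name]


def _orient_5p_to_3p(residues: List[NucleotideResidue]) -> List[NucleotideResidue]:
    """Order residues 5'->3' using O3'(i)->P(i+1) connectivity when present."""
    if len(residues) < 2:
        return residues

    def link_score(rs):
        score = 0
        for a, b in zip(rs, rs[1:]):
            if a.has_atom("O3'") and b.has_atom("P"):
                d = np.linalg.norm(a.atom("O3'").position - b.atom("P").position)
                if d < 2.5:
                    score += 1
        return score

    fwd = link_score(residues)
    rev = link_score(residues[::-1])
    return residues[::-1] if rev > fwd else residues


def read_structure(path, model_limit: Optional[int] = None,
                   allow_mismatch: bool = False) -> NucleicStructure:
    """Read a PDB file into a :class:`NucleicStructure`.

    MODEL/ENDMDL blocks become coordinate models; atom names are normalised;
    residues are reordered 5'->3' per chain where backbone connectivity says
    the author order is reversed.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.setup_entities()

    first = st[0]
    strands: List[Strand] = []
    reversed_flags: List[bool] = []
    for chain in first:
        residues = []
        for res in chain:
            base = _residue_base(res.name)
            atoms = []
            for atom in res:
                name = normalize_atom_name(atom.name)
                el = atom.element.name if atom.element and atom.element.name != "X" \
                    else element_from_name(name)
                atoms.append(AtomRecord(name, el.upper(),
                                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                        atom.occ, atom.b_iso))
            residues.append(NucleotideResidue(base, chain.name, res.seqid.num, atoms))
        if not residues:
            continue
        oriented = _orient_5p_to_3p(residues)
        was_reversed = oriented is not residues
        if was_reversed and oriented[0].seq_index >= oriented[-1].seq_index:
            # renumber so seq_index stays strictly increasing 5'->3'
            for i, r in enumerate(oriented):
                r.seq_index = i + 1
        strands.append(Strand(oriented))
        reversed_flags.append(was_reversed)
    if not strands:
        raise ValueError(f"{path}: no nucleotide chains found")
    if len(strands) > 2:
        raise ValueError(f"{path}: {len(strands)} chains found; only 1 or 2 supported")

    n_atoms = sum(len(r.atoms) for s in strands for r in s)
    n_models = len(st) if model_limit is None else min(model_limit, len(st))
    models = np.empty((n_models, n_atoms, 3))
    for mi in range(n_models):
        model = st[mi]
        k = 0
        count = sum(len(res) for chain in model for res in chain)
        if count != n_atoms:
            raise ValueError(f"{path}: model {mi + 1} has {count} atoms, "
                             f"expected {n_atoms} (inconsistent topology)")
        for chain, was_reversed in zip(model, reversed_flags):
            # same chain order as model 1; replay the 5'->3' orientation
            chain_res = list(chain)
            if was_reversed:
                chain_res = chain_res[::-1]
            for res in chain_res:
                for atom in res:
                    models[mi, k] = [atom.pos.x, atom.pos.y, atom.pos.z]
                    k += 1
    return NucleicStructure(strands, models, allow_mismatch=allow_mismatch)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_structure(structure: NucleicStructure, path) -> None:
    """Write the structure (all models) as a PDB file."""
    n_atoms = sum(len(r.atoms) for s in structure.strands for r in s)
    if n_atoms > 99999:
        raise ValueError("structure exceeds the PDB serial-number limit (99999 atoms)")
    st = gemmi.Structure()
    st.name = "strandkit"
    chain_ids = ["A", "B"]
    for mi in range(structure.n_models):
        model = gemmi.Model(mi + 1)
        k = 0
        for si, strand in enumerate(structure.strands):
            chain = gemmi.Chain(chain_ids[si])
            for r in strand:
                res = gemmi.Residue()
                res.name = "D" + r.base
                res.seqid = gemmi.SeqId(r.seq_index, " ")
                for a in r.atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    p = structure.models[mi, k]
                    atom.pos = gemmi.Position(*p)
                    atom.occ = a.occupancy
                    atom.b_iso = a.b_factor
                    res.add_atom(atom)
                    k += 1
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)
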