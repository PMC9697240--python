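"""Per-structure conformational descriptors.

Aggregates the per-step rigid coordinates into the summary numbers used to
characterise a conformation: coordinate averages over all dinucleotide steps,
end-to-end distance (C5' of the first to C3' of the last nucleotide), RMSD
after optimal superposition, slide-roll A/B-form classification, and pooled
averages for homo-dinucleotide steps (AA, CC, GG, TT).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._geom import kabsch
from .base_frames import base_center, fit_base_frame, pair_frame
from .nucleic_io import NucleicStructure, Strand
from .step_geometry import StepParameters, helical_parameters, step_parameters
from .sugar_pucker import PuckerResult, pucker_result

__all__ = [
    "StepClassification",
    "StructureReport",
    "DEFAULT_AB_BOUNDARY",
    "average_step_params",
    "end_to_end",
    "rmsd_superposed",
    "classify_form",
    "analyze_structure",
]

#: slide-roll dividing line between the A and B forms: a step is A-like when
#: roll > a + b * slide.  The default line is calibrated so canonical fiber
#: A and B steps fall on their proper sides; it is fully configurable.
DEFAULT_AB_BOUNDARY = (4.0, -4.0)  # (a [degrees], b [degrees per Angstrom])

_SELECTIONS: Dict[str, Callable] = {
    "all": lambda a: True,
    "heavy": lambda a: a.element != "H",
    "backbone": lambda a: a.name in ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
}


@dataclasses.dataclass
class StepClassification:
    """A/B-form verdict of one step from its slide-roll coordinates."""

    step_label: str
    slide: float
    roll: float
    form: str  # "A" or "B"


@dataclasses.dataclass
class StructureReport:
    """Everything analyze_structure computed for one structure."""

    mode: str
    steps: pd.DataFrame                    # per-step table (all strands)
    averages: Dict[str, float]             # means over all steps
    puckers: List[PuckerResult]
    pucker_distribution: Dict[str, int]
    end_to_end: Dict[str, float]           # strand chain id -> distance
    classifications: List[StepClassification]
    homo_step_averages: Dict[str, Dict[str, float]]
    rmsd_vs_reference: Optional[float] = None

    def summary_text(self) -> str:
        lines = [f"mode\t{self.mode}", f"n_steps\t{len(self.steps)}"]
        for k, v in self.averages.items():
            lines.append(f"avg_{k}\t{v:.4f}")
        for cid, d in self.end_to_end.items():
            lines.append(f"end_to_end_{cid}\t{d:.4f}")
        for label, count in sorted(self.pucker_distribution.items()):
            lines.append(f"pucker_{label}\t{count}")
        for t, av in sorted(self.homo_step_averages.items()):
            lines.append(f"{t}_rise\t{av['rise']:.4f}")
            lines.append(f"{t}_twist\t{av['twist']:.4f}")
        if self.rmsd_vs_reference is not None:
            lines.append(f"rmsd_vs_reference\t{self.rmsd_vs_reference:.4f}")
        return "\n".join(lines) + "\n"

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.steps.to_csv(d / "steps.tsv", sep="\t", index=False)
        (d / "summary.tsv").write_text(self.summary_text())
        scatter = self.steps[["step_label", "slide", "roll"]]
        scatter.to_csv(d / "slide_roll.tsv", sep="\t", index=False)


def average_step_params(steps: Sequence[StepParameters]) -> Dict[str, float]:
    """Arithmetic mean of each coordinate over the steps.

    Angles are averaged arithmetically; every coordinate analysed here stays
    far from the +/-180 wrap, where that is the intended convention.
    """
    if not steps:
        raise ValueError("cannot average an empty step list")
    out: Dict[str, float] = {}
    for name in StepParameters.COLUMNS:
        vals = [getattr(s, name) for s in steps]
        if any(v is None for v in vals):
            continue
        out[name] = float(np.mean(vals))
    return out


def end_to_end(strand: Strand) -> float:
    """Distance between the 5' carbon of the first nucleotide and the
    3' carbon of the last nucleotide."""
    first, last = strand.residues[0], strand.residues[-1]
    for res, name in ((first, "C5'"), (last, "C3'")):
        if not res.has_atom(name):
            raise ValueError(f"residue {res.label()}: atom {name!r} missing, "
                             "end-to-end distance undefined")
    return float(np.linalg.norm(first.atom("C5'").position
                                - last.atom("C3'").position))


def rmsd_superposed(s1: NucleicStructure, s2: NucleicStructure,
                    selection: Union[str, Callable] = "heavy") -> float:
    """RMSD after optimal proper superposition over the selected atoms.

    `selection` is "all", "heavy", "backbone", or a predicate on AtomRecord;
    the selections must pick the same number of atoms from both structures
    (matched by order).
    """
    pred = _SELECTIONS.get(selection, selection) if isinstance(selection, str) \
        else selection
    if not callable(pred):
        raise ValueError(f"unknown selection {selection!r}")
    p1 = np.array([a.position for a in s1.all_atoms() if pred(a)])
    p2 = np.array([a.position for a in s2.all_atoms() if pred(a)])
    if len(p1) != len(p2) or len(p1) == 0:
        raise ValueError(f"selection mismatch: {len(p1)} vs {len(p2)} atoms")
    _, _, rmsd = kabsch(p1, p2)
    return rmsd


def classify_form(step: StepParameters,
                  boundary: Tuple[float, float] = DEFAULT_AB_BOUNDARY
                  ) -> StepClassification:
    """A-like iff roll > a + b * slide; points on the line classify B-like."""
    a, b = boundary
    if not (np.isfinite(step.slide) and np.isfinite(step.roll)):
        raise ValueError("slide/roll must be finite")
    form = "A" if step.roll > a + b * step.slide else "B"
    return StepClassification(step_label=step.step_label, slide=step.slide,
                              roll=step.roll, form=form)


def _strand_steps(strand: Strand, h_rise_from_centers: bool) -> List[StepParameters]:
    frames = [fit_base_frame(r) for r in strand]
    steps = []
    for i in range(len(frames) - 1):
        lab = f"{strand.residues[i].label()}/{strand.residues[i + 1].label()}"
        p = step_parameters(frames[i], frames[i + 1], label=lab)
        if h_rise_from_centers:
            ci = base_center(strand.residues[i], mass_weighted=False)
            cj = base_center(strand.residues[i + 1], mass_weighted=False)
            fi = dataclasses.replace(frames[i], origin=ci)
            fj = dataclasses.replace(frames[i + 1], origin=cj)
            p.h_rise, _ = helical_parameters(fi, fj)
        steps.append(p)
    return steps


def _pair_steps(structure: NucleicStructure,
                h_rise_from_centers: bool) -> List[StepParameters]:
    s1, s2 = structure.strands
    n = len(s1)
    pairs = [pair_frame(fit_base_frame(s1.residues[k]),
                        fit_base_frame(s2.residues[n - 1 - k]))
             for k in range(n)]
    steps = []
    for i in range(n - 1):
        lab = f"{s1.residues[i].label()}/{s1.residues[i + 1].label()}"
        p = step_parameters(pairs[i], pairs[i + 1], label=lab)
        if h_rise_from_centers:
            def centre(k):
                c1 = base_center(s1.residues[k], mass_weighted=False)
                c2 = base_center(s2.residues[n - 1 - k], mass_weighted=False)
                return 0.5 * (c1 + c2)
            fi = dataclasses.replace(pairs[i], origin=centre(i))
            fj = dataclasses.replace(pairs[i + 1], origin=centre(i + 1))
            p.h_rise, _ = helical_parameters(fi, fj)
        steps.append(p)
    return steps


def analyze_structure(structure: NucleicStructure, mode: str = "per-strand",
                      reference: Optional[NucleicStructure] = None,
                      boundary: Tuple[float, float] = DEFAULT_AB_BOUNDARY,
                      selection: Union[str, Callable] = "heavy",
                      h_rise_from_centers: bool = False,
                      fine_pucker: bool = False) -> StructureReport:
    """Full conformational report for one (single-model) structure.

    per-strand mode computes base steps within each strand independently (the
    single-strand analysis, also applied strand-by-strand to duplexes);
    base-pair-steps mode builds Watson-Crick pair frames first and computes
    steps between pairs (duplexes only).
    """
    if structure.n_models > 1:
        structure = structure.model(0)
    rows = []
    all_steps: List[StepParameters] = []
    per_strand_steps: List[Tuple[str, Strand, List[StepParameters]]] = []

    if mode == "per-strand":
        for strand in structure.strands:
            cid = strand.residues[0].chain_id
            steps = _strand_steps(strand, h_rise_from_centers)
            per_strand_steps.append((cid, strand, steps))
            all_steps.extend(steps)
    elif mode == "base-pair-steps":
        if not structure.is_duplex:
            raise ValueError("base-pair-steps mode requires a duplex")
        steps = _pair_steps(structure, h_rise_from_centers)
        per_strand_steps.append(("pair", structure.strands[0], steps))
        all_steps.extend(steps)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not all_steps:
        raise ValueError("structure has no steps to analyze")

    classifications = [classify_form(p, boundary) for p in all_steps]
    for (cid, strand, steps) in per_strand_steps:
        for p, c in zip(steps, [classify_form(p, boundary) for p in steps]):
            rows.append({"strand": cid, "step_label": p.step_label,
                         **{k: getattr(p, k) for k in StepParameters.COLUMNS},
                         "form": c.form})
    table = pd.DataFrame(rows)

    puckers = []
    for strand in structure.strands:
        for r in strand:
            try:
                puckers.append(pucker_result(r, fine=fine_pucker))
            except ValueError:
                pass  # missing sugar atoms: pucker simply not reported
    distribution = dict(Counter(p.label for p in puckers))

    e2e = {}
    for strand in structure.strands:
        cid = strand.residues[0].chain_id
        try:
            e2e[cid] = end_to_end(strand)
        except ValueError:
            pass

    homo: Dict[str, List[StepParameters]] = {}
    if mode == "per-strand":
        sources = [(strand, steps) for (_c, strand, steps) in per_strand_steps]
    else:
        sources = [(structure.strands[0], all_steps)]
    for strand, steps in sources:
        seq = strand.sequence()
        for i, p in enumerate(steps):
            t = seq[i:i + 2]
            if len(set(t)) == 1:  # homo-dinucleotide (AA, CC, GG, TT)
                homo.setdefault(t, []).append(p)
    homo_avgs = {t: average_step_params(ps) for t, ps in homo.items()}

    rmsd = None
    if reference is not None:
        ref = reference.model(0) if reference.n_models > 1 else reference
        rmsd = rmsd_superposed(structure, ref, selection=selection)

    return StructureReport(
        mode=mode,
        steps=table,
        averages=average_step_params(all_steps),
        puckers=puckers,
        pucker_distribution=distribution,
        end_to_end=e2e,
        classifications=classifications,
        homo_step_averages=homo_avgs,
        rmsd_vs_reference=rmsd,
    )
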