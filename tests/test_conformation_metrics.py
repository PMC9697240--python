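"""Summary descriptors: averages, end-to-end, RMSD, A/B classification."""

import numpy as np
import pytest

from strandkit import (FiberSpec, StepParameters, analyze_structure,
                       average_step_params, build_fiber, build_unstacked,
                       classify_form, end_to_end, rmsd_superposed)
from strandkit.nucleic_io import NucleicStructure

from conftest import apply_rigid_motion, random_rigid_motion


def test_average_of_single_step_is_itself():
    p = StepParameters(shift=0.1, slide=-0.4, rise=3.3, tilt=1.0, roll=2.0,
                       twist=35.0, h_rise=3.2, h_twist=36.0)
    avg = average_step_params([p])
    for name in StepParameters.COLUMNS:
        assert avg[name] == pytest.approx(getattr(p, name))


def test_average_twist_is_arithmetic_mean():
    steps = [StepParameters(twist=30.0), StepParameters(twist=42.0)]
    assert average_step_params(steps)["twist"] == pytest.approx(36.0)
    with pytest.raises(ValueError):
        average_step_params([])


def test_fiber_b_duplex_average_twist_is_36(b_duplex_12):
    rep = analyze_structure(b_duplex_12, mode="base-pair-steps")
    assert rep.averages["twist"] == pytest.approx(36.0, abs=1e-6)
    assert len(rep.steps) == 11


def test_end_to_end_degenerate_and_invariance(b_fiber_c6):
    single = build_fiber(FiberSpec("G", form="B"))
    res = single.strands[0].residues[0]
    want = np.linalg.norm(res.atom("C5'").position - res.atom("C3'").position)
    assert end_to_end(single.strands[0]) == pytest.approx(want)

    rng = np.random.default_rng(2)
    R0, t0 = random_rigid_motion(rng)
    moved = apply_rigid_motion(b_fiber_c6, R0, t0)
    assert end_to_end(moved.strands[0]) == pytest.approx(
        end_to_end(b_fiber_c6.strands[0]), abs=1e-9)


def test_end_to_end_missing_atom_is_named(b_fiber_c6):
    s = b_fiber_c6.model(0).strands[0]
    s.residues[-1].atoms = [a for a in s.residues[-1].atoms if a.name != "C3'"]
    with pytest.raises(ValueError, match="C3'"):
        end_to_end(s)


def test_unstacked_conformer_is_longer(b_fiber_c6, unstacked_c6):
    assert end_to_end(unstacked_c6.strands[0]) > end_to_end(b_fiber_c6.strands[0])


def test_rmsd_identical_and_rigid_copy(b_fiber_c6):
    assert rmsd_superposed(b_fiber_c6, b_fiber_c6) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(4)
    R0, t0 = random_rigid_motion(rng)
    moved = apply_rigid_motion(b_fiber_c6, R0, t0)
    assert rmsd_superposed(b_fiber_c6, moved, selection="all") < 1e-9


def test_rmsd_single_displaced_atom_is_bounded(b_fiber_c6):
    moved = b_fiber_c6.model(0)
    coords = moved.coordinates()
    d = 2.0
    coords[7] = coords[7] + [0.0, 0.0, d]
    moved.set_coordinates(coords)
    n = len(coords)
    rmsd = rmsd_superposed(b_fiber_c6, moved, selection="all")
    assert 0.0 < rmsd <= d / np.sqrt(n) + 1e-12


def test_rmsd_selection_mismatch_raises(b_fiber_c6, b_duplex_g4):
    with pytest.raises(ValueError, match="mismatch"):
        rmsd_superposed(b_fiber_c6, b_duplex_g4)


@pytest.mark.parametrize("slide,roll,form", [
    (0.4, 0.6, "B"),      # fiber-B-like
    (-1.5, 12.0, "A"),    # fiber-A-like
    (0.0, 4.0, "B"),      # exactly on the default line: tie-break to B
])
def test_classify_form_default_boundary(slide, roll, form):
    c = classify_form(StepParameters(slide=slide, roll=roll))
    assert c.form == form


def test_classify_form_with_custom_boundary():
    step = StepParameters(slide=0.0, roll=2.0)
    assert classify_form(step, boundary=(1.0, 0.0)).form == "A"
    assert classify_form(step, boundary=(3.0, 0.0)).form == "B"


def test_all_fiber_steps_classify_to_their_form(b_duplex_12, a_duplex_12):
    rep_b = analyze_structure(b_duplex_12, mode="base-pair-steps")
    rep_a = analyze_structure(a_duplex_12, mode="base-pair-steps")
    assert {c.form for c in rep_b.classifications} == {"B"}
    assert {c.form for c in rep_a.classifications} == {"A"}


def test_per_strand_mode_reports_both_strands(b_duplex_12):
    rep = analyze_structure(b_duplex_12, mode="per-strand")
    assert set(rep.steps["strand"]) == {"A", "B"}
    assert (rep.steps["strand"] == "A").sum() == 11
    assert (rep.steps["strand"] == "B").sum() == 11


def test_per_strand_and_pair_modes_agree_on_fiber(b_duplex_12):
    rep_s = analyze_structure(b_duplex_12, mode="per-strand")
    rep_p = analyze_structure(b_duplex_12, mode="base-pair-steps")
    assert abs(rep_s.averages["twist"] - rep_p.averages["twist"]) < 0.1
    assert abs(rep_s.averages["rise"] - rep_p.averages["rise"]) < 0.05


def test_report_averages_equal_table_means(b_duplex_12):
    rep = analyze_structure(b_duplex_12, mode="per-strand")
    for name in ("shift", "slide", "rise", "tilt", "roll", "twist"):
        assert rep.averages[name] == pytest.approx(rep.steps[name].mean())


def test_homo_step_groups_by_hand_enumeration():
    """ds-CTGGGGACTTTCCAGG: strand I has GG steps at 3,4,5,15, TT at 9,10 and
    CC at 12; strand II (CCTGGAAAGTCCCCAG) has CC at 1,11,12,13, GG at 4 and
    AA at 6,7.  Pooled homo-step groups must match those counts."""
    d = build_fiber(FiberSpec("CTGGGGACTTTCCAGG", form="B", duplex=True))
    rep = analyze_structure(d, mode="per-strand")
    counts = {}
    for _, row in rep.steps.iterrows():
        b1 = row["step_label"][0]
        b2 = row["step_label"].split("/")[1][0]
        if b1 == b2:
            counts[b1 + b2] = counts.get(b1 + b2, 0) + 1
    assert counts == {"GG": 5, "TT": 2, "CC": 5, "AA": 2}
    assert set(rep.homo_step_averages) == {"GG", "TT", "CC", "AA"}
    # on the uniform fiber every pooled average equals the fiber rise
    for avg in rep.homo_step_averages.values():
        assert avg["rise"] == pytest.approx(3.38, abs=1e-6)


def test_homo_step_averages_track_perturbations():
    """Raising the rise of only the TT steps moves the pooled TT average and
    leaves AA/GG/CC untouched (the per-strand homo-step analysis)."""
    from strandkit import perturb_steps
    d = build_fiber(FiberSpec("CTGGGGACTTTCCAGG", form="B", duplex=True))
    # strand-I steps 9 and 10 are the TT steps
    p = perturb_steps(d, deltas={9: {"rise": 0.5}, 10: {"rise": 0.5}})
    rep = analyze_structure(p, mode="per-strand")
    assert rep.homo_step_averages["TT"]["rise"] == pytest.approx(3.88, abs=1e-3)
    assert rep.homo_step_averages["GG"]["rise"] == pytest.approx(3.38, abs=1e-2)


def test_analyze_with_reference_reports_rmsd(b_duplex_12):
    rep = analyze_structure(b_duplex_12, mode="base-pair-steps",
                            reference=b_duplex_12)
    assert rep.rmsd_vs_reference == pytest.approx(0.0, abs=1e-12)


def test_pair_mode_requires_duplex(b_fiber_c6):
    with pytest.raises(ValueError, match="duplex"):
        analyze_structure(b_fiber_c6, mode="base-pair-steps")


def test_pucker_distribution_in_report(b_duplex_12):
    rep = analyze_structure(b_duplex_12)
    assert sum(rep.pucker_distribution.values()) == 24
    assert "C3'-endo" not in rep.pucker_distribution


def test_report_serialization(tmp_path, b_duplex_12):
    rep = analyze_structure(b_duplex_12, mode="base-pair-steps")
    rep.write(tmp_path / "out")
    assert (tmp_path / "out" / "steps.tsv").exists()
    summary = (tmp_path / "out" / "summary.tsv").read_text()
    assert "avg_twist\t36.0000" in summary
    scatter = (tmp_path / "out" / "slide_roll.tsv").read_text().splitlines()
    assert scatter[0].split("\t") == ["step_label", "slide", "roll"]
    assert len(scatter) == 12
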