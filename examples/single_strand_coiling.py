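"""Compare a helically coiled single strand with an unstacked conformer.

Single-stranded DNA can retain B-DNA-like coiling.  Here the same hexamer
sequence (ss-C6) is built twice: once as an ideal B-form single helix and
once as a deliberately elongated, unstacked conformer.  The stacking
detector and the end-to-end distance (C5' of the first to C3' of the last
nucleotide) tell the two apart.
"""

from strandkit import (FiberSpec, build_fiber, build_unstacked, end_to_end,
                       is_stacked, pucker_result)

helical = build_fiber(FiberSpec("CCCCCC", form="B"))
unstacked = build_unstacked("CCCCCC")

for name, s in (("B-form ss-C6", helical), ("unstacked ss-C6", unstacked)):
    residues = s.strands[0].residues
    stacked = [is_stacked(residues[i], residues[i + 1]).stacked
               for i in range(len(residues) - 1)]
    print(f"{name:16s} stacked adjacent pairs: {sum(stacked)}/5, "
          f"end-to-end {end_to_end(s.strands[0]):6.2f} A")

labels = [pucker_result(r).label for r in helical.strands[0]]
print(f"\nsugar puckers (helical strand): {set(labels)}")
print("""
All five adjacent pairs of the helical strand satisfy the three stacking
criteria (heavy-atom contact < 4 A, base centres < 5 A, near-parallel
normals); none do in the elongated conformer, which is correspondingly much
longer end to end.""")
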