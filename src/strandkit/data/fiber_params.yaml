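# strandkit parameter file, version 1.
#
# standard_bases: heavy-atom coordinates (Angstrom) of the four canonical
#   deoxynucleobases expressed in the standard nucleic-acid base reference
#   frame (the Tsukuba convention adopted by Olson et al., J Mol Biol 313,
#   229-237, 2001, and used by the 3DNA family of programs).  The base plane
#   is z = 0; the frame origin sits in the base-pair C1'...C1' region; the
#   y-axis points toward the attached strand's backbone.  C1' is included so
#   the sugar can be attached at the canonical glycosidic geometry.
#
# steps: uniform base-(pair-)step rigid-body parameters of the ideal fiber
#   models.  B is the calf-thymus fiber-diffraction B-DNA standard (twist 36
#   degrees, rise 3.38 A, vanishing slide/shift/roll/tilt, i.e. helical rise
#   equals rise).  A holds the fiber A-DNA step values (negative slide,
#   positive roll), for which the helical rise (~2.56 A) is markedly smaller
#   than the rise.  Values follow the published fiber tables (Chandrasekaran
#   & Arnott fibre models as analysed with mid-frame step coordinates).
#
# sugar: parameters from which the deoxyribose/phosphate template of each
#   form is constructed at load time: pseudorotation phase P and amplitude
#   tau_m (degrees), glycosidic torsion chi, backbone torsions, and the bond
#   lengths/angles used for atom placement.  B uses the C2'-endo family,
#   A the C3'-endo family.  beta/gamma/epsilon-like placement torsions were
#   calibrated once so that chaining the B-form template with the B step
#   transform leaves O3'(i) -> P(i+1) near covalent-bond distance.

version: 1

steps:
  B: {shift: 0.0, slide: 0.0, rise: 3.38, tilt: 0.0, roll: 0.0, twist: 36.0}
  A: {shift: 0.0, slide: -1.53, rise: 3.29, tilt: 0.0, roll: 11.8, twist: 31.1}

sugar:
  B:
    P: 162.0        # C2'-endo
    tau_m: 36.0
    chi: -107.85    # calibrated (with gamma/beta) so O3'(i)->P(i+1) = 1.595 A
    gamma: 24.99    # under the B step transform; chi stays anti, gamma
    beta: 180.48    # gauche+, beta trans as in fiber B-DNA
    alpha_p: -63.0  # torsion used to place OP1/OP2 about the O5'-P bond
    op_torsions: [-60.0, 60.0]
  A:
    P: 18.0         # C3'-endo
    tau_m: 36.0
    chi: -157.0
    gamma: 42.0
    beta: 175.0
    alpha_p: -52.0
    op_torsions: [-60.0, 60.0]

bonds:
  C1p_N: 1.47
  C1p_O4p: 1.42
  C1p_C2p: 1.52
  C2p_C3p: 1.52
  C3p_C4p: 1.53
  C4p_O4p: 1.44
  C4p_C5p: 1.51
  C3p_O3p: 1.42
  C5p_O5p: 1.44
  O5p_P: 1.59
  P_OP: 1.48

angles:
  N_C1p_O4p: 108.2
  N_C1p_C2p: 113.0
  ring_C1p: 106.0
  ring_C2p: 102.5
  ring_C3p: 102.5
  ring_C4p: 105.5
  ring_O4p: 109.5
  C3p_C4p_C5p: 114.7
  O4p_C4p_C5p: 109.3
  C4p_C3p_O3p: 110.3
  C2p_C3p_O3p: 111.0
  C4p_C5p_O5p: 110.2
  C5p_O5p_P: 119.0
  O5p_P_OP: 108.0

standard_bases:
  A:
    C1': [-2.479, 5.346, 0.000]
    N9:  [-1.291, 4.498, 0.000]
    C8:  [ 0.024, 4.897, 0.000]
    N7:  [ 0.877, 3.902, 0.000]
    C5:  [ 0.071, 2.771, 0.000]
    C6:  [ 0.369, 1.398, 0.000]
    N6:  [ 1.611, 0.909, 0.000]
    N1:  [-0.668, 0.532, 0.000]
    C2:  [-1.912, 1.023, 0.000]
    N3:  [-2.320, 2.290, 0.000]
    C4:  [-1.267, 3.124, 0.000]
  G:
    C1': [-2.477, 5.399, 0.000]
    N9:  [-1.289, 4.551, 0.000]
    C8:  [ 0.023, 4.962, 0.000]
    N7:  [ 0.870, 3.969, 0.000]
    C5:  [ 0.071, 2.833, 0.000]
    C6:  [ 0.424, 1.460, 0.000]
    O6:  [ 1.554, 0.955, 0.000]
    N1:  [-0.700, 0.641, 0.000]
    C2:  [-1.999, 1.087, 0.000]
    N2:  [-2.949, 0.139, -0.001]
    N3:  [-2.342, 2.364, 0.001]
    C4:  [-1.265, 3.177, 0.000]
  C:
    C1': [-2.477, 5.402, 0.000]
    N1:  [-1.285, 4.542, 0.000]
    C2:  [-1.472, 3.158, 0.000]
    O2:  [-2.628, 2.709, 0.001]
    N3:  [-0.391, 2.344, 0.000]
    C4:  [ 0.837, 2.868, 0.000]
    N4:  [ 1.875, 2.027, 0.001]
    C5:  [ 1.056, 4.275, 0.000]
    C6:  [-0.023, 5.068, 0.000]
  T:
    C1': [-2.481, 5.354, 0.000]
    N1:  [-1.284, 4.500, 0.000]
    C2:  [-1.462, 3.135, 0.000]
    O2:  [-2.562, 2.608, 0.000]
    N3:  [-0.298, 2.407, 0.000]
    C4:  [ 0.994, 2.897, 0.000]
    O4:  [ 1.944, 2.119, 0.000]
    C5:  [ 1.106, 4.338, 0.000]
    C7:  [ 2.466, 4.961, 0.001]
    C6:  [-0.024, 5.057, 0.000]
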