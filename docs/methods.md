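# Methods

## Base reference frames

Each base carries an orthonormal right-handed triad + origin obtained by
least-squares superposition (SVD/Kabsch with determinant sign correction, so
mirror solutions are rejected) of the standard base geometry onto the
observed ring atoms — 9 atoms for purines, 6 for pyrimidines. The standard
base coordinates are the published standard-reference-frame geometries (the
Tsukuba convention adopted by the 3DNA family of programs) and ship in
`strandkit/data/fiber_params.yaml`. Because the standard bases are expressed
in their own reference frame, the fitted rotation/translation *is* the frame.
The frame z-axis is the base normal used by the stacking criterion; the
plane-fit normal (`base_normal`) is sign-matched to it.

Watson–Crick pair frames flip the second strand's frame (y and z negated)
into the strand-I convention and take the rigid mean: average origin and the
half-geodesic rotation. Frames whose z-axes disagree by more than 90° after
flipping are rejected as non-pairs.

`base_center` averages the nucleobase atoms only (ring plus exocyclic
substituents, no sugar/phosphate), mass-weighted by default and including
hydrogens when present; flags expose the unweighted and heavy-atom-only
variants because published "centre of mass" usages vary.

## Step coordinates (mid-frame / CEHS convention)

For consecutive frames (T₁, o₁), (T₂, o₂) the bending angle γ between the
z-axes is split symmetrically: both triads are rotated by ∓γ/2 about the
hinge axis ẑ₁×ẑ₂ so their z-axes coincide. Twist ω is the signed angle
between the resulting y-axes about the common z. The mid-frame takes that
common z and the y-axis halfway along the twist (equivalent to the y
bisector, but still defined at ω = 180°); (shift, slide, rise) are the
components of o₂−o₁ in mid-frame axes. With φ the signed angle from the
mid-frame y-axis to the hinge, roll = γ·cos φ and tilt = −γ·sin φ, which
makes positive tilt a rotation about the mid-frame +x axis and positive roll
about +y. Anti-aligned z-axes (γ ≥ 90°) are an error: a step between flipped
bases is not meaningful. Twist is reported in (−180°, 180°] with ties at
±180° resolved to +180°.

The exact inverse (`build_step`) is
T₂ = T₁·Rz(ω/2+φ′)·Ry(γ)·Rz(ω/2−φ′) with φ′ = atan2(−tilt, roll), and the
mid-frame T₁·Rz(ω/2+φ′)·Ry(γ/2)·Rz(−φ′). Build-then-measure round trips
recover 1000 random parameter sets to < 1e-6 in the test suite; this
identity is what lets the fiber generator chain steps and the perturbation
tool add exact offsets.

Helical coordinates decompose the same relative rotation T₂T₁ᵀ as a single
axis–angle pair: helical twist is the rotation angle about the helical axis
(oriented along the 5′→3′ advance, i.e. positive projection on the average
base normal), and helical rise is (o₂−o₁) projected onto that axis. For
rotation angles below 0.01° the helical axis falls back to the mid-frame
z-axis, so a pure translation reports h_twist = 0 and h_rise equal to its
length. By default h_rise uses frame origins; a flag in the analysis layer
switches to base geometric centres, the literal reading of the alternative
convention, so the (small) difference is visible rather than hidden.

## Sugar pucker and backbone torsions

Ring torsions follow the standard quadruples (ν₀ = C4′–O4′–C1′–C2′, …) with
IUPAC dihedral signs (cross-checked against an independent MD library during
development). Pseudorotation uses the Altona–Sundaralingam inversion
tan P = ((ν₄+ν₁) − (ν₃+ν₀)) / (2ν₂(sin 36° + sin 72°)) with the quadrant
fixed by the sign of ν₂ (via atan2) and τm = ν₂/cos P ≥ 0; the generating
convention is ν_j = τm·cos(P + 144°·(j−2)), i.e. ν₂ = τm·cos P. An all-zero
(planar) torsion set raises rather than returning an arbitrary phase.
Conformer names cover the ten primary 36°-wide sectors centred at 18° + k·36°
(C3′-endo, C4′-exo, O4′-endo, C1′-exo, C2′-endo, …), half-open on the upper
edge so P = 144° classifies C2′-endo; a `fine` flag splits each boundary into
the twenty 18° twist/envelope sectors. Backbone torsions α–ζ and glycosidic χ
(O4′–C1′–N9–C4 purines, O4′–C1′–N1–C2 pyrimidines) return missing values at
chain termini or for absent atoms, with a warning, never an error.

## Stacking and hydrogen-bond criteria

Stacking requires all three of: minimum base heavy-atom distance < 4 Å, base
centre-of-mass distance < 5 Å, and base-normal angle in [0°, 45°] ∪
[135°, 180°]. Hydrogen bonds X⋯H–Y (X, Y nitrogen/oxygen heteroatoms of
*different* nucleobases, H covalently bound to Y, i.e. within 1.2 Å) require
d(X,Y) < 3.3 Å and ∠XHY ∈ [150°, 180°]. Boundary values are excluded — the
criteria say "lower than" — and all thresholds are configurable
(`StackingThresholds`, `HBondThresholds`). Detection needs explicit
hydrogens; `idealize_h` places base hydrogens at idealised sp² positions
(N–H 1.01 Å, C–H 1.08 Å, in-plane) for hydrogen-free inputs.

`trajectory_stats` evaluates every residue pair in every model, reporting
stacked fractions for adjacent intra-strand pairs, occurrence counts for all
other pairs, per-snapshot H-bond counts, and persistence (the same (X, H, Y)
triple detected in consecutive snapshots). It runs on precomputed atom
indices; a test asserts exact agreement with the brute-force double loop
over the single-pair detectors on small structures, so the fast path is an
optimisation, never a second definition.

## Fiber generator

Structures are built by chaining the form's uniform step transform from the
parameter file — B (calf-thymus fiber): twist 36°, rise 3.38 Å, zero
shift/slide/tilt/roll, so helical rise = rise; A: twist 31.1°, rise 3.29 Å,
slide −1.53 Å, roll +11.8°, giving helical rise ≈ 2.56 Å — and stamping a
per-base nucleotide template into every frame. Duplexes place the
complementary strand by flipping each pair frame; with zero intra-pair
deformation both bases of a pair share the pair frame exactly, which is why
per-strand and pair-step analyses agree on generated fibers.

The template combines the standard-frame base (plus idealised base
hydrogens) with a deoxyribose built at load time from the form's
pseudorotation target (B: P = 162°, C2′-endo; A: P = 18°, C3′-endo; τm = 36°)
by least-squares ring closure over the five bond lengths and five torsions,
then attached at the glycosidic bond with the form's χ. Stereocentre
handedness at C1′/C3′/C4′ was validated against an independent ideal
deoxynucleotide geometry. The remaining backbone torsions come from the
parameter file; for the B form, χ/γ/β were calibrated once (χ = −107.85°,
γ = 24.99°, β = 180.48° — anti, gauche+, trans) so that chaining the template
under the B step transform leaves O3′(i)→P(i+1) at the bond length
(1.595 Å). The A-form backbone cannot be closed this way with idealised
internal coordinates and canonical torsions; its O3′→P gap is ≈ 1.8 Å, close
enough for connectivity-based strand-direction inference but not a covalent
geometry. Backbone closure under heavy perturbation is explicitly out of
scope: base-dependent quantities (frames, steps, stacking, pairing) are exact
by construction, backbone-dependent ones (α/ε/ζ across residues) are
approximate.

The unstacked conformer uses a deterministic elongated geometry (per-step
rise 7 Å, roll ±60° alternating, twist 36°) chosen so that no adjacent pair
satisfies the stacking criteria — a geometric surrogate whose only defining
property is "no stacked pairs", standing in for a force-field-optimised
unstacked start.

## Mock trajectories

`make_mock_trajectory` samples every adjacent step independently per
snapshot: stacked steps get the fiber transform, unstacked steps the
elongated offset, and isotropic Gaussian coordinate noise (default study
setting 0.05 Å) is added last; all randomness comes from one seed, so output
is byte-identical across runs. Hydrogen-bond events (expected `hbond_rate`
per snapshot, Poisson-sampled) replace a randomly chosen *unstacked* step by
a coplanar edge-contact geometry in which one donor H lies on the X⋯Y line
at d(X,Y) = 2.9 Å: this satisfies the H-bond criteria while keeping the base
centres > 5 Å apart, so the pair still fails stacking criterion (ii) and the
programmed stacked/unstacked labels stay truthful. Event steps within one
snapshot are kept pairwise non-adjacent so each inserted contact is a single
countable bond. Steps are sampled without kinetics (no temporal correlation)
— the aggregators and detectors, not dynamics, are what the mock data
validate. The generator emulates the *statistics* of an MD snapshot ensemble
(per-step stacking frequencies, rare transient H-bonds), not its physics: no
solvent, no counterions, no backbone relaxation, no correlated motion.
Passing tests therefore demonstrate that the detectors and aggregators
recover known ground truth, not that real MD would show these fractions.

Study-condition regimes used by the test suite: per-step stacking
probabilities (0.6, 0.6, 0.6, 0.02, 0.0) on a C6 single strand — the
"common" 60% regime on the first three CC steps and the rare 2% regime on
the fourth — and an H-bond event rate of 104 events per 5×10⁴ snapshots.
Recovery is asserted within 3 binomial / 3 Poisson standard deviations at
the simulated length (5000 snapshots in the acceptance suite, smaller in
unit tests), chosen to keep the full suite under a minute on one CPU.

## A/B classification

A step is A-like iff roll > a + b·slide with defaults (a, b) = (4°, −4°/Å);
points on the line classify B-like. The default line is a stand-in
calibrated so canonical fiber A and B steps fall on their proper sides
(fiber B: (0, 0) → B; fiber A: (−1.53, 11.8) → A, margin ≈ 1.7°); published
dividing lines vary, so both parameters are configurable everywhere the
classification is exposed.

## Averaging and report conventions

Per-structure averages are arithmetic means over all dinucleotide steps;
angles are averaged arithmetically, justified because every in-scope angle
stays far from the ±180° wrap. Homo-dinucleotide (AA/CC/GG/TT) averages pool
steps from both strands in per-strand mode, matching how per-step-type
numbers are quoted for duplexes. Duplexes can be analysed per strand (each
strand's own base steps) or as base-pair steps (pair frames first); both are
provided because published duplex averages do not always state which was
used. NMR ensembles default to model 1 — a choice, since source analyses
rarely state the model — with any model selectable and full-ensemble
statistics available through the trajectory machinery.

## Degenerate inputs and tie-breaks

Zero-length vectors raise; twist ties at ±180° resolve to +180°; helical
axis falls back to mid-frame z below 0.01° of relative rotation; planar
sugar rings are flagged rather than classified; pucker sectors are half-open
upward; missing backbone atoms warn and yield missing angles; residues
missing ring atoms name the atom in the error. PDB atom-name dialects
(asterisk primes, O1P/O2P, C5M) are normalised on input; strand direction is
inferred from O3′(i)→P(i+1) connectivity (< 2.5 Å) with author order as the
fallback when phosphates are absent.

## Known limitations

- The A-form template backbone is not covalently closed (see above).
- Only canonical deoxynucleotides are handled: no RNA, modified bases,
  mmCIF, or binary trajectory formats.
- Non-Watson–Crick pairing (Hoogsteen, wobble, quadruplex) is out of scope;
  pair frames assume antiparallel complementary strands.
- Base-pair (intra-pair) parameters such as propeller or buckle are not
  computed; the pair frame itself is the only intra-pair construct.
- The stacking criteria are geometric; no energetic or π-overlap scoring.
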