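# Methods

This note documents the models, numerical choices and conventions behind
flexsas, and what the synthetic-data tests do and do not establish.

## Particle models and units

A `ParticleModel` is a set of point scatterers with positions (Å), X-ray
electron counts (e), neutron bound coherent scattering lengths (fm,
protonated state), displaced solvent volumes (Å³), labile-hydrogen counts
and segment/residue/chain labels. All lengths are Å, q is Å⁻¹, b is fm
(1 fm = 10⁻⁵ Å), SLD is Å⁻², electron density is e/Å³; unit conversion
happens only at I/O boundaries.

Neutron scattering lengths are the Sears (1992) bound coherent values
(H −3.739, D 6.671, C 6.646, N 9.36, O 5.803 fm, …). X-ray amplitudes are
carried as constant electron counts: the q-dependence of atomic form factors
is negligible over the q ≲ 0.5 Å⁻¹ range of solution scattering and is
ignored. No explicit hydration shell is modelled; its contribution is
absorbed into the fitted scale. These simplifications matter only for
absolute-scale comparisons with hydration-aware evaluators, not for the
shape/oligomer discrimination the package is built for.

Coarse granularity is one bead per residue (composition-averaged residue:
58.8 e, 25.4 fm protonated, 135 Å³, 1.8 exchangeable H). At the resolution
of the data (q ≲ 0.4 Å⁻¹, real-space features ≳ 15 Å) sub-residue detail is
invisible, and residue beads keep the 343-member ensemble computations at
desk scale.

## Membrane frame, hinges, trimer assembly

`orient_membrane` puts the transmembrane (TM) centroid at the origin and the
assembly's principal axis on +z with the cytoplasmic rod pointing up — a
rigid transform only. Hinge bending rotates all scatterers distal to the
hinge residue (larger residue index) about an axis through the hinge-residue
centroid, perpendicular to the distal rod axis (ẑ × rod-axis,
sign-normalised so its largest component is positive; x̂ when the rod lies
on z). The sign normalisation makes bend(θ) followed by bend(−θ) an exact
identity on oriented rods. Hinge pivot residues default to the
HAMP1/inter-HAMP boundary (136), the HAMP2/adaptation boundary and the
glycine-hinge centre, all overridable — the exact pivots are a modelling
choice, not an observable at this resolution.

`assemble_c3` builds trimers of dimers with *exact* C3 symmetry (copies are
generated by 120° rotations, so the symmetry check is limited only by
floating point). In tripod mode each copy is tilted toward the axis by
atan(radial_offset / tip height) before radial displacement, so cytoplasmic
tips converge on the axis while TM parts separate; a radial offset of
90/√3 ≈ 52 Å gives the 90 Å inter-TM-centroid distance used in the examples.
Inter-dimer distance is reported between TM-bundle centroids (the
alternative — helix-axis distance — differs by a few Å and is not resolvable
in the data).

## Detergent corona

The DDM belt is a two-shell elliptical torus of pseudo-atoms on a jittered
hexagonal lattice (fixed seed): a hydrophobic shell (|z| ≤ half-thickness,
inside the (a, b) ellipse) and a hydrophilic shell wrapping it radially and
axially; points within 1.8 Å of a protein scatterer are discarded. Default
dimensions (a = b = 45 Å, t = 15 Å, head 8 Å) are plausible for a DDM-
solubilized TM bundle; when fitting real data they should be scanned, which
is deliberately out of scope here (the full MEMPROT-style five-parameter
search is not reimplemented).

Scattering assignment is exact by construction: tail pseudo-atoms carry
9 e = (9/97)·97 and b = (9/97)·Σb(C12H25) = −1.273 fm; head pseudo-atoms
carry 10 e and b = (10/181)·Σb(head) with the seven exchangeable hydrogens
deuterated at the solvent D2O fraction (7.621 fm in pure D2O). The
`equivalent_deuteration_fraction` inverse (b_C + 3[(1−f)b_H + f·b_D] = b*)
yields f = 0.1056 and 0.3904 for the two shells. Default moiety volumes
354/352 Å³ reproduce the shell SLDs −0.388×10⁻⁶ and 3.92×10⁻⁶ Å⁻²; they are
configurable since detergent volumetry varies by a few percent between
sources.

In D2O the protein and both belt shells all sit below the solvent SLD (one
contrast sign), which is what makes SANS sensitive to the oligomeric state
rather than to the belt; for X-rays the tail (0.27 e/Å³) and head
(0.51 e/Å³) straddle the buffer and have opposite contrasts.

## Forward model and solvent

`debye_curve` evaluates the Debye double sum with a pair-distance histogram
(default bin 0.2 Å) using amplitude-weighted mean distances per bin; this
reproduces the exact O(N²) sum to well below 0.3 % over the working q range
for N ≤ 5000 and makes 343-member basis builds a ~2 s operation. The exact
path is kept for validation and small models.

The solvent model fills a litre with water/D2O at its molar volume plus NaCl
at a 20 cm³/mol apparent molar volume: ρₑ = 0.334 e/Å³ for pure water,
≈ 0.374 at 4 M NaCl; neutron SLD 6.36×10⁻⁶ Å⁻² for D2O, 6.17×10⁻⁶ at 4 M.
Minor buffer components (phosphate, EDTA, free detergent monomers) are not
modelled; they shift the SLD at the percent level.

Sphere-form-factor validation compares the bead-model curve against the
analytic sphere of equal Rg (R_eff = √(5/3)·Rg of the bead cloud) and
measures relative error outside the interference nulls (F > 10⁻² F(0)): the
exact zeros of an ideal sphere cannot be matched in relative terms by any
finite bead model, while everywhere else the 3000-bead model agrees to
≈ 0.1 %.

## Guinier, IFT, Kratky

`guinier_fit` iterates the window to self-consistency under q·Rg ≤ 1.3
(default). For strongly elongated particles the Guinier law converges slowly
and the window should be tightened (q·Rg ≤ 0.8 recovers a thin rod's L/√12
to 1.5 %; the default window is biased ~5 % low for that extreme case).

`ift_pr` solves the regularized indirect Fourier transform
min ‖(I − A·P)/σ‖² + α‖P″‖² with P ≥ 0 and P(0) = P(Dmax) = 0, by NNLS on
the Tikhonov-stacked system (uniform r grid, M = 101, trapezoid quadrature).
α = "auto" applies the discrepancy principle: the strongest smoothing whose
reduced χ² stays below max(1, 1.1·χ²_min). The more common L-curve corner
was tried first and abandoned: for these NNLS systems the L-curve is
corner-free, the maximum-curvature picker lands at near-zero α, and P(r)
ripples. Dmax must be supplied (CLI) or defaults to 3.5·Rg_Guinier in the
pipeline — an elongated-particle heuristic; publication-grade numbers need a
user-chosen Dmax.

The dimensionless Kratky transform (qRg, (qRg)²I/I(0)) peaks at √3 (height
3/e) for an ideal globule; the synthetic flexible-rod ensembles peak at
qRg ≈ 4–7, the diagnostic used to call the low-salt dimer flexible rather
than globular.

## Ensemble and mixture fitting

`build_hinge_basis` applies every hinge-angle triple (proximal to distal:
HAMP1 → HAMP2 → Gly) to the oriented dimer, optionally adds the belt, and
evaluates one curve per conformer (343 for the full −90°…90°/30° grid;
sterically clashing conformers — non-adjacent scatterers < 1 Å — are
excluded and reported; 2 of 343 for the default toy dimer).

`tikhonov_nnls` minimises ‖(A·u − I)/σ‖² + α‖u‖² over u ≥ 0 (Γ = identity),
normalises w = u/Σu and refits the scale; α = "auto" again uses the
discrepancy principle (strongest damping within 2 % of the best residual
norm). The physically meaningful summary is the per-hinge RMS bending angle
√(Σ w θ²): on synthetic ensembles drawn at 55° RMS it is recovered to a few
degrees. Individual member weights are *not* identifiable at realistic
noise: conformers related by bend-sign mirroring have nearly identical
distance spectra (χ²-distance ≪ 1 at 2 % noise), so weight vectors are
exchangeable within such classes. Member-level statements are only
meaningful aggregated over these indistinguishability classes, or on a
coarse well-separated grid.

`mixture_fractions` fits per-complex-mass normalized component curves by
NNLS; fractions are scale-invariant, reported in percent with 1σ
uncertainties from the χ²-inflated normal-equations covariance (optionally
cross-checked by residual bootstrap). `compare_trimer_models` runs the fit
once per trimer hypothesis (tripod vs TM-bound) and ranks by χ²; ties are
reported, not broken.

## Synthetic data: what it emulates, what it does not

The toy dimer is a TM cylinder bundle (30 Å high, 83 residues) carrying two
parallel 200 Å bead rods (2.5 Å spacing, 10 Å apart) with three labelled
hinges at fractions 0.20/0.40/0.65 along the rod — the architecture (long
thin rod on a membrane anchor, total extent ≈ 230 Å) and scattering mass
scale of a solubilized receptor/transducer dimer. Geometry is a pure
function of its parameters; the seed only tags metadata.

Noise is heteroscedastic Gaussian, σ = 0.02·I + 0.006·√(I·I₀) + floor,
giving σ/I ≈ 2 % at low q to ≈ 15 % at high q — the error profile of
bench-quality SANS on dilute membrane-protein samples. The generated σ
column is the generating σ, so χ² of truth against a replicate averages 1
(verified over 60 seeds).

Not emulated: instrument resolution smearing, inter-particle structure
factor, incoherent background, partial unfolding of the rod, belt-geometry
variability, and the atomic detail of real side chains. Passing the
recovery tests therefore shows the *inference machinery* is correct and
well-calibrated at realistic counting noise — not that real data are free
of these additional systematics. χ² values against real deposited curves
additionally depend on hydration-shell and belt treatments this package
deliberately simplifies, so such benchmarks should be read with ±30 %
latitude on χ².

Notable geometric fact surfaced by the generator: the tripod trimer is not
"longer" than the dimer (tips converge; max extent 233 vs 231 Å) — its size
signature is lateral, a larger Rg (85 vs 75 Å) and a second P(r) population
near the 90 Å inter-dimer distance.

## Degenerate inputs and tie-breaks

Empty TM selections, unlabeled belt atoms, non-ascending q, non-positive σ,
zero contrast weights and all-zero NNLS solutions raise errors naming the
offending input. Nearly collinear mixture components (condition number
> 10⁸) attach a warning to the result instead of failing. χ² uses N − p
normalisation with p the number of fitted scale parameters (the convention
is stated because it is not universal).

## Problem sizes

Defaults are chosen so the full test suite runs in seconds on one core: toy
dimer 328 beads, belt ~1900 pseudo-atoms at 0.004 Å⁻³, 343-member basis on a
121-point q grid (~2 s to build), recovery experiments with 2000-conformer
ensembles and 101-point SANS grids. All scale linearly (curves) or
quadratically (Debye pair sums) if finer models are needed.
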