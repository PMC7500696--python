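# Methods

This note documents the models, conventions and defaults behind
`helixcheck`, and what the synthetic-data generators do and do not
emulate.

## Coordinate handling

Structures are ordered multi-model collections of chains → residues →
named atoms (Å). All models of a file must share one atom topology; this
is enforced on construction and on read. PDB parsing/writing is delegated
to gemmi; only ATOM records are read by default, altlocs other than
blank/'A' are dropped, and residue numbering is taken verbatim. Trajectories
are represented as multi-model PDB files with uniform frame spacing; time-based
lags (e.g. "1 ns") are converted to frames via a frames-per-ns setting in the CLI.
Selections (`chain:start-end:atoms`) resolve in file order, so repeated
resolution is deterministic.

## Torsion predictions, rigidity, and restraints

Prediction tables carry per-residue φ/ψ (degrees, [−180, 180)), their
standard deviations, the RCI-S² order parameter (0 = fully flexible,
1 = rigid), a database-match count and a 4-level class
(None/Good/Warn/Dyn). Residues with RCI-S² ≥ 0.7 (inclusive) are treated
as well-structured; the threshold is an argument.

Restraint generation emits one φ and one ψ flat-bottom restraint per
rigid residue with rk2 = rk3 = 32.0 kcal·mol⁻¹·rad⁻¹ by default. A φ
restraint requires residue i−1 to be present in the table and ψ requires
i+1, because the torsions are undefined at chain termini; an explicit
exclusion list supports leaving individual residues (e.g. a loop residue
under mutational study) unrestrained. The flat-bottom half-width defaults
to max(prediction SD, 10°): prediction tables state per-angle SDs but no
well width, so the floor is a package decision chosen to keep wells from
collapsing below the predictor's typical accuracy. The text rendering is
a generic flat-bottom record; an AMBER-namelist-like rendering is a
formatting option only.

## Superposition and RMSD metrics

Superposition uses the Kabsch solution (via
`scipy.spatial.transform.Rotation.align_vectors`), always returning a
proper rotation; collinear fit sets are flagged degenerate. RMSDs are
unweighted. Ensemble statistics are computed over all n(n−1)/2 unordered
model pairs with SEM = SD/√(n_pairs); the pair-count denominator is the
documented convention and is what the summary reports.

Rolling RMSD superposes frame t−lag onto frame t over the fit selection
and evaluates the RMSD over the (possibly different) calc selection, so
rigid-body motion contributes nothing and the metric isolates
conformational drift.

Dihedral RMSD against predicted targets pools φ and ψ equally and wraps
every difference circularly into (−180°, 180°] before squaring; it is
therefore invariant to adding full turns to any angle.

Convergence analysis between two independently generated ensembles first
drops dissociated replicas — fewer than 10 inter-chain heavy-atom
contacts within 5 Å (both numbers configurable; an explicit version of
the usual visual "lost most interstrand contacts" call) — then averages
each ensemble (plain coordinate mean after superposing every model onto
the first; geometry is not re-idealised), superposes the two averages and
reports global and subunit RMSDs plus pooled pairwise statistics. All
reported scalars are symmetric in the ensemble order.

## Helix geometry

A helix axis is the dominant principal component of the Cα positions
after 4-point sliding-window averaging; the window (≈ one turn) removes
the 3.6-residue helical wobble that would otherwise tilt a plain PCA on
short segments. Axis sign points N→C, and the interhelix angle is taken
between signed directions (antiparallel = 180°). Axis algorithms differ
between packages at the level of a few degrees on short helices, which is
why crossing-angle checks in the tests use a ±2–3° tolerance.

Helix assignment from dihedrals uses the α window φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°] with a minimum run of 4 consecutive residues; residues
with undefined angles (termini) are coil. This is a deliberately simple,
reproducible rule — not a hydrogen-bond (DSSP-style) assignment.

Contour length of a linker is L = 4 Å·n_coil + 1.5 Å·n_helix: ~4 Å per
residue for a fully extended coil and the 1.5 Å/residue rise of an
α-helix. It is an upper bound on end-to-end extension, used for
feasibility checks, not an average dimension.

## CSP, titration, classification

Compound CSP: Δδ = [(Δδ_H)² + (Δδ_N/s)²]^½ with s = 6.5 by default
(the conventional ¹⁵N dispersion scale; configurable). Peaks are matched
across conditions by residue index only — overlapped pairs must be
flagged in the input table, there is no peak tracking in ppm space.
Attenuation is I/I₀ against an explicit reference condition; the
reference itself is reported as exactly 1, and residues with I₀ = 0 or
non-ok status are undetermined.

Effect classes split the scored residues at the quartiles of the score
distribution, computed with linear interpolation between order statistics
(Hyndman–Fan type 7, numpy's default). Ties at a boundary fall to the
lower class, and the ordering is oriented so q4 is always the strongest
effect (for attenuation, the smallest ratios). The convention is
documented because classifications of residues sitting exactly at a
quartile boundary depend on it.

## RDC validation

D(i) = D_max · v̂ᵢᵀ S v̂ᵢ with S the symmetric traceless Saupe matrix in
the 5-element parameterisation (Sxx, Syy, Sxy, Sxz, Syz). The fit is
linear least squares and requires ≥5 residues with both an observed
coupling and an N–H vector plus a full-rank design; with exactly five
independent vectors it interpolates. D_max defaults to 1, i.e. the
dipolar scale is absorbed into the reported product-form tensor — all
quality metrics are invariant to that choice. Q uses the Cornilescu
normalisation rms(D_calc − D_obs)/rms(D_obs).

Amide protons missing from the coordinates are built geometrically:
1.02 Å from N along the bisector opposite the C'(i−1)–N and Cα–N bonds
(planar amide). This matches the builder's own proton placement to better
than 0.1°, but against experimental structures it adds a small systematic
component to Q (order 0.03).

The dipolar wave is D(n) = A_v + A_II·cos(2πn/period + φ) with the period
fixed at 3.6 residues/turn by default, which makes the fit exactly linear
(solved in the cos/sin basis; amplitude/phase recovered with
first-order error propagation from the residual-scaled covariance). An
optional second harmonic is off by default. A_v, the mean coupling level
over the stretch, is the most robust parameter; A_II depends on the exact
functional form and period convention.

## Synthetic-data generators

All generators are pure functions of their arguments; a seed fixes every
output bit for bit.

* `build_ideal_helix` places N/CA/C/O (+ amide H) by natural-extension
  from standard internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å,
  C–N 1.329 Å, τ(N–CA–C) 111.2°, ω = 180°) at uniform (φ, ψ), default
  (−60°, −45°), the α_R region. Torsion measurement inverts the
  construction to < 10⁻³ deg.
* `build_bundle` rigidly places two or four such helices at a requested
  crossing angle and axis separation (default 10 Å; tests use 7 Å so that
  backbone-only chains make inter-chain contacts).
* `perturb_ensemble` adds i.i.d. isotropic Gaussian noise per atom per
  model — a stand-in for an NMR-style ensemble with a known, analytically
  tractable spread.
* `synth_trajectory` combines a Gaussian random-walk drift of the frame
  mean with per-frame jitter, giving trajectories whose rolling-RMSD
  behaviour (stationary vs drifting) is known by construction.
* `synth_rdc` back-calculates couplings from a known tensor and adds
  Gaussian noise, enabling exact-recovery and residual-expectation tests.
* `synth_titration` implements two-state fast exchange: the bound
  fraction comes from the exact quadratic equilibrium solution at the
  default study conditions (0.3 mM observed peptide, K_d = 1 μM, ligand
  at protein:ligand molar ratios 40:1 … 7:1), observed shifts move by
  f_bound·Δδ_bound, and intensities attenuate as
  I/I₀ = exp(−k·f_bound·Δδ_bound) with k = 5 ppm⁻¹. The exponential
  attenuation is a deliberately simple surrogate for
  intermediate-exchange broadening: it reproduces the qualitative
  structure the classification pipeline needs (interface residues with
  large bound-state shifts attenuate most) without any spin physics.

What the generators do **not** emulate: force-field energetics and
correlated conformational motion, realistic NMR lineshapes or relaxation,
peak overlap in ppm space (overlap is injected by flag), side chains, and
experimental baseline/phase artefacts. Tests passing on synthetic data
therefore demonstrate correctness of the computations and their
statistical behaviour under the stated noise models — not agreement with
any particular experimental system.

## Problem sizes and numerical choices

The test suite runs everything at desk scale: ensembles of 5–10 models of
20–50-residue helices, trajectories of 20–80 frames, 500-seed
simulations for residual expectations, and 100–150-replicate bands for
ensemble statistics. Angle comparisons use circular wrapping throughout;
equality tolerances are 10⁻⁹ for algebraic identities, 10⁻³ deg for the
builder/measurement round trip, and 3-standard-error bands for stochastic
expectations. Degenerate inputs (collinear fit sets, rank-deficient RDC
designs, all-excluded ensembles, empty selections) raise informative
errors rather than returning numbers.

## Known limitations

* No mmCIF or binary trajectory formats; trajectories are multi-model PDB.
* Peak matching is index-based; no assignment transfer or peak tracking.
* The dissociation filter and the helix-assignment window are explicit
  but heuristic conventions; both are configurable.
* RDC fitting treats a single model at a time; no ensemble-averaged fits.
* K_d estimation, lineshape/exchange-regime analysis, and
  secondary-structure prediction are out of scope.
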