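# Methods

## The many-body PIP potential

The total energy of a two-element molecule (the reference case is an alkane
C_nH_{2n+2}, elements C and H) is expanded over its atoms as bodies:

    V = Σ_i V1b(i) + Σ_{i<j} V2b(i,j) + Σ_{i<j<k} V3b(i,j,k) + Σ_{i<j<k<l} V4b(i,j,k,l)

Five-body and higher terms are not considered.  Each n-body term is typed by
the element composition of its atom tuple — CC, CH, HH for pairs; CCC, CCH,
CHH, HHH for triples; CCCC … HHHH for quadruples (twelve types in all) — and
written as a linear combination of permutationally invariant polynomial
(PIP) basis functions in Morse variables

    y_ij = exp(−r_ij / λ),

where r_ij is an internuclear distance and λ a range hyperparameter (bohr).
Compositions sharing a permutation structure share a basis but carry their
own coefficients: CCC and HHH use the A3 basis, CCH and CHH the A2B basis,
and the quadruples use A4, A3B or A2B2.

### Basis convention

For each symmetry type the basis consists of orbit sums of monomials in the
edge variables (no constant term), capped by total degree.  Two details pin
the convention down:

* **Connectedness.**  Only monomials whose positive-exponent edges form a
  connected graph spanning every atom of the tuple are kept.  Each retained
  function is then a genuine n-body interaction: it vanishes whenever the
  tuple fragments into separated pieces, so no 2-body content is duplicated
  inside 3- and 4-body terms.  At the correction-surface orders used here
  (2-b: 6, 3-b: 7, 4-b: 5) this convention gives exactly 383 linear
  coefficients over the twelve types.  The all-invariants convention
  (`connected=False`) is retained for analysis; its per-degree counts are
  validated against a Burnside/Molien counting oracle.
* **Bitwise invariance.**  Each monomial is evaluated as a product of its
  factors in value-sorted order, each orbit is summed in value-sorted order,
  and the per-tuple contributions of the full potential are accumulated in
  value-sorted order.  Relabelling like atoms therefore changes the energy
  by exactly zero — not merely to round-off.  The fitter, optimizer and
  integrator use a faster log-space evaluation path that is equivalent to
  round-off.

### Range cutoffs

A tuple contributes only if its largest internal distance is below the
per-type cutoff (defaults: pairs unrestricted, triples 10 bohr, quadruples
8 bohr).  The hard cutoff introduces a step discontinuity at the tuple
boundary; an optional cosine switching window (`switch_width`) ramps each
tuple's contribution smoothly to zero for dynamics applications.  Energies
are in hartree and geometry in bohr throughout; file I/O defaults to
angstrom.

## Fitting

All coefficients of all types are determined in a single overdetermined
linear least-squares solve against total energies ("at once"), using the
rank-revealing SVD solver; rank deficiency yields the minimum-norm solution
plus a warning, and the ratio of extreme singular values is reported as a
condition diagnostic.  Because the basis has no constant term, a reference
constant is solved alongside the coefficients and absorbed, together with
the dataset-minimum shift, into the model's `energy_offset`.  Optional
per-frame weights are supported; the inverse-energy form
w = E_ref/(E − E_min + E_ref) emphasizes low-energy configurations.

## Delta correction

A corrected surface is the exact sum of a low-level model and a correction
model fit to high-minus-low energy differences of a modest configuration
set.  The differences span a small energy range compared to the raw
high-level data, which is why a compact (383-coefficient) basis fits them
to high precision.  The correction training set follows a three-source
protocol: frames strided from NVE trajectories started at stationary
points, Gaussian coordinate displacements of those points (default σ =
0.05 Å), and random picks from the low-level training pool.  Both
difference conventions are supported: against direct low-level reference
energies (default) or against the fitted low-level model.

## The synthetic reference system

The toy potential makes the whole pipeline testable without external data.
Its terms, with frozen fixture constants chosen for qualitative realism:

| term | form | constants |
|---|---|---|
| bond | k_b (r − r₀)² | k_b = 300 kcal/mol/Å²; r₀ = 1.54 (CC), 1.09 Å (CH) |
| angle | k_θ (θ − θ₀)² | k_θ = 60 kcal/mol/rad²; θ₀ = arccos(−1/3) |
| backbone torsion | (V₃/2)(1 + cos 3φ) | V₃ = 3 kcal/mol |
| repulsive core | C₁₂ / r¹² | C₁₂ = C₆ r_m⁶/2; r_m = 4.0/3.4/2.9 Å (CC/CH/HH) |
| dispersion (high level only) | −C₆ / (r⁶ + d⁶) | C₆ = 1200/330/90 kcal·Å⁶/mol; d = 1.2 Å |

Nonbonded terms act on pairs at least three bonds apart.  The "low" level
omits dispersion only, so high − low is exactly the dispersion sum — the
lone driver of chain folding.  The shared repulsive core is essential: with
a purely attractive, bounded nonbonded term (well depth ≈ −C₆/d⁶ ≈ −400
kcal/mol at CC overlap) every chain collapses onto itself under
minimization, which is useless as a conformational testbed.  With the core
in both levels the dispersionless surface favors the extended chain at
every length (gap ≈ +7 kcal/mol) while the dispersion-containing surface
folds increasingly with length and crosses over near C14 — the qualitative
pattern the correction workflow is meant to capture.

The chain builder produces C_nH_{2n+2} templates with ideal bond lengths,
tetrahedral angles, and all-anti backbones; the hairpin template inserts
the adjacent-reentry U-turn g+ g+ t g+ g+ mid-chain (five backbone
dihedrals, hence n ≥ 8).  Four-dihedral all-gauche turns were rejected:
they kink the backbone without folding it back, so the strands never pack.
Custom backbone dihedral lists support gauche-defect conformers and
partially folded chains.

What the toy does *not* emulate: electronic effects (bond breaking, charge
transfer), realistic torsional asymmetry between gauche and anti (its
threefold torsion makes them degenerate; folding cost comes entirely from
the nonbonded core), hydrogen-atom torsional barriers, or quantitative
alkane thermochemistry.  Tests passing on the toy therefore demonstrate the
machinery — symmetry handling, fitting, correction stacking, transfer,
dynamics — not chemical accuracy for real alkanes.

## The delta-correction study

`mbpip.workflows.toy_delta_study` runs the package end to end at desk
scale.  Frozen study conditions:

* training chain C9 — the smallest chain whose hairpin turn is flanked by
  an anti strand dihedral, so the turn-strand junction environment of every
  longer chain is represented in training (the C8 turn occupies all five
  backbone dihedrals and transfers poorly); transfer scored at C10 with no
  length-10 configuration entering any fit;
* gaps are evaluated as single-point energies at stationary configurations
  optimized once on the reference (dispersion-containing) surface and
  shared by all potentials — the same consistency convention as comparing
  several electronic-structure surfaces at one set of reference-optimized
  geometries;
* nine sampling centers: linear and hairpin minima of both surfaces plus
  five gauche-defect conformer minima of the low-level surface; each
  contributes a 300 K NVE trajectory (151 frames at stride 10, step 5 au)
  and 51 Gaussian displacements (σ = 0.05 Å); 2544 further frames are
  picked from a pool of perturbed and partially folded chains; dense σ =
  0.03 Å clouds around the two reference minima enter with weight 5;
* the low-level surface is fit with orders {2-b: 14, 3-b: 10, 4-b: 6}
  (λ = 2 bohr) after windowing the data to 150 kcal/mol above the minimum
  and weighting by E_ref = 20 kcal/mol; the correction uses the reference
  orders {6, 7, 5} (383 coefficients) on unweighted direct differences;
* three independent sampling realizations are drawn and their models
  averaged — the models are linear in their coefficients, so averaging
  coefficients is exactly averaging predictions, and it damps the
  sampling noise of any single realization.

The problem sizes (C9 training molecule, ≈4000 frames per realization,
three realizations) are the package's desk-scale defaults; they make the
full study reproducible in minutes on one CPU.

## Dynamics and spectra

NVE dynamics uses velocity Verlet (default step 5.0 au ≈ 0.121 fs, 10,000
equilibration and 22,500 production steps).  Initial velocities are
Maxwell–Boltzmann draws with center-of-mass momentum and total angular
momentum projected out, rescaled so the kinetic energy equals the
classical-oscillator correspondence ⟨E⟩ = (3N − 6)·kT (126·kT for
C14H30).  Atomic masses are standard atomic weights.

Power spectra are the time-averaged Fourier transform of the Cartesian
velocity autocorrelation function, computed by the periodogram route
(Wiener–Khinchin): Hann-tapered, mass-weighted velocities are zero-padded
×2, FFT'd, squared, summed over atoms and components, and averaged over
trajectories (default five).  Intensities are manifestly non-negative and
satisfy Parseval consistency with the windowed kinetic-energy content;
mass weighting, taper and padding are all switchable.

## Numerical choices and limitations

* Geometry optimization is L-BFGS in Cartesians; convergence means the
  largest gradient component is below `gtol` (default 1e−6 hartree/bohr).
  An optional per-coordinate trust box (`max_displacement`) keeps local
  optimization on fitted surfaces inside their sampled region — a
  polynomial surface extrapolates freely and can have spurious holes at
  short range unless the training data covers the repulsive wall.
* Degenerate geometries (r → 0) are well-defined (y → 1), but the fitter
  warns when training distances fall below 0.5 bohr, where Morse variables
  saturate.
* Model files are JSON; coefficient round-trips are bit-exact (Python's
  shortest-repr float serialization).
* Linear dependence of basis functions cannot occur across orbits (disjoint
  monomial support), but the *sampled* design matrix can still be
  rank-deficient for narrow data distributions; the solver's minimum-norm
  behavior plus the condition diagnostic make this visible rather than
  fatal.
* Transferability of a model trained at one chain length degrades with the
  conformational diversity gap between training and evaluation; the study's
  gauche-defect and partial-fold centers exist precisely to close it.
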