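# Methods

## The model

A solute in water at infinite dilution is assigned the free-energy function

    G = E_C − T·S_C + μ_H,      μ_H = ε_VH − T·S_VH,

with conformational energy `E_C = E_B + E_LJ + E_ES` (bonded,
Lennard-Jones, electrostatic), conformational entropy `S_C`, and the
hydration free energy split into its energetic (`ε_VH`) and entropic
(`S_VH`) parts under *isochoric* insertion.  Association of a rigid
receptor R and a peptide P that folds upon binding is decomposed along
three paths:

* **path I** — the bound partners are separated rigidly: ΔE_B = 0 and
  ΔS_C = 0 by construction;
* **path III** — the isolated peptide passes from a random-coil ensemble
  to its bound compact structure;
* **path II** — the physical binding; every component obeys
  Δ<sup>II</sup> = Δ<sup>I</sup> + Δ<sup>III</sup> exactly.

All entropic quantities are carried as `T·S` in kcal/mol at the stated
temperature (conversion to k_B units uses k_B·T = R·T = 0.5925 kcal/mol at
298 K), so ledger tables read directly in energy units.

## Hydration entropy by the morphometric approach

`S_VH` is insensitive to the solute–water attractions, so the solute is
reduced to fused neutral hard spheres with atomic diameters equal to the
force-field LJ σ.  The water-accessible body (the region forbidden to
water *centers*; each atom contributes a ball of radius (σᵢ + d_S)/2,
d_S = 2.8 Å) enters through its four Minkowski measures:

    S_VH / k_B = C1·V_ex + C2·A + C3·X + C4·Y.

`X` uses the ∫H dA convention with H = (κ₁+κ₂)/2 — forced by the
requirement that a sphere of accessible radius R contribute C3·(4πR).
The coefficients are solvent properties, obtained by ordinary least
squares on hard-sphere solute entropies over a diameter grid
(default: 40 diameters, 0.1–10 water diameters; the design matrix is the
sphere specialisation of the four measures).  The fit is unweighted; rank
deficiency (fewer than four distinct diameters) is rejected.

### The bundled calibration source (SPT)

For a hard-sphere fluid the insertion work is purely entropic, so
`S_VH/k_B = −βW(R)` with `W` the cavity-creation work.  The bundled
generator implements classic scaled-particle theory: the exact
`−ln(1 − η(2R/d_S)³)` for `R ≤ d_S/2`, and beyond it a cubic in `R`
matched in value and slope at `R = d_S/2` and anchored by the SPT
(Percus–Yevick compressibility) pressure.  Consequences used by the tests:

* at `d_U = 0` the value is exactly `ln(1 − η)`;
* as `η → 0`, `C1 → −ρ_S` and the other coefficients vanish (ideal-dilute
  limit);
* an SPT table is *exactly* cubic in R, so the fit recovers it to
  round-off (residual RMS < 1e−10) and the coefficients are independent of
  the diameter grid.

The default packing fraction is `η = π·ρ_S·d_S³/6 = 0.3828` with
`ρ_S = 0.0333 Å⁻³` (water's density at 298 K on the saturation curve).
Against Monte-Carlo trial insertion into an equilibrated hard-sphere fluid,
the SPT work is accurate to ≈1–2% at liquid densities; the oracle test
asserts 2.5% agreement, since demanding agreement within MC sampling error
(~0.2%) is not meaningful for an approximate closed form.

**What SPT calibration does and does not stand for.**  The original
analysis calibrated C1–C4 against a multipolar water model; those
coefficients are not published, so results here are *hard-sphere-solvent*
entropies.  Identities, additivity, signs (C1 < 0, S_VH < 0, ΔS_VH > 0 on
overlap-forming association) and orders of magnitude carry over; absolute
gains do not.  One known casualty: for two large spheres in contact the
C1·ΔV_ex and C2·ΔA contributions nearly cancel under SPT coefficients
(e.g. +24.9 vs −27.1 k_B at d_L = 6d_S), because SPT's planar-wall surface
tension, βγd_S² = −(9/2π)η²(1+η)/(1−η)³ = −1.23 at η = 0.383, is ~15% too
negative compared with the simulated hard-sphere value.  The net gain then
grows sublinearly over d_L/d_S = 6–14 (measured log–log exponent ≈ 0.48
rather than the linear law expected with water-calibrated coefficients,
for which the volume term dominates).  The disc-stacking exponent is
likewise steepened (≈ 2.44 vs the ideal 2).  The shape experiments
therefore report exponents as *measured*; the suite asserts the
water-like bands and the corresponding test documents this calibration
sensitivity by failing under SPT.

## Geometry engine

The measures of a union of balls are computed as follows
(`resolution`, default 0.25 Å, controls everything):

* **V_ex** — divergence-theorem quadrature `V = (1/3)∮ x·n dA` over the
  exposed spherical patches; exact for isolated spheres, with the same
  deterministic Fibonacci-lattice sampling as the area (the number of
  points per sphere scales as `4πr²/h²`).  Far-separated clusters are
  detected by union-find and integrated with per-cluster origins so the
  quadrature error stays local.
* **A** — fraction of lattice points on each sphere outside every other
  ball, times `4πr²`.
* **X** — smooth-patch term ΣAᵢ/rᵢ plus concave-crease edge terms
  `−(1/2)·θᵢⱼ·Lᵢⱼ` along exposed intersection-circle arcs, where θᵢⱼ is
  the angle between the outward normals of the meeting patches (constant
  along the circle: cos θ = (rᵢ²+rⱼ²−d²)/(2rᵢrⱼ)).  The sign and weight of
  the edge term were fixed against the valuation identity
  X(A∪B) = X(A)+X(B)−X(A∩B) with the convex-lens closed form, at both
  shallow and deep overlap.
* **Y** — exactly `2π·χ(∂body) = 4π·χ(body)`; the Euler characteristic is
  computed from the cubical complex of the voxelized body
  (vertices − edges + faces − cells).  This resolves connected components,
  sealed cavities and handles without any surface integration, making Y a
  topological (resolution-independent) output once the voxel grid resolves
  the features.
* **Sealed cavities** — free-space voxel components not connected to the
  boundary of the grid are cavities water centers cannot reach; they are
  counted inside V_ex, their walls are excluded from A and X, and the body
  is topologically filled (a hollow shell has Y = 4π).  Tested with a
  bead-shell fixture whose measured V_ex exceeds the smooth-wall upper
  bound.

Accuracy at the default resolution: single- and two-sphere bodies agree
with closed forms to ≤0.05% (contract: 0.5%); halving the resolution moves
V_ex of the reference sphere by ≪0.2%.  Degenerate inputs (empty body,
non-finite coordinates, non-positive diameters or resolution) raise
immediately; a nested ball contributes nothing to the surface terms.

## Energetics

Isolated-solute molecular mechanics with no cutoff, periodicity or lattice
summation.  Lorentz–Berthelot combining; Coulomb constant
332.0637 kcal·Å/(mol·e²) evaluated from CODATA constants.  Intramolecular
sums honour an exclusion/scaling map (Amber convention by default: 1-2 and
1-3 excluded, 1-4 scaled by 1/1.2 (ES) and 1/2 (LJ), both configurable).
Bonded terms (harmonic bonds/angles, cosine torsions) are evaluated when
parameters are supplied and reported absent otherwise — path I never needs
them.  The identity
`E(complex) − E(A) − E(B) = E_inter(A,B)` for rigid partitions holds to
round-off and is property-tested; it is the operational meaning of the
path-I interaction components.

## Random-coil ensembles

The unstructured peptide state is an ensemble of conformers with backbone
dihedrals drawn uniformly over the allowed Ramachandran regions
(generic: Φ ∈ [−180°,−30°], Ψ ∈ [−180°,−150°] ∪ [−90°,180°]; glycine:
Φ ∈ [−180°,−30°] ∪ [30°,180°], Ψ free; proline pinned at (−65°,180°)).
Union sampling weights each interval by its length; the draw is
deterministic per seed.  Coordinates are rebuilt from ideal internal
coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°) by
natural-extension placement; a Cβ pseudo side chain rides along for all
residues but glycine.  Rebuilt geometry reproduces the sampled dihedrals
and ideal bonds to round-off.

The clash filter rejects a conformer when any heavy-atom pair more than
three bonds apart comes closer than `0.6·(σᵢ+σⱼ)/2` (an energy-threshold
variant is provided, since "divergently high LJ energy" is a qualitative
criterion); the report names the violating pair.  For the bundled
12-residue sequence, seeds 0–199 retain 170/200 conformers — the published
workflow retained 103/200 under an unstated threshold and an additional
minimization stage (not reimplemented; a hook accepts externally
minimized coordinates), so the retention count here is a regression
fixture, not a reproduction target.  The unbound reference state is the
arithmetic mean of the per-conformer components; optional components are
averaged only when present on every member.

## Bundled reference ledger

The published R12:P16 decomposition (five NMR models; paths I, II, III
with the path-I component split) ships as data, together with the
reported ΔV_PH/d_S³ values (5.51, 5.47, −0.04 for paths I, II, III), the
mean excluded-volume changes (−33.33 and −12.49 d_S³ for paths I and III),
the conformational-entropy estimate (+8.83 kcal/mol from the residue-wise
free-motion-radius extrapolation to 298 K) and the experimental binding
free energy (−6.45 kcal/mol).  Since only deltas are published,
`species_fixture` synthesises fixed per-species absolute components whose
differences reproduce every printed cell; printed rounding makes some
identities hold only to ±0.01 kcal/mol (e.g. the path-I ES components of
model 1 sum to 9.40 against a printed 9.41), and the additivity check for
model 4 carries the same ±0.01 tie.

The dissociation-constant conversion follows the *reported-value* sign
convention, `ΔG = RT·ln k_D` (negative for sub-molar k_D); the commonly
quoted formula `−RT·ln k_D` yields the opposite sign and is deliberately
not used.

## Isochoric → isobaric conversion

With pure-water properties α (2.57×10⁻⁴ K⁻¹) and κ_T (4.52×10⁻¹⁰ Pa⁻¹) at
298 K, α* = αT and κ_T* = κ_T·k_B·T/d_S³ give

    ΔH = Δε_VH + k_B T (α*/κ_T*)·ΔV_PH/d_S³,
    ΔS_PH/k_B = ΔS_VH/k_B + (α*/κ_T*)·ΔV_PH/d_S³,

and Δμ_H = Δε_VH − TΔS_VH = ΔH − TΔS_PH is invariant by construction
(property-tested to 1e−9).  For the binding path (ΔV_PH/d_S³ = 5.51) the
correction is 2.95 kcal/mol with these textbook water properties — within
1% of the reported 2.92, whose exact α/κ_T inputs are unstated.

## Synthetic fixtures

Shape generators are deterministic per seed: single spheres; sphere pairs
at controlled surface separation; hexagonally packed single-layer discs
spanning a given diameter (atom count cross-checked against an independent
axial-coordinate lattice census); self-avoiding bead chains; Fibonacci
bead shells that seal a cavity.  The shape experiments evaluate the
entropy gain on contact (sphere pairs) or stacking (discs, layer
separation one bead diameter) and regress log-gain on log-size.

## Problem sizes and numerical choices

Defaults were chosen so each stage completes in seconds on one CPU:
geometry resolution 0.25 Å (oracle errors ≤0.05%), 40-point calibration
grid, 200-conformer ensembles, 5 sizes per shape experiment, MC oracle
with 216 solvent spheres and 8×10⁵ insertions.  Burial tests use a 1e−9
tolerance so tangency does not bury surface points; voxel grids refuse to
exceed 4×10⁸ cells rather than exhaust memory; bodies are split into
proximity clusters before voxelization so separated fragments never
inflate the grid.

## Known limitations

* Coefficients are hard-sphere-solvent unless supplied; absolute S_VH
  values (and the shape-scaling exponents, see above) are
  calibration-dependent.
* The accessible surface is the center-accessible one throughout; no
  Connolly/reentrant surfaces.
* No force-field parameter assignment from residue templates, no energy
  minimization, no NMR-restrained refinement: structures and parameter
  tables are taken as given.
* The conformer builder uses ideal backbone geometry and a Cβ-only side
  chain; it emulates the dihedral statistics and clash structure of a
  random-coil ensemble, not the detailed energetics of refined all-atom
  coils — tests passing on it say nothing about force-field accuracy on
  real peptides.
* Y is exact only once the voxel grid resolves the body's topology;
  marginal features (tunnels comparable to the grid spacing) can flip its
  topological count between resolutions.
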