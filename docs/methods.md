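# Methods

`patchylat` models the physics of a C4-symmetric, disulfide-linked
patchy protein assembling into 2D crystals, at the level of analytic
and semi-analytic calculations: rigid-tip AFM image simulation,
screened dipolar pair energetics, rotating-squares lattice geometry,
dipole-sheet electrostatics, and a random-adsorption null model.  This
note records the models, their assumptions, the defaults, and what the
package deliberately does not compute.

## Coordinate and unit conventions

Atomic structures use Å and elementary charges; colloid- and
lattice-scale quantities use nm and debye.  The support (mica) plane is
z = 0 and the sample occupies z ≥ 0.  Energies are computed per pair in
joule and converted only at reporting boundaries (1 e·Å = 4.8032 D,
1 kBT at 300 K = 0.59616 kcal/mol).  Constants are CODATA 2018 via
`scipy.constants`; 1 D = 3.33564e-30 C·m.

## Simulated AFM topographs

The probe is a rigid sphere of radius R (default 10.0 Å) capped by a
truncated cone of half-angle β = 20°.  The cone flank rises from the
circle where it crosses the apex sphere — radius `R·cos β` at height
`R·sin β` above the sphere center — so the tip cross-section at and
below the apex-center height is the sphere alone (an atom exactly one
radius to the side of the apex center registers no overlap).  The cone
truncation height `z_cutoff` defaults to
60 Å — taller than any single-layer scene, so the choice is inert
there; it matters only for scenes with features taller than the cone.

For each raster node (default step 0.5 Å) the recorded height is the
lowest apex height at which at most `overlap_threshold` heavy atoms lie
strictly inside the tip volume, minus R, floored at zero.  The
implementation solves the first-contact height per atom in closed form
(sphere contact `z_a + √(R²−ρ²)`; cone-flank contact
`z_a − R·sin β − max(0, ρ − R·cos β)/tan β`) and takes the
(k+1)-th largest per node, which is exactly the grayscale dilation of
the point set by the reflected tip with the k most obstructive atoms
ignored.  This closed-form descent is deterministic and introduces no
vertical step-size parameter.  Two conventions are fixed here: the tip
approaches from above (so with a truncated cone, where the overlap
count is not monotone in apex height, the settling height is the
descending first-contact), and tangency does not count as overlap,
making the infimum attainable.  Atoms are points by default; per-atom
radii, when set, inflate the effective tip radius for that atom (the
exact Minkowski offset of the sphere-cone solid).

A brute-force oracle recomputes every image by bisecting the boolean
inside-the-tip predicate per (node, atom) pair, sharing no contact
algebra with the scanner; the two agree to better than 1e-9 Å on
randomized scenes, and a third route through `scipy.ndimage`
grayscale dilation agrees for atoms snapped to grid nodes.

The overlap threshold "ignores the k most obstructive atoms" to mimic
compliant disordered loops; its value is a free parameter (default 0).

## Screened dipolar pair potential

Two like-charged particles with permanent dipoles interact through a
screened three-term potential (charge–charge, charge–dipole,
dipole–dipole), each damped by `exp(−κr)` with finite-size factors

    C0 = e^{κa}/(1+κa),
    C1 = 3e^{κa}/(2 + 2κa + (κa)² + (1+κa)/ε).

The inverse Debye length is derived for a symmetric 1:1 electrolyte,
`κ² = 2e²N_A(1000·I)/(ε₀ε k_B T)`; at I = 20 mM, ε = 78, T = 300 K
this yields κ⁻¹ = 2.1508 nm.  The temperature for this derivation is
taken as 300 K, consistent with the rest of the parameter set.

Lateral bonding within a 2D crystal constrains both dipoles normal to
the lattice plane (θ = 90°), which cancels the charge–dipole term and
the longitudinal dipole–dipole part, leaving

    U(r, Δφ) = k_e q² e^{−κr} C0²/r
             + k_e μ² cos(Δφ)(1+κr) e^{−κr} C1²/r³.

With the reference parameter set (q = −16 e, μ = 1200 D, a = 4.0 nm,
ε = 78, κ⁻¹ = 2.1508 nm) the parallel-minus-antiparallel gap
`2 k_e μ² (1+κr) e^{−κr} C1²/r³` evaluates to 1.11 kcal/mol at
r = 7 nm and 0.13 kcal/mol at r = 10 nm; the gap is independent of the
net charge.  The dihedral landscape is a smooth funnel whose minimum is
always at Δφ = 180° — the antiparallel (p42₁2) arrangement.

For unequal particles, the charge–dipole cross terms pair each charge's
C0 with the other particle's C1 (`q_i μ_j` term uses `C0(i)·C1(j)`),
which reduces to the standard identical-particle expression.

## Rotating-squares lattice

Squares of edge L hinged at their corners counter-rotate by an opening
angle θ ∈ [0°, 45°], giving spacing `d = L(cos θ + sin θ)`, cell area
`A = d²`, and area ratio `(cos θ + sin θ)² ∈ [1, 2]`.  The hinge angle
α is exposed as an affine alias (default α = 2θ): the literature's
numeric α convention is not uniquely determined, so the geometry is
parameterized by θ and the alias kept configurable.  The fully open
L = 7.0711 nm lattice has d = 10.0 nm, matching the open-state
per-protein cell of the electret calculations; the most compressed
simulated conformation has a cell edge of 7.5595 nm.

Site generation places an nx×ny grid with alternating ±θ in-plane
rotations; p4 assigns all sites the same out-of-plane dipole sign and
p42₁2 a checkerboard, so every nearest-neighbour pair in p42₁2 is
antiparallel and every diagonal pair parallel.

Two energy summaries are reported because they answer different
questions: `lattice_energy_per_monomer` divides the total pairwise
energy by the site count (each pair shared half-and-half), while
`site_interaction_energy` is one monomer's full interaction with the
patch — the attachment energy relevant to growth.  For an interior
monomer with only nearest neighbours in range, the p4 − p42₁2
attachment difference is exactly 4× the single-pair gap
(≈ 4.45 kcal/mol at d = 7 nm, decaying to ≈ 0.50 kcal/mol at 10 nm).
Charge–charge repulsion is included in absolute sums and cancels in
symmetry differences.  `symmetry_preference_curve` reports the full
ΔE(d) curve over the conformationally accessible range rather than any
single amplification value, because the nearest-neighbour distance at
which an amplified figure applies is conformation-dependent.

## Electret and piezoelectric estimates

A p4 lattice is a 2D electret: one dipole μ per cell of area A, all
parallel.  Treated as a uniform dipole sheet in a medium of relative
permittivity ε (water, ε = 78, used uniformly as a conservative
choice), the potential step is

    ΔV = −s·(μ/A)/(ε₀ε),

independent of slab thickness; s = +1 for the N-terminus-up lattice
(dipole pointing from the negative C-terminal face to the positive
N-terminal face, i.e. along +z), which yields a negative voltage.  At
μ = 1200 D and A = (10 nm)² this gives −57.96 mV; at the most
compressed cell, (7.5595 nm)², the magnitude is 101.4 mV.  A
checkerboard lattice has equal up and down sheet densities and zero
net voltage.

The volumetric polarization density ρ_μ = μ/(A·t) does depend on the
slab thickness t, defaulting to 4.5 nm (the approximate monomer height,
half the 9.5-nm tail-to-tail dimer); with that convention ρ_μ spans
0.0089–0.0156 C/m² from the open to the most compressed conformation.
t is a configuration parameter, and ρ_μ and ΔV are reported separately
and never conflated.  The bound charge separated across a patch is
Q = ρ_μ × area (≈ 40 e for 0.016 C/m² over the (20 nm)² open-state
2×2 patch).  The voltage–conformation sweep (`piezo_curve`) composes
these pieces: |ΔV| scales as 1/A(θ) and decreases strictly as the
lattice opens — the piezoelectric coupling.

## Random-adsorption null model

Second-layer monomers occupy discrete lattice sites.  The null model
occupies each site independently with probability θ; the expected
fraction of isolated occupied sites (no occupied nearest neighbour) on
the interior is θ(1−θ)^z with z = 4 for the default von Neumann
neighbourhood (the second layer bonds laterally to at most 4
neighbours; Moore with z = 8 is selectable).  At θ = 0.23 the closed
form gives 0.0808.  Sequential-exclusion effects are deliberately
absent: monomers occupy single sites and adsorb without bias, which is
the hypothesis being rejected when observed isolated coverages fall
tens of fold below the null.  Boundaries are edge-aware by default;
the toroidal option exists for exact comparison with the closed form.

## Synthetic test particle

The built-in fixture is a C4-symmetric point-atom particle with a flat
square top plate (default 60 Å wide at 45 Å height) and four corner
legs leaving a central dip — the coarse topography and charge
anisotropy of the real tetramer (flat negatively charged top,
four-legged positively charged bottom).  Charges sit on the top plate
and on the leg feet, so its macrodipole is exactly
`top_charge × height` (1729 D with the ±8 e / 45 Å defaults, the same
order as the protein's ≈1200 D).  It reproduces the geometric and
electrostatic features the algorithms exercise — C4 symmetry, central
dip, tip-convolution-scale dimensions, a vertical macrodipole — but
none of the atomic detail, flexibility, or force-field charge
distribution of a real protein, so passing tests demonstrate
correctness of the algorithms, not fidelity to any particular protein.

Protein macrodipoles from real PDB files use an integer formal-charge
scheme at pH 7 (Asp/Glu −1, Lys/Arg +1, His 0, chain termini ±1) on
side-chain charge centers, excluding hydrogens.  This approximates a
force-field charge set only at the level of overall charge anisotropy;
magnitudes within a few tens of percent of equilibrated-structure
values are the realistic expectation.

## Problem sizes

Randomized verification uses 100 scenes of up to 50 point atoms in a
30×30 Å window at 0.5 Å raster for the scanner/oracle comparison, 1000
random parameter draws for the potential-reduction identity, and 100
replicates of 200×200 occupancy fields for the adsorption statistics —
sizes at which the closed-form oracles are exact and the Monte Carlo
standard errors are well below the tested tolerances.

## Known limitations

* All-atom molecular dynamics is out of scope.  Simulation-derived
  quantities — the steady-state membrane potentials (−56.09 ± 5.71 mV
  for p4, −3.09 ± 5.85 mV for p42₁2, which bracket the analytic
  −57.96 mV and 0 mV within one standard deviation), the dimerization
  free-energy profile, and the 8–9 Å adsorption height above the mica
  slipping plane — are documentation-level consistency context here,
  not computed outputs.
* A single amplified symmetry-preference value (e.g. 4.2 kcal/mol)
  corresponds to one unspecified nearest-neighbour distance slightly
  above contact; the package reports the full ΔE(d) curve (4.45 down
  to 0.50 kcal/mol over 7–10 nm) instead of asserting one point.
* The dipole-sheet electret model ignores ion dynamics, image charges,
  and dielectric contrast between protein and solvent; the lattice
  sums use point dipoles with no multipoles beyond the screened
  dipole–dipole term.
* The rotating-squares model treats monomers as rigid squares; real
  hinge (disulfide) mechanics and conformational dynamics are not
  modelled.
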