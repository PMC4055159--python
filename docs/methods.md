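# Methods

This note documents the models implemented in `gridock`, their
assumptions and defaults, the numerical choices made where the underlying
methods leave them open, and what the synthetic test systems do and do
not establish.

## Energy model

Nonbonded interactions use MMFF94-style functional forms:

- **Electrostatics** — buffered Coulomb,
  E = 332.0716·qᵢqⱼ / (ε_in·(r + 0.05 Å)), charges in e, r in Å,
  energies in kcal/mol.
- **van der Waals** — buffered-14-7,
  E = ε·(1.07R*/(r+0.07R*))⁷·(1.12R*⁷/(r⁷+0.12R*⁷) − 2).
  The value at r = R* is exactly −ε; the true minimum of this form sits
  at ≈ 0.9962·R* with depth ≈ 1.0006·ε, so the slope at R* is small but
  not zero.  Combination rules: geometric-mean ε, arithmetic-mean R*.
  Per-element parameters ship in a small built-in table
  (`DefaultParameterProvider`); a full published atom-typing scheme can
  be plugged in through the `ParameterProvider` contract.  The provider
  question left open — which charge scheme the original preparation tool
  used — is deliberately unresolved: charges are taken from the input or
  from RDKit Gasteiger assignment.
- **Polar desolvation** — Still pairwise generalized Born with fixed
  per-type Born radii,
  ΔG = −166·(1/ε_in − 1/ε_out)·Σᵢⱼ qᵢqⱼ/f_GB, f_GB = √(r² + aᵢaⱼ·e^(−r²/4aᵢaⱼ)),
  self terms included, so one charge recovers the Born equation.  The GB
  family is the only continuum model implemented; SGB/COSMO/PCM variants
  used elsewhere in the literature are acknowledged, not emulated.
  Complex desolvation is ΔG_pol(complex) − ΔG_pol(protein) − ΔG_pol(ligand).
- **Nonpolar desolvation** — γ_np × buried solvent-accessible area
  (probe 1.4 Å), with buried area from exact two-sphere caps summed
  pairwise (no multi-body overlap correction).  Default
  γ_np = 0.0072 kcal/(mol·Å²).
- **Intramolecular energy** — ligand bond lengths and angles are rigid
  throughout, so the internal energy keeps only (a) a generic 3-fold
  torsion term V₃/2·(1+cos 3φ), V₃ = 1.4 kcal/mol, per rotatable torsion
  (the published force field's torsion parameter tables are not
  reproduced; the methods here do not depend on them), and (b) nonbonded
  interactions between atoms more than three bonds apart.

Defaults: ε_in = 1, ε_out = 80, T = 298.15 K; all exposed in
`SolventModel` and the relevant function signatures.

## Grids and broadening

Receptor potentials are tabulated on a uniform lattice over the docking
cube (node count per axis = ⌊edge/spacing⌋ + 1; default edge 22 Å,
spacing 0.35 Å, configurable).  The broadening operator — the literature
describes the idea but not a formula — is the simplest choice with the
right monotonicity: each node takes the **minimum** of the direct
potential over the 7-point stencil {x, x ± b·ê}, so clash energies are
non-increasing in b and b = 0 degenerates to the plain potential.  It is
isolated in `build_grid` and swappable.

Node values are clamped symmetrically to ±1000 kcal/mol.  The upper
clamp bounds the repulsive wall; the lower clamp is needed because a
lattice node can coincide with a charged receptor atom, where the bare
−1/r Coulomb potential would otherwise plant a spurious −10³-scale well
that corrupts both the search landscape and any node-scan reference.

The desolvation lattice stores a per-unit-charge² penalty: the loss of
Born self-energy of a probe whose effective radius grows by pairwise
descreening, 1/a_eff = 1/a₀ − Σⱼ ρⱼ/(2rⱼ²) (clamped to [0.1/a₀, 1/a₀],
probe a₀ = 1.6 Å).  Whether the original desolvation grid was linear or
quadratic in probe charge is not documented; the quadratic self-term
form is implemented and flagged here.  The gridless `direct_energy`
evaluates exactly the same per-atom potentials, which is what makes the
grid/exact-sum equivalence at nodes a well-defined test (it holds to
1e-9 at zero broadening).

Trilinear interpolation is exact on nodes and on linear fields; points
outside the cube return a +1000 kcal/mol sentinel per atom term, so the
GA can recover poses that drift out rather than having them rejected.
Because trilinear interpolation is multilinear, the continuous minimum
of an interpolated field over the cube is attained at a lattice node —
the property behind the exhaustive node-scan reference used to validate
the GA.

## Genetic-algorithm search

A pose genome is translation (3), unit quaternion (4), and one delta
angle per rotatable torsion, applied to the reference conformer
(torsions, then rotation about the centroid, then translation; internal
geometry preserved exactly).  The GA uses tournament selection (k = 3),
uniform crossover, Gaussian mutation with a two-scale step (full-width
exploration kicks and 0.05× refinement kicks, equal probability), and
elitism; `n_runs` independent runs are pooled, deduplicated at 1 Å
all-atom RMSD (lower score kept), and sorted with deterministic
tie-breaks.  There is deliberately **no** local optimization inside the
search.  The original GA hyperparameters are unpublished; defaults here
(population 300, generations 100, 10 runs) are desk-scale choices, and
the tests/acceptance script use smaller explicit settings (population
60, generations 60–80, 3–4 runs) sized to the toy systems, where they
reproduce the exhaustive-scan optimum in 10/10 seeds.  The contract is
"global minimum found vs an independent reference", not specific GA
internals.

## Seven-component rescoring

Components at the relaxed pose: direct Coulomb and vdW pair sums, GB
polar and surface nonpolar desolvation, ligand strain ΔG_LS (bound
internal energy minus the free-ligand global minimum, clipped at ≥ 0),
the torsion-entropy column 0.33·N_TORS, and ΔG_rot-tr.  The rot-tr
reference gives no formula; here it is the rigid-body translational +
rotational free-energy change between the 1 M standard-state volume
(1660 Å³) and an effective bound volume (default 1 Å³, configurable) —
nearly constant across similar ligands, consistent with its role as a
small correction.

Pose relaxation is Cartesian L-BFGS over ligand atoms (receptor fixed;
an optional tethered shell of nearby receptor atoms can co-optimize).
Because the internal energy carries no bond/angle terms, unrestrained
Cartesian minimization would be unbounded; rigidity is realized as stiff
harmonic restraints to the reference bond lengths (300 kcal/mol/Å²) and
angles (60 kcal/mol/rad²), which vanish at the reference geometry and
leave torsions and rigid motions soft.  Convergence: gradient tolerance
0.05 kcal/(mol·Å) or 2000 iterations; the optimizer never returns a
higher energy than the start.

Coefficient fitting is ordinary least squares on the 7-column design
matrix — the closed-form optimum of the iterative mean-square
minimization it replaces — with rank checking that names the degenerate
column.  Noiseless synthetic data are recovered to ~1e-15; under
0.5 kcal/mol Gaussian noise the expected RMS coefficient error falls
roughly as 1/√n (verified at n = 50 vs 500).

## Multiwell free energies

Minima search: random torsion deformations (uniform, half-width π) plus
random rigid perturbations (Gaussian, 0.5 Å / 0.5 rad) of the start
pose, each followed by L-BFGS minimization; converged conformers enter a
pool of capacity 1024 under the dedup rule RMSD < 0.5 Å **and**
|ΔE₀| < 0.1 kcal/mol (worst member evicted at capacity).  In the
receptor frame the RMSD is raw — distinct wells of the site must stay
distinct; free-ligand pools set `dedup_align=True` to superpose before
comparing, merging minima that differ only by rigid drift.  The search
runs without solvent; a continuum term can be added at final scoring.

Per-well thermodynamics are classical: Z_v = Π kT/hν over normal modes
(a mode at hν = kT contributes zero; the quantum form with zero-point
energy is available behind a flag), particle-in-volume Z_t, classical
rigid-rotor Z_r (linear and point-mass limits handled).  Frequencies
come from a central-difference Hessian (step 1e-3 Å), mass-weighted,
with the six/five/three rigid modes projected out — projection matching
the Eq-style decomposition where rigid DOFs live in Z_t and Z_r; a
negative remaining eigenvalue raises "not a minimum".  The translational
and rotational normalizations are this package's choices (the source
they would come from is not reproduced in the literature this follows)
and are stated here rather than hidden.

The pool combines by a shifted log-sum-exp; G is monotone non-increasing
as wells are added, never exceeds the lowest Gⁱ, and a well 20 kT above
the minimum changes G by < 1e-8 kcal/mol.  Binding free energy is
G(complex) − G(free ligand) − G_protein with the protein reference a
cancelling constant (default 0).

## Synthetic systems and what the tests show

`make_toy_pocket` builds an apolar hemispherical shell (radius ~6 Å,
golden-spiral placement with 0.05 Å seeded jitter) with one charged
atom at the base — the geometry, not the chemistry, of a trypsin-like S1
pocket.  `make_toy_ligand` builds a heavy-atom chain (1.5 Å bonds, 112°
angles, n+3 atoms for n torsions) with a +1 head group.  Both are pure
functions of (parameters, seed).

These fixtures exercise every code path with known references:
closed-form pair energies, exhaustive lattice scans, dense torsion
scans, an independent differential-evolution optimizer for the planted
redocking pose, and brute-force enumeration for ranking statistics.
They do **not** demonstrate accuracy on real protein–ligand complexes:
real systems add polarization, protonation ambiguity, water structure,
receptor flexibility beyond broadening, and force-field torsion detail
that the generic 3-fold term ignores.  Vacuum minimization of the toy
complex produces bare ±1 ion-pair energies (~−130 kcal/mol) that no
solvated system would show; the docking grids include the desolvation
penalty and are not comparable to those vacuum values.

## Known limitations

- Receptor flexibility only through potential broadening (docking) or an
  optional tethered shell (rescoring); no backbone motion.
- One generic torsion barrier for all rotatable bonds; no 1-4 scaling
  conventions.
- Pairwise-cap SASA and pairwise-descreening Born radii are first-order
  approximations; both are isolated behind small functions.
- RMSD uses fixed atom correspondence (an automorphism-aware mode exists
  but is off by default), so symmetric ligands can be over-penalized.
- Quantum-chemistry rescoring is supported only as an imported external
  enthalpy column with a −40 kcal/mol activity threshold; no
  semiempirical calculation is performed.
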