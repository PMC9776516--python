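# Methods

This note records the models implemented in `ionatmos`, the
assumptions behind them, the tunable parameters that matter, and the
numerical and design choices made where more than one defensible
option existed.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

Lengths are Å, charges protonic units (e), energies kT, potentials
kT/e, concentrations mol/L with the conversion 1 Å³ = 10⁻²⁷ L, and
molalities mol/kg with M_water = 0.018015 kg/mol.  Physical constants
come from `scipy.constants` (CODATA): at 300 K the vacuum Bjerrum
length is 557.003 Å, so water at ε = 80 has lB = 6.9625 Å and 0.1 M
1:1 salt has a Debye length of 9.7414 Å.

## Concentration maps from trajectories

Each retained ion sample deposits an isotropic radial triangular
(cone) kernel K(d) ∝ max(0, 1 − d/h) on the grid nodes within the
support radius h.  Two interpretation choices are fixed here:

* **h is the compact support radius** of the kernel (default 2 Å on a
  1 Å mesh).  A compact-support reading keeps kernel locality exactly
  testable: no node farther than h from every sample is ever nonzero.
* **Per-sample on-grid renormalization.**  Each sample's node weights
  are rescaled so the sample contributes a total count of exactly one
  on the grid.  Count conservation then holds to rounding error — the
  whole-grid integral N_A ∫ c dr equals the mean number of retained
  ions per frame — including for samples near the grid edge, whose
  kernels would otherwise lose mass off-grid.  The alternative
  (analytic free-space normalization) differs only at edge nodes.

Nodes carry values and each node represents one voxel of volume
sx·sy·sz in every integral; grids are node-addressed as
position = origin + index · spacing.  Samples outside the grid are
dropped with a warning (or can raise); analyses are restricted to
nodes within a boundary-exclusion distance of the closest protein
atom (default 15 Å) because a rectangular, nonperiodic analysis grid
cannot represent the far field of a periodic simulation box.

Frames are superposed onto a user-supplied reference structure by
least-squares rigid fitting (Kabsch/SVD, reflections corrected to
proper rotations); the per-frame transform fitted on the protein is
applied to all mobile particles.  The choice of reference structure is
the user's; no central-structure selection is implemented.

## Distances and regions

All distances — node-to-protein, ion-to-protein, RDF abscissa — are
Euclidean distances to the **closest atom center**.  Center-based
distance is unambiguous; a surface convention would additionally
depend on the radius set.  Region masks are thresholds on the distance
map (d ≤ cutoff), intersected with the boundary-exclusion limit.

## Poisson–Boltzmann solver

The solver discretizes ∇·(ε∇φ) − κ̄² a(r) f(φ) = −4π lB₀ ρ_f with the
standard 7-point stencil on a regular grid, f(φ) = φ (linear) or
sinh φ (nonlinear, 1:1 salt hard-wired; general valences only in the
linear form).  Components:

* **Molecular surface, two-pass approximation.**  Nodes within
  (atom radius + probe, default probe 1.4 Å) of any atom are
  tentatively interior; tentative nodes within one probe radius of a
  definitely-exterior node are reclassified exterior.  This captures
  probe inflation to first order; its error relative to a full
  rolling-probe re-entrant surface is bounded by about one probe
  radius and it is entirely grid-local.
* **Dielectrics** (defaults 4 interior / 80 solvent) are assigned per
  node and harmonic-mean averaged onto cell faces.
* **Ion accessibility** a(r) is 0 within (atom radius + Stern,
  default 2.0 Å) of any atom, 1 elsewhere; κ̄² = 8π lB₀ I N_A carries
  the 1:1-salt screening on accessible nodes only.
* **Charges** spread to the 8 surrounding nodes with trilinear
  weights; the node-charge grid sums to the structure's total charge
  exactly.
* **Boundary conditions** are Dirichlet values from superposing
  per-charge Debye–Hückel monopoles (exact for one isolated charge);
  two-level focusing — a fine solve whose boundary is trilinearly
  interpolated from a coarse solution — reduces their influence.
* **Iteration.**  Linear: red–black SOR, ω default 1.6 (ω ≈ 1.9 is
  near-optimal for 65³–129³ grids and can be configured per run).
  Nonlinear: per-node Newton linearization of the sinh term inside a
  red–black Gauss–Seidel sweep.  The Newton-linearized update is
  stable under over-relaxation; the default relaxation is 1.5, and on
  detected divergence (sustained residual growth) the solver halves
  the factor and restarts, at most twice.  Convergence is declared at
  a relative residual (ℓ² of the discrete defect over ℓ² of the
  source) below 1e-6 by default; sinh arguments are clamped at |φ| =
  60 to avoid overflow during early iterations.

Inverting a potential to concentrations uses the full exponential
c± = c_bulk exp(∓φ) with hard zeros below the Stern surface.  For a
nonlinear potential this is self-consistent; for a linear potential it
reintroduces the exponential the linearization discarded — an
inconsistency the package keeps reproducible on purpose, since
comparing the two routes is a supported analysis.

## Ion statistics

* **Ion addition.**  N± = I N_A V ∓ Z/2 satisfies neutrality and bulk
  ionic strength simultaneously; integers are rounded half away from
  zero (the convention is fixed here; any nearest-integer rule is
  defensible).  V is the solvent volume; the pipeline approximates it
  as box volume minus Σ (4/3)πr³ over atoms, ignoring overlaps —
  adequate for non-overlapping bead structures, an underestimate of
  excluded volume for overlapping atomic radii.
* **Profiles.**  Total charge at cutoff d is Z + N₊(≤d) − N₋(≤d);
  the region ionic strength is (N₊ + N₋)/(2 N_A V_region).  The
  latter formula is a definitional choice: it is the unique reading
  for a 1:1 salt under which uniform bulk maps give exactly I.
* **Molality RDF.**  g_i(r) = [h_i(r)/(h_w(r) M_water)] / m_i^bulk
  with h the ensemble-averaged per-frame histograms in closest-atom
  distance (bin width default 0.2 Å) and m_i^bulk from whole-box
  counts.  Bins with water but no ions give g = 0; bins with no water
  give g = NaN (undefined — the quotient has no value there, and
  reporting 0 would fake depletion).  Atomistic (multi-site) water is
  supported by dividing the site histogram by the sites-per-molecule
  count, which equals averaging the per-site histograms.
* **Dispersion summaries** use linear-interpolation quantiles
  (`numpy.quantile` default); whiskers sit at the 0.0005/0.9995
  empirical quantiles so they enclose the central 0.999 fraction, and
  values outside them are reported as outliers.  Nodes are unweighted.
* **Bound-ion cutoffs.**  There is no sharp criterion for territorial
  binding; the named presets `first_peak` (3.5 Å) and `second_peak`
  (5.0 Å) bracket the window where ion–protein RDFs typically lose
  their near peaks, and profile functions accept arbitrary ladders.

## Synthetic systems

The generator exists so every stage can be validated against known
statistics; it emulates an equilibrated ionic atmosphere, not a
molecular-dynamics engine.

* **Structures**: single charged spheres (with the closed-form
  screened potential φ(r) = q lB e^{−κ(r−a)}/((1+κa) r) as oracle) and
  compact random bead clusters whose per-bead charges are either
  uniform or zero-mean "patches" shifted to an exact total — an
  irregular charge pattern standing in for a protein's positive and
  negative surface patches.
* **Mobile ions** are sampled by Metropolis Monte Carlo with
  single-particle displacement moves (default 4 Å) mixed with 10 %
  box-uniform reinsertions (both symmetric proposals, so detailed
  balance holds; reinsertion shortens correlation times).  The pair
  potential is screened Coulomb with the Debye–Hückel excluded-sphere
  contact factor, u(r) = lB z₁z₂ [e^{κa}/(1+κa)] e^{−κr}/r at contact
  radius a, plus hard-sphere rejection (ion radius default 1.5 Å).
  The contact factor matters: with it, the mean field implied by a
  single bead is exactly the linearized PB solution outside contact,
  so the sampler and the grid PB model describe the same physics in
  the weak-coupling limit.  The box has hard walls, matching the
  nonperiodic analysis grid by construction.  The first 30 % of sweeps
  are discarded as equilibration by default.  Total energy is tracked
  incrementally and verified against from-scratch recomputation.
* **Water** is an ideal uniform background redrawn each frame outside
  the bead cores.  It exists solely to exercise the molality
  denominator; it has no structure, no hydration shells and no
  excluded volume against ions.
* **Explicit ion–ion interactions** are available but off in the
  MD-versus-PB consistency analyses: the κ in the pair potential
  already represents the salt implicitly, so adding explicit Yukawa
  ion–ion forces double-counts screening and systematically weakens
  the counterion cloud relative to PB.  With them enabled the sampler
  is a stand-alone model, not a PB surrogate.

What passing tests on these systems do **not** show: agreement with
real protein trajectories.  The generator has fixed charges (no
protonation-state fluctuation, so the charge-fluctuation contribution
of constant-pH ensembles is absent by design), no solvent structure,
no conformational flexibility and no ion–ion correlation beyond the
optional Yukawa term.  These are fidelity gaps, not bugs.

## Study conditions used in the checks

The cross-route consistency check runs five independent sampler seeds
of a Z = +2 e, 8-bead protein (patch scale 0.5 e) in an 80 Å box at
I = 0.1 M, with a uniform solvent dielectric and the PB Stern
thickness set to the ion radius so both routes share one exclusion
surface, and compares ion excesses at a 10 Å cutoff against the NLPB
inversion within three standard errors of the seed scatter.  The
conditions were chosen to satisfy the weak-coupling premise under
which the two routes describe the same model (small per-bead charges;
a box large enough that fixing the ion counts by the neutrality
protocol perturbs the far field by well under a percent).  The RDF
bulk-limit check uses 234 frames of 50 + 50 non-interacting ions and
2000 water sites around an uncharged bead in a 60 Å box, averaging g
over the outer half of a 24 Å analysis range.  The solver oracle runs
on 65³ (1 Å) and 129³ (0.5 Å) grids; brute-force equivalence checks
run on ≤ 9³ grids and ≤ 10-frame fixtures, where nested loops are
exact.

## Known limitations

* The nonlinear solver assumes a 1:1 salt; valence mixtures are
  linear-only.
* No periodic PB, no size-modified or correlation-corrected PB, no
  multigrid; large grids rely on SOR and focusing.
* The two-pass surface is an approximation; pointwise agreement with
  any particular molecular-surface implementation is not a goal, and
  only oracle and symmetry properties are asserted.
* Rhombic dodecahedral boxes are not modeled; rectangular boxes plus
  boundary exclusion reproduce the analysis geometry, not the
  simulation geometry.
* KDE bandwidth and mesh are global; no adaptive or periodic kernels.
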