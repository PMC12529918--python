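# Methods

This note documents the models, algorithms and numerical choices behind
`framonc`, and what the desk-scale validation does and does not show.

## State representation and units

Molecules are rigid bodies: a shared template holds per-site parameters
(element, label, partial charge in e, Lennard-Jones σ in Å and ε in
kJ·mol⁻¹) and one or more body-frame geometries ("conformers", a discrete
presampled pool); an instance holds only a center-of-mass position, a
unit quaternion and a conformer index.  Boxes are orthorhombic and
periodic; all studied systems are isotropic liquids, so no triclinic
support is provided.  Molecules are wrapped by center of mass; sites may
protrude past a box face, which the minimum-image convention handles.

Units are fixed package-wide: Å, kJ·mol⁻¹, K, bar, g·mol⁻¹.  Constants:
R = 8.31446×10⁻³ kJ·mol⁻¹·K⁻¹, 1 bar·Å³ = 6.02214×10⁻⁵ kJ·mol⁻¹ (per
box), e²/(4πε₀) = 1389.35458 kJ·mol⁻¹·Å.

## Generator force field

The inner-loop potential is a truncated site–site pair sum over
intermolecular pairs under minimum image:

* Lennard-Jones 12-6 with Lorentz–Berthelot combining by default
  (geometric selectable), truncated at `r_cut`.  An optional mean-field
  tail correction (assuming g = 1 beyond the cutoff) is available for
  homogeneous liquid boxes and is never applied to the single-molecule
  vapor box; it is off by default so that truncated energies compare
  exactly against brute-force oracles.
* Electrostatics use the damped shifted-force (Wolf-type) form,
  `u(r) = k q_a q_b [erfc(αr)/r − erfc(αr_c)/r_c + F_c (r − r_c)]`,
  which vanishes with continuous first derivative at the cutoff.  Default
  damping α = 0.2 Å⁻¹.  This was chosen over Ewald because the generator
  tier only needs a deterministic, O(N), smoothly truncated potential; an
  Ewald backend could be added behind the same contract.

`r_cut = None` selects a *dynamic* cutoff of half the smallest box edge
at evaluation time.  This keeps NpT volume moves valid at any density
(the potential is still a deterministic function of the state, which is
all Metropolis requires) at the cost of a cutoff that breathes with the
box.  Desk-scale boxes (20–32 molecules) have half-edges near 4–5 Å, so
the generator potential is short-ranged and the toy liquids undercohere
relative to their real counterparts; this is a property of the fixture,
not of the sampling machinery.

Any intermolecular site pair closer than 0.1 Å marks a degenerate
configuration: the public energy function raises, and the sampler treats
the proposal as infinite-energy (rejected).

## Composite many-body-expansion energy

The outer-loop energy is
`E = E_medium(full) + Σ_d [E_int_high(d) − E_int_medium(d)]` over
proximate dimers.  Choices:

* **Contact metric** — minimum intermolecular site–site distance under
  minimum image (not center-of-mass distance), because dimers are
  classified by the atom types forming the closest contact.  Default
  dimer cutoff 4.0 Å.
* **Fragment geometries** — dimers are reassembled across periodic
  boundaries by shifting the second molecule's center of mass to its
  minimum-image position, so every exported fragment is contiguous in
  free space, as an external engine requires.
* **Monomer references** — in-box rigid geometries.  With rigid
  molecules the monomer energy is a pure function of (template,
  conformer) and is cached per backend.
* **Three-body terms** — a `r_cut_trimer` hook is reserved on the model
  but the pipeline is pairs-only; setting it raises rather than silently
  ignoring it.
* The cutoff-restricted dimer set *is* the short-range focus of the
  composite model; no additional reweighting of the first solvation
  shell is applied.

Backends satisfy one contract (`full_system`, `monomer`, `dimer`
capabilities; fragment evaluations pure in geometry; dimer energies
symmetric).  The external-engine adapter writes plain XYZ, runs a shell
command, parses one energy by regex, and caches results by a geometry
hash (coordinates rounded to 10⁻⁶ Å in canonical atom order — tight
enough to avoid false merges, loose enough to absorb formatting noise).
Exit status, parse failures and timeouts raise distinct errors naming the
fragment.

## Nested sampling

Inner moves: rigid translations (uniform in a cube), rotations (random
axis, uniform angle), conformer swaps, and — in NpT — proposals uniform
in ln V with molecule centers scaled affinely.  Acceptance
`min{1, exp(−[ΔU + pΔV]/RT + (N+1)Δln V)}` for volume moves, plain
Metropolis otherwise.  The period *P* counts *attempted* inner moves
(default 100, configurable); volume moves participate in the inner loop
only, at the generating pressure.

The outer rule
`min{1, exp(−[ΔU_high + p ΔV]/(R T) + [ΔU_low + p_gen ΔV]/(R T_gen))}`
is the standard nested/multipotential acceptance derived from detailed
balance under the assumption that the inner sequence is a sequence of
Metropolis moves w.r.t. the generator potential at the generating
conditions.  It is exact for any P; P only controls decorrelation.  The
Jacobian factors of the ln-V proposals appear identically in the
generating and target ensembles and cancel.  On rejection the
pre-sequence configuration, including both energy caches, is restored
exactly.

Randomness is split into per-purpose substreams (inner moves, move
selection, outer acceptance) spawned from one master seed, so changing P
does not shift unrelated draws.  Runs are bit-reproducible per seed.
The incremental inner-loop energy is re-synchronized against a full
recomputation after every accepted outer proposal, bounding float drift
far below the 10⁻⁸ relative cache tolerance.

### Acceptance-window adaptation

High outer acceptance is the productive regime (the inner loop already
decorrelates), so a windowed controller tunes the generating temperature:
after every 50 outer proposals the observed acceptance a_obs is compared
with the target window (0.75, 0.90); if outside,
`T_gen ← T_gen (1 + 0.5 (a_obs − 0.825))`, clipped to [0.5, 2]·T_target;
if inside, nothing changes.  Two consecutive in-window observations
freeze the controller.  Lowering T_gen keeps inner sequences closer to
the current state and raises outer acceptance; raising it does the
opposite.  Adaptation violates strict stationarity while active, so all
samples collected before the freeze are treated as burn-in (the default
production burn-in is the pre-freeze segment plus 10 % of the remainder).
Only T_gen is adapted; the generating-pressure scale is exposed but left
at the target by default, since no principled schedule for it is
available and temperature alone controls the energy-distribution overlap
at these box sizes.

## Estimators

* **Density** ρ = Σ M_i /(N_A V), g·cm⁻³.
* **Vaporization enthalpy** ΔvapH = (⟨U_gas⟩ + RT) − (⟨U_liq⟩/N + p⟨V⟩/N).
  The vapor is a single molecule in a large box treated as an ideal gas;
  its pV term is therefore exactly RT and is not simulated.
* **Thermal expansivity and ΔvapCp** by central differences (one-sided at
  the ends) over independent runs on a temperature grid, with
  uncertainties propagated from the per-point errors.  Fluctuation
  estimators were rejected as too noisy at 20–100-molecule box sizes; the
  finite-difference route needs ≥ 3 temperatures for interior stencils
  and degrades gracefully to one-sided slopes on a 2-point grid.
* **Block uncertainties** by block doubling: SEM estimates at block sizes
  1, 2, 4, …; the reported value is the first estimate stable to 10 %
  over the next two doublings, else the largest-block estimate.  At least
  16 post-burn-in samples are required.
* **g(r)**: intermolecular site–site histogram under minimum image,
  normalized per frame by the ideal-gas shell expectation
  N_a (N_b/V) 4πr²Δr (self pair removed for identical labels); default
  bin width 0.05 Å; the cumulative coordination number is reported
  alongside.  Intramolecular contacts are excluded.

## Pair-interaction library

Every composite evaluation yields one record per proximate dimer: both
interaction energies, the contact distance, the contact class, and
provenance (snapshot, T, material, backend names).  The contact class
label joins, for each of the two closest-contact sites,
`<element>_<element of its nearest bonded neighbor>` (`·` if unbonded),
ordered heavier-primary-first so molecule order cannot change the label —
e.g. `O_H···H_O` for a hydrogen bond, `O_H···H_C` for a methyl contact.

Libraries are stored as multi-frame extended-XYZ (one frame per dimer,
metadata in the comment line).  Coordinates are printed with 12 decimals:
replaying a stored geometry through the steep short-range wall of the
high-level backend must reproduce the stored energy to 10⁻⁶ kJ·mol⁻¹,
which needs coordinate round-trip error well below 10⁻⁸ Å.  Rewriting a
read library is byte-identical (canonical ordering and formatting).
Near-duplicate geometries are *not* deduplicated: thermal ensembles
legitimately contain them.

## Toy systems

Four presets make the pipeline testable without external data: a
single-site LJ fluid (argon-like), a rigid 3-site water-like model
(TIP3P-magnitude charges and LJ on oxygen), a 3-site methanol-like model
(hydroxyl O–H plus a united-atom methyl site) and a 3-site bent
ether-like model with small charges.  They reproduce the *phenomenology*
needed by the pipeline — hydrogen-bonded vs dispersion-bound vs repulsive
contact classes, liquid-like structure, NpT response — but not the
absolute observables of the real materials: the united-atom sites carry
bare atomic masses, and the short dynamic cutoff weakens cohesion (the
water-like liquid equilibrates near 0.63 g·cm⁻³ at 300 K / 1 bar).
Passing tests therefore demonstrate correctness of the sampling and
estimator machinery, not force-field accuracy.  Default sizes: ~30
molecules for tests; a production-like water box of 100 molecules (300
sites) is exercised in the packing tests.

## Validation problem sizes

The validation suite was sized for a single CPU: the nested-vs-direct
exactness check uses a 33-point discretized double well (quartic barrier
≈ 2 RT, harmonic generator at 450 K vs a 300 K target) with 10⁵ outer
proposals, thinned by 100 and tail-merged so every expected χ² bin count
is ≥ 5; the ideal-gas equation-of-state check uses 1 and 10 molecules
with 4×10⁴ ln-V moves; the nested-vs-single-potential density identity
uses the 30-molecule water-like box with 400 outer proposals of period
10 against an equal-length plain Metropolis chain (agreement within 3×
the combined block errors); the adaptation check starts a 24-molecule box
from a deliberately mismatched T_gen = 600 K and requires the controller
to freeze within 20 windows and the following 500 proposals to sit in the
0.75–0.90 window up to 2σ binomial noise.

## Known limitations

* No molecular dynamics, replica exchange, grand-canonical moves or
  phase-coexistence ensembles.
* Pairs-only composite energy; the trimer hook is declarative.
* Rigid molecules with a discrete conformer pool; no continuous
  intramolecular flexibility, no presampling procedure for building the
  pool.
* No nuclear quantum effects.
* The adaptation controller is a pragmatic design choice; other
  schedules (e.g. stochastic approximation with decaying gain) would
  also work behind the same interface.
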