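# Methods

## The model

`glycoflow` studies how imposed solvent flow reorients a tethered,
branched N-glycan, using a coarse-grained analog of an all-atom
nonequilibrium MD setup.  The solute is a Man6GlcNAc2 octasaccharide
(two core GlcNAc, six mannoses in two branches) attached to an
asparagine aglycon.  The aglycon's five heavy atoms (C, CA, CB, CG and
the amide N) are harmonically restrained to their initial coordinates
(force −k(x − x_ref), k = 10 kcal·mol⁻¹·Å⁻²), standing in for the
transmembrane protein anchor.  The solute sits in a periodic
orthorhombic box of single-bead solvent plus Na⁺/Cl⁻-like ion beads.
Flow is imposed as a constant body force along +x on every solvent
bead at every timestep; the diffusion (no-flow) condition is the same
system with the force zeroed.

### Coarse solute

Each sugar is represented by the pseudo-atoms that the analyses
actually consume: the six ring atoms (C1–C5, O5), the exocyclic C6,
the glycosidic oxygen O1 (absent on residue 2, which bonds to the
aglycon N directly), and pseudo-protons H1–H5, H61, H62.  This covers
every torsion quadruple (φ, ψ, ω per linkage; aglycon φ, ψ, χ2) and
every inter-proton pair of the NOE table.  Pseudo-protons carry a
repartitioned mass of 3 amu so the 2 fs timestep is stable without
bond constraints; other masses are elemental.

The idealized template (regular hexagonal rings, 120° glycosidic
bridges, branches splayed outward and upward) defines the bonded
equilibrium: bond lengths r₀ and angle values θ₀ are measured from the
template, so the force field's bonded minimum is the template itself.
The template stands about 33 Å tall above the anchor — the same scale
as the real molecule's maximum extension.

### Potentials and integration

Units are Å, ps, amu, kcal/mol (1 kcal/mol = 418.4 amu·Å²·ps⁻²;
velocities reported externally in m/s via 1 Å/ps = 100 m/s).

* bonds V = ½k(r−r₀)², k = 200 kcal·mol⁻¹·Å⁻²;
  angles V = ½k(θ−θ₀)², k = 100 kcal·mol⁻¹·rad⁻².
* torsions: one 3-fold cosine term V = k(1 + cos 3φ),
  k = 1.5 kcal/mol, on every linkage torsion quadruple.  Minima at
  −60/+60/180° give the rotamer analysis genuine states to find; the
  3 kcal/mol barrier (≈5 k_BT at 300 K) makes transitions rare but
  observable on the tens-of-picoseconds scale.
* nonbonded: purely repulsive soft spheres V = ε(σᵢⱼ/r)¹², ε = 0.15
  kcal/mol, σ = 3.0 Å (solvent/ions) and 2.0 Å (solute pseudo-atoms),
  arithmetic mixing, truncated and shifted at the cutoff, minimum
  image in the orthorhombic box.  1-2 and 1-3 pairs are excluded;
  1-4 pairs interact unscaled.
* integration: velocity Verlet.  Forces are exact analytic gradients
  (checked against finite differences in the tests); with thermostat
  and body force off, total energy drifts by well under 0.5 kcal/mol
  over 10⁴ steps.

### Thermostat

Temperature is held at T₀ = 300 K by Berendsen weak coupling with
τ = 0.2 ps: after each step all velocities are multiplied by
λ = √(1 + (Δt/τ)(T₀/T − 1)).  The essential property for flow work is
that the rescale is uniform and positive — it never randomizes or
reverses a velocity, so directionally biased (flow) regions survive,
which a stochastic thermostat would wash out.  The instantaneous
temperature uses N_dof = 3N − n_constraints with n_constraints a
config knob (0 by default; the coarse model has no rigid constraints).
Written as a rate, the coupling constant is a time; the package
treats τ in ps throughout.

Uniform rescaling deliberately leaves collective drift almost
untouched, and the periodic fluid has no wall to absorb momentum: the
only channel that relaxes a net solvent drift is momentum exchange
with the tethered solute (whose restraints do exchange momentum with
their fixed anchor).  Two consequences are handled explicitly:

* initialization zeroes the net momentum of each species separately
  (otherwise a random ~0.1 Å/ps solvent drift would persist for the
  whole run and masquerade as flow);
* the zero-force null check uses independent replicate runs for its
  standard error, because within one run the drift mode decorrelates
  too slowly for frame blocks to be honest.

### System construction

Ion pairs follow the water-molarity convention
round(n_solvent × M / 55.5) — 6133 solvent at 0.15 M gives 17 pairs.
Beads are placed on a jittered lattice whose spacing guarantees the
overlap threshold (0.8σ), filtered against the solute; an impossible
request raises a packing error instead of overlapping silently.
Velocities are Maxwell–Boltzmann at T₀ from a counter-based
(Philox) generator keyed by the run seed, so runs are bitwise
reproducible.  Solvent and ion coordinates are saved wrapped into the
box; solute coordinates are saved unwrapped so extension, torsion and
orientation analyses never cross a boundary.

## Reference vs desk scale

The default `SimulationConfig` carries the full-scale reference
conditions: 62×66×61 Å box, 6133 solvent, 0.15 M NaCl, Δt = 2 fs,
12 Å cutoff, body force 5×10⁻⁴ kcal·mol⁻¹·Å⁻¹, frames every 0.4 ps,
200 ns (500,000 frames).  Those runs take cluster-weeks and are not
exercised by the tests.

`desk_config()` is the package's own scaled-down condition, chosen
once: 26×44×26 Å box (tall along the tether axis so the ~33 Å solute
never meets its periodic image), 450 solvent beads, 8 Å cutoff, 40 ps
runs saved every 0.2 ps (200 frames), and a body force of 0.02
kcal·mol⁻¹·Å⁻¹.  The force is deliberately larger than the full-scale
value: with a few hundred beads and tens of picoseconds, the drift
must rise well above the ~0.17 Å/ps thermal noise of a frame mean
within the run, the same "too small is cancelled by the thermostat,
too large outruns the solute's drag" trade-off the body-force method
always faces.  At this setting the desk system reaches a steady bulk
velocity of roughly 5 Å/ps (≈500 m/s), an order of magnitude above
the full-scale 0.5 m/s regime; all flow-effect claims are therefore
directional, never quantitative.

## What the generator does and does not emulate

It does reproduce, at desk scale: a thermostatted periodic electrolyte
with a tethered branched solute; steady body-force-driven flow whose
bulk velocity grows monotonically with the force; a velocity-profile
dip inside the solute's range of movement; flow alignment of the
branches (mean ∠ABx drops under flow); and flow-induced shifts in
aglycon rotamer populations, including the dominance switch of χ2.

It does not emulate: electrostatics or hydrogen-bonded hydration
shells, real sugar ring geometry/puckering, pressure coupling, the
GLYCAM-class torsional surface, or quantitative NOE distances.
Passing tests therefore demonstrate that the analysis machinery is
correct and that the qualitative flow phenomenology emerges from a
minimal tethered-polymer-in-flow model — not that the coarse numbers
transfer to the all-atom system.

## Analysis conventions

* **Bulk velocity**: mean over frames of the per-frame mean over
  selected atoms; the ± is the standard deviation of the per-frame
  means (the reference for that spread is not uniquely fixed by
  convention; this choice is documented rather than assumed).
* **Slab profile**: overlapping 7 Å slabs, 1 Å stride, periodic
  membership, pooled atom-frame averaging.  With overlapping slabs the
  mean of slab means need not equal the bulk mean; with non-overlapping
  slabs the count-weighted mean equals it exactly (tested).
* **Burn-in**: analysis entry points discard the first 10% of frames
  by default; the pipeline and the desk-scale comparisons discard 25%
  because desk flow runs start from rest and need ~10 ps to reach
  steady state.
* **Torsions**: signed dihedrals in (−180, 180]; 2-D histograms on a
  5° grid by default (binning is an analysis choice, not a measured
  quantity); a sample at exactly 180° lands in the last bin.
* **Boltzmann maps**: E = −k_B·T·ln(c/c_max) in kcal/mol at the
  simulation T₀ (300 K, k_BT = 0.596 kcal/mol); the most populated bin
  is the zero of energy; empty bins are masked, never zero-filled.
* **Rotamer states**: centers −60/+60/180°, halfwidth 60° (full
  coverage); exactly equidistant samples resolve to the lower center.
* **NOE averaging**: ⟨r⁻⁶⟩⁻¹ᐟ⁶ by default; the exponent is a knob
  (−3 alternative) because either convention appears in practice.
  Effective distances above 4.0 Å are annotated "No-NOE" with the
  numeric value retained.  Experimental reference values are carried
  as annotations only, never computed.
* **∠ABx**: A = CA, B = CB (configurable), x = residue centre of mass
  over member atoms.  2° histogram bins.
* **RDF**: dr = 0.1 Å default, r_max ≤ half the smallest box
  dimension enforced; same-selection RDFs count unordered pairs once;
  residue-ion cross RDFs use the member-atom convention.
* **Maximum extension**: highest solute coordinate along the tether
  axis minus the anchor (aglycon C, first frame) coordinate; requires
  unwrapped solute and refuses wrapped input.

## Design choices made where the design was open

* The two dominant aglycon conformers are reported as a table of the
  top-2 (φ, ψ, χ2) state combinations with occupancies and circular
  mean angles, instead of rendered structures.
* The "slow flow" variant is a config multiplier on the body force
  (0.9 reproduces a 10%-reduced force condition) rather than a
  separate configuration.
* The aglycon is residue 1, keeping residue indices contiguous with
  the sugar numbering 2–9.
* Trajectories are stored as extended XYZ with velocity columns
  because the flow analysis needs instantaneous velocities;
  position-only formats would force finite-difference reconstruction,
  which is out of scope by design.

## Known limitations

* Quantitative full-scale observables (0.50 m/s bulk velocity, the
  printed NOE distances, χ2 energy shifts of ~0.6/−0.3 kcal/mol) are
  all-atom results and are not reproduced by the coarse model.
* The Berendsen thermostat does not sample a canonical ensemble;
  population-derived energies are relative and qualitative.
* Desk-scale occupancy tables from 40 ps runs are sampling-limited:
  rare rotamer states may appear unpopulated.
* The soft-sphere electrolyte has no charge: ion-specific structure
  in the RDFs is packing structure only.
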