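# Methods

## The model

`amylattice` implements a coarse-grained cubic-lattice model of amyloid
fibril elongation.  Each residue occupies one lattice site; consecutive
residues sit on nearest-neighbour sites (self-avoiding).  Every residue
carries a side-chain *orientation* (one of the six axis directions) and a
boolean β-strand state.  Empty sites are solvent.

The Hamiltonian (reduced units, k_B = 1) is

    H = E_hb + E_steric + E_state + E_aa + Φ_solvent(T)

* **E_aa** — directed side-chain contacts: a side chain pointing at a site
  occupied by a residue of another molecule (or a non-adjacent residue of
  its own chain) contributes ε(a_i, a_j).  A mutually buried pair therefore
  counts twice.  The shipped table gives hydrophobic pairs
  ε_ij = −1.35·s_i·s_j/s_F² (Fauchère–Pliška side-chain hydrophobicities,
  ε_FF = −1.35, ε_LL ≈ −1.22) and zero otherwise.
* **E_hb** — hydrogen bonds: ε_hb (default −1.4) per unordered pair of
  residues on different molecules at unit distance, both in the β state,
  with identical side-chain directions perpendicular to their separation.
  This is the geometry of in-register β-sheet stacking along the fibril
  axis.
* **E_state** — chain entropy of strand formation: ln(N_β) per β residue
  (default N_β = e, i.e. one unit per residue), the multiplicity of
  non-strand alternatives a residue gives up.  The net gain of a bonded β
  residue is |ε_hb| − ln N_β = 0.4 with the defaults.
* **E_steric** — side-chain crowding: 2.0 per pair of side chains pointing
  at the same site and per side chain pointing at its own backbone
  neighbour.  Backbone excluded volume is a hard constraint (overlapping
  moves are rejected).
* **Φ_solvent(T)** — each solvent-exposed side chain contributes
  ε_solv(a_i) (0.9·s_i/s_F for the nine hydrophobic residues C F L W V I M
  Y A, zero otherwise) plus, if hydrophobic, the temperature-dependent
  hydrophobic free energy F_hydr = −α(T−T0)² with T0 = 0.4.  Sites beyond
  the hard-wall box count as solvent.

Only Φ_solvent depends on temperature, so H = E_int + Φ_solvent(T).
Because F_hydr is a free energy (a solvent potential of mean force), the
*enthalpy* of a configuration replaces each exposed F_hydr by the
Gibbs–Helmholtz derivative E_hydr = −α(T0²−T²); this estimator equals H
when α = 0 and is the quantity averaged in all enthalpy analyses.

## Geometry and order parameters

The seed fibril is a double β-sheet of 2×4 in-register TFTFTFT strands:
each layer holds two anti-facing strands whose phenylalanine side chains
point at each other's backbone across the inter-sheet core, and layers
stack along z.  Two free chains may dock as the next layer.  This is the
unique simple geometry that reproduces the model's two printed constants
from first principles: a docked layer makes C_ext = 21 external contacts
(7 lateral + 2×7 stacking) and buries ΔC_h = 6 hydrophobic side chains, so
the elongation-level hydrophobic strength is γ = 6α.

Order parameters per sample: C_ext (inter-molecular backbone contacts
involving a free chain), the native-contact fraction (best match over the
16 docking symmetry variants — sheet exchange, either fibril end, and
backbone reversal of either chain, the last being exact for the
palindromic sequence), and C_h (solvent-exposed hydrophobic side chains of
the free chains).

State classification (configurable thresholds): *monomeric* C_ext ≤ 1;
*fibrillar* native fraction ≥ 2/3 with a formed core (C_h ≤ 1); *fully
aggregated* C_ext ≥ 21 with native fraction ≥ 18/21 and a formed core;
otherwise *amorphous*.  The core condition is essential: a backbone-docked
layer with solvent-everted side chains reproduces all 21 contacts but is
the cold, attached-without-core aggregate, not a fibril.  The 2/3 native
threshold tolerates frayed chain ends, which are thermally populated
throughout the stability window.

## Calibration of the default parameterisation

The pair table, solvent vector and ε_hb were calibrated once, jointly,
against the qualitative behaviour the model is meant to display: a TFTFTFT
fibril stable over an intermediate temperature window at α = 0 with heat
denaturation near T ≈ 0.4, and cold denaturation into monomers near
T ≈ 0.25 at α = 60.  The controlling balances, documented because they are
not obvious:

* The solvent scale (0.9 per F) sets the cold crossover: exposure of a
  hydrophobic side chain becomes favourable below T0 − sqrt(0.9/α)
  (≈ 0.28 at α = 60).  Larger values also drive warm monomers to collapse
  intramolecularly, which distorts the ΔC_h = 6 signature.
* The net hydrogen-bond gain (0.4/bond) pins the docked layer in register
  but also glues single end-docked chains (7 bonds); it must stay below
  ≈ 0.4 for dissociated monomers to win a temperature band below the
  fibril window.
* The lateral F–F contacts (requiring both chains of a layer) carry the
  remainder of the docked-layer stability without stabilising single
  docked chains.

The α = 0 docking enthalpy of the reference states is −19.1 with these
defaults.  In physical terms the box (edge 20) puts two free chains at a
monomer concentration of a few mM for a ~4.5 Å lattice spacing, matching
the convention that ΔG = 0 corresponds to a millimolar-scale critical
concentration; experimental depolymerisation free energies are referenced
to far lower critical concentrations and differ by several k_B T, so only
temperature dependences should be compared across that divide.

## Sampling

Metropolis Monte Carlo on the two free chains (the seed moves only as a
rigid body): end rotations, corner flips, crankshafts, rigid chain
translations/rotations/teleports, side-chain re-orientations and β flips,
all with symmetric proposal distributions; invalid proposals are rejected.
The engine recomputes the full Hamiltonian each step (the system is ≤ 70
residues; a compiled pass takes ~1 µs), which removes incremental-update
bookkeeping as an error source; tests verify the running energy against
independent recomputation and validate the sampler against exact
enumeration of small systems.

Replica exchange couples the temperature grid with the exchange criterion
for a temperature-dependent Hamiltonian (both configurations re-evaluated
at both temperatures).  Default protocol: 13 temperatures (0.15–0.45,
step 0.025), 1×10⁵ sweeps of ~16 moves, first 25% discarded, samples
every 5 sweeps.  These problem sizes are chosen for desk-scale
reproduction; analyses at 2.6×10⁵ sweeps are used for the shipped
acceptance computations.

**Nucleation is excluded by construction and by kinetics.**  Spontaneous
assembly of an in-register two-chain layer from free monomers is a rare
collective fluctuation that does not occur within ~3×10⁵ sweeps at any
temperature; the physical elongation experiment likewise requires
pre-formed seeds.  Production analyses therefore start replicas from the
docked (fibrillar) reference and measure the local elongation equilibrium;
the cold side of the diagram (melting into monomers or amorphous
aggregates) was additionally verified to converge to the same answer from
both monomeric and fibrillar starts.  Because replica exchange transports
the finite pool of docked configurations toward temperatures where they
are destroyed irreversibly, state diagrams are sampled in two separate
ladders split at the cold transition (0.15–0.25 and 0.275–0.45) rather
than one.

## Analyses

* **State diagrams** report the modal state per (parameter, temperature)
  cell; cells with too few samples are flagged unsampled, never
  interpolated.
* **Elongation curves**: ΔG(T) = −T ln(P_fib/P_mono) from visitation
  ratios; ΔE(T) as the difference of state-conditional means of the
  Gibbs–Helmholtz enthalpy estimator; −TΔS = ΔG − ΔE.  Errors by block
  averaging (20 blocks); temperatures with fewer than 50 visits to either
  state are excluded.  For quantitative comparison with the analytic form
  ΔÊ(T) = γ(T0²−T²) + E_int (γ = 6α), the monomeric reference class is
  additionally conditioned on solvent exposure (C_h ≥ 5), because the
  ΔC_h = 6 construction presumes exposed monomers; conditional means are
  equilibrium properties of each basin even when absolute visitation
  weights are still relaxing, so these runs discard only a short
  transient.  Warm monomers in this model partially bury their side chains
  intramolecularly (the contract allows non-adjacent intra-chain
  contacts), a documented difference from the idealised construction.
* **Heat capacity of elongation**: centred finite differences of ΔE(T),
  with error propagation; the analytic slope is −2γT.
* **Free-energy landscapes**: F = −T ln P over binned order-parameter
  pairs, minimum shifted to zero, empty bins reported absent.

## Experimental-data fits (physical units)

ITC-style molar enthalpies ΔH(T) (kJ/mol) are fitted to
ΔH = γ(T0²−T²) + E_int with T0 = 343.15 K fixed — linear least squares,
weighted when uncertainties are given — yielding γ (kJ/(mol K²)) and
ΔC_p(T) = −2γT.  Chemical depolymerisation curves are fitted to the
isodesmic linear-polymerisation model: with K = exp(−(ΔG⁰+m[D])/RT) (1 M
standard state) and x = K[M]_T, the free monomer fraction is
y = (2x+1−√(4x+1))/(2x²), evaluated in the cancellation-free equivalent
form y = 4/(1+√(4x+1))².  Buried hydrophobic surface areas A_h sum
per-residue maximal solvent-accessible areas (Tien et al. 2013 values
shipped, overridable) over the hydrophobic residues of the fibril-core
sequence, and fitted γ values are regressed on A_h through the origin.

The synthetic-data generators emulate reduced experimental data only:
noiseless model curves plus i.i.d. Gaussian noise at configurable σ, on
the designs used in practice (ΔH every 5 K over 278–323 K; 25
denaturant points over 0–8 M at 10 µM protein).  They do not emulate
instrument baselines, dilution heats, or concentration-dependent
depolymerisation; passing recovery tests therefore demonstrates the
correctness of the fitting procedures, not robustness to raw-thermogram
artefacts.

## Numerical choices and limitations

* RNG: xorshift128+ with one independent stream per replica, seeds derived
  from a single user seed; runs are bit-reproducible.
* The isodesmic fit starts from the mid-transition denaturant
  concentration (K[M]_T ≈ 0.57 at y = 1/2) and m = 2 kJ/(mol M).
* Degenerate inputs raise: non-positive temperatures, all-equal fit
  temperatures, all-zero surface areas, histograms with no counts.
* Known limitations: the heat-denatured ensemble contains free two-chain
  layers (dimers) in addition to monomers, so monomer dominance at high T
  appears slightly above the fibril melting temperature; the α = 60
  fibrillar window is thermodynamically marginal (fibrillar fractions
  0.4–0.6 near its edges), so modal-state boundaries at 0.025 resolution
  can shift by one grid step between seeds; quantitative free energies are
  tied to the simulation's own concentration scale.
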