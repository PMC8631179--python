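# Methods

## The kinetic model

The solver treats a finite self-assembly network as a bipartite graph:
stable states (clusters of ν monomers at local free-energy minima, tracked
by per-cluster concentration) and transition states (free-energy maxima on
transformation paths). Three assumptions define the model's scope:

1. **Single barrier per path.** Any transformation between two stable
   states crosses exactly one transition state; a path with two maxima is
   represented by inserting the intervening minimum as a state of its own.
2. **Barriers are high and transiently populated.** Transition states carry
   no concentration variable; they only gate flow.
3. **First-order kinetics.** The rate-determining step is the activation of
   a monomer out of its cluster, so outflow from state s over barrier t is
   `k_t^s · exp(−(G_t − G_s)/RT) · C_s` on the *per-monomer* free energies
   G = (total assembly energy)/ν. The downhill side of each barrier is
   barrierless and splits over the linked states by the column-stochastic
   linking-fraction matrix Lf[s,t] = k_t^s / Σ_s' k_t^s'. This
   normalisation is exactly what makes the Boltzmann distribution
   stationary, so zero net flow at equilibrium is an algebraic identity of
   the implementation, not a fitted property — the test suite holds it to
   1e−10 relative.

Cluster stoichiometry enters as ν_src/ν_dst factors on inter-cluster flows;
consequently the monomer-count vector ν is an exact left null vector of the
kinetic matrix A and Σ ν_s C_s is conserved along every trajectory.

### Parameters

| parameter | units | default | role |
|---|---|---|---|
| temperature | K | 310 | sets RT = 0.6160 kcal/mol with R = 1.9872e−3 |
| c0_monomer | any conc. | 1 | total analytical monomer pool; all rates are linear in it |
| frequency factors A | — | 1 | per-path correction for dissociation/conformational preprocessing |
| k_scale | reduced | 1 | absorbs the (k_B T/h)·A prefactor |

No calibration recipe exists for the frequency factors, so absolute rates
are reported in reduced units; every conclusion the solver is designed for
(dominance, ratios, relative relaxation times) is invariant to k_scale.

### Numerics

Boltzmann weights span tens of orders of magnitude at 310 K (|G| ≈ 30
kcal/mol gives e^{±48}), so the equilibrium distribution is computed as a
shifted softmax and path rates factor a per-barrier maximum exponent out of
each column before summation — the cancellation that makes equilibrium
rates vanish survives to round-off. Time courses use the eigen-solution
C(t) = Σ z_i ξ_i e^{λ_i t}; if the eigenvector basis has condition number
above 1e12 (defective or near-defective A), the solver silently switches to
the matrix exponential and logs the switch. Dominant-path ties within 1e−9
relative are reported as joint ranks rather than ordered arbitrarily.
Per-monomer vs per-cluster energy conventions for transition states are
both supported (barrier tops have no natural ν of their own; when a
cluster-level barrier is supplied the file schema divides it by the ν of a
named destination state). The packaged PD-L1 analysis reaches the same
dominant path under either reading.

## Energy bookkeeping

MM-PBSA recombination follows the standard single-trajectory convention:
internal-energy terms cancel in binding deltas and are optional metadata;
ΔG_PB and TΔS are inputs (PB solving and normal-mode analysis live
upstream). Stored values are never rounded — presentation rounding is a
separate `round()` view — so the defining identities hold exactly on the
stored numbers. The nonpolar solvation term is the linear SASA model
γ·SASA + β with the common parametrisation (γ = 0.00542 kcal mol⁻¹ Å⁻²,
β = 0.92 kcal/mol) as overridable defaults.

Barrier composition: the endpoint of a ligand-extraction PMF contains both
the ligand's thermodynamic stabilisation and the geometric resistance of
the exit channel; subtracting the former isolates the latter, and the
barrier top of the insertion path sits at G_state + barrier on the assembly
free-energy surface. In the packaged PD-L1 network, the holo dimer's total
energy (−43.97 kcal/mol) and the insertion barrier top (−10.87 kcal/mol)
are composed this way from the IS^PP assembly energy (−31.15), the drug's
stabilisation (12.82) and the extraction-PMF endpoint (33.10); the network
file documents both as derived values.

## Jarzynski estimation

The estimator ΔG = −kT ln⟨e^{−W/kT}⟩ is evaluated in log-sum-exp form. For
Gaussian work of variance σ² the exact limit is μ − σ²/(2kT), which the
test suite uses as a closed-form oracle together with the Jensen bound
ΔG ≤ ⟨W⟩. Staged profiles apply the estimator pointwise along the pulling
coordinate within each stage and chain stage offsets so the profile is
continuous; the replicate whose end-of-stage work is closest to the stage's
estimate is flagged as the seed the adaptive protocol would propagate
(metadata only — stages here restart from the exact restrained
equilibrium).

### The synthetic pulling generator

The generator emulates a staged steered-MD pull with an overdamped-Langevin
particle in a quadratic well (stiffness `well_k`) dragged by a moving
harmonic restraint. Protocol defaults mirror the emulated experiment:
restraint spring 20 kcal mol⁻¹ Å⁻², speed 2 Å ns⁻¹, a 20 Å coordinate in
10 stages of 20 replicates at 310 K. The combined potential's free energy
is exactly G(λ) = ½ k_eff λ² with k_eff = well_k·spring_k/(well_k+spring_k),
giving an analytic oracle for every test. `well_k = 0.17` (k_eff ≈ 0.168)
was chosen once so the end-to-end profile (~33.4 kcal/mol) matches the
scale of a realistic ligand-extraction PMF; friction 50 kcal ps mol⁻¹ Å⁻²
and dt = 0.1 ps keep the Euler–Maruyama step stable
((well_k+spring_k)·dt/γ ≈ 0.04) and the per-stage dissipation small
(~0.2–0.5 kcal/mol), which is the regime the staged protocol targets.

What the generator does *not* emulate: a sinuous multi-dimensional exit
channel, anharmonic and history-dependent friction, or side-chain
rearrangements coupled to the pull. Passing tests therefore demonstrate
estimator correctness on a solvable model, not the accuracy of any given
MD protocol.

## Trajectory metrics

Superposition is the least-squares Kabsch/quaternion rotation on an atom
selection; RMSD is mass-weighted by default; atomic RMSF is measured about
the time-mean position (the static-reference variant is an option), and
residue RMSF is the mass-weighted mean of the atomic values. The DCCM uses
full 3-D displacement dot products; zero-variance atoms yield NaN entries
reported as missing rather than 0. The geometric H-bond criterion is
distance < 3.5 Å and D–H···A angle strictly between 120° and 180°; the
distance is donor–acceptor by default (the hydrogen–acceptor variant is a
flag) since the criterion's distance convention is a genuine ambiguity —
both are offered and the choice is prominent in the API.

## Random-network generator

Property tests draw connected bipartite networks with ν uniform in 1–4,
per-monomer state energies uniform in (−3, 3) kcal/mol, barrier energies
uniform in (3, 9) (above the typical minima), and frequency factors uniform
in (0.5, 2) — sized so Boltzmann exponents stay within float64 while still
spanning several orders of magnitude of rate. Connectivity is guaranteed by
spanning attachment before random extra links.

## Problem sizes

The shipped test and reproduction runs use networks of up to 7 states,
work ensembles up to 10⁶ Gaussian samples, a 10-stage × 20-replicate
synthetic pull (10⁴ steps/stage), and trajectories up to 10⁴ frames —
sizes at which every oracle comparison is exact or statistically
well-resolved.

## Known limitations

- Rates are relative; absolute time scales require calibrating k_scale.
- No nonlinear (concentration-dependent rate-constant) kinetics and no
  stochastic simulation: the solver is the linear eigen-solution.
- No periodic-boundary handling in trajectory metrics; inputs are assumed
  imaged.
- The equilibrium partition is over a caller-chosen accessible set — the
  package deliberately refuses to guess which states are reachable in a
  given experimental stage.
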