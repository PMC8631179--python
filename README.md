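# gitr

Kinetics of multi-state self-assembly networks: which transformation path
dominates when a system of protein clusters can rearrange through several
competing routes?

The package is built for structural modellers studying systems like the
PD-L1 dimerization problem it ships as a worked example: the cancer-cell
surface protein PD-L1 forms an apo dimer (the 4Z18-type interface), a second
apo dimer mode (IS^PP), and a drug-bound "sandwich" holo dimer (5J89-type,
with the small-molecule blocker BMS-202 entrapped between the monomers).
Whether the drug *induces* the holo dimer or merely *stabilizes* a
pre-formed apo dimer is a question about transformation rates, not just
energies.

## The model

A self-assembly network is a bipartite graph of **stable states** S
(clusters of ν monomers at free-energy minima, counted by cluster
concentration C_s) and **transition states** T (free-energy maxima on
transformation paths), with the free-monomer state as the zero of the
energy scale. All energies are per monomer: G_s = (1/ν_s) Σ ΔG_bind.

Activation out of a state is transition-state-theory-like; the downhill
side of each barrier splits over its linked states by the column-stochastic
**linking-fraction matrix** Lf[s,t] = k_t^s / Σ_s' k_t^s', with
k_t^s = (k_B T/h)·A_t^s absorbed into one configurable scale (rates are
reported in reduced units — conclusions are rate ratios). The net path
rate is

    R_st = −k_t^s e^{−(G_t−G_s)/RT} C_s
           + Lf[s,t] Σ_s' k_t^s' e^{−(G_t−G_s')/RT} (ν_s'/ν_s) C_s' ,

the equilibrium monomer distribution is Boltzmann, P_s ∝ e^{−G_s/RT} with
C_s^eq = P_s C0/ν_s, and the linear system dC/dt = A·C is solved by
eigen-superposition C(t) = Σ z_i ξ_i e^{λ_i t}. The monomer-count vector ν
is a left null vector of A, so total monomer content is conserved exactly.

Supporting modules cover the standard energy bookkeeping around the solver:
MM-PBSA recombination (ΔE_polar = ΔE_ele + ΔG_PB, ΔE_nonpolar = ΔE_vdw +
ΔG_SA, ΔG_mmpbsa = ΔE_polar + ΔE_nonpolar, ΔG_bind = ΔG_mmpbsa − TΔS),
Jarzynski-equality PMF estimation from staged pulling work
(e^{−ΔG/kT} = ⟨e^{−W/kT}⟩), and trajectory metrics (Kabsch superposition,
mass-weighted RMSD, atomic/residue RMSF, dynamic cross-correlation
matrices, geometric H-bond occupancy: distance < 3.5 Å, 120° < angle
< 180°).

## Worked example

```sh
gitr demo pdl1
```

prints the full PD-L1 analysis:

```
PD-L1 dimerization-mode transformation (pre-drug equilibrium)
  T = 310 K, C0 = 1 (monomer), rates in reduced units
  monomer fractions: P(S1) = 0.0022, P(S2) = 0.9978
  cluster concentrations: C1 = 1.1149e-03, C2 = 4.9889e-01
  linking fractions: T1 -> (S1,S2,S3) = (0.3333, 0.3333, 0.3333); T2 -> (S2,S3) = (0.5000, 0.5000)
  path rates (negative = outflow toward S3):
    rank 1: S2->T2  R = -1.7718e-08
    rank 1: S3->T2  R =  1.7718e-08
    rank 3: S3->T1  R =  3.4813e-12
    rank 4: S1->T1  R = -1.7406e-12
    rank 4: S2->T1  R = -1.7406e-12
  dominant path: S2 -> T2 -> S3 (drug insertion into the IS^PP dimer)
```

Reading the numbers: before the drug is added only the two apo dimers are
accessible, and the deeper IS^PP mode holds ~99.8 % of the monomers. Of the
three transformation paths toward the holo dimer — full three-body
separation out of either apo mode (via T1, barrier at 0 kcal/mol) or direct
drug insertion into IS^PP (via T2, barrier top at −10.87 kcal/mol total) —
the insertion path's rate magnitude is ~10⁴ times the separation paths'.
The drug acts as a stabilizer of a pre-formed apo dimer, not an inducer of
dimerization from free monomers. The equal-magnitude rank-1 pair is the two
ends of the same path (outflow from S2, inflow to S3).

The same analysis is available programmatically:

```python
import gitr

net = gitr.pdl1_network()
conc = gitr.equilibrium_distribution(net, accessible=("S1", "S2"))
ranking = gitr.dominant_path(net, conc)
```

Other CLI surfaces: `gitr rates`, `gitr evolve`, `gitr dominant` for
arbitrary network files, `gitr energy` for MM-PBSA component tables,
`gitr pmf` for staged work tables, and `gitr traj rmsd|rmsf|dccm|hbond`.

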