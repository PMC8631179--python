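# Five-node PD-L1 dimerization network (all energies kcal/mol, per cluster).
#
# Stable states:
#   S1: apo dimer, 4Z18-type interface            (printed binding energy)
#   S2: apo dimer, IS^PP interface                (printed binding energy)
#   S3: holo (drug-bound) dimer, 5J89-type        (derived: -31.15 - 12.82;
#       the drug's stabilisation added to the IS^PP assembly energy — the
#       holo total is not printed anywhere)
# Transition states:
#   T1: three-body separation (free-monomer reference, 0 kcal/mol)
#   T2: drug-insertion barrier top, cluster total -10.87 = -31.15 + 20.28,
#       expressed per monomer through the nu of the destination dimer S3.
#
# The free-monomer reference state is implicit (energy zero); ligands do not
# count toward nu, so every dimer has nu = 2. All frequency factors equal 1.
temperature_K: 310.0
c0: 1.0
states:
  - {id: S1, nu: 2, g_bind_total: -23.63}
  - {id: S2, nu: 2, g_bind_total: -31.15}
  - {id: S3, nu: 2, g_bind_total: -43.97}
transitions:
  - id: T1
    g_monomer: 0.0
    links:
      - {state: S1, A: 1.0}
      - {state: S2, A: 1.0}
      - {state: S3, A: 1.0}
  - id: T2
    g_total: -10.87
    g_total_over_nu_of: S3
    links:
      - {state: S2, A: 1.0}
      - {state: S3, A: 1.0}
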