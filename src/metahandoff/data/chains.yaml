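# Default sequential-redox chains for handoff analysis.
#
# Each chain is an ordered list of steps; each step names the trait that
# confers the capability, the number of marker genes m behind the step
# (used by the incompleteness null), and an optional standard Gibbs free
# energy (kJ/mol, textbook-order defaults; denitrification steps written
# with H2 as electron donor).  delta_g0 is only a per-step covariate for
# the energy-yield correlation — replace with measured values when
# available.
chains:
  - chain: sulfur_oxidation
    steps:
      - {step: A, trait: sulfide_oxidation_to_S0, substrate: "S2-",    product: "S0",     m: 1, delta_g0: -209.0}
      - {step: B, trait: S0_oxidation,            substrate: "S0",     product: "SO3^2-", m: 1, delta_g0: -332.0}
      - {step: C, trait: sulfite_oxidation,       substrate: "SO3^2-", product: "SO4^2-", m: 1, delta_g0: -258.0}
  - chain: denitrification
    steps:
      - {step: D, trait: nitrate_reduction, substrate: "NO3-", product: "NO2-", m: 1, delta_g0: -163.0}
      - {step: E, trait: nitrite_to_NO,     substrate: "NO2-", product: "NO",   m: 1, delta_g0: -76.0, possible_detox: true}
      - {step: F, trait: NO_to_N2O,         substrate: "NO",   product: "N2O",  m: 1, delta_g0: -306.0}
      - {step: G, trait: N2O_to_N2,         substrate: "N2O",  product: "N2",   m: 1, delta_g0: -340.0}
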