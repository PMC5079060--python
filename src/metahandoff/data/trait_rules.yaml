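# Default marker -> trait rules for the C/N/S/H cycle transformations.
#
# Each rule turns cutoff-passing marker hits into one boolean trait:
#   any_of : list of marker sets; one set fully present suffices
#   all_of : every marker required
#   none_of: markers that must be absent (conditional/negative rules)
#
# Marker names follow common gene nomenclature.  The exact marker
# composition behind each transformation in any given study lives in that
# study's cutoff tables; this file is a documented, editable default.
#
# Hydrogenase and Rubisco "groups" are distinct marker ids feeding one
# trait via any_of (each group has its own HMM in practice).
rules:
  - trait: sulfide_oxidation_to_S0          # S2- -> S0 (sqr or fccAB)
    any_of: [[sqr], [fccA, fccB]]
  - trait: S0_oxidation                     # S0 -> SO3^2-
    any_of: [[dsrA_ox, dsrB_ox], [sor]]
  - trait: sulfite_oxidation                # SO3^2- -> SO4^2-
    any_of: [[soeA], [sorA]]
  - trait: thiosulfate_oxidation_S0_producing   # sox system lacking soxCD
    all_of: [soxA, soxB, soxX, soxY, soxZ]
    none_of: [soxC, soxD]
  - trait: sulfate_reduction                # SO4^2- -> H2S (dissimilatory)
    all_of: [dsrA, dsrB, sat]
  - trait: S0_reduction                     # S0 -> H2S
    any_of: [[sreA], [psrA]]
  - trait: nitrate_reduction                # NO3- -> NO2-
    any_of: [[narG], [napA]]
  - trait: nitrite_to_NO                    # NO2- -> NO (possible detox step)
    any_of: [[nirK], [nirS]]
  - trait: NO_to_N2O                        # NO -> N2O
    any_of: [[norB]]
  - trait: N2O_to_N2                        # N2O -> N2
    any_of: [[nosZ]]
  - trait: DNRA                             # NO2- -> NH4+
    any_of: [[nrfA]]
  - trait: anammox                          # NH4+ + NO2- -> N2
    all_of: [hzsA]
  - trait: nitrogen_fixation                # N2 -> NH4+
    all_of: [nifH, nifD, nifK]
  - trait: oxygen_respiration               # O2 as terminal acceptor
    any_of: [[coxA], [ccoN], [cydA]]
  - trait: carbon_fixation                  # CO2 fixation (Rubisco groups, rTCA)
    any_of: [[rbcL_I], [rbcL_II], [rbcL_III], [aclB]]
  - trait: CO_oxidation                     # CO -> CO2
    any_of: [[coxL]]
  - trait: H2_metabolism_by_group           # NiFe / FeFe hydrogenase groups
    any_of: [[nife_group1], [nife_group3], [nife_group4], [fefe_groupA]]
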