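"""Call metabolic traits from marker hits, including a conditional rule.

Shows the rule engine on hand-built marker sets: alternative enzyme systems
(sqr vs fccAB for sulfide oxidation), multi-subunit requirements, and the
negative soxCD condition for S0-producing thiosulfate oxidation.
"""

from metahandoff.trait_calling import call_traits, default_trait_rules, trait_prevalence

rules = default_trait_rules()

genome_markers = {
    "sqr_only":      {"sqr"},
    "fcc_complete":  {"fccA", "fccB"},
    "fcc_partial":   {"fccA"},
    "sox_no_soxCD":  {"soxA", "soxB", "soxX", "soxY", "soxZ"},
    "sox_with_soxCD": {"soxA", "soxB", "soxX", "soxY", "soxZ", "soxC", "soxD"},
    "denitrifier":   {"narG", "nirK", "norB", "nosZ"},
}

matrix = call_traits(genome_markers, rules)
show = ["sulfide_oxidation_to_S0", "thiosulfate_oxidation_S0_producing",
        "nitrate_reduction", "N2O_to_N2"]
print(matrix.values[show].to_string())

prev = trait_prevalence(matrix)
print("\nprevalence of sulfide oxidation:",
      f"{prev.loc['sulfide_oxidation_to_S0', 'count']}/6 genomes "
      f"({prev.loc['sulfide_oxidation_to_S0', 'fraction']:.0%})")
print("Note the sox system row: with soxCD present the trait is false — the "
      "complete sox pathway oxidizes thiosulfate to sulfate without "
      "releasing elemental sulfur.")
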