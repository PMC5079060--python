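"""Apply the three-condition phylum-level novelty test.

A candidate lineage is 'novel' when its 16S identity to every known phylum
is below ~75%, it is monophyletic in both the 16S and ribosomal-protein
trees, and at least one member genome passes the completeness filter.
"""

from metahandoff.completeness import default_scg_config
from metahandoff.completeness import SCGProfile
from metahandoff.novelty import assess_novelty, pairwise_identity

markers = sorted(default_scg_config("bacteria").marker_ids)
profiles = {
    "cand1": SCGProfile("cand1", "bacteria", frozenset(markers),
                        frozenset(markers[:40]), frozenset()),  # 93% complete
    "cand2": SCGProfile("cand2", "bacteria", frozenset(markers),
                        frozenset(markers[:25]), frozenset()),
}

# 16S rows from one multiple alignment: candidate vs a known-phylum reference
cand_16s = "ACGTACGTAC" * 10
ref_16s = "ACGTACGTAC" * 7 + "TGCATGCATG" * 3  # 70% identical
identity = pairwise_identity(cand_16s, ref_16s)
print(f"16S identity to closest known phylum: {identity:.2f}")

ssu_tree = "((cand1,cand2),(refA,(refB,refC)));"
rp_tree = "(((cand1,cand2),refA),(refB,refC));"

call = assess_novelty(
    "candidate_lineage", {"cand1", "cand2"},
    {"cand1": {"known_phylum_ref": identity}},
    ssu_tree, rp_tree, profiles,
)
print(f"ssu monophyletic: {call.ssu_monophyletic}, "
      f"rp monophyletic: {call.rp_monophyletic}, "
      f"quality genome: {call.has_quality_genome}")
print(f"verdict: {call.verdict}")
print("All three conditions hold (identity 0.70 < 0.75, monophyly in both "
      "trees, one member >70% complete), so the lineage qualifies as a "
      "candidate novel phylum.")
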