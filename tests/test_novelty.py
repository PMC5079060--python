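"""16S identity, monophyly testing and the three-condition novelty call."""

import random

import dendropy
import pytest
from treeutils import oracle_monophyletic, random_topology, to_newick

from metahandoff.completeness import SCGProfile, default_scg_config
from metahandoff.formats_io import ValidationError
from metahandoff.novelty import (
    assess_novelty,
    filter_gap_columns,
    is_monophyletic,
    pairwise_identity,
)

MARKERS = sorted(default_scg_config("bacteria").marker_ids)


def _profile(genome, n_found):
    return SCGProfile(genome, "bacteria", frozenset(MARKERS),
                      frozenset(MARKERS[:n_found]), frozenset())


class TestPairwiseIdentity:
    def test_identical_rows(self):
        assert pairwise_identity("ACGT" * 25, "ACGT" * 25) == 1.0

    def test_thirty_substitutions_in_hundred_columns(self):
        a = "A" * 100
        b = "C" * 30 + "A" * 70
        assert pairwise_identity(a, b) == pytest.approx(0.70)

    def test_dual_gaps_ignored_single_gap_mismatch(self):
        #   col: 1=match, 2=dual gap (ignored), 3=single gap (mismatch)
        assert pairwise_identity("A-A", "A-C") == pytest.approx(0.5)
        assert pairwise_identity("AA-", "AAG") == pytest.approx(2 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            pairwise_identity("ACGT", "ACG")

    def test_agrees_with_naive_per_column_oracle(self):
        rng = random.Random(9)
        alphabet = "ACGT-"
        for _ in range(30):
            n = rng.randint(10, 80)
            a = "".join(rng.choice(alphabet) for _ in range(n))
            b = "".join(rng.choice(alphabet) for _ in range(n))
            matches = compared = 0
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    continue
                compared += 1
                if x == y and x != "-":
                    matches += 1
            if compared == 0:
                continue
            assert pairwise_identity(a, b) == pytest.approx(matches / compared)


class TestGapColumnFilter:
    def test_drops_columns_above_threshold(self):
        aln = {"a": "A--", "b": "A-C", "c": "A--"}
        # col2 gap fraction 1.0 > 0.97 -> dropped; col3 is 2/3 <= 0.97 -> kept
        out = filter_gap_columns(aln, max_gap_fraction=0.97)
        assert out == {"a": "A-", "b": "AC", "c": "A-"}

    def test_threshold_is_a_knob(self):
        aln = {"a": "A-", "b": "AC", "c": "A-"}
        out = filter_gap_columns(aln, max_gap_fraction=0.5)
        assert out == {"a": "A", "b": "A", "c": "A"}


class TestMonophyly:
    TREE = "((A,B),(C,D));"

    def test_sister_pair_is_monophyletic(self):
        assert is_monophyletic(self.TREE, {"A", "B"})

    def test_non_clade_is_not(self):
        assert not is_monophyletic(self.TREE, {"A", "C"})

    def test_absent_taxon_named_in_error(self):
        with pytest.raises(ValidationError, match="Z"):
            is_monophyletic(self.TREE, {"A", "Z"})

    def test_invariant_under_rerooting_outside_group(self):
        tree = dendropy.Tree.get(data="((A,B),((C,D),E));", schema="newick")
        assert is_monophyletic(tree, {"C", "D"})
        outgroup = tree.find_node_with_taxon_label("A")
        tree.reroot_at_edge(outgroup.edge, update_bipartitions=False)
        assert is_monophyletic(tree, {"C", "D"})

    def test_matches_bipartition_enumeration_on_random_trees(self):
        rng = random.Random(13)
        for _ in range(200):
            n = rng.randint(4, 8)
            leaves = [f"t{i}" for i in range(n)]
            topology = random_topology(rng, leaves)
            newick = to_newick(topology) + ";"
            tree = dendropy.Tree.get(data=newick, schema="newick")
            for _ in range(6):
                k = rng.randint(1, n - 1)
                taxa = set(rng.sample(leaves, k))
                assert is_monophyletic(tree, taxa) == oracle_monophyletic(
                    topology, leaves, taxa
                ), (newick, taxa)


class TestAssessNovelty:
    SSU = "((L1,L2),(R1,R2));"
    RP = "((L1,L2),(R1,(R2,R3)));"
    PROFILES = {"L1": _profile("L1", 40), "L2": _profile("L2", 20)}

    def test_all_three_conditions_met(self):
        call = assess_novelty(
            "lineage", {"L1", "L2"},
            {"L1": {"ref_phylum": 0.70}},
            self.SSU, self.RP, self.PROFILES,
        )
        assert call.verdict == "novel"
        assert call.max_identity_to_known == pytest.approx(0.70)

    def test_identity_at_threshold_fails(self):
        call = assess_novelty(
            "lineage", {"L1", "L2"},
            {"L1": {"ref_phylum": 0.80}},
            self.SSU, self.RP, self.PROFILES,
        )
        assert call.verdict == "not_novel"

    def test_paraphyly_fails(self):
        call = assess_novelty(
            "lineage", {"L1", "R1"},
            {"L1": {"ref_phylum": 0.60}},
            self.SSU, self.RP, self.PROFILES | {"R1": _profile("R1", 40)},
        )
        assert call.verdict == "not_novel"

    def test_missing_16s_is_insufficient_data(self):
        call = assess_novelty(
            "lineage", {"L1", "L2"}, {}, self.SSU, self.RP, self.PROFILES,
        )
        assert call.verdict == "insufficient_data"

    def test_member_absent_from_tree_is_insufficient_data(self):
        call = assess_novelty(
            "lineage", {"L1", "X9"},
            {"L1": {"ref_phylum": 0.60}},
            self.SSU, self.RP, self.PROFILES,
        )
        assert call.verdict == "insufficient_data"

    def test_no_quality_genome_fails(self):
        profiles = {"L1": _profile("L1", 20), "L2": _profile("L2", 10)}
        call = assess_novelty(
            "lineage", {"L1", "L2"},
            {"L1": {"ref_phylum": 0.60}},
            self.SSU, self.RP, profiles,
        )
        assert not call.has_quality_genome
        assert call.verdict == "not_novel"

    def test_threshold_monotonicity(self):
        # lowering the identity threshold can only move novel -> not_novel
        for high, low in [(0.80, 0.75), (0.75, 0.60)]:
            kwargs = dict(
                members={"L1", "L2"},
                identity_to_references={"L1": {"ref": 0.70}},
                ssu_tree=self.SSU, rp_tree=self.RP, profiles=self.PROFILES,
            )
            v_high = assess_novelty("l", identity_threshold=high, **kwargs).verdict
            v_low = assess_novelty("l", identity_threshold=low, **kwargs).verdict
            assert not (v_high == "not_novel" and v_low == "novel")
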