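"""Similarity, single-linkage grouping and representative selection."""

import itertools
import random

import numpy as np
import pytest

from metahandoff.completeness import SCGProfile, default_scg_config
from metahandoff.dereplication import (
    GenomeCluster,
    SimilarityEdge,
    choose_representative,
    cluster_genomes,
    estimate_similarity_kmer,
    pairwise_kmer_similarity,
    pairwise_similarity,
)
from metahandoff.formats_io import AlignmentBlock, GenomeBin, Scaffold, ValidationError
from metahandoff.synthetic import CommunityScenario, simulate_community

MARKERS = sorted(default_scg_config("bacteria").marker_ids)


def _profile(genome, n_found, n_multi=0):
    return SCGProfile(
        genome, "bacteria", frozenset(MARKERS),
        frozenset(MARKERS[:n_found]), frozenset(MARKERS[:n_multi]),
    )


def _random_bin(genome, length, seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return GenomeBin(genome, [Scaffold(f"{genome}_s1", seq)])


class TestAlignedFractionSimilarity:
    LENGTHS = {"a": 1_000_000, "b": 1_000_000}

    def test_identical_genomes_full_block(self):
        blocks = [
            AlignmentBlock("a", "b", 1_000_000, 1.0),
            AlignmentBlock("b", "a", 1_000_000, 1.0),
        ]
        (edge,) = pairwise_similarity(blocks, self.LENGTHS)
        assert edge.similarity_ab == edge.similarity_ba == 1.0

    def test_half_length_block(self):
        blocks = [
            AlignmentBlock("a", "b", 500_000, 0.99),
            AlignmentBlock("b", "a", 500_000, 0.99),
        ]
        (edge,) = pairwise_similarity(blocks, self.LENGTHS)
        assert edge.similarity_ab == pytest.approx(0.5)
        assert edge.similarity_ba == pytest.approx(0.5)

    def test_block_below_identity_floor_contributes_nothing(self):
        blocks = [AlignmentBlock("a", "b", 900_000, 0.97)]
        assert pairwise_similarity(blocks, self.LENGTHS) == []

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValidationError, match="unknown genome"):
            pairwise_similarity([AlignmentBlock("a", "zz", 10, 1.0)], self.LENGTHS)


class TestKmerSimilarity:
    def test_self_similarity_is_one(self):
        bin = _random_bin("g", 50_000, seed=0)
        edge = estimate_similarity_kmer(bin, bin)
        assert edge.similarity_ab == edge.similarity_ba == 1.0

    def test_unrelated_sequences_share_almost_nothing(self):
        a = _random_bin("a", 100_000, seed=1)
        b = _random_bin("b", 100_000, seed=2)
        assert estimate_similarity_kmer(a, b).max_similarity < 0.01

    def test_strain_containment_matches_kmer_survival(self):
        # per-base substitution at 1%: expected 21-mer survival (1-0.01)^21
        scenario = CommunityScenario(
            n_archetypes=1, genes_per_genome=60, trait_probs={},
            strain_groups=[(0, 2, 0.01)], completeness_targets=[1.0],
            n_scaffolds=4, scaffold_length=25_000, n_samples=1, seed=7,
        )
        a, b = simulate_community(scenario).bins
        edge = estimate_similarity_kmer(a, b, k=21)
        assert edge.max_similarity == pytest.approx(0.99**21, abs=0.03)

    def test_short_k_rejected(self):
        bin = _random_bin("g", 1000, seed=0)
        with pytest.raises(ValidationError, match="k must be >= 11"):
            estimate_similarity_kmer(bin, bin, k=9)


def _brute_force_components(n_names, pairs):
    """Independent oracle: repeated merging until fixpoint."""
    groups = [{n} for n in n_names]
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                groups.remove(gb)
                ga |= gb
                changed = True
    return {frozenset(g) for g in groups}


class TestClustering:
    def test_single_linkage_chains_transitively(self):
        edges = [
            SimilarityEdge("A", "B", 0.9, 0.9),
            SimilarityEdge("B", "C", 0.6, 0.2),
            SimilarityEdge("A", "C", 0.0, 0.0),
        ]
        clusters = cluster_genomes(edges, ["A", "B", "C"])
        expected = _brute_force_components("ABC", [("A", "B"), ("B", "C")])
        assert {c.members for c in clusters} == expected

    def test_boundary_similarity_does_not_group(self):
        edges = [
            SimilarityEdge(a, b, 0.50, 0.50)
            for a, b in itertools.combinations("ABCD", 2)
        ]
        clusters = cluster_genomes(edges, list("ABCD"))
        assert all(len(c.members) == 1 for c in clusters)
        assert len(clusters) == 4

    def test_no_edges_gives_singletons(self):
        clusters = cluster_genomes([], [f"g{i}" for i in range(5)])
        assert len(clusters) == 5

    def test_partition_and_edge_order_invariance(self):
        rng = random.Random(4)
        names = [f"g{i}" for i in range(12)]
        edges = [
            SimilarityEdge(a, b, rng.random(), rng.random())
            for a, b in itertools.combinations(names, 2)
        ]
        reference = cluster_genomes(edges, names)
        # partition: every genome in exactly one cluster
        all_members = [g for c in reference for g in c.members]
        assert sorted(all_members) == sorted(names)
        shuffled = edges[:]
        rng.shuffle(shuffled)
        assert [c.members for c in cluster_genomes(shuffled, reversed(names))] == [
            c.members for c in reference
        ]


class TestRepresentative:
    LENGTHS = {"A": 2_100_000, "B": 2_400_000}

    def test_highest_score_wins(self):
        cluster = GenomeCluster("c1", frozenset("AB"))
        profiles = {"A": _profile("A", 40), "B": _profile("B", 36)}
        assert choose_representative(cluster, profiles, self.LENGTHS).representative == "A"

    def test_score_tie_broken_by_nucleotide_information(self):
        cluster = GenomeCluster("c1", frozenset("AB"))
        profiles = {"A": _profile("A", 40), "B": _profile("B", 40)}
        assert choose_representative(cluster, profiles, self.LENGTHS).representative == "B"

    def test_full_tie_broken_lexicographically(self):
        cluster = GenomeCluster("c1", frozenset("AB"))
        profiles = {"A": _profile("A", 40), "B": _profile("B", 40)}
        lengths = {"A": 1000, "B": 1000}
        assert choose_representative(cluster, profiles, lengths).representative == "A"

    def test_multi_copy_penalty_can_flip_choice(self):
        cluster = GenomeCluster("c1", frozenset("AB"))
        # A: 43 found, 5 multi -> 33; B: 36 found, 0 multi -> 36
        profiles = {"A": _profile("A", 43, 5), "B": _profile("B", 36)}
        assert choose_representative(cluster, profiles, self.LENGTHS).representative == "B"

    def test_missing_profile_rejected(self):
        cluster = GenomeCluster("c1", frozenset("AB"))
        with pytest.raises(ValidationError, match="no SCG profile"):
            choose_representative(cluster, {"A": _profile("A", 40)}, self.LENGTHS)


def test_planted_strain_groups_recovered_exactly():
    """Strain pairs at 0.5% divergence group; unrelated genomes stay apart."""
    scenario = CommunityScenario(
        n_archetypes=8, genes_per_genome=60, completeness_targets=[1.0],
        strain_groups=[(0, 2, 0.005), (1, 3, 0.005)],
        n_scaffolds=4, scaffold_length=8000, n_samples=1, seed=21,
    )
    community = simulate_community(scenario)
    edges = pairwise_kmer_similarity(community.bins)
    clusters = cluster_genomes(edges, [b.genome_id for b in community.bins])
    assert {c.members for c in clusters} == set(community.truth.strain_clusters())
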