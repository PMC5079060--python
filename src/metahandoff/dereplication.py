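"""Genome dereplication: strain-level clustering and representative choice.

Near-identical genome bins (strains assembled from different samples) are
collapsed into clusters.  Similarity between two genomes is the fraction of
one genome's length covered by alignment blocks at >=98% nucleotide
identity; genomes are grouped by single-linkage at >50% similarity, and one
representative per cluster is chosen by maximizing

    score = n_single_copy_genes_found - 2 * n_multi_copy

with ties broken by total nucleotide length, then lexicographic genome id.

An alignment-free k-mer containment estimator is provided as an internal
similarity proxy so pipelines and tests need no external aligner; for a
strain at per-base substitution rate d the expected containment of
canonical k-mers is approximately (1-d)^k.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .completeness import SCGProfile
from .formats_io import AlignmentBlock, GenomeBin, ValidationError

__all__ = [
    "SimilarityEdge",
    "GenomeCluster",
    "pairwise_similarity",
    "kmer_profile",
    "estimate_similarity_kmer",
    "pairwise_kmer_similarity",
    "cluster_genomes",
    "choose_representative",
    "dereplicate",
    "write_cluster_report",
]

BLOCK_IDENTITY_MIN = 0.98  # per-block identity floor ("98% or greater")


@dataclass(frozen=True)
class SimilarityEdge:
    """Directed similarity between two genomes, both directions reported.

    ``similarity_ab`` is the fraction of genome_a's length covered by
    qualifying alignment (or the containment of a's k-mers in b);
    ``similarity_ba`` the converse.
    """

    genome_a: str
    genome_b: str
    similarity_ab: float
    similarity_ba: float

    def __post_init__(self) -> None:
        for v in (self.similarity_ab, self.similarity_ba):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(
                    f"similarity {self.genome_a}/{self.genome_b}: {v} outside [0,1]"
                )

    @property
    def max_similarity(self) -> float:
        return max(self.similarity_ab, self.similarity_ba)


@dataclass
class GenomeCluster:
    cluster_id: str
    members: frozenset[str]
    representative: str | None = None

    def __post_init__(self) -> None:
        if self.representative is not None and self.representative not in self.members:
            raise ValidationError(
                f"{self.cluster_id}: representative {self.representative!r} not a member"
            )


# ---------------------------------------------------------------------------
# similarity from alignment blocks
# ---------------------------------------------------------------------------


def pairwise_similarity(
    blocks: Iterable[AlignmentBlock],
    genome_lengths: Mapping[str, int],
    min_block_identity: float = BLOCK_IDENTITY_MIN,
) -> list[SimilarityEdge]:
    """Directed aligned-fraction similarity per genome pair.

    For each ordered pair, sums aligned_length over blocks whose identity is
    >= ``min_block_identity`` (applied per block, not to a genome-wide
    average), divides by the query genome's length and caps at 1.
    """
    aligned: dict[tuple[str, str], int] = {}
    for b in blocks:
        for g in (b.query_genome, b.target_genome):
            if g not in genome_lengths:
                raise ValidationError(f"alignment block names unknown genome {g!r}")
        if b.query_genome == b.target_genome:
            continue
        if b.identity >= min_block_identity:
            key = (b.query_genome, b.target_genome)
            aligned[key] = aligned.get(key, 0) + b.aligned_length

    pairs = sorted({tuple(sorted(k)) for k in aligned})
    edges = []
    for a, b in pairs:
        sim_ab = min(1.0, aligned.get((a, b), 0) / genome_lengths[a])
        sim_ba = min(1.0, aligned.get((b, a), 0) / genome_lengths[b])
        edges.append(SimilarityEdge(a, b, sim_ab, sim_ba))
    return edges


# ---------------------------------------------------------------------------
# k-mer containment proxy
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G


def _encode_kmers(sequence: str, k: int) -> np.ndarray:
    """Canonical k-mers of one sequence as sorted unique 2-bit-packed ints."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes >= 0
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    rev = np.zeros(n - k + 1, dtype=np.uint64)
    ok = np.ones(n - k + 1, dtype=bool)
    comp = np.where(valid, _COMP[np.clip(codes, 0, 3)], 0)
    fcodes = np.where(valid, codes, 0).astype(np.uint64)
    ccodes = comp.astype(np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | fcodes[i : n - k + 1 + i]
        rev = rev | (ccodes[i : n - k + 1 + i] << np.uint64(2 * i))
        ok &= valid[i : n - k + 1 + i]
    canon = np.minimum(fwd, rev)[ok]
    return np.unique(canon)


def kmer_profile(bin: GenomeBin, k: int = 21) -> np.ndarray:
    """Sorted unique canonical k-mer codes over all scaffolds of a bin."""
    if k < 11:
        raise ValidationError("k must be >= 11 (shorter k-mers match spuriously)")
    if k > 31:
        raise ValidationError("k must be <= 31 (2-bit packing into 64 bits)")
    parts = [_encode_kmers(s.sequence, k) for s in bin.scaffolds]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def estimate_similarity_kmer(
    bin_a: GenomeBin, bin_b: GenomeBin, k: int = 21
) -> SimilarityEdge:
    """Similarity proxy: containment of canonical k-mer sets, both directions.

    For identical genomes this is 1; for unrelated sequence it is ~0; for a
    strain pair at substitution rate d it concentrates around (1-d)^k.
    """
    ka, kb = kmer_profile(bin_a, k), kmer_profile(bin_b, k)
    if ka.size == 0 or kb.size == 0:
        raise ValidationError("both genomes must be non-empty")
    shared = np.intersect1d(ka, kb, assume_unique=True).size
    return SimilarityEdge(bin_a.genome_id, bin_b.genome_id, shared / ka.size, shared / kb.size)


def pairwise_kmer_similarity(
    bins: Sequence[GenomeBin], k: int = 21, min_report: float = 0.0
) -> list[SimilarityEdge]:
    """k-mer containment for every genome pair (profiles computed once)."""
    profiles = {b.genome_id: kmer_profile(b, k) for b in bins}
    for gid, prof in profiles.items():
        if prof.size == 0:
            raise ValidationError(f"genome {gid} has no valid {k}-mers")
    ids = [b.genome_id for b in bins]
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = np.intersect1d(
                profiles[a], profiles[b], assume_unique=True
            ).size
            edge = SimilarityEdge(
                a, b, shared / profiles[a].size, shared / profiles[b].size
            )
            if edge.max_similarity >= min_report:
                edges.append(edge)
    return edges


# ---------------------------------------------------------------------------
# clustering and representatives
# ---------------------------------------------------------------------------


def cluster_genomes(
    edges: Iterable[SimilarityEdge],
    genome_ids: Iterable[str] | None = None,
    grouping_threshold: float = 0.50,
) -> list[GenomeCluster]:
    """Single-linkage grouping at strictly > ``grouping_threshold`` similarity.

    Two genomes join when max(similarity_ab, similarity_ba) exceeds the
    threshold; connected components of that graph are the clusters.  Genomes
    named in ``genome_ids`` but in no qualifying edge become singletons.
    Output is deterministic: clusters ordered by their smallest member id.
    """
    graph = nx.Graph()
    for e in edges:
        graph.add_node(e.genome_a)
        graph.add_node(e.genome_b)
        if e.max_similarity > grouping_threshold:
            graph.add_edge(e.genome_a, e.genome_b)
    if genome_ids is not None:
        graph.add_nodes_from(genome_ids)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)), key=min
    )
    width = max(3, len(str(len(components))))
    return [
        GenomeCluster(f"cluster_{i:0{width}d}", members)
        for i, members in enumerate(components, start=1)
    ]


def choose_representative(
    cluster: GenomeCluster,
    profiles: Mapping[str, SCGProfile],
    genome_lengths: Mapping[str, int],
) -> GenomeCluster:
    """Pick the cluster representative: best score, then longest, then id.

    The score is the SCG-based `found - 2*multi`; a score tie goes to the
    genome with the greatest nucleotide information (total bp), and any
    remaining tie to the lexicographically smallest genome id so the choice
    is deterministic.
    """
    for g in cluster.members:
        if g not in profiles:
            raise ValidationError(f"{cluster.cluster_id}: no SCG profile for {g!r}")
        if g not in genome_lengths:
            raise ValidationError(f"{cluster.cluster_id}: no length for {g!r}")
    best = min(
        sorted(cluster.members),
        key=lambda g: (-profiles[g].score, -genome_lengths[g], g),
    )
    return GenomeCluster(cluster.cluster_id, cluster.members, best)


def dereplicate(
    edges: Iterable[SimilarityEdge],
    profiles: Mapping[str, SCGProfile],
    genome_lengths: Mapping[str, int],
    grouping_threshold: float = 0.50,
) -> list[GenomeCluster]:
    """Cluster all profiled genomes and choose a representative for each."""
    clusters = cluster_genomes(edges, genome_ids=profiles.keys(),
                               grouping_threshold=grouping_threshold)
    return [choose_representative(c, profiles, genome_lengths) for c in clusters]


def write_cluster_report(
    clusters: Sequence[GenomeCluster],
    profiles: Mapping[str, SCGProfile],
    genome_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """TSV report: cluster_id, member, is_representative, score, length."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember\tis_representative\tscore\tlength\n")
        for c in clusters:
            for g in sorted(c.members):
                fh.write(
                    f"{c.cluster_id}\t{g}\t{int(g == c.representative)}\t"
                    f"{profiles[g].score}\t{genome_lengths[g]}\n"
                )
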