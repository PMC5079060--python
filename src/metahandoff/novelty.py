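"""Three-condition test for proposing a new phylum-level lineage.

A lineage qualifies as a candidate novel phylum when (1) its 16S rRNA genes
share less than ~75% pairwise identity with every known phylum-level
reference, (2) it is monophyletic in both the 16S (SSU) tree and the
concatenated ribosomal-protein (RP) tree, and (3) at least one member has a
high-quality (completeness-filtered) genome.  Trees arrive as newick,
alignments as aligned FASTA; tree inference itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .completeness import SCGProfile
from .formats_io import ValidationError

__all__ = [
    "NoveltyCall",
    "pairwise_identity",
    "filter_gap_columns",
    "is_monophyletic",
    "assess_novelty",
    "write_novelty_table",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class NoveltyCall:
    lineage_id: str
    member_genomes: frozenset[str]
    max_identity_to_known: float | None
    ssu_monophyletic: bool | None
    rp_monophyletic: bool | None
    has_quality_genome: bool
    verdict: str  # novel | not_novel | insufficient_data

    def __post_init__(self) -> None:
        if self.verdict not in ("novel", "not_novel", "insufficient_data"):
            raise ValidationError(f"{self.lineage_id}: bad verdict {self.verdict!r}")


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Identity between two rows of one multiple alignment.

    matches / columns where at least one row has a base: columns where both
    rows are gaps are ignored, columns where exactly one is a gap count as
    mismatch (penalizing indels without rewarding missing data).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError(
            f"aligned rows differ in length ({len(aligned_a)} vs {len(aligned_b)})"
        )
    matches = 0
    compared = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        gap_x, gap_y = x in GAP_CHARS, y in GAP_CHARS
        if gap_x and gap_y:
            continue
        compared += 1
        if not gap_x and not gap_y and x == y:
            matches += 1
    if compared == 0:
        raise ValidationError("no comparable columns (all dual-gap)")
    return matches / compared


def filter_gap_columns(
    alignment: Mapping[str, str], max_gap_fraction: float = 0.97
) -> dict[str, str]:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    Common pre-tree column filtering (e.g. drop columns with >97% gaps for
    protein alignments, >95% for 16S); the threshold is a knob.
    """
    if not alignment:
        return {}
    rows = list(alignment.values())
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValidationError("alignment rows differ in length")
    n = len(rows)
    keep = [
        i
        for i in range(length)
        if sum(r[i] in GAP_CHARS for r in rows) / n <= max_gap_fraction
    ]
    return {name: "".join(row[i] for i in keep) for name, row in alignment.items()}


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree | str, taxa: Iterable[str]) -> bool:
    """True iff some edge of the tree separates exactly ``taxa`` from the rest.

    Accepts a dendropy Tree or a newick string.  The test is split-based, so
    it is invariant to leaf order and to rerooting on any edge outside the
    group; on an unrooted tree it asks whether the taxa form one side of
    some bipartition.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    taxa = set(taxa)
    if not taxa:
        raise ValidationError("empty taxon set")
    leaves = _leaf_labels(tree)
    missing = sorted(taxa - leaves)
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")
    if taxa == leaves:
        return True
    # leaf set under every internal edge (clades of the tree as rooted),
    # plus complements to cover the unrooted interpretation
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            clade = {node.taxon.label}
        else:
            clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        if clade == taxa or leaves - clade == taxa:
            return True
    return False


def assess_novelty(
    lineage_id: str,
    members: Iterable[str],
    identity_to_references: Mapping[str, Mapping[str, float]] | pd.DataFrame | None,
    ssu_tree: dendropy.Tree | str | None,
    rp_tree: dendropy.Tree | str | None,
    profiles: Mapping[str, SCGProfile],
    identity_threshold: float = 0.75,
    completeness_threshold: float = 0.70,
) -> NoveltyCall:
    """Apply the three novelty conditions to one candidate lineage.

    ``identity_to_references``: per member with a 16S sequence, identities
    against known-phylum references (members without 16S may be absent —
    16S genes often cannot be linked to every genome).  A condition whose
    input is missing (no member with 16S, or a tree lacking the members)
    yields verdict ``insufficient_data``.
    """
    members = frozenset(members)
    if not members:
        raise ValidationError("lineage has no members")

    has_quality = any(
        g in profiles and profiles[g].completeness > completeness_threshold
        for g in members
    )

    max_identity: float | None = None
    if identity_to_references is not None:
        if isinstance(identity_to_references, pd.DataFrame):
            rows = {
                g: identity_to_references.loc[g]
                for g in members
                if g in identity_to_references.index
            }
            values = [v for row in rows.values() for v in row.dropna()]
        else:
            values = [
                v
                for g in members
                if g in identity_to_references
                for v in dict(identity_to_references[g]).values()
            ]
        if values:
            if not all(0.0 <= v <= 1.0 for v in values):
                raise ValidationError("identities must be fractions in [0, 1]")
            max_identity = max(values)

    def _mono(tree):
        if tree is None:
            return None
        try:
            return is_monophyletic(tree, members)
        except ValidationError:
            return None  # members missing from the tree -> insufficient data

    ssu_mono = _mono(ssu_tree)
    rp_mono = _mono(rp_tree)

    if max_identity is None or ssu_mono is None or rp_mono is None:
        verdict = "insufficient_data"
    elif (
        max_identity < identity_threshold
        and ssu_mono
        and rp_mono
        and has_quality
    ):
        verdict = "novel"
    else:
        verdict = "not_novel"
    return NoveltyCall(
        lineage_id, members, max_identity, ssu_mono, rp_mono, has_quality, verdict
    )


def write_novelty_table(calls: Sequence[NoveltyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "lineage_id\tn_members\tmax_identity_to_known\tssu_monophyletic\t"
            "rp_monophyletic\thas_quality_genome\tverdict\n"
        )
        for c in calls:
            ident = "" if c.max_identity_to_known is None else f"{c.max_identity_to_known:.6g}"
            ssu = "" if c.ssu_monophyletic is None else int(c.ssu_monophyletic)
            rp = "" if c.rp_monophyletic is None else int(c.rp_monophyletic)
            fh.write(
                f"{c.lineage_id}\t{len(c.member_genomes)}\t{ident}\t{ssu}\t{rp}\t"
                f"{int(c.has_quality_genome)}\t{c.verdict}\n"
            )
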