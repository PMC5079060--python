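"""Genome coverage and community relative abundance.

Per-scaffold mean read depths are combined into genome coverage as a
length-weighted mean; coverage can be normalized for sequencing-depth
differences against a reference sample, converted to within-sample relative
abundance, and summarized as rank-abundance lists with a coverage cap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import CoverageRecord, GenomeBin, ValidationError

__all__ = [
    "scaffold_index",
    "genome_coverage",
    "normalize_by_reads",
    "relative_abundance",
    "rank_abundance",
]


def scaffold_index(bins: Iterable[GenomeBin]) -> dict[str, tuple[str, int]]:
    """Map scaffold_id -> (genome_id, length) over a set of bins."""
    index: dict[str, tuple[str, int]] = {}
    for b in bins:
        for s in b.scaffolds:
            if s.scaffold_id in index:
                raise ValidationError(
                    f"scaffold {s.scaffold_id!r} appears in more than one bin"
                )
            index[s.scaffold_id] = (b.genome_id, s.length)
    return index


def genome_coverage(
    records: Iterable[CoverageRecord],
    scaffolds: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Genome x sample coverage as the length-weighted mean of scaffold depths.

    ``scaffolds`` maps scaffold_id -> (genome_id, length), see
    :func:`scaffold_index`.  Scaffolds of a genome missing from a sample's
    records count as depth 0 (they still carry their length weight).
    A record naming a scaffold not in the index is an error.
    """
    records = list(records)
    orphans = sorted({r.scaffold_id for r in records if r.scaffold_id not in scaffolds})
    if orphans:
        raise ValidationError(f"coverage records name unknown scaffolds: {orphans}")

    genome_length: dict[str, int] = {}
    for _sid, (gid, length) in scaffolds.items():
        genome_length[gid] = genome_length.get(gid, 0) + length

    samples = sorted({r.sample_id for r in records})
    genomes = sorted(genome_length)
    depth_sum = pd.DataFrame(0.0, index=genomes, columns=samples)
    for r in records:
        gid, length = scaffolds[r.scaffold_id]
        depth_sum.at[gid, r.sample_id] += r.mean_depth * length
    return depth_sum.div(pd.Series(genome_length), axis=0)


def normalize_by_reads(
    table: pd.DataFrame,
    sample_read_counts: Mapping[str, float],
    reference_sample: str,
) -> pd.DataFrame:
    """Normalize coverage for read-count differences between samples.

    normalized = coverage * reads(reference) / reads(sample); the reference
    sample maps onto itself.  Doubling every read count leaves the result
    unchanged.
    """
    if reference_sample not in table.columns:
        raise ValidationError(f"reference sample {reference_sample!r} not in table")
    factors = {}
    for sample in table.columns:
        reads = sample_read_counts.get(sample)
        if reads is None:
            raise ValidationError(f"no read count for sample {sample!r}")
        if reads <= 0:
            raise ValidationError(f"sample {sample!r}: read count must be > 0")
        factors[sample] = sample_read_counts[reference_sample] / reads
    return table.mul(pd.Series(factors), axis=1)


def relative_abundance(
    table: pd.DataFrame,
    sample: str,
    denominator_inflation: float = 1.0,
) -> pd.Series:
    """Per-genome fraction of the (binned) community in one sample.

    ``denominator_inflation`` >= 1 lets the caller account for the unbinned
    community fraction (e.g. a marker-gene-derived estimate of total
    organisms): fractions then sum to 1/denominator_inflation.
    """
    if sample not in table.columns:
        raise ValidationError(f"sample {sample!r} not in table")
    if denominator_inflation < 1.0:
        raise ValidationError("denominator_inflation must be >= 1")
    col = table[sample]
    total = col.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample!r}: total coverage is zero")
    return col / (total * denominator_inflation)


def rank_abundance(
    table: pd.DataFrame, sample: str, cap: float = 500.0
) -> pd.DataFrame:
    """Descending rank-abundance list, excluding coverage above ``cap``.

    Extremely high-coverage genomes (> cap, default 500x) are excluded, the
    convention for keeping rank-abundance plots readable.  Ties keep stable
    input order.  Columns: rank, genome_id, coverage.
    """
    if sample not in table.columns:
        raise ValidationError(f"sample {sample!r} not in table")
    col = table[sample]
    kept = col[col <= cap]
    ordered = kept.sort_values(ascending=False, kind="stable")
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "genome_id": ordered.index,
            "coverage": ordered.values,
        }
    )
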