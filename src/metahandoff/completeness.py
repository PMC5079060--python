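"""Single-copy-gene completeness estimation and the dereplication score.

A genome bin's completeness is estimated as the fraction of a universal
single-copy gene (SCG) set detected in the bin: 43 markers for bacteria,
38 for archaea by default (editable YAML configs under ``data/``).  Markers
found in more than one copy hint at contamination and are penalized by the
dereplication score

    score = n_found - 2 * n_multi

which downstream cluster-representative selection maximizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .formats_io import HmmHit, MarkerConfig, ValidationError, read_marker_config

__all__ = [
    "SCGProfile",
    "default_scg_config",
    "inventory_scgs",
    "filter_by_completeness",
    "write_scg_report",
    "read_scg_report",
]


@dataclass(frozen=True)
class SCGProfile:
    """Single-copy-gene inventory of one genome.

    ``found`` holds markers seen at least once above their cutoff, ``multi``
    those seen at least twice.  ``completeness`` = |found| / |expected|;
    ``score`` = |found| - 2 |multi| (integer, may be negative).
    """

    genome_id: str
    domain: str
    expected_set: frozenset[str]
    found: frozenset[str]
    multi: frozenset[str]

    def __post_init__(self) -> None:
        if self.domain not in ("bacteria", "archaea"):
            raise ValidationError(f"{self.genome_id}: domain must be bacteria|archaea")
        if not self.multi <= self.found:
            raise ValidationError(f"{self.genome_id}: multi set not within found set")
        if not self.found <= self.expected_set:
            extra = sorted(self.found - self.expected_set)
            raise ValidationError(
                f"{self.genome_id}: markers outside expected set: {extra}"
            )

    @property
    def completeness(self) -> float:
        if not self.expected_set:
            return 0.0
        return len(self.found) / len(self.expected_set)

    @property
    def score(self) -> int:
        return len(self.found) - 2 * len(self.multi)


def default_scg_config(domain: str) -> MarkerConfig:
    """The shipped default SCG marker config for ``bacteria`` or ``archaea``."""
    name = {"bacteria": "scg_bacteria.yaml", "archaea": "scg_archaea.yaml"}.get(domain)
    if name is None:
        raise ValidationError("domain must be 'bacteria' or 'archaea'")
    with resources.as_file(resources.files("metahandoff.data") / name) as path:
        return read_marker_config(path)


def inventory_scgs(
    hits: Iterable[HmmHit],
    scg_config: MarkerConfig | None = None,
    domain: str = "unknown",
    genome_id: str | None = None,
) -> SCGProfile:
    """Build the SCG profile of one genome from its HMM hits.

    Only hits whose model appears in ``scg_config`` and whose bitscore
    reaches the model's cutoff are counted.  Copy number per marker is the
    number of distinct genes hitting it.  ``domain`` selects the expected
    marker set; with no usable domain the caller must supply one.
    """
    if domain not in ("bacteria", "archaea"):
        raise ValidationError(
            "domain is 'unknown': set domain='bacteria' or 'archaea' "
            "(the expected SCG set differs between the two)"
        )
    config = scg_config if scg_config is not None else default_scg_config(domain)
    cutoffs = config.cutoffs
    model_to_marker = config.model_to_marker

    hits = list(hits)
    genomes = {h.genome_id for h in hits}
    if genome_id is None:
        if len(genomes) > 1:
            raise ValidationError(
                f"hits span several genomes ({sorted(genomes)}); pass genome_id"
            )
        genome_id = next(iter(genomes)) if genomes else "unknown"

    genes_per_marker: dict[str, set[str]] = {}
    for h in hits:
        cutoff = cutoffs.get(h.model_name)
        if cutoff is None or h.bitscore < cutoff:
            continue
        marker = model_to_marker[h.model_name]
        genes_per_marker.setdefault(marker, set()).add(h.gene_id)

    expected = frozenset(config.marker_ids)
    found = frozenset(m for m in genes_per_marker if m in expected)
    multi = frozenset(m for m in found if len(genes_per_marker[m]) >= 2)
    return SCGProfile(genome_id, domain, expected, found, multi)


def filter_by_completeness(
    profiles: Iterable[SCGProfile], threshold: float = 0.70
) -> list[str]:
    """Genome ids whose completeness is strictly greater than ``threshold``.

    The default reproduces the conventional inclusion filter of keeping
    bins with an initial completeness estimate above 70%.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must be within [0, 1]")
    return [p.genome_id for p in profiles if p.completeness > threshold]


# -- TSV report (genome_id, domain, n_found, n_multi, completeness, score) --


def write_scg_report(profiles: Sequence[SCGProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tdomain\tn_found\tn_multi\tcompleteness\tscore\n")
        for p in profiles:
            fh.write(
                f"{p.genome_id}\t{p.domain}\t{len(p.found)}\t{len(p.multi)}\t"
                f"{p.completeness:.6g}\t{p.score}\n"
            )


def read_scg_report(path: str | Path) -> "list[dict]":
    """Read back a completeness report as a list of plain dict rows.

    Accepts the report this package writes and, more loosely, any TSV with
    at least ``genome_id`` and ``completeness`` columns (so externally
    produced SCG tables can be summarized).
    """
    import csv

    rows: list[dict] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "completeness" not in reader.fieldnames:
            raise ValidationError(f"{path}: no 'completeness' column")
        for row in reader:
            row["completeness"] = float(row["completeness"])
            if "score" in row and row["score"] not in (None, ""):
                row["score"] = int(row["score"])
            rows.append(row)
    return rows
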