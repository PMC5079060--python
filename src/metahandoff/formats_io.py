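"""Readers, writers and shared domain records.

All external formats the pipeline touches go through this module: nucleotide
and protein FASTA (via Biopython), hmmscan ``--tblout`` tables, TSV coverage
tables, show-coords-style alignment-block TSVs, and YAML marker
configurations.  Coordinates are 1-based inclusive throughout, matching
common gene-call output.

Protein FASTA headers carry ``genomeid|scaffoldid|start|end|strand`` so the
gene <-> scaffold linkage survives a FASTA round trip; the same string is the
gene identifier used in hit tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ValidationError",
    "Gene",
    "Scaffold",
    "GenomeBin",
    "HmmHit",
    "CoverageRecord",
    "AlignmentBlock",
    "MarkerConfig",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_hmm_table",
    "write_hmm_table",
    "read_coverage_table",
    "write_coverage_table",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "read_marker_config",
    "write_marker_config",
]


class FormatError(ValueError):
    """A file violates its expected format; message locates the offence."""


class ValidationError(ValueError):
    """An in-memory record violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scaffold:
    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """A predicted gene; coordinates 1-based inclusive on its scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 1 <= start <= end, got "
                f"{self.start}..{self.end}"
            )


@dataclass
class GenomeBin:
    """One organism's scaffolds plus predicted genes.

    The unit of every downstream analysis.  ``domain_hint`` records whether
    the bin is believed bacterial or archaeal (which single-copy marker set
    applies); ``unknown`` forces the caller to decide before completeness
    estimation.
    """

    genome_id: str
    scaffolds: list[Scaffold] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)
    domain_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.domain_hint not in ("bacteria", "archaea", "unknown"):
            raise ValidationError(
                f"{self.genome_id}: domain_hint must be bacteria|archaea|unknown"
            )
        ids = [s.scaffold_id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(
                f"{self.genome_id}: duplicate scaffold id {dup!r}"
            )
        lengths = {s.scaffold_id: s.length for s in self.scaffolds}
        for g in self.genes:
            if g.scaffold_id not in lengths:
                raise ValidationError(
                    f"{self.genome_id}: gene {g.gene_id} references unknown "
                    f"scaffold {g.scaffold_id!r}"
                )
            if g.end > lengths[g.scaffold_id]:
                raise ValidationError(
                    f"{self.genome_id}: gene {g.gene_id} ends at {g.end} beyond "
                    f"scaffold {g.scaffold_id} length {lengths[g.scaffold_id]}"
                )

    @property
    def length(self) -> int:
        """Total nucleotide length (sum over scaffolds)."""
        return sum(s.length for s in self.scaffolds)

    def scaffold_lengths(self) -> dict[str, int]:
        return {s.scaffold_id: s.length for s in self.scaffolds}


@dataclass(frozen=True)
class HmmHit:
    """One hmmscan hit of a gene against a profile HMM."""

    gene_id: str
    model_name: str
    bitscore: float
    evalue: float
    genome_id: str

    def __post_init__(self) -> None:
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValidationError(f"hit {self.gene_id}/{self.model_name}: bitscore not finite")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.gene_id}/{self.model_name}: evalue < 0")


@dataclass(frozen=True)
class CoverageRecord:
    """Mean read depth of one scaffold in one sample."""

    scaffold_id: str
    genome_id: str
    sample_id: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValidationError(
                f"coverage of {self.scaffold_id} in {self.sample_id}: negative depth"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """One nucleotide alignment block between two genomes (NUCmer-style)."""

    query_genome: str
    target_genome: str
    aligned_length: int
    identity: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.aligned_length < 0:
            raise ValidationError("alignment block: negative aligned_length")
        if not (0.0 <= self.identity <= 1.0):
            raise ValidationError(
                f"alignment block {self.query_genome}->{self.target_genome}: "
                f"identity {self.identity} outside [0, 1]"
            )


@dataclass
class MarkerConfig:
    """Per-HMM bitscore cutoffs and the marker id each model reports.

    entries: list of (model_name, cutoff_bits, marker_id).  One cutoff per
    model.  The study determined cutoffs per model by manual inspection;
    here they are plain configuration.
    """

    entries: list[tuple[str, float, str]]
    source: str = "default"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for model, cutoff, _marker in self.entries:
            if model in seen:
                raise ValidationError(f"duplicate cutoff for model {model!r}")
            if not (cutoff == cutoff and abs(cutoff) != float("inf")):
                raise ValidationError(f"cutoff for model {model!r} not finite")
            seen.add(model)

    @property
    def cutoffs(self) -> dict[str, float]:
        return {m: c for m, c, _ in self.entries}

    @property
    def model_to_marker(self) -> dict[str, str]:
        return {m: k for m, _, k in self.entries}

    @property
    def marker_ids(self) -> set[str]:
        return {k for _, _, k in self.entries}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_gene_header(header: str) -> Gene:
    parts = header.split("|")
    if len(parts) != 5:
        raise FormatError(
            f"protein header {header!r}: expected genome|scaffold|start|end|strand"
        )
    genome, scaffold, start, end, strand = parts
    try:
        return Gene(
            gene_id=header,
            scaffold_id=scaffold,
            start=int(start),
            end=int(end),
            strand=strand,
        )
    except ValueError as exc:
        raise FormatError(f"protein header {header!r}: {exc}") from exc


def read_genome_fasta(
    path: str | Path,
    genome_id: str,
    proteins_path: str | Path | None = None,
    domain_hint: str = "unknown",
) -> GenomeBin:
    """Read a genome bin from a nucleotide FASTA, optionally with proteins.

    The protein FASTA, if given, must use ``genome|scaffold|start|end|strand``
    headers (the dialect this package writes).
    """
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate scaffold header {rec.id!r}")
        seen.add(rec.id)
        scaffolds.append(Scaffold(rec.id, str(rec.seq).upper()))
    if not scaffolds:
        raise FormatError(f"{path}: empty or not FASTA")

    genes: list[Gene] = []
    if proteins_path is not None:
        for rec in SeqIO.parse(str(proteins_path), "fasta"):
            gene = _parse_gene_header(rec.id)
            genes.append(dataclasses.replace(gene, protein=str(rec.seq)))
    return GenomeBin(genome_id, scaffolds, genes, domain_hint)


def write_genome_fasta(
    bin: GenomeBin,
    path: str | Path,
    proteins_path: str | Path | None = None,
    line_width: int = 80,
) -> None:
    """Write scaffolds to FASTA; optionally write genes to a protein FASTA."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.scaffold_id, description="")
        for s in bin.scaffolds
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
    if proteins_path is not None:
        precs = [
            SeqRecord(Seq(g.protein), id=g.gene_id, description="")
            for g in bin.genes
        ]
        with open(proteins_path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(precs)


# ---------------------------------------------------------------------------
# hmmscan tblout
# ---------------------------------------------------------------------------

_TBLOUT_HEADER = (
    "#{:<29s} {:<10s} {:<29s} {:<10s} {:>9s} {:>6s} {:>5s} {:>9s} {:>6s} {:>5s} "
    "{:>5s} {:>3s} {:>3s} {:>3s} {:>3s} {:>3s} {:>3s} {:>3s} {:s}".format(
        " target name", "accession", "query name", "accession", "E-value",
        "score", "bias", "E-value", "score", "bias", "exp", "reg", "clu",
        "ov", "env", "dom", "rep", "inc", "description of target",
    )
)


def genome_of_gene(gene_id: str) -> str:
    """Genome id encoded as the first ``|``-separated field of a gene id."""
    return gene_id.split("|", 1)[0]


def read_hmm_table(path: str | Path) -> list[HmmHit]:
    """Parse hmmscan per-sequence tabular output (``--tblout`` dialect).

    Whitespace-separated, ``#`` comment lines skipped.  The target (column 1)
    is the model, the query (column 3) the gene; the *full-sequence* bitscore
    (column 6) is the score compared against cutoffs downstream, not the
    best-domain score.
    """
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 18:
                raise FormatError(
                    f"{path}:{lineno}: expected >=18 tblout columns, got {len(fields)}"
                )
            model, gene = fields[0], fields[2]
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field ({exc})")
            hits.append(HmmHit(gene, model, score, evalue, genome_of_gene(gene)))
    return hits


def write_hmm_table(hits: Iterable[HmmHit], path: str | Path) -> None:
    """Write hits in hmmscan ``--tblout`` layout (19 columns, '#' header)."""
    with open(path, "w") as fh:
        fh.write(_TBLOUT_HEADER + "\n")
        for h in hits:
            fh.write(
                f"{h.model_name:<30s} {'-':<10s} {h.gene_id:<30s} {'-':<10s} "
                f"{h.evalue:9.3g} {h.bitscore:6.1f} {0.0:5.1f} "
                f"{h.evalue:9.3g} {h.bitscore:6.1f} {0.0:5.1f} "
                f"{1.0:5.1f} {1:>3d} {0:>3d} {0:>3d} {1:>3d} {1:>3d} {1:>3d} {1:>3d} -\n"
            )


# ---------------------------------------------------------------------------
# coverage TSV
# ---------------------------------------------------------------------------

_COVERAGE_COLUMNS = ["scaffold_id", "genome_id", "sample_id", "mean_depth"]


def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a coverage TSV with header scaffold_id, genome_id, sample_id, mean_depth."""
    records: list[CoverageRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COVERAGE_COLUMNS:
            raise FormatError(
                f"{path}: expected columns {_COVERAGE_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                depth = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed depth ({exc})")
            try:
                records.append(CoverageRecord(fields[0], fields[1], fields[2], depth))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_coverage_table(records: Iterable[CoverageRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COVERAGE_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.scaffold_id}\t{r.genome_id}\t{r.sample_id}\t{r.mean_depth:.6g}\n")


# ---------------------------------------------------------------------------
# alignment blocks (show-coords-style)
# ---------------------------------------------------------------------------


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read a show-coords-style TSV: query, target, aligned_length, %identity.

    Percent identity in [0, 100] is converted to a fraction.  A header line
    starting with ``query`` is tolerated.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if lineno == 1 and fields[0].lower() in ("query", "query_genome"):
                continue
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                length = int(fields[2])
                pct = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field ({exc})")
            if not (0.0 <= pct <= 100.0):
                raise FormatError(
                    f"{path}:{lineno}: identity {pct} outside [0, 100]"
                )
            try:
                blocks.append(AlignmentBlock(fields[0], fields[1], length, pct / 100.0))
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return blocks


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_genome\ttarget_genome\taligned_length\tpct_identity\n")
        for b in blocks:
            fh.write(
                f"{b.query_genome}\t{b.target_genome}\t{b.aligned_length}\t"
                f"{100.0 * b.identity:.6g}\n"
            )


# ---------------------------------------------------------------------------
# marker config YAML
# ---------------------------------------------------------------------------


def read_marker_config(path: str | Path) -> MarkerConfig:
    """Load a YAML marker config: list of {model, cutoff, marker} mappings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "markers" not in doc:
        raise FormatError(f"{path}: expected a mapping with a 'markers' list")
    entries: list[tuple[str, float, str]] = []
    for i, item in enumerate(doc["markers"]):
        try:
            entries.append(
                (str(item["model"]), float(item["cutoff"]), str(item.get("marker", item["model"])))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: markers[{i}]: {exc}") from exc
    try:
        return MarkerConfig(entries, source=str(doc.get("source", "user")))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_marker_config(config: MarkerConfig, path: str | Path) -> None:
    doc = {
        "source": config.source,
        "markers": [
            {"model": m, "cutoff": float(c), "marker": k} for m, c, k in config.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
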