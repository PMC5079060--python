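"""End-to-end orchestration: simulate/load -> profile -> dereplicate ->
traits -> abundance -> handoff -> report, with a reproducible manifest.

Each stage writes its tabular output into the run directory and records a
row-count line in the manifest; any stage error aborts the run with the
stage name and cause, leaving partial outputs suffixed ``.partial``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .abundance import genome_coverage, normalize_by_reads, relative_abundance, scaffold_index
from .completeness import (
    default_scg_config,
    filter_by_completeness,
    inventory_scgs,
    write_scg_report,
)
from .dereplication import dereplicate, pairwise_kmer_similarity, write_cluster_report
from .formats_io import (
    MarkerConfig,
    ValidationError,
    read_coverage_table,
    read_genome_fasta,
    read_hmm_table,
    read_marker_config,
)
from .handoff import (
    default_chains,
    incompleteness_null,
    load_chains,
    partition_by_windows,
    step_capability,
)
from .synthetic import CommunityScenario, scenario_presets, simulate_community
from .trait_calling import (
    call_traits,
    default_trait_marker_config,
    default_trait_rules,
    load_trait_rules,
    markers_by_genome,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "report"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and the seed of one pipeline run.

    Either ``simulate_preset`` (a named synthetic scenario) or the three
    input paths (genome FASTA directory, hit table, coverage TSV) must be
    given.  Thresholds default to the conventional values: completeness
    filter 0.70, per-block identity 0.98, grouping 0.50, phylum identity
    0.75, handoff abundance floor 0.0001, rank-abundance cap 500x.
    """

    output_dir: str | Path = "metahandoff_run"
    simulate_preset: str | None = None
    genomes_dir: str | Path | None = None
    hits_path: str | Path | None = None
    coverage_path: str | Path | None = None
    scg_config_path: str | Path | None = None
    trait_rules_path: str | Path | None = None
    trait_config_path: str | Path | None = None
    chains_path: str | Path | None = None
    domain: str = "bacteria"
    completeness_threshold: float = 0.70
    block_identity: float = 0.98
    grouping_threshold: float = 0.50
    phylum_identity: float = 0.75
    min_abundance: float = 0.0001
    rank_cap: float = 500.0
    kmer_size: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("completeness_threshold", self.completeness_threshold, 0.0, 1.0),
            ("block_identity", self.block_identity, 0.5, 1.0),
            ("grouping_threshold", self.grouping_threshold, 0.0, 1.0),
            ("phylum_identity", self.phylum_identity, 0.0, 1.0),
            ("min_abundance", self.min_abundance, 0.0, 1.0),
        ):
            if not (lo <= value <= hi):
                raise ValidationError(f"{name}={value} outside [{lo}, {hi}]")
        if self.simulate_preset is None and (
            self.genomes_dir is None or self.hits_path is None
            or self.coverage_path is None
        ):
            raise ValidationError(
                "need simulate_preset or genomes_dir + hits_path + coverage_path"
            )

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in doc.items()}


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; return (and write) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": [],
    }

    def stage(name: str):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                partial = outdir / "manifest.json.partial"
                with open(partial, "w") as fh:
                    json.dump(manifest, fh, indent=2)
                raise StageError(name, exc) from exc
            elapsed = time.perf_counter() - t0
            entry = {"stage": name, "seconds": round(elapsed, 3), **counts}
            manifest["stages"].append(entry)
            logger.info("stage %-12s %s (%.2fs)", name, counts, elapsed)
            return entry

        return wrap

    state: dict = {}

    @stage("inputs")
    def _inputs():
        if config.simulate_preset is not None:
            scenario = scenario_presets(seed=config.seed)[config.simulate_preset]
            community = simulate_community(scenario)
            community.write(outdir / "simulated")
            state["bins"] = community.bins
            state["hits"] = community.hits
            state["coverage"] = community.coverage
        else:
            genomes_dir = Path(config.genomes_dir)
            bins = []
            for fna in sorted(genomes_dir.glob("*.fna")):
                faa = fna.with_suffix(".faa")
                bins.append(
                    read_genome_fasta(
                        fna, fna.stem,
                        proteins_path=faa if faa.exists() else None,
                        domain_hint=config.domain,
                    )
                )
            if not bins:
                raise ValidationError(f"no *.fna genomes under {genomes_dir}")
            state["bins"] = bins
            state["hits"] = read_hmm_table(config.hits_path)
            state["coverage"] = read_coverage_table(config.coverage_path)
        return {
            "genomes": len(state["bins"]),
            "hits": len(state["hits"]),
            "coverage_records": len(state["coverage"]),
        }

    @stage("completeness")
    def _completeness():
        scg_config = (
            read_marker_config(config.scg_config_path)
            if config.scg_config_path
            else default_scg_config(config.domain)
        )
        hits_by_genome: dict[str, list] = {}
        for h in state["hits"]:
            hits_by_genome.setdefault(h.genome_id, []).append(h)
        profiles = {
            b.genome_id: inventory_scgs(
                hits_by_genome.get(b.genome_id, []),
                scg_config,
                domain=config.domain,
                genome_id=b.genome_id,
            )
            for b in state["bins"]
        }
        state["profiles"] = profiles
        write_scg_report(list(profiles.values()), outdir / "scg_report.tsv")
        return {"profiles": len(profiles)}

    @stage("filter")
    def _filter():
        kept = filter_by_completeness(
            state["profiles"].values(), config.completeness_threshold
        )
        state["kept"] = set(kept)
        (outdir / "kept_genomes.txt").write_text("\n".join(sorted(kept)) + "\n")
        return {"kept": len(kept), "dropped": len(state["profiles"]) - len(kept)}

    @stage("dereplicate")
    def _dereplicate():
        kept_bins = [b for b in state["bins"] if b.genome_id in state["kept"]]
        lengths = {b.genome_id: b.length for b in kept_bins}
        edges = pairwise_kmer_similarity(kept_bins, k=config.kmer_size)
        profiles = {g: state["profiles"][g] for g in lengths}
        clusters = dereplicate(
            edges, profiles, lengths, grouping_threshold=config.grouping_threshold
        )
        state["clusters"] = clusters
        state["representatives"] = sorted(c.representative for c in clusters)
        write_cluster_report(clusters, profiles, lengths, outdir / "clusters.tsv")
        return {"clusters": len(clusters), "genomes": len(lengths)}

    @stage("traits")
    def _traits():
        if config.trait_rules_path:
            rules = load_trait_rules(config.trait_rules_path)
        else:
            rules = default_trait_rules()
        trait_config = (
            read_marker_config(config.trait_config_path)
            if config.trait_config_path
            else default_trait_marker_config()
        )
        reps = state["representatives"]
        genome_markers = markers_by_genome(state["hits"], trait_config)
        matrix = call_traits(genome_markers, rules, genome_ids=reps)
        state["matrix"] = matrix
        matrix.to_tsv(outdir / "traits.tsv")
        return {"genomes": len(matrix.genome_ids), "traits": len(matrix.trait_ids)}

    @stage("abundance")
    def _abundance():
        index = scaffold_index(state["bins"])
        table = genome_coverage(state["coverage"], index)
        table.to_csv(outdir / "coverage_raw.tsv", sep="\t", index_label="genome_id")
        reps = state["representatives"]
        rep_table = table.loc[reps]
        rel = pd.DataFrame(
            {s: relative_abundance(rep_table, s) for s in rep_table.columns}
        )
        rel.to_csv(outdir / "relative_abundance.tsv", sep="\t", index_label="genome_id")
        state["relative"] = rel
        return {"genomes": len(rep_table.index), "samples": len(rep_table.columns)}

    @stage("handoff")
    def _handoff():
        chains = (
            load_chains(config.chains_path) if config.chains_path else default_chains()
        )
        rel = state["relative"]
        mean_abundance = rel.mean(axis=1)
        results = {}
        for cid, chain in chains.items():
            caps = step_capability(state["matrix"], chain)
            summary = partition_by_windows(
                caps, mean_abundance, config.min_abundance, chain_id=cid
            )
            summary.to_tsv(outdir / f"handoff_{cid}.tsv")
            incapable = [
                (state["profiles"][g].completeness, 1)
                for g, row in caps.iterrows()
                if row.any() and not row.all()
            ]
            if incapable:
                null = incompleteness_null(
                    incapable,
                    completeness_floor=config.completeness_threshold,
                    conservative=True,
                )
                null.to_json(outdir / f"incompleteness_{cid}.json")
                results[cid] = {
                    "windows": len(summary.window_counts),
                    "complete": summary.complete_pathway_count,
                    "log10_p_null": round(null.log10_p, 3),
                }
            else:
                results[cid] = {
                    "windows": len(summary.window_counts),
                    "complete": summary.complete_pathway_count,
                }
        state["handoff"] = results
        return {"chains": len(chains)}

    @stage("report")
    def _report():
        text = report(outdir)
        (outdir / "report.txt").write_text(text)
        return {"lines": text.count("\n")}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report(outdir: str | Path) -> str:
    """Human-readable summary regenerated from saved pipeline outputs."""
    outdir = Path(outdir)
    lines: list[str] = ["metahandoff run summary", "======================="]
    traits_path = outdir / "traits.tsv"
    if traits_path.exists():
        matrix = pd.read_csv(traits_path, sep="\t", index_col=0)
        lines.append(f"\ngenomes analysed: {len(matrix.index)}")
        lines.append("\ntrait prevalence (count, fraction):")
        n = max(len(matrix.index), 1)
        for trait in matrix.columns:
            count = int(matrix[trait].sum())
            lines.append(f"  {trait:<38s} {count:4d}  {count / n:6.1%}")
    for handoff_tsv in sorted(outdir.glob("handoff_*.tsv")):
        chain = handoff_tsv.stem.removeprefix("handoff_")
        lines.append(f"\nstep windows, chain {chain} (organisms, abundance):")
        table = pd.read_csv(handoff_tsv, sep="\t")
        if table.empty:
            lines.append("  (no organisms above the abundance floor)")
        for _, row in table.iterrows():
            lines.append(
                f"  {row.start_step}->{row.end_step} ({row.n_steps} step(s)): "
                f"{row.organism_count:4d} organisms, "
                f"{row.total_relative_abundance:6.1%}"
            )
        null_json = outdir / f"incompleteness_{chain}.json"
        if null_json.exists():
            doc = json.loads(null_json.read_text())
            lines.append(
                f"  incompleteness null over {doc['n_organisms']} organisms: "
                f"log10 p = {doc['log10_p']:.1f}"
            )
    lines.append("")
    return "\n".join(lines)
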