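"""Synthetic aquifer-style communities with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a community of organism archetypes with known pathway-step
capabilities and accessory traits; strain clusters at a controlled
nucleotide divergence; independent gene dropout at a target completeness
(single-copy genes included, so completeness stays estimable); and
lognormal per-sample abundances realized as noisy per-scaffold coverage.

Marker hits are synthesized directly (at cutoff + 10 bits) rather than by
running a profile search on fake proteins: the contract under test is the
pipeline downstream of the search step.  Non-marker "filler" genes are not
materialized; ``genes_per_genome`` is carried as the total gene count per
genome (the N of the exact hypergeometric null).

Everything is driven by one integer seed; the same seed yields
byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .formats_io import (
    CoverageRecord,
    Gene,
    GenomeBin,
    HmmHit,
    MarkerConfig,
    Scaffold,
    ValidationError,
    write_coverage_table,
    write_genome_fasta,
    write_hmm_table,
)
from .completeness import default_scg_config
from .handoff import PathwayChain, default_chains
from .trait_calling import TraitRule, default_trait_rules

__all__ = [
    "CommunityScenario",
    "GroundTruth",
    "SimulatedCommunity",
    "simulate_community",
    "scenario_presets",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AMINO = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


@dataclass
class CommunityScenario:
    """Parameters of one synthetic community.

    Defaults describe a small but realistic draft-genome cohort; the
    ``rifle-like`` preset scales it to an aquifer-style community.
    Completeness targets are drawn uniformly in
    [median - spread, min(1, median + spread)] unless given explicitly.
    """

    name: str = "custom"
    n_archetypes: int = 10
    genes_per_genome: int = 1000
    completeness_median: float = 0.93
    completeness_spread: float = 0.07
    completeness_targets: Sequence[float] | None = None
    chain_step_probs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    chain_complete_probs: Mapping[str, float] = field(default_factory=dict)
    trait_probs: Mapping[str, float] = field(default_factory=dict)
    strain_groups: Sequence[tuple[int, int, float]] = ()  # (archetype, n_strains, divergence)
    n_scaffolds: int = 4
    scaffold_length: int = 8000
    gene_length: int = 300
    gene_spacing: int = 50
    n_samples: int = 3
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    coverage_noise: float = 0.05
    read_count_base: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archetypes < 1:
            raise ValidationError("need at least one archetype")
        for frac in (self.completeness_median, self.coverage_noise):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"fraction {frac} outside [0, 1]")
        for _a, n, d in self.strain_groups:
            if n < 1 or not (0.0 <= d <= 1.0):
                raise ValidationError("bad strain group (n >= 1, divergence in [0,1])")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["chain_step_probs"] = {k: list(v) for k, v in self.chain_step_probs.items()}
        doc["chain_complete_probs"] = dict(self.chain_complete_probs)
        doc["trait_probs"] = dict(self.trait_probs)
        doc["strain_groups"] = [list(g) for g in self.strain_groups]
        if self.completeness_targets is not None:
            doc["completeness_targets"] = list(self.completeness_targets)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunityScenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["strain_groups"] = [tuple(g) for g in doc.get("strain_groups", [])]
        return cls(**doc)


@dataclass
class GroundTruth:
    """Planted truth behind a simulated community."""

    archetype_of: dict[str, str]          # genome -> archetype cluster label
    true_traits: dict[str, list[str]]     # genome -> planted traits (pre-dropout)
    true_completeness: dict[str, float]   # genome -> dropout retention target
    sample_abundance: dict[str, dict[str, float]]  # sample -> genome -> rel. abundance
    read_counts: dict[str, int]
    genes_per_genome: int

    def strain_clusters(self) -> list[frozenset[str]]:
        """Planted strain clusters (genomes sharing an archetype)."""
        groups: dict[str, set[str]] = {}
        for g, a in self.archetype_of.items():
            groups.setdefault(a, set()).add(g)
        return sorted((frozenset(v) for v in groups.values()), key=min)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "archetype_of": self.archetype_of,
                    "true_traits": self.true_traits,
                    "true_completeness": self.true_completeness,
                    "sample_abundance": self.sample_abundance,
                    "read_counts": self.read_counts,
                    "genes_per_genome": self.genes_per_genome,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)


@dataclass
class SimulatedCommunity:
    scenario: CommunityScenario
    bins: list[GenomeBin]
    hits: list[HmmHit]
    coverage: list[CoverageRecord]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write genomes/*.fna(+.faa), hits.tblout, coverage.tsv, truth.json,
        scenario.yaml into a self-contained directory."""
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        for b in self.bins:
            write_genome_fasta(
                b,
                outdir / "genomes" / f"{b.genome_id}.fna",
                outdir / "genomes" / f"{b.genome_id}.faa",
            )
        write_hmm_table(self.hits, outdir / "hits.tblout")
        write_coverage_table(self.coverage, outdir / "coverage.tsv")
        self.truth.to_json(outdir / "truth.json")
        self.scenario.to_yaml(outdir / "scenario.yaml")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Per-base substitution at ``rate``; substitutions always change the base."""
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = {b: i for i, b in enumerate(b"ACGT")}
    codes = np.array([idx[b] for b in arr.tobytes()], dtype=np.int64)
    shifts = rng.integers(1, 4, size=arr.size)
    new_codes = np.where(hit, (codes + shifts) % 4, codes)
    return _BASES[new_codes].tobytes().decode("ascii")


def _planted_markers(rule: TraitRule, rng: np.random.Generator) -> frozenset[str]:
    """Markers planted to confer a trait: one any_of alternative, plus all_of."""
    markers: set[str] = set(rule.all_of)
    if rule.any_of:
        choice = rule.any_of[int(rng.integers(0, len(rule.any_of)))]
        markers |= set(choice)
    return frozenset(markers)


def simulate_community(
    scenario: CommunityScenario,
    rules: Sequence[TraitRule] | None = None,
    chains: Mapping[str, PathwayChain] | None = None,
    scg_config: MarkerConfig | None = None,
    marker_cutoff: float = 50.0,
) -> SimulatedCommunity:
    """Generate a community with known ground truth.

    Per archetype: chain-step capabilities are drawn per-step Bernoulli from
    ``chain_step_probs`` and accessory traits from ``trait_probs``; marker
    genes for each planted trait plus the full single-copy set are laid out
    on random scaffolds.  Strain copies substitute bases at the group's
    divergence.  Each genome then loses each gene independently with
    probability 1 - completeness_target, and hit rows are emitted only for
    retained markers (at cutoff + 10 bits).  Per-sample genome abundances
    are lognormal; scaffold coverage adds +-``coverage_noise`` relative noise.
    """
    rules = list(default_trait_rules() if rules is None else rules)
    chains = dict(default_chains() if chains is None else chains)
    scg_config = scg_config if scg_config is not None else default_scg_config("bacteria")
    rule_by_trait = {r.trait_id: r for r in rules}
    for cid, chain in chains.items():
        for t in chain.trait_ids:
            if t not in rule_by_trait:
                raise ValidationError(f"chain {cid}: no rule for trait {t!r}")
        probs = scenario.chain_step_probs.get(cid, ())
        if probs and len(probs) != len(chain.steps):
            raise ValidationError(
                f"chain {cid}: {len(probs)} step probabilities for "
                f"{len(chain.steps)} steps"
            )

    rng = np.random.default_rng(scenario.seed)
    scg_markers = sorted(scg_config.marker_ids)
    scg_model = {v: k for k, v in scg_config.model_to_marker.items()}
    scg_cutoffs = scg_config.cutoffs

    n_strains_of = {a: 1 for a in range(scenario.n_archetypes)}
    divergence_of = {a: 0.0 for a in range(scenario.n_archetypes)}
    for a, n, d in scenario.strain_groups:
        if not (0 <= a < scenario.n_archetypes):
            raise ValidationError(f"strain group references archetype {a}")
        n_strains_of[a] = n
        divergence_of[a] = d

    bins: list[GenomeBin] = []
    hits: list[HmmHit] = []
    archetype_of: dict[str, str] = {}
    true_traits: dict[str, list[str]] = {}
    true_completeness: dict[str, float] = {}
    genome_order: list[str] = []

    width = max(3, len(str(scenario.n_archetypes)))
    for a in range(scenario.n_archetypes):
        label = f"arch{a:0{width}d}"
        # --- archetype traits -------------------------------------------------
        traits: set[str] = set()
        for cid in sorted(chains):
            probs = scenario.chain_step_probs.get(cid)
            if probs is None:
                continue
            # a small fraction of organisms carry the whole chain; the rest
            # draw each step independently
            if rng.random() < scenario.chain_complete_probs.get(cid, 0.0):
                traits.update(s.trait_id for s in chains[cid].steps)
            else:
                for step, p in zip(chains[cid].steps, probs):
                    if rng.random() < p:
                        traits.add(step.trait_id)
        for t in sorted(scenario.trait_probs):
            if t not in rule_by_trait:
                raise ValidationError(f"trait_probs names unknown trait {t!r}")
            if rng.random() < scenario.trait_probs[t]:
                traits.add(t)

        trait_markers: set[str] = set()
        for t in sorted(traits):
            trait_markers |= _planted_markers(rule_by_trait[t], rng)
        # conditional rules: never plant a marker some planted trait forbids
        forbidden = set()
        for t in sorted(traits):
            forbidden |= rule_by_trait[t].none_of
        trait_markers -= forbidden

        marker_names = scg_markers + sorted(trait_markers)
        if scenario.genes_per_genome < len(marker_names):
            raise ValidationError(
                f"infeasible scenario: {len(marker_names)} markers but only "
                f"{scenario.genes_per_genome} genes per genome"
            )
        slot = scenario.gene_length + scenario.gene_spacing
        per_scaffold = scenario.scaffold_length // slot
        if per_scaffold * scenario.n_scaffolds < len(marker_names):
            raise ValidationError(
                "infeasible scenario: marker genes do not fit on scaffolds "
                f"({len(marker_names)} markers, capacity "
                f"{per_scaffold * scenario.n_scaffolds})"
            )

        # --- archetype sequence and gene layout ------------------------------
        base_seqs = [
            _random_seq(rng, scenario.scaffold_length)
            for _ in range(scenario.n_scaffolds)
        ]
        proteins = {
            m: _AMINO[rng.integers(0, 20, size=scenario.gene_length // 3)]
            .tobytes().decode("ascii")
            for m in marker_names
        }
        layout: list[tuple[str, int, int, int]] = []  # (marker, scaffold_idx, start, end)
        for i, m in enumerate(marker_names):
            scf, pos = divmod(i, per_scaffold)
            start = pos * slot + 1
            layout.append((m, scf, start, start + scenario.gene_length - 1))

        # --- strains ----------------------------------------------------------
        for s in range(n_strains_of[a]):
            gid = f"g{a:0{width}d}_s{s + 1}"
            genome_order.append(gid)
            archetype_of[gid] = label
            true_traits[gid] = sorted(traits)
            if scenario.completeness_targets is not None:
                c = float(scenario.completeness_targets[a % len(scenario.completeness_targets)])
            else:
                lo = scenario.completeness_median - scenario.completeness_spread
                hi = min(1.0, scenario.completeness_median + scenario.completeness_spread)
                c = float(rng.uniform(lo, hi))
            true_completeness[gid] = c

            seqs = [
                _mutate(rng, seq, divergence_of[a]) if s > 0 else seq
                for seq in base_seqs
            ]
            scaffolds = [
                Scaffold(f"{gid}_scf{k + 1}", seq) for k, seq in enumerate(seqs)
            ]
            genes: list[Gene] = []
            for m, scf, start, end in layout:
                if rng.random() >= c:  # gene dropped
                    continue
                scaffold_id = scaffolds[scf].scaffold_id
                gene_id = f"{gid}|{scaffold_id}|{start}|{end}|+"
                genes.append(Gene(gene_id, scaffold_id, start, end, "+", proteins[m]))
                model = scg_model.get(m, m)
                cutoff = scg_cutoffs.get(model, marker_cutoff)
                hits.append(HmmHit(gene_id, model, cutoff + 10.0, 1e-20, gid))
            bins.append(GenomeBin(gid, scaffolds, genes, "bacteria"))

    # --- abundance and coverage ----------------------------------------------
    coverage: list[CoverageRecord] = []
    sample_abundance: dict[str, dict[str, float]] = {}
    read_counts: dict[str, int] = {}
    for j in range(scenario.n_samples):
        sample = f"sample_{j + 1:02d}"
        depths = rng.lognormal(scenario.lognormal_mu, scenario.lognormal_sigma,
                               size=len(genome_order))
        total = float(depths.sum())
        sample_abundance[sample] = {
            g: float(d) / total for g, d in zip(genome_order, depths)
        }
        read_counts[sample] = int(
            scenario.read_count_base * (0.5 + rng.random())
        )
        for b, depth in zip(bins, depths):
            for s in b.scaffolds:
                noisy = float(depth) * (
                    1.0 + float(rng.uniform(-scenario.coverage_noise,
                                            scenario.coverage_noise))
                )
                coverage.append(
                    CoverageRecord(s.scaffold_id, b.genome_id, sample, noisy)
                )

    truth = GroundTruth(
        archetype_of=archetype_of,
        true_traits=true_traits,
        true_completeness=true_completeness,
        sample_abundance=sample_abundance,
        read_counts=read_counts,
        genes_per_genome=scenario.genes_per_genome,
    )
    return SimulatedCommunity(scenario, bins, hits, coverage, truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def scenario_presets(seed: int = 0) -> dict[str, CommunityScenario]:
    """Named scenarios.

    ``tiny``
        5 archetypes (one 2-strain pair), small scaffolds: a smoke-test
        community the whole pipeline processes in seconds.
    ``rifle-like``
        150 archetypes with trait frequencies mimicking an aquifer
        community: roughly a third of organisms with CO / H2 / reduced-S
        electron-donor traits, under 2% sulfate reducers, 34% / 17%
        O2 / NO3- respirers, median completeness 0.93, 25 strain groups at
        0.5% divergence.
    """
    tiny = CommunityScenario(
        name="tiny",
        n_archetypes=5,
        genes_per_genome=200,
        completeness_median=0.95,
        completeness_spread=0.04,
        chain_step_probs={
            "sulfur_oxidation": [0.5, 0.3, 0.3],
            "denitrification": [0.5, 0.4, 0.3, 0.3],
        },
        trait_probs={"oxygen_respiration": 0.5, "CO_oxidation": 0.3},
        strain_groups=[(0, 2, 0.005)],
        n_scaffolds=4,
        scaffold_length=6000,
        n_samples=2,
        seed=seed,
    )
    rifle = CommunityScenario(
        name="rifle-like",
        n_archetypes=150,
        genes_per_genome=1000,
        completeness_median=0.93,
        completeness_spread=0.07,
        chain_step_probs={
            "sulfur_oxidation": [0.11, 0.04, 0.08],
            "denitrification": [0.17, 0.12, 0.10, 0.08],
        },
        # complete multi-step organisms are rare (of order 1% of the
        # community) but present
        chain_complete_probs={"sulfur_oxidation": 0.008, "denitrification": 0.009},
        trait_probs={
            "oxygen_respiration": 0.34,
            "CO_oxidation": 0.30,
            "H2_metabolism_by_group": 0.33,
            "sulfate_reduction": 0.015,
            "S0_reduction": 0.17,
            "DNRA": 0.05,
            "anammox": 0.01,
            "nitrogen_fixation": 0.10,
            "carbon_fixation": 0.15,
            "thiosulfate_oxidation_S0_producing": 0.05,
        },
        strain_groups=[(a, 2, 0.005) for a in range(20)]
        + [(a, 3, 0.005) for a in range(20, 25)],
        n_scaffolds=5,
        scaffold_length=8000,
        n_samples=4,
        lognormal_sigma=1.5,
        seed=seed,
    )
    return {"tiny": tiny, "rifle-like": rifle}
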