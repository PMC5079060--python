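"""Metabolic-handoff statistics over sequential redox chains.

A pathway chain is an ordered list of redox steps (e.g. sulfide -> S0 ->
sulfite -> sulfate, or nitrate -> nitrite -> NO -> N2O -> N2).  For each
organism the chain induces a boolean step-capability vector; organisms are
partitioned by the maximal contiguous runs of steps they can perform
("windows").  Communities dominated by single-step windows imply metabolic
handoffs: the product of one organism's step is the substrate of another's.

The incompleteness null asks whether the observed scarcity of multi-step
organisms could instead be an artifact of draft-genome incompleteness: for
each organism apparently missing a step, the probability that all m marker
genes of that step were missed by chance in a genome recovered at
completeness c is (1-c)^m (or its exact hypergeometric analogue), and the
joint probability over organisms is the product, computed in log space.
A conservative mode floors every completeness at a configurable value
(default 0.70, a typical inclusion threshold), which only inflates the
null probability.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .formats_io import FormatError, ValidationError
from .trait_calling import TraitMatrix

__all__ = [
    "PathwayStep",
    "PathwayChain",
    "load_chains",
    "default_chains",
    "HandoffSummary",
    "IncompletenessTestResult",
    "step_capability",
    "partition_by_windows",
    "incompleteness_null",
    "cycle_summary",
    "energy_yield_correlation",
]


# ---------------------------------------------------------------------------
# chain configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayStep:
    step_id: str
    trait_id: str
    n_markers: int = 1
    delta_g0: float | None = None  # kJ/mol, standard conditions
    substrate: str | None = None
    product: str | None = None
    possible_detox: bool = False  # capability may reflect detoxification

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValidationError(f"step {self.step_id}: n_markers must be >= 1")


@dataclass(frozen=True)
class PathwayChain:
    chain_id: str
    steps: tuple[PathwayStep, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValidationError(f"chain {self.chain_id}: needs >= 2 steps")
        ids = [s.step_id for s in self.steps]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"chain {self.chain_id}: duplicate step id")

    @property
    def step_ids(self) -> list[str]:
        return [s.step_id for s in self.steps]

    @property
    def trait_ids(self) -> list[str]:
        return [s.trait_id for s in self.steps]


def load_chains(path: str | Path) -> dict[str, PathwayChain]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "chains" not in doc:
        raise FormatError(f"{path}: expected a mapping with a 'chains' list")
    chains: dict[str, PathwayChain] = {}
    for item in doc["chains"]:
        steps = tuple(
            PathwayStep(
                step_id=str(s["step"]),
                trait_id=str(s["trait"]),
                n_markers=int(s.get("m", 1)),
                delta_g0=None if s.get("delta_g0") is None else float(s["delta_g0"]),
                substrate=s.get("substrate"),
                product=s.get("product"),
                possible_detox=bool(s.get("possible_detox", False)),
            )
            for s in item["steps"]
        )
        chain = PathwayChain(str(item["chain"]), steps)
        chains[chain.chain_id] = chain
    return chains


def default_chains() -> dict[str, PathwayChain]:
    """Shipped defaults: 3-step sulfur oxidation, 4-step denitrification."""
    with resources.as_file(resources.files("metahandoff.data") / "chains.yaml") as path:
        return load_chains(path)


# ---------------------------------------------------------------------------
# step capability and window partition
# ---------------------------------------------------------------------------


def step_capability(matrix: TraitMatrix, chain: PathwayChain) -> pd.DataFrame:
    """Genomes x steps boolean table from the trait matrix."""
    missing = [t for t in chain.trait_ids if t not in matrix.trait_ids]
    if missing:
        raise ValidationError(
            f"chain {chain.chain_id}: trait columns missing from matrix: {missing}"
        )
    caps = matrix.values[chain.trait_ids].astype(bool)
    caps.columns = chain.step_ids
    return caps


def maximal_runs(vector: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True as (start, end) 0-based inclusive."""
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i, v in enumerate(vector):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(vector) - 1))
    return runs


@dataclass
class HandoffSummary:
    """Window partition of a community over one chain.

    ``window_counts``/``window_abundance`` are keyed by (start_step_id,
    end_step_id); every retained organism contributes once to each of its
    maximal contiguous capability runs.  ``complete_pathway_count`` counts
    organisms capable of every step.
    """

    chain_id: str
    step_ids: list[str]
    window_counts: dict[tuple[str, str], int]
    window_abundance: dict[tuple[str, str], float]
    complete_pathway_count: int
    n_considered: int
    min_abundance: float

    def count(self, start: str, end: str) -> int:
        return self.window_counts.get((start, end), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "start_step": k[0],
                "end_step": k[1],
                "n_steps": self.step_ids.index(k[1]) - self.step_ids.index(k[0]) + 1,
                "organism_count": self.window_counts[k],
                "total_relative_abundance": self.window_abundance[k],
            }
            for k in sorted(
                self.window_counts,
                key=lambda k: (self.step_ids.index(k[0]), self.step_ids.index(k[1])),
            )
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "start_step", "end_step", "n_steps",
                "organism_count", "total_relative_abundance",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def partition_by_windows(
    capabilities: pd.DataFrame,
    abundance: Mapping[str, float] | pd.Series,
    min_abundance: float = 0.0001,
    chain_id: str = "chain",
) -> HandoffSummary:
    """Partition organisms into step windows of one chain.

    Organisms at relative abundance strictly greater than ``min_abundance``
    (default 0.01% of the community) are considered; each contributes one
    count, and its abundance, to every maximal contiguous run of steps it
    can perform.  An organism able to perform non-adjacent steps therefore
    appears in several windows, one per run.
    """
    abundance = pd.Series(abundance)
    missing = [g for g in capabilities.index if g not in abundance.index]
    if missing:
        raise ValidationError(f"no abundance for organisms: {missing[:5]}")
    steps = list(capabilities.columns)
    counts: dict[tuple[str, str], int] = {}
    masses: dict[tuple[str, str], float] = {}
    complete = 0
    considered = 0
    for gid, row in capabilities.iterrows():
        if abundance[gid] <= min_abundance:
            continue
        vec = row.to_numpy(dtype=bool)
        if not vec.any():
            continue
        considered += 1
        if vec.all():
            complete += 1
        for a, b in maximal_runs(vec):
            key = (steps[a], steps[b])
            counts[key] = counts.get(key, 0) + 1
            masses[key] = masses.get(key, 0.0) + float(abundance[gid])
    return HandoffSummary(
        chain_id, steps, counts, masses, complete, considered, min_abundance
    )


# ---------------------------------------------------------------------------
# incompleteness null
# ---------------------------------------------------------------------------


@dataclass
class IncompletenessTestResult:
    """Joint null probability that apparent incapability is missed genes.

    ``log10_p`` is exact (sum of per-organism log10 probabilities); ``p_joint``
    is 10**log10_p and underflows to 0.0 for strongly negative exponents,
    which is why the log is the primary statistic.
    """

    n_organisms: int
    completeness: list[float]      # c_i actually used (after any flooring)
    missing_markers: list[int]     # m_i per organism
    completeness_floor: float
    conservative: bool
    method: str
    log10_p: float
    degenerate: bool = False       # some c_i == 1 under approx (p_i = 0)

    @property
    def p_joint(self) -> float:
        return 10.0 ** self.log10_p if self.log10_p > -308 else 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_organisms": self.n_organisms,
                    "method": self.method,
                    "conservative": self.conservative,
                    "completeness_floor": self.completeness_floor,
                    "completeness": self.completeness,
                    "missing_markers": self.missing_markers,
                    "log10_p": self.log10_p,
                    "p_joint": self.p_joint,
                    "degenerate": self.degenerate,
                },
                fh,
                indent=2,
            )


def _log10_p_exact(c: float, m: int, n_genes: int) -> float:
    """log10 P(all m markers among the missed genes), hypergeometric.

    A genome with N total genes recovered at completeness c retains
    n = round(c*N) genes drawn without replacement; the probability that
    none of the m marker genes is retained is C(N-m, n) / C(N, n),
    i.e. the hypergeometric pmf at 0 successes.
    """
    n_recovered = int(round(c * n_genes))
    if m > n_genes:
        raise ValidationError("more markers than genes")
    if n_genes - m < n_recovered:
        return -math.inf  # pigeonhole: a marker must have been recovered
    return float(stats.hypergeom.logpmf(0, n_genes, m, n_recovered)) / math.log(10)


def incompleteness_null(
    organisms: Sequence[tuple],
    completeness_floor: float = 0.70,
    method: str = "approx",
    conservative: bool = False,
) -> IncompletenessTestResult:
    """Joint probability that every organism's missing step genes were missed.

    ``organisms`` is a sequence of (c_i, m_i) or (c_i, m_i, N_i) tuples:
    estimated completeness, number of marker genes behind the apparently
    absent step, and (exact method only) total genes in the genome.

    * approx: p_i = (1 - c_i)**m_i — each of m_i independent genes falls in
      the unrecovered fraction.
    * exact: hypergeometric without replacement (needs N_i).

    ``conservative=True`` replaces every c_i by ``completeness_floor``:
    genomes are assumed to be as incomplete as the inclusion threshold
    allows, which maximizes the null probability.  All arithmetic is in
    log10 space; c_i == 1 under approx yields log10_p = -inf with the
    ``degenerate`` flag set rather than an exception.
    """
    if method not in ("approx", "exact"):
        raise ValidationError("method must be 'approx' or 'exact'")
    if not organisms:
        raise ValidationError("need at least one organism")
    if not (0.0 < completeness_floor < 1.0):
        raise ValidationError("completeness_floor must be in (0, 1)")

    used_c: list[float] = []
    used_m: list[int] = []
    log10_p = 0.0
    degenerate = False
    for org in organisms:
        if len(org) == 2:
            c, m, n_genes = org[0], org[1], None
        else:
            c, m, n_genes = org[:3]
        if not (0.0 < c <= 1.0):
            raise ValidationError(f"completeness {c} outside (0, 1]")
        if m < 1:
            raise ValidationError("missing-marker count must be >= 1")
        c_eff = completeness_floor if conservative else c
        used_c.append(c_eff)
        used_m.append(int(m))
        if method == "approx":
            if c_eff >= 1.0:
                degenerate = True
                log10_p = -math.inf
            elif math.isfinite(log10_p):
                log10_p += m * math.log10(1.0 - c_eff)
        else:
            if n_genes is None:
                raise ValidationError("exact method needs (c, m, N_genes) tuples")
            contribution = _log10_p_exact(c_eff, int(m), int(n_genes))
            if not math.isfinite(contribution):
                degenerate = True
            log10_p += contribution
    return IncompletenessTestResult(
        n_organisms=len(organisms),
        completeness=used_c,
        missing_markers=used_m,
        completeness_floor=completeness_floor,
        conservative=conservative,
        method=method,
        log10_p=log10_p,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# whole-cycle summary and energy-yield correlation
# ---------------------------------------------------------------------------


def cycle_summary(
    matrix: TraitMatrix,
    abundance: Mapping[str, float] | pd.Series,
    transformations: Sequence[str],
) -> pd.DataFrame:
    """Per-transformation organism count and total relative abundance.

    The table behind whole-cycle diagrams: for each trait, how many
    organisms carry it and what fraction of the community they sum to.
    """
    abundance = pd.Series(abundance)
    missing = [t for t in transformations if t not in matrix.trait_ids]
    if missing:
        raise ValidationError(f"traits not in matrix: {missing}")
    rows = []
    for t in transformations:
        col = matrix.values[t].astype(bool)
        carriers = col[col].index
        rows.append(
            {
                "trait_id": t,
                "organism_count": int(col.sum()),
                "total_relative_abundance": float(
                    abundance.reindex(carriers).fillna(0.0).sum()
                ),
            }
        )
    return pd.DataFrame(rows, columns=["trait_id", "organism_count", "total_relative_abundance"])


def energy_yield_correlation(
    per_step_values: Sequence[float],
    delta_g0: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 42,
    exhaustive_max_steps: int = 8,
) -> dict:
    """Spearman correlation of per-step organism counts/abundance vs -dG0.

    Tests whether more organisms mediate the more energetically favourable
    steps.  Correlates the supplied per-step values against -delta_g0 (so a
    positive rho means "more exergonic, more organisms").  The permutation
    p-value is two-sided over |rho|: exhaustive over all step orderings for
    <= ``exhaustive_max_steps`` steps, otherwise ``n_permutations`` draws
    with a fixed, recorded seed.  Constant inputs make rho undefined;
    reported as 0 with ``degenerate=True``.
    """
    values = np.asarray(per_step_values, dtype=float)
    energy = -np.asarray(delta_g0, dtype=float)
    if values.size != energy.size:
        raise ValidationError("per-step values and delta_g0 differ in length")
    if values.size < 3:
        raise ValidationError("need >= 3 steps with both a value and delta_g0")
    if np.allclose(values, values[0]) or np.allclose(energy, energy[0]):
        return {"rho": 0.0, "p_value": 1.0, "degenerate": True,
                "method": "degenerate", "seed": seed}

    rho_obs = float(stats.spearmanr(values, energy).statistic)
    n = values.size
    if n <= exhaustive_max_steps:
        perms = itertools.permutations(range(n))
        rhos = np.array(
            [stats.spearmanr(values[list(p)], energy).statistic for p in perms]
        )
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        rhos = np.array(
            [
                stats.spearmanr(values[rng.permutation(n)], energy).statistic
                for _ in range(n_permutations)
            ]
        )
        method = "resampled"
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return {"rho": rho_obs, "p_value": p, "degenerate": False,
            "method": method, "seed": seed}
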