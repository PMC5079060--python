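"""Marker-rule trait calling: cutoff-passing HMM hits -> boolean trait matrix.

Hits are first gated by per-model bitscore cutoffs ("above the cutoff" is
implemented as >=, the convention for noise cutoffs).  A rule then maps
marker presence to one metabolic trait:

* ``any_of`` — a list of marker sets; one set fully present suffices
  (alternative enzyme systems, e.g. sqr vs fccAB for sulfide oxidation);
* ``all_of`` — every listed marker required (multi-subunit systems);
* ``none_of`` — markers that must be absent (conditional rules, e.g. the
  sox system produces elemental sulfur only when soxCD are lacking).

The result is a genomes x traits 0/1 matrix serialized as TSV, the shape
used by study supplementary trait tables, so externally produced matrices
load directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .formats_io import FormatError, HmmHit, MarkerConfig, ValidationError

__all__ = [
    "TraitRule",
    "TraitMatrix",
    "load_trait_rules",
    "default_trait_rules",
    "default_trait_marker_config",
    "filter_hits",
    "markers_by_genome",
    "call_traits",
    "trait_prevalence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitRule:
    trait_id: str
    any_of: tuple[frozenset[str], ...] = ()
    all_of: frozenset[str] = frozenset()
    none_of: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.any_of and not self.all_of:
            raise ValidationError(
                f"rule {self.trait_id}: needs any_of and/or all_of markers"
            )
        if any(not s for s in self.any_of):
            raise ValidationError(f"rule {self.trait_id}: empty any_of alternative")
        if self.none_of & self.all_of:
            raise ValidationError(
                f"rule {self.trait_id}: none_of overlaps all_of"
            )

    @property
    def referenced_markers(self) -> frozenset[str]:
        out: set[str] = set(self.all_of) | set(self.none_of)
        for s in self.any_of:
            out |= s
        return frozenset(out)

    def applies(self, markers: frozenset[str] | set[str]) -> bool:
        """True iff the marker set confers this trait."""
        if self.none_of & markers:
            return False
        positive = False
        if self.any_of and any(s <= markers for s in self.any_of):
            positive = True
        if self.all_of and self.all_of <= markers:
            positive = True
        return positive


@dataclass
class TraitMatrix:
    """Genomes x traits boolean table, backed by a pandas DataFrame (0/1)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.isin([0, 1]).all().all():
            raise ValidationError("trait matrix values must be 0/1")
        self.values = self.values.astype(int)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.values.columns)

    def has_trait(self, genome_id: str, trait_id: str) -> bool:
        return bool(self.values.at[genome_id, trait_id])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not df.map(lambda v: v in (0, 1)).all().all():
            raise FormatError(f"{path}: non-binary cell in trait matrix")
        return cls(df.astype(int))


# ---------------------------------------------------------------------------
# rule loading
# ---------------------------------------------------------------------------


def _as_rule(item: Mapping, index: int) -> TraitRule:
    try:
        return TraitRule(
            trait_id=str(item["trait"]),
            any_of=tuple(frozenset(map(str, s)) for s in item.get("any_of", [])),
            all_of=frozenset(map(str, item.get("all_of", []))),
            none_of=frozenset(map(str, item.get("none_of", []))),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"rules[{index}]: {exc}") from exc


def load_trait_rules(
    path: str | Path, known_markers: Iterable[str] | None = None
) -> list[TraitRule]:
    """Load trait rules from YAML; optionally validate marker references.

    With ``known_markers`` given, a rule referencing no known marker is an
    error at load time (it could never fire and is almost surely a typo).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise FormatError(f"{path}: expected a mapping with a 'rules' list")
    rules = [_as_rule(item, i) for i, item in enumerate(doc["rules"])]
    ids = [r.trait_id for r in rules]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate trait id")
    if known_markers is not None:
        known = set(known_markers)
        for r in rules:
            if not (r.referenced_markers & known):
                raise FormatError(
                    f"{path}: rule {r.trait_id} references no known marker"
                )
    return rules


def default_trait_rules() -> list[TraitRule]:
    with resources.as_file(
        resources.files("metahandoff.data") / "trait_rules.yaml"
    ) as path:
        return load_trait_rules(path)


def default_trait_marker_config(cutoff: float = 50.0) -> MarkerConfig:
    """A MarkerConfig covering every marker referenced by the default rules.

    Model name == marker id and a single default cutoff; real projects
    override with their per-model cutoff table.
    """
    markers = sorted(set().union(*(r.referenced_markers for r in default_trait_rules())))
    return MarkerConfig([(m, cutoff, m) for m in markers], source="default")


# ---------------------------------------------------------------------------
# hit gating and trait calling
# ---------------------------------------------------------------------------


def filter_hits(hits: Iterable[HmmHit], config: MarkerConfig) -> list[HmmHit]:
    """Hits whose full-sequence bitscore reaches the model's cutoff (>=).

    Hits against models absent from the config are dropped; their count is
    logged as a warning rather than raising, since hit tables routinely mix
    marker sets.
    """
    cutoffs = config.cutoffs
    passing: list[HmmHit] = []
    unlisted = 0
    for h in hits:
        cutoff = cutoffs.get(h.model_name)
        if cutoff is None:
            unlisted += 1
            continue
        if h.bitscore >= cutoff:
            passing.append(h)
    if unlisted:
        logger.warning("dropped %d hits against models not in the cutoff config", unlisted)
    return passing


def markers_by_genome(
    hits: Iterable[HmmHit], config: MarkerConfig
) -> dict[str, frozenset[str]]:
    """Map genome -> set of marker ids with at least one passing hit."""
    model_to_marker = config.model_to_marker
    out: dict[str, set[str]] = {}
    for h in filter_hits(hits, config):
        out.setdefault(h.genome_id, set()).add(model_to_marker[h.model_name])
    return {g: frozenset(m) for g, m in out.items()}


def call_traits(
    genome_markers: Mapping[str, Iterable[str]],
    rules: Sequence[TraitRule],
    genome_ids: Sequence[str] | None = None,
) -> TraitMatrix:
    """Evaluate every rule for every genome.

    ``genome_markers`` maps genome id to its passing marker ids (see
    :func:`markers_by_genome`).  ``genome_ids`` fixes row order and may add
    genomes with no hits (all traits false); default is sorted keys.
    Deterministic: same markers + rules give a bit-identical matrix.
    """
    if genome_ids is None:
        genome_ids = sorted(genome_markers)
    data = {}
    for g in genome_ids:
        markers = frozenset(genome_markers.get(g, ()))
        data[g] = [int(rule.applies(markers)) for rule in rules]
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=[r.trait_id for r in rules]
    ).reindex(index=list(genome_ids))
    return TraitMatrix(df)


def trait_prevalence(
    matrix: TraitMatrix, subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-trait (count, fraction) over a genome subset (default: all).

    This is the statistic behind community-level statements such as "34%
    of genomes encode aerobic respiration".
    """
    genomes = list(matrix.genome_ids if subset is None else subset)
    if not genomes:
        raise ValidationError("empty genome subset")
    missing = set(genomes) - set(matrix.genome_ids)
    if missing:
        raise ValidationError(f"subset genomes not in matrix: {sorted(missing)}")
    sub = matrix.values.loc[genomes]
    counts = sub.sum(axis=0)
    return pd.DataFrame(
        {"count": counts.astype(int), "fraction": counts / len(genomes)}
    )
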