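"""Window partitioning, the incompleteness null, cycle summaries and the
energy-yield correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metahandoff.formats_io import ValidationError
from metahandoff.handoff import (
    PathwayChain,
    PathwayStep,
    cycle_summary,
    default_chains,
    energy_yield_correlation,
    incompleteness_null,
    maximal_runs,
    partition_by_windows,
    step_capability,
)
from metahandoff.trait_calling import TraitMatrix

SULFUR = default_chains()["sulfur_oxidation"]


def _caps(vectors, steps=3):
    cols = [chr(ord("A") + i) for i in range(steps)]
    return pd.DataFrame(
        {c: [bool(v[i]) for v in vectors] for i, c in enumerate(cols)},
        index=[f"g{i}" for i in range(len(vectors))],
    )


class TestStepCapability:
    def test_matches_direct_column_lookup(self):
        df = pd.DataFrame(
            {t: [1, 0] for t in SULFUR.trait_ids} | {"other": [1, 1]},
            index=["g1", "g2"],
        )
        caps = step_capability(TraitMatrix(df), SULFUR)
        assert list(caps.columns) == SULFUR.step_ids
        assert caps.loc["g1"].all() and not caps.loc["g2"].any()

    def test_missing_trait_column_named(self):
        matrix = TraitMatrix(pd.DataFrame({"x": [1]}, index=["g1"]))
        with pytest.raises(ValidationError, match="sulfide_oxidation_to_S0"):
            step_capability(matrix, SULFUR)


def _oracle_windows(vectors):
    """Brute-force enumeration of maximal-run window counts."""
    counts = {}
    for v in vectors:
        i = 0
        while i < len(v):
            if v[i]:
                j = i
                while j + 1 < len(v) and v[j + 1]:
                    j += 1
                key = (chr(ord("A") + i), chr(ord("A") + j))
                counts[key] = counts.get(key, 0) + 1
                i = j + 1
            else:
                i += 1
    return counts


class TestWindowPartition:
    def test_one_two_and_three_step_organisms(self):
        vectors = [(1, 0, 0), (1, 1, 0), (1, 1, 1)]
        caps = _caps(vectors)
        abundance = {g: 0.01 for g in caps.index}
        summary = partition_by_windows(caps, abundance)
        assert summary.window_counts == _oracle_windows(vectors)
        assert summary.count("A", "A") == 1
        assert summary.count("A", "B") == 1
        assert summary.count("A", "C") == 1
        assert summary.complete_pathway_count == 1

    def test_disjoint_runs_count_separately(self):
        caps = _caps([(1, 0, 1)])
        summary = partition_by_windows(caps, {"g0": 0.5})
        assert summary.window_counts == {("A", "A"): 1, ("C", "C"): 1}

    def test_abundance_floor_is_strict(self):
        caps = _caps([(1, 0, 0), (1, 0, 0)])
        abundance = {"g0": 0.00009, "g1": 0.0002}  # 0.009% vs 0.02%
        summary = partition_by_windows(caps, abundance, min_abundance=0.0001)
        assert summary.count("A", "A") == 1
        assert summary.n_considered == 1

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(3)
        vectors = [tuple(rng.integers(0, 2, size=5)) for _ in range(60)]
        caps = _caps(vectors, steps=5)
        summary = partition_by_windows(caps, {g: 0.01 for g in caps.index})
        assert summary.window_counts == _oracle_windows(vectors)

    def test_window_abundance_accumulates(self):
        caps = _caps([(1, 0, 0), (1, 0, 0)])
        summary = partition_by_windows(caps, {"g0": 0.1, "g1": 0.2})
        assert summary.window_abundance[("A", "A")] == pytest.approx(0.3)


def _exact_oracle(n_genes, m, n_recovered):
    """Combinatorial enumeration: P(no marker among recovered genes)."""
    return math.comb(n_genes - m, n_recovered) / math.comb(n_genes, n_recovered)


class TestIncompletenessNull:
    def test_single_organism_approx(self):
        result = incompleteness_null([(0.70, 1)])
        assert 10**result.log10_p == pytest.approx(0.30)

    def test_exact_matches_combinatorics(self):
        # N=100 genes, 93 recovered, 2 markers: (7*6)/(100*99)
        result = incompleteness_null([(0.93, 2, 100)], method="exact")
        assert 10**result.log10_p == pytest.approx((7 * 6) / (100 * 99))
        assert 10**result.log10_p == pytest.approx(_exact_oracle(100, 2, 93))

    def test_conservative_floor_reproduces_paper_scale_bound(self):
        result = incompleteness_null([(0.95, 1)] * 319, conservative=True)
        assert result.log10_p == pytest.approx(319 * math.log10(0.3))
        assert result.log10_p < -50

    def test_joint_probability_decreases_with_organisms(self):
        values = [
            incompleteness_null([(0.8, 1)] * n).log10_p for n in (1, 5, 20, 100)
        ]
        assert values == sorted(values, reverse=True)

    def test_adding_floor_organism_multiplies_by_expected_factor(self):
        base = incompleteness_null([(0.70, 2)] * 4, conservative=True)
        more = incompleteness_null([(0.70, 2)] * 5, conservative=True)
        assert more.log10_p - base.log10_p == pytest.approx(2 * math.log10(0.30))

    def test_complete_genome_flags_degenerate_not_raises(self):
        result = incompleteness_null([(1.0, 1)])
        assert result.degenerate
        assert result.log10_p == -math.inf
        assert result.p_joint == 0.0

    def test_no_underflow_at_1e5_organisms(self):
        result = incompleteness_null([(0.70, 1)] * 100_000, conservative=True)
        assert math.isfinite(result.log10_p)
        assert result.log10_p == pytest.approx(100_000 * math.log10(0.3))

    def test_exact_needs_gene_totals(self):
        with pytest.raises(ValidationError, match="N_genes"):
            incompleteness_null([(0.9, 1)], method="exact")

    def test_approx_and_exact_agree_for_large_genomes(self):
        for m in (1, 2, 3):
            approx = incompleteness_null([(0.85, m)]).log10_p
            exact = incompleteness_null([(0.85, m, 2000)], method="exact").log10_p
            assert abs(approx - exact) < math.log10(2)


class TestCycleSummary:
    def test_count_and_abundance(self):
        df = pd.DataFrame({"t": [1, 1, 0, 0]}, index=list("abcd"))
        out = cycle_summary(TraitMatrix(df), {"a": 0.1, "b": 0.2, "c": 0.5, "d": 0.1}, ["t"])
        assert out.loc[0, "organism_count"] == 2
        assert out.loc[0, "total_relative_abundance"] == pytest.approx(0.30)

    def test_absent_trait_gives_zeros(self):
        df = pd.DataFrame({"t": [0, 0]}, index=["a", "b"])
        out = cycle_summary(TraitMatrix(df), {"a": 0.1, "b": 0.2}, ["t"])
        assert out.loc[0, "organism_count"] == 0
        assert out.loc[0, "total_relative_abundance"] == 0.0

    def test_matches_brute_force_filter_and_sum(self):
        rng = np.random.default_rng(8)
        genomes = [f"g{i}" for i in range(40)]
        df = pd.DataFrame({"t": rng.integers(0, 2, size=40)}, index=genomes)
        ab = {g: float(rng.random()) for g in genomes}
        out = cycle_summary(TraitMatrix(df), ab, ["t"])
        expected = sum(ab[g] for g in genomes if df.at[g, "t"])
        assert out.loc[0, "total_relative_abundance"] == pytest.approx(expected)


class TestEnergyCorrelation:
    def test_perfectly_ordered_counts(self):
        # counts increase with energy yield (-dG0)
        result = energy_yield_correlation([5, 10, 20, 40], [-100, -200, -300, -400])
        assert result["rho"] == pytest.approx(1.0)

    def test_constant_counts_flagged_degenerate(self):
        result = energy_yield_correlation([7, 7, 7], [-1, -2, -3])
        assert result["degenerate"] and result["rho"] == 0.0

    def test_exhaustive_p_matches_enumeration_for_four_steps(self):
        values = np.array([3.0, 9.0, 1.0, 5.0])
        energy = np.array([-10.0, -40.0, -20.0, -30.0])
        result = energy_yield_correlation(values, energy)
        rho_obs = stats.spearmanr(values, -energy).statistic
        rhos = [
            stats.spearmanr(values[list(p)], -energy).statistic
            for p in itertools.permutations(range(4))
        ]
        expected = sum(abs(r) >= abs(rho_obs) - 1e-12 for r in rhos) / len(rhos)
        assert result["method"] == "exhaustive"
        assert result["p_value"] == pytest.approx(expected)

    def test_fewer_than_three_steps_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            energy_yield_correlation([1, 2], [-1.0, -2.0])


def test_chain_validation():
    with pytest.raises(ValidationError, match=">= 2 steps"):
        PathwayChain("c", (PathwayStep("A", "t"),))
    with pytest.raises(ValidationError, match="n_markers"):
        PathwayStep("A", "t", n_markers=0)


def test_maximal_runs_cover_all_true_positions():
    rng = np.random.default_rng(5)
    for _ in range(50):
        v = list(rng.integers(0, 2, size=8).astype(bool))
        runs = maximal_runs(v)
        covered = set()
        for a, b in runs:
            assert all(v[a : b + 1])  # runs are all-true
            assert a == 0 or not v[a - 1]  # and maximal
            assert b == len(v) - 1 or not v[b + 1]
            covered |= set(range(a, b + 1))
        assert covered == {i for i, x in enumerate(v) if x}
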