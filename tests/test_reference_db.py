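"""Database construction: thresholds, counts, clade sets, greedy cover."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from magqc import (
    DbConfig,
    MarkerCountMatrix,
    ProfileHit,
    build_count_matrix,
    build_reference_set,
    calibrate_threshold,
    calibrate_thresholds,
    define_clade_sets,
    select_balanced_subset,
    single_copy_prevalence,
)
from magqc.errors import InputError
from magqc.tree import ReferenceTree


def threshold_oracle(scores_by_genome: dict[str, list[float]]) -> float:
    """Exhaustive scan over every distinct observed bit score."""
    grid = sorted({s for scores in scores_by_genome.values() for s in scores})
    best_t, best_n = None, -1
    for t in grid:
        n = sum(
            1 for scores in scores_by_genome.values()
            if sum(s >= t for s in scores) == 1
        )
        if n >= best_n:  # later (larger) threshold wins ties
            best_t, best_n = t, n
    return best_t


class TestCalibrateThreshold:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ({"A": [50, 30], "B": [45], "C": [40, 35]}, 40.0),
            ({"A": [42]}, 42.0),
            ({"A": [50], "B": [50]}, 50.0),  # tie -> largest threshold
        ],
    )
    def test_examples(self, scores, expected):
        assert calibrate_threshold(scores) == expected
        assert threshold_oracle(scores) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(InputError, match="no hits"):
            calibrate_threshold({})

    def test_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_genomes = int(rng.integers(1, 21))
            table = {}
            for g in range(n_genomes):
                n_hits = int(rng.integers(1, 11))
                table[f"g{g}"] = list(
                    np.round(rng.uniform(10, 100, size=n_hits), 1)
                )
            assert calibrate_threshold(table) == threshold_oracle(table)

    def test_grouped_calibration_restricts_to_given_genomes(self):
        hits = [
            ProfileHit("g1", "p1", "PF1", 50.0),
            ProfileHit("g1", "p2", "PF1", 30.0),
            ProfileHit("g2", "p3", "PF1", 45.0),
        ]
        # only g2 considered: its sole hit sets the threshold
        assert calibrate_thresholds(hits, genomes=["g2"]) == {"PF1": 45.0}


class TestCountMatrix:
    def test_inclusive_threshold_and_protein_dedup(self):
        hits = [
            ProfileHit("g1", "p1", "PF1", 40.0),  # exactly at threshold
            ProfileHit("g1", "p2", "PF2", 60.0),
            ProfileHit("g1", "p2", "PF2", 55.0),  # same protein, same profile
            ProfileHit("g1", "p3", "PF2", 10.0),  # below threshold
        ]
        m = build_count_matrix(hits, {"PF1": 40.0, "PF2": 50.0})
        assert m.count("g1", "PF1") == 1
        assert m.count("g1", "PF2") == 1

    def test_all_below_threshold_gives_declared_zero_shape(self):
        hits = [ProfileHit("g1", "p1", "PF1", 5.0), ProfileHit("g2", "p1", "PF2", 5.0)]
        m = build_count_matrix(hits, {"PF1": 40.0, "PF2": 40.0, "PF3": 40.0})
        assert m.genomes == ["g1", "g2"]
        assert m.profiles == ["PF1", "PF2", "PF3"]
        assert (m.df.values == 0).all()

    def test_unknown_profile_named_in_error(self):
        with pytest.raises(InputError, match="PFX"):
            build_count_matrix([ProfileHit("g", "p", "PFX", 50.0)], {"PF1": 10.0})

    def test_raising_thresholds_never_increases_counts(self):
        rng = np.random.default_rng(5)
        hits = [
            ProfileHit(f"g{rng.integers(4)}", f"p{i}", f"PF{rng.integers(5)}",
                       float(rng.uniform(10, 100)))
            for i in range(200)
        ]
        thresholds = {f"PF{j}": 30.0 for j in range(5)}
        base = build_count_matrix(hits, thresholds).df
        for j in range(5):
            raised = dict(thresholds)
            raised[f"PF{j}"] = 60.0
            bumped = build_count_matrix(hits, raised).df
            assert (bumped.values <= base.values).all()


class TestPrevalence:
    @pytest.mark.parametrize(
        "counts, expected",
        [([1, 1, 1, 1], 1.0), ([1, 1, 2, 0], 0.5), ([0, 0], 0.0)],
    )
    def test_exact_single_copy_fraction(self, counts, expected):
        frame = pd.DataFrame({"PF1": counts},
                             index=[f"g{i}" for i in range(len(counts))])
        m = MarkerCountMatrix(frame)
        assert single_copy_prevalence(m, m.genomes, "PF1") == expected

    def test_unknown_genome_rejected(self):
        m = MarkerCountMatrix(pd.DataFrame({"PF1": [1]}, index=["g1"]))
        with pytest.raises(InputError, match="gX"):
            single_copy_prevalence(m, ["gX"], "PF1")


class TestCladeSets:
    @staticmethod
    def toy_matrix(counts_by_genome: dict[str, int], profiles: list[str]):
        frame = pd.DataFrame(
            {p: list(counts_by_genome.values()) for p in profiles},
            index=list(counts_by_genome),
        )
        return MarkerCountMatrix(frame)

    def test_joint_thresholds_met_emits_set(self):
        tree = ReferenceTree.from_newick("(((A,B),(C,D)),(E,F));")
        profiles = [f"PF{i:02d}" for i in range(25)]
        counts = {g: 1 for g in "ABCD"} | {g: 0 for g in "EF"}
        sets = define_clade_sets(tree, self.toy_matrix(counts, profiles),
                                 DbConfig(min_species=3, min_profiles=20))
        abcd = [s for s in sets
                if set(s.species_ids) == {"A", "B", "C", "D"}]
        assert len(abcd) == 1 and len(abcd[0]) == 25

    def test_nineteen_profiles_is_not_enough(self):
        tree = ReferenceTree.from_newick("((A,B),(C,D));")
        profiles = [f"PF{i:02d}" for i in range(19)]
        counts = {g: 1 for g in "ABCD"}
        sets = define_clade_sets(tree, self.toy_matrix(counts, profiles),
                                 DbConfig(min_species=3, min_profiles=20))
        assert sets == []

    def test_prevalence_below_cutoff_excludes_profile(self):
        # 97% < 98%: one genome in 34 with a duplicate puts prevalence at ~0.97
        genomes = [f"g{i:02d}" for i in range(34)]
        frame = pd.DataFrame(
            {f"PF{i:02d}": [1] * 34 for i in range(20)}, index=genomes
        )
        frame.loc["g00", "PF00"] = 2  # prevalence 33/34 = 0.971
        newick = "(" * 33 + "g00," + ",".join(g + ")" for g in genomes[1:]) + ";"
        tree = ReferenceTree.from_newick(newick)
        sets = define_clade_sets(tree, MarkerCountMatrix(frame),
                                 DbConfig(min_species=3, min_profiles=19))
        for s in sets:
            if len(s.species_ids) == 34:
                assert "PF00" not in s.profile_ids

    def test_missing_leaf_named_in_error(self):
        tree = ReferenceTree.from_newick("((A,B),(C,D));")
        m = self.toy_matrix({"A": 1, "B": 1, "C": 1}, ["PF1"])
        with pytest.raises(InputError, match="D"):
            define_clade_sets(tree, m, DbConfig(min_species=2, min_profiles=1))

    def test_emitted_sets_satisfy_constraints_and_stored_prevalence(self):
        from magqc import synthesize_reference_fixture

        config = DbConfig(prevalence_cutoff=0.98, min_species=3, min_profiles=20)
        for seed in range(5):
            fx = synthesize_reference_fixture(
                n_species=10, n_profiles=40,
                per_profile_dropout=0.01 * seed, duplication_rate=0.3,
                seed=seed, genome_length=100_000, n_contigs=1,
            )
            for s in define_clade_sets(fx.tree, fx.matrix, config):
                assert len(s) >= config.min_profiles
                assert len(s.species_ids) >= config.min_species
                for p in s.profile_ids:
                    prev = single_copy_prevalence(fx.matrix, list(s.species_ids), p)
                    assert prev == s.prevalence[p]
                    assert prev >= config.prevalence_cutoff


class TestGreedyReferenceSet:
    @staticmethod
    def matrix_from_singles(singles: dict[str, set[str]], genomes: list[str]):
        frame = pd.DataFrame(
            {p: [1 if g in gs else 0 for g in genomes]
             for p, gs in singles.items()},
            index=genomes,
        )
        return MarkerCountMatrix(frame)

    def test_single_universal_profile_suffices(self):
        m = self.matrix_from_singles({"PF1": {"A", "B", "C"}}, ["A", "B", "C"])
        result = build_reference_set(m, DbConfig(min_cover=1))
        assert result.profiles == ("PF1",) and result.feasible

    def test_greedy_matches_enumerated_optimum_on_triangle(self):
        m = self.matrix_from_singles(
            {"P1": {"A", "B"}, "P2": {"B", "C"}, "P3": {"A", "C"}}, ["A", "B", "C"]
        )
        result = build_reference_set(m, DbConfig(min_cover=1))
        assert result.feasible and len(result.profiles) == 2
        assert len(result.profiles) == self.enumerated_optimum(m, 1)

    def test_infeasible_returns_best_effort_and_reports(self):
        m = self.matrix_from_singles({"P1": {"A", "B"}, "P2": {"A"}}, ["A", "B"])
        result = build_reference_set(m, DbConfig(min_cover=3))
        assert set(result.profiles) == {"P1", "P2"}
        assert "B" in result.under_covered and not result.feasible

    @staticmethod
    def enumerated_optimum(matrix: MarkerCountMatrix, min_cover: int) -> int | None:
        single = matrix.df.values == 1
        n_profiles = single.shape[1]
        for size in range(1, n_profiles + 1):
            for combo in itertools.combinations(range(n_profiles), size):
                if (single[:, combo].sum(axis=1) >= min_cover).all():
                    return size
        return None

    def test_cover_feasibility_and_ln_approximation_bound(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n_genomes = int(rng.integers(3, 8))
            n_profiles = int(rng.integers(3, 11))
            genomes = [f"g{i}" for i in range(n_genomes)]
            frame = pd.DataFrame(
                rng.integers(0, 2, size=(n_genomes, n_profiles)),
                index=genomes,
                columns=[f"P{j:02d}" for j in range(n_profiles)],
            )
            m = MarkerCountMatrix(frame)
            config = DbConfig(min_cover=1)
            result = build_reference_set(m, config)
            optimum = self.enumerated_optimum(m, config.min_cover)
            coverage = (frame[list(result.profiles)].values == 1).sum(axis=1)
            if optimum is None:
                assert not result.feasible
            else:
                assert result.feasible
                assert (coverage >= config.min_cover).all()
                assert len(result.profiles) <= optimum * (1 + math.log(n_genomes))


class TestBalancedSubset:
    @staticmethod
    def table(spec: dict[str, dict[str, int]]) -> pd.DataFrame:
        rows = []
        for clade, phyla in spec.items():
            for phylum, n in phyla.items():
                for i in range(n):
                    rows.append((f"{clade}_{phylum}_{i}", clade, phylum))
        return pd.DataFrame(rows, columns=["genome_id", "clade", "phylum"])

    def test_cap_arithmetic_across_clades(self):
        table = self.table({"c1": {"p": 40}, "c2": {"p": 10}, "c3": {"p": 5}})
        picked = select_balanced_subset(table, DbConfig(max_per_clade=30))
        assert len(picked) == 45

    def test_small_clade_taken_whole(self):
        table = self.table({"c1": {"p1": 5, "p2": 3}})
        assert len(select_balanced_subset(table, DbConfig(max_per_clade=30))) == 8

    def test_round_robin_even_allocation(self):
        table = self.table({"c1": {"pa": 20, "pb": 6, "pc": 4}})
        picked = select_balanced_subset(table, DbConfig(max_per_clade=12, seed=3))
        assert len(picked) == 12
        per_phylum = {
            p: sum(1 for g in picked if g.startswith(f"c1_{p}_"))
            for p in ("pa", "pb", "pc")
        }
        assert per_phylum == {"pa": 4, "pb": 4, "pc": 4}

    def test_even_allocation_among_unexhausted_phyla(self):
        # brute-force invariant over random configurations
        rng = np.random.default_rng(9)
        for trial in range(20):
            phyla = {f"p{j}": int(rng.integers(1, 12)) for j in range(int(rng.integers(2, 5)))}
            cap = int(rng.integers(2, 15))
            table = self.table({"c": phyla})
            picked = select_balanced_subset(
                table, DbConfig(max_per_clade=cap, seed=trial)
            )
            assert len(picked) == min(cap, sum(phyla.values()))
            taken = {p: sum(1 for g in picked if g.startswith(f"c_{p}_"))
                     for p in phyla}
            if len(table) > cap:
                unexhausted = [p for p in phyla if taken[p] < phyla[p]]
                if unexhausted:
                    values = [taken[p] for p in unexhausted]
                    assert max(values) - min(values) <= 1

    def test_deterministic_given_seed_and_empty_rejected(self):
        table = self.table({"c1": {"pa": 9, "pb": 9}})
        a = select_balanced_subset(table, DbConfig(max_per_clade=6, seed=5))
        b = select_balanced_subset(table, DbConfig(max_per_clade=6, seed=5))
        assert a == b
        with pytest.raises(InputError, match="no genomes"):
            select_balanced_subset(table.iloc[0:0], DbConfig())
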