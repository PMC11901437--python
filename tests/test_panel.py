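"""Panel selection: stats, union rates, greedy vs exhaustive, transferability."""

import numpy as np
import pandas as pd
import pytest

from indelmark import (
    GenotypingMatrix,
    combined_rate,
    exact_minimal_panel,
    greedy_panel,
    identification_stats,
    transferability,
)

B, M, A = "both_parents", "maternal_only", "ambiguous"


def matrix_from_sets(identified: dict[str, set[int]], n: int, population_id="pop", poly=None):
    """Build a matrix where marker m identifies exactly the given individuals."""
    inds = [f"I{i:02d}" for i in range(n)]
    calls = pd.DataFrame(
        {ind: {m: (B if i in s else M) for m, s in identified.items()} for i, ind in enumerate(inds)}
    ).loc[list(identified)]
    return GenotypingMatrix(population_id, calls, poly)


class TestIdentificationStats:
    def test_published_rate_arithmetic(self):
        matrix = matrix_from_sets({"InDel1-7": set(range(35)), "zero": set()}, 62)
        stats = identification_stats(matrix)
        assert stats.loc["InDel1-7", "n_identified"] == 35
        assert stats.loc["InDel1-7", "rate_pct"] == 56.5
        assert stats.loc["zero", "rate_pct"] == 0.0

    def test_counts_match_matrix_truth(self, genotyped, study):
        """Per-marker identified counts equal the truth derivable from the
        simulated call sets: marker allele AND linked paternal allele present."""
        matrix, _ = genotyped
        truth = study.truth
        stats = identification_stats(matrix)
        by_id = {t.sample_id: t for t in study.progeny.tables}
        from indelmark import discover

        markers = {
            m.marker_id: m
            for m in discover(
                study.parents.maternal_table,
                study.parents.paternal_table,
                study.progeny.tables,
            ).markers
        }
        for marker_id, row in stats.iterrows():
            mk = markers[marker_id].variant.key
            lk = truth.linked_paternal[mk]
            expected = sum(
                1
                for ind, t in by_id.items()
                if t.contains_informative(mk) and t.contains_informative(lk)
            )
            assert row["n_identified"] == expected


class TestCombinedRate:
    def test_disjoint_halves_union_to_full(self):
        matrix = matrix_from_sets(
            {"a": set(range(31)), "b": set(range(31, 62))}, 62
        )
        panel = combined_rate(matrix, ["a", "b"])
        assert panel.combined_rate_pct == 100.0

    def test_single_marker_panel_equals_marker_rate(self, genotyped):
        matrix, _ = genotyped
        stats = identification_stats(matrix)
        m = matrix.markers[0]
        assert combined_rate(matrix, [m]).combined_rate == stats.loc[m, "rate"]

    def test_unknown_marker_rejected(self, genotyped):
        matrix, _ = genotyped
        with pytest.raises(KeyError):
            combined_rate(matrix, ["nope"])

    def test_union_monotone_and_dominates_best_single(self, genotyped):
        matrix, _ = genotyped
        rates = []
        for k in range(1, len(matrix.markers) + 1):
            rates.append(combined_rate(matrix, matrix.markers[:k]).combined_rate)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        best_single = identification_stats(matrix)["rate"].max()
        assert rates[-1] >= best_single


class TestGreedyPanel:
    def test_single_covering_marker(self):
        matrix = matrix_from_sets({"a": set(range(10)), "b": set(range(5))}, 10)
        panel = greedy_panel(matrix)
        assert panel.marker_ids == ("a",) and panel.reached

    def test_planted_minimal_cover_of_four(self):
        sets = {
            "m1": set(range(0, 16)),
            "m2": set(range(16, 32)),
            "m3": set(range(32, 48)),
            "m4": set(range(48, 62)),
            "weak": set(range(0, 8)),
        }
        panel = greedy_panel(matrix_from_sets(sets, 62))
        assert panel.reached and panel.combined_rate == 1.0
        assert len(panel.marker_ids) >= 4

    def test_unreachable_target_flagged(self):
        matrix = matrix_from_sets({"a": set(range(5))}, 10)
        panel = greedy_panel(matrix, target_rate=1.0)
        assert not panel.reached and panel.combined_rate == 0.5

    def test_deterministic_tie_breaking(self):
        # b and c tie on gain; c has the higher total count at a later step,
        # equal-everything ties resolve lexicographically
        sets = {"b": {0, 1}, "a": {0, 1}, "c": {2, 3}}
        panel = greedy_panel(matrix_from_sets(sets, 4))
        assert panel.marker_ids == ("a", "c")

    def test_classic_trap_greedy_suboptimal_but_exact_minimal(self):
        """Set-cover trap: greedy picks the large overlap set first and needs
        three markers; the exact solver finds the planted two-marker cover."""
        trap = {
            "big": set(range(0, 4)),  # overlaps both halves
            "left": set(range(0, 3)),
            "right": set(range(3, 6)),
        }
        trap["big"] = {0, 1, 3, 4}
        matrix = matrix_from_sets(trap, 6)
        greedy = greedy_panel(matrix)
        exact = exact_minimal_panel(matrix)
        assert len(exact.marker_ids) == 2
        assert exact.combined_rate == 1.0
        assert len(greedy.marker_ids) > len(exact.marker_ids)

    def test_exact_refuses_large_instances(self):
        sets = {f"m{i:02d}": {i} for i in range(25)}
        with pytest.raises(ValueError, match="greedy_panel"):
            exact_minimal_panel(matrix_from_sets(sets, 25))

    def test_exact_equals_greedy_when_greedy_provably_optimal(self):
        # single full-cover marker and disjoint equal covers
        full = matrix_from_sets({"a": set(range(6)), "b": {0}}, 6)
        assert exact_minimal_panel(full).marker_ids == greedy_panel(full).marker_ids
        disjoint = matrix_from_sets({"a": set(range(3)), "b": set(range(3, 6))}, 6)
        g, e = greedy_panel(disjoint), exact_minimal_panel(disjoint)
        assert g.combined_rate == e.combined_rate == 1.0
        assert len(g.marker_ids) == len(e.marker_ids) == 2

    def test_max_coverage_guarantee_on_random_matrices(self):
        """Greedy coverage at size k >= (1 - 1/e) x optimal coverage at size k,
        over random 20 x 60 matrices (brute-force optimum)."""
        from itertools import combinations

        rng = np.random.default_rng(17)
        k = 3
        bound = 1 - 1 / np.e
        for _ in range(100):
            sets = {
                f"m{j:02d}": set(np.flatnonzero(rng.random(60) < 0.15).tolist())
                for j in range(20)
            }
            matrix = matrix_from_sets(sets, 60)
            greedy_cov = len(greedy_panel(matrix, max_size=k).identified_individuals)
            opt = max(
                len(set().union(*(sets[m] for m in combo)))
                for combo in combinations(sets, k)
            )
            assert greedy_cov >= bound * opt - 1e-9


class TestTransferability:
    def test_published_rate_arithmetic(self):
        """46 F1 / 38 hybrids / 45 of 51 effective -> 82.6% and 88.2%."""
        markers = [f"M{j:02d}" for j in range(51)]
        sets = {m: (set(range(38)) if j < 45 else set()) for j, m in enumerate(markers)}
        poly = {m: j < 45 for j, m in enumerate(markers)}
        matrix = matrix_from_sets(sets, 46, poly=poly)
        report = transferability(matrix, markers)
        assert report.n_true_hybrid == 38
        assert report.hybrid_rate_pct == 82.6
        assert report.n_effective_markers == 45
        assert report.universality_rate_pct == 88.2

    def test_no_effective_markers(self):
        markers = ["M0", "M1"]
        matrix = matrix_from_sets({m: set() for m in markers}, 10)
        report = transferability(matrix, markers)
        assert report.universality_rate_pct == 0.0
        assert report.n_true_hybrid == 0

    def test_polymorphic_but_uninformative_marker_not_effective(self):
        sets = {"a": {0}, "b": set()}
        matrix = matrix_from_sets(sets, 4)
        report = transferability(matrix, ["a", "b"])
        assert report.n_polymorphic_markers == 2
        assert report.n_effective_markers == 1
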