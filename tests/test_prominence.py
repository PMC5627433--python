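"""Background simulation, Fisher's exact test, and prominence calling."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from blockspec import (
    AMINO_ACIDS,
    BLOCK_BY_LABEL,
    BlockCombination,
    ContingencyTable,
    ProminenceRecord,
    SubstrateSet,
    SubstrateWindow,
    estimate_background,
    find_prominent,
    fisher_exact_greater,
    hypergeom_point_prob,
    protease_block_proportions,
    simulate_background,
    substrate_coverage,
)
from blockspec.prominence import BlockCoverage
from blockspec.synthetic import (
    PlantedMotif,
    SyntheticSpec,
    generate_substrate_set,
)
from conftest import random_gapfree_set


def fisher_oracle(a, b, c, d):
    """Exhaustive one-sided Fisher p: exact integer enumeration over the tail."""
    r1, r2, m = a + b, c + d, a + c
    denom = math.comb(r1 + r2, m)
    num = sum(math.comb(r1, ap) * math.comb(r2, m - ap)
              for ap in range(a, min(r1, m) + 1))
    return num / denom


class TestEstimateBackground:
    def test_identical_windows_give_point_masses(self):
        sset = SubstrateSet("x", [SubstrateWindow("DEVDGSAK")] * 4)
        model = estimate_background(sset)
        for pos, aa in enumerate("DEVDGSAK"):
            assert model.frequencies[pos, AMINO_ACIDS.index(aa)] == 1.0

    def test_two_windows_differing_everywhere_split_half(self):
        sset = SubstrateSet("x", [SubstrateWindow("DEVDGSAK"),
                                  SubstrateWindow("KASGDVED")])
        model = estimate_background(sset)
        assert np.all(np.isin(model.frequencies, [0.0, 0.5]))

    def test_rows_sum_to_one(self, rng):
        model = estimate_background(random_gapfree_set(rng, 37))
        assert np.allclose(model.frequencies.sum(axis=1), 1.0)

    def test_unobserved_position_is_an_error(self):
        sset = SubstrateSet("x", [SubstrateWindow("-EVDGSAK")])
        with pytest.raises(ValueError, match="P4"):
            estimate_background(sset)

    def test_pooled_mode_gives_single_distribution(self, rng):
        model = estimate_background(random_gapfree_set(rng, 20), mode="pooled")
        assert model.frequencies.shape == (20,)
        assert model.frequencies.sum() == pytest.approx(1.0)


class TestSimulateBackground:
    def test_zero_windows(self, rng):
        model = estimate_background(random_gapfree_set(rng, 10))
        assert len(simulate_background(model, 0, seed=1).windows) == 0

    def test_point_mass_model_repeats_one_window(self):
        sset = SubstrateSet("x", [SubstrateWindow("DEVDGSAK")] * 3)
        model = estimate_background(sset)
        out = simulate_background(model, 5, seed=9)
        assert all(w.residues == "DEVDGSAK" for w in out.windows)

    def test_same_seed_same_output(self, rng):
        model = estimate_background(random_gapfree_set(rng, 30))
        a = simulate_background(model, 50, seed=4)
        b = simulate_background(model, 50, seed=4)
        assert [w.residues for w in a.windows] == [w.residues for w in b.windows]

    def test_empirical_frequencies_approach_model(self, rng):
        # total-variation distance shrinks as ~1/sqrt(n) per position
        model = estimate_background(random_gapfree_set(rng, 200))
        n = 20000
        out = simulate_background(model, n, seed=12)
        for pos in range(8):
            observed = np.zeros(20)
            for w in out.windows:
                observed[AMINO_ACIDS.index(w.residues[pos])] += 1
            tv = 0.5 * np.abs(observed / n - model.frequencies[pos]).sum()
            assert tv < 0.03


class TestHypergeomPointProb:
    def test_balanced_disjoint_table(self):
        assert hypergeom_point_prob(ContingencyTable(5, 0, 0, 5)) == \
            pytest.approx(1 / 252, rel=1e-12)

    def test_degenerate_single_cell_table(self):
        assert hypergeom_point_prob(ContingencyTable(1, 0, 0, 0)) == pytest.approx(1.0)

    def test_normalization_over_feasible_tables(self, rng):
        for _ in range(25):
            r1, r2 = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            m = int(rng.integers(0, r1 + r2 + 1))
            total = sum(
                hypergeom_point_prob(ContingencyTable(a, r1 - a, m - a, r2 - m + a))
                for a in range(max(0, m - r2), min(r1, m) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestFisherExactGreater:
    def test_fully_disjoint_table_tail_is_single_term(self):
        assert fisher_exact_greater(ContingencyTable(5, 0, 0, 5)) == \
            pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert fisher_exact_greater(ContingencyTable(0, 5, 3, 2)) == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        p = fisher_exact_greater(ContingencyTable(2, 3, 2, 3))
        assert p == pytest.approx(fisher_oracle(2, 3, 2, 3), abs=1e-12)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    def test_matches_scipy_reference(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        mine = fisher_exact_greater(ContingencyTable(a, b, c, d))
        ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_p_non_increasing_in_overlap_at_fixed_margins(self):
        # margins (10, 10) rows, column total 8
        ps = [fisher_exact_greater(ContingencyTable(a, 10 - a, 8 - a, 2 + a))
              for a in range(0, 9)]
        assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


class TestFindProminent:
    @pytest.mark.parametrize("kwargs", [{"reps": 0}, {"reps": -3},
                                        {"alpha": 0.0}, {"alpha": 1.0}])
    def test_invalid_parameters_rejected(self, rng, kwargs):
        sset = random_gapfree_set(rng, 10)
        with pytest.raises(ValueError):
            find_prominent(sset, seed=1, **kwargs)

    def test_identical_windows_never_prominent(self):
        sset = SubstrateSet("x", [SubstrateWindow("DEVDGSAK")] * 20)
        records = find_prominent(sset, reps=100, seed=2)
        assert all(not r.prominent for r in records)
        assert all(r.median_p == pytest.approx(1.0) for r in records)

    def test_planted_combination_detected(self):
        spec = SyntheticSpec(
            n_windows=200,
            planted=(PlantedMotif(
                BlockCombination(BLOCK_BY_LABEL["B2"], "LK"), 0.6),),
            seed=7,
        )
        sset = generate_substrate_set(spec)
        records = find_prominent(sset, reps=200, seed=13)
        prominent = {str(r.combination) for r in records if r.prominent}
        assert "LK@B2" in prominent

    def test_reproducible_under_fixed_seed(self, rng):
        sset = random_gapfree_set(rng, 60)
        a = find_prominent(sset, reps=50, seed=5)
        b = find_prominent(sset, reps=50, seed=5)
        assert a == b

    def test_votes_bounded_and_bonferroni_recorded(self, rng):
        sset = random_gapfree_set(rng, 50)
        records = find_prominent(sset, reps=60, seed=8)
        for r in records:
            assert 0 <= r.votes <= 60
            assert r.alpha_corrected == pytest.approx(0.05 / r.n_tests)
            assert r.prominent == (r.votes > 30)

    def test_truncated_windows_drop_out_per_block(self):
        # gap at P4 removes windows from B4 only; B4 totals shrink
        texts = ["-EVDGSAK"] * 4 + ["DEVDGSAK"] * 4
        sset = SubstrateSet("x", [SubstrateWindow(t) for t in texts])
        records = find_prominent(sset, reps=10, seed=3)
        totals = {r.combination.block.label: r.experiment_total for r in records}
        assert totals["B4"] == 4
        assert totals["B3"] == 8

    def test_records_sorted_by_block_then_count(self, rng):
        sset = random_gapfree_set(rng, 80)
        records = find_prominent(sset, reps=10, seed=4)
        block_order = [b.label for b in
                       (BLOCK_BY_LABEL[l] for l in
                        ("B4", "B3", "B2", "B1", "B1'", "B2'", "B3'", "B4'"))]
        seen = [r.combination.block.label for r in records]
        assert seen == sorted(seen, key=block_order.index)
        for label in set(seen):
            counts = [r.experiment_count for r in records
                      if r.combination.block.label == label]
            assert counts == sorted(counts, reverse=True)


def make_record(block_label, kmer, count, total, prominent, reps=10):
    votes = reps if prominent else 0
    return ProminenceRecord(
        combination=BlockCombination(BLOCK_BY_LABEL[block_label], kmer),
        experiment_count=count, experiment_total=total, n_tests=5,
        alpha_corrected=0.01, reps=reps, votes=votes,
        median_p=0.001 if prominent else 0.9, prominent=prominent,
    )


class TestCoverageSummaries:
    def test_block_without_prominent_combination_is_none_state(self, rng):
        sset = random_gapfree_set(rng, 20)
        cov = substrate_coverage(sset, [])
        assert all(bc.bin is None and bc.state == "none" for bc in cov.values())

    @pytest.mark.parametrize("fraction,expected_bin",
                             [(0.15, 0), (0.25, 1), (0.45, 2), (0.65, 3),
                              (0.85, 4), (0.80, 4), (0.19, 0)])
    def test_five_shade_binning(self, fraction, expected_bin, rng):
        n = 100
        k = int(fraction * n)
        windows = [SubstrateWindow("DEVDGSAK")] * k + \
            [SubstrateWindow("AAAAGSAK")] * (n - k)
        sset = SubstrateSet("x", windows)
        records = [make_record("B4", "DEVD", k, n, True)]
        bc = substrate_coverage(sset, records)["B4"]
        assert bc.fraction == pytest.approx(fraction)
        assert bc.bin == expected_bin

    def test_proportions_over_proteases(self):
        results = {
            "p1": [make_record("B2", "LK", 10, 20, True)],
            "p2": [make_record("B2", "AR", 8, 20, True),
                   make_record("B1", "K", 12, 20, True)],
            "p3": [make_record("B2", "LK", 2, 20, False)],
            "p4": [],
        }
        props = protease_block_proportions(results)
        assert props["B2"] == pytest.approx(50.0)
        assert props["B1"] == pytest.approx(25.0)
        assert props["B4'"] == 0.0

    def test_proportions_need_at_least_one_protease(self):
        with pytest.raises(ValueError):
            protease_block_proportions({})
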