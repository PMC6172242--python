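"""Probe panel selection: scoring, knowledge gradient, greedy cover, baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from accessprobe import design, thermo
from accessprobe.design import (
    CoverageError,
    KnowledgeState,
    baseline_design,
    enumerate_candidate_regions,
    experimental_effort,
    greedy_set_cover,
    hybridization_score,
    kg_value,
    kg_values,
    rescale_efforts,
    score_regions,
    top_fraction,
)


class TestEnumerateRegions:
    def test_exhaustive_window_count_matches_closed_form(self):
        ta = "A" * 20
        regions = enumerate_candidate_regions(ta, 9, 16)
        expected = sum(20 - w + 1 for w in range(9, 17))
        assert len(regions) == expected == 68

    def test_single_window(self):
        regions = enumerate_candidate_regions("ACGUACGUA", 9, 9)
        assert len(regions) == 1
        assert regions[0].interval == (1, 9)

    def test_random_mode_is_seeded(self):
        ta = "ACGU" * 10
        a = enumerate_candidate_regions(ta, mode="random", sample_size=10, seed=5)
        b = enumerate_candidate_regions(ta, mode="random", sample_size=10, seed=5)
        assert a == b

    def test_oversized_sample_capped_with_warning(self):
        with pytest.warns(UserWarning):
            regions = enumerate_candidate_regions("A" * 12, 9, 9, mode="random",
                                                  sample_size=100, seed=0)
        assert len(regions) == 4

    def test_probe_is_reverse_complement(self):
        (r,) = enumerate_candidate_regions("GAUCGAUCG", 9, 9)
        assert r.probe_seq == thermo.reverse_complement(r.region_seq)


class TestHybridizationScore:
    def test_all_A_target_forced_arithmetic(self, model):
        # fully unpaired target, unstructured probe: nu = L * (0 - (-2L))
        ta = "A" * 30
        (region,) = enumerate_candidate_regions(ta, 9, 9)[:1]
        s = hybridization_score(region, ta, model)
        assert s.theta_bar == pytest.approx(9.0)
        assert s.dG_tf == pytest.approx(0.0)
        assert s.dG_asF == pytest.approx(0.0)
        assert s.dG_asT == pytest.approx(-18.0)
        assert s.nu == pytest.approx(162.0)

    def test_zero_theta_reduces_to_probe_folding(self, model):
        region = enumerate_candidate_regions("A" * 30, 9, 9)[0]
        s = hybridization_score(region, "A" * 30, model)
        assert 0.0 * (s.dG_tf - s.dG_asT) + s.dG_asF == pytest.approx(s.dG_asF)

    def test_components_match_oracle_composition(self, model):
        # compose nu by hand from brute-force ensemble terms
        ta = "GGGAAACCC"
        _, _, _, up, _ = thermo.enumerate_structures(ta, model)
        region = design.CandidateRegion("ta", 4, 6, "AAA",
                                        thermo.reverse_complement("AAA"))
        s = hybridization_score(region, ta, model)
        theta = up[3:6].sum()
        dg_tf = thermo.opening_energy(ta, 4, 6, model)
        dg_ast = thermo.duplex_energy("UUU", "AAA", model)
        expected = theta * (dg_tf - dg_ast) + thermo._mfe("UUU", model)  # UUU folds to 0
        assert s.theta_bar == pytest.approx(theta, rel=1e-9)
        assert s.nu == pytest.approx(expected, rel=1e-9)

    def test_score_regions_shares_ensemble(self, model):
        ta = "GGGAAACCCAAA"
        regions = enumerate_candidate_regions(ta, 9, 10)
        batch = score_regions(regions, ta, model)
        single = [hybridization_score(r, ta, model) for r in regions]
        assert [s.nu for s in batch] == pytest.approx([s.nu for s in single])


class TestKnowledgeGradient:
    def test_closed_form_symmetric_case(self):
        state = KnowledgeState([0.0, 0.0], [1.0, 1.0], 1.0)
        v = kg_values(state)
        expected = norm.pdf(0.0) / np.sqrt(2.0)
        assert v == pytest.approx([expected, expected])
        assert expected == pytest.approx(0.28209, abs=1e-5)

    def test_zero_variance_gives_zero_value(self):
        state = KnowledgeState([1.0, 0.0], [0.0, 1.0], 1.0)
        assert kg_value(state, 0) == 0.0

    def test_monte_carlo_cross_check(self):
        # v_k = E[max posterior mean after one measurement] - max prior mean
        rng = np.random.default_rng(123)
        mu = np.array([0.3, 0.0])
        sigma2 = np.array([0.8, 0.5])
        s2e = 0.7
        v = kg_values(KnowledgeState(mu, sigma2, s2e))
        for k in range(2):
            y = rng.normal(mu[k], np.sqrt(sigma2[k] + s2e), size=400_000)
            post_k = mu[k] + sigma2[k] / (sigma2[k] + s2e) * (y - mu[k])
            other = mu[1 - k]
            gain = np.maximum(post_k, other).mean() - max(mu)
            assert v[k] == pytest.approx(gain, abs=2e-3)

    def test_value_decreases_with_mean_gap(self):
        vals = [
            kg_value(KnowledgeState([gap, 0.0], [1.0, 1.0], 1.0), 0)
            for gap in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)

    def test_needs_two_regions(self):
        with pytest.raises(ValueError):
            kg_values(KnowledgeState([0.0], [1.0], 1.0))


class TestGreedyCover:
    def test_single_spanning_candidate(self):
        d = greedy_set_cover([(1, 10)], [0.0], lam=1.0, L=10)
        assert d.selected == [0]
        assert d.full_coverage

    def test_worked_three_candidate_instance(self):
        d = greedy_set_cover([(1, 6), (5, 10), (1, 10)], [0.5, 0.5, 0.1], lam=1.0, L=10)
        assert d.selected == [0, 1]
        step1, step2 = d.alpha_trace
        assert step1[0] == pytest.approx(0.5 / 6)
        assert step1[1] == pytest.approx(0.5 / 6)
        assert step1[2] == pytest.approx(0.9 / 10)
        assert step2[1] == pytest.approx(0.5 / 4)
        assert step2[2] == pytest.approx(0.9 / 4)

    def test_covered_candidate_leaves_pool(self):
        # after [1,10] is chosen, [2,5] has zero marginal gain and must not appear
        d = greedy_set_cover([(1, 10), (2, 5)], [5.0, 0.5], lam=1.0, L=10)
        assert d.selected == [0]

    def test_high_value_regions_beat_lambda(self):
        # v > lambda makes alpha negative: the dense small region goes first
        d = greedy_set_cover([(1, 10), (2, 5)], [5.0, 4.0], lam=1.0, L=10)
        assert d.selected == [1, 0]

    def test_infeasible_names_uncovered(self):
        with pytest.raises(CoverageError, match="9"):
            greedy_set_cover([(1, 6)], [0.0], lam=1.0, L=10)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_random_instances_cover_without_waste(self, data):
        L = data.draw(st.integers(8, 25))
        n = data.draw(st.integers(1, 12))
        intervals = [(1, L)]  # guarantee feasibility
        for _ in range(n - 1):
            s = data.draw(st.integers(1, L))
            e = data.draw(st.integers(s, L))
            intervals.append((s, e))
        v = [data.draw(st.floats(0, 2)) for _ in intervals]
        d = greedy_set_cover(intervals, v, lam=1.0, L=L)
        assert d.full_coverage
        # every selection had nonzero marginal gain at selection time
        covered = set()
        for k in d.selected:
            s, e = intervals[k]
            gain = set(range(s, e + 1)) - covered
            assert gain
            covered |= gain

    def test_greedy_objective_bounded_by_exhaustive_optimum(self, rng):
        lam = 1.0
        for _ in range(40):
            L = int(rng.integers(8, 16))
            n = int(rng.integers(2, 10))
            intervals = [(1, L)] + [
                tuple(sorted(rng.integers(1, L + 1, size=2))) for _ in range(n - 1)
            ]
            v = rng.uniform(0, 2, size=n)
            d = greedy_set_cover(intervals, v, lam=lam, L=L)
            greedy_obj = sum(v[k] for k in d.selected) - lam * len(d.selected)
            best = -np.inf
            universe = set(range(1, L + 1))
            for r in range(1, n + 1):
                for combo in itertools.combinations(range(n), r):
                    cov = set()
                    for k in combo:
                        cov.update(range(intervals[k][0], intervals[k][1] + 1))
                    if cov == universe:
                        best = max(best, sum(v[k] for k in combo) - lam * r)
            assert greedy_obj <= best + 1e-9


class TestBaselines:
    def test_exploration_is_seeded_and_covers(self):
        ta = thermo.NucleotideSequence("ACGU" * 15, id="ta")
        a = baseline_design(ta, "exploration", seed=3)
        b = baseline_design(ta, "exploration", seed=3)
        assert a.selected == b.selected
        assert a.full_coverage
        assert all(r.length == 12 for r in a.regions)

    def test_exploitation_covers_fully(self):
        ta = thermo.NucleotideSequence("GGGAAACCCAAAGGGAAACCC", id="ta")
        d = baseline_design(ta, "exploitation", lam=1.0)
        assert d.full_coverage

    def test_uniform_scores_reduce_to_coverage_minimization(self):
        # all-A taRNA: every window scores identically, so lambda dominates and
        # the greedy picks the fewest, earliest windows
        # same-length windows on an all-A taRNA score identically, so the
        # normalized values vanish and lambda alone drives the cover
        ta = thermo.NucleotideSequence("A" * 40, id="ta")
        d = baseline_design(ta, "exploitation", lam=1.0, min_len=16, max_len=16)
        picked = [d.regions[k].interval for k in d.selected]
        assert picked[0] == (1, 16)
        assert len(picked) == 3


class TestEffort:
    def test_optimal_selection_costs_nothing(self):
        assert experimental_effort([0.2, 1.0], [0.1, 0.2, 1.0]) == 0.0

    def test_raw_effort_arithmetic(self):
        assert experimental_effort([0.2], [1.0, 0.2]) == pytest.approx(0.8)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            experimental_effort([], [1.0])

    def test_rescale_contract(self):
        scaled = rescale_efforts({"a": 0.5, "b": 0.1, "c": 0.3})
        assert min(scaled.values()) == 0.0
        assert max(scaled.values()) == 1.0
        assert scaled["b"] == 0.0 and scaled["a"] == 1.0


def test_top_fraction_rank_filter():
    values = np.arange(1000)
    keep = top_fraction(values, 0.015)
    assert len(keep) == 15
    assert set(values[keep]) == set(range(985, 1000))
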