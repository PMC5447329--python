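"""Relative-rate framework: depths, rates, merging, SEs, relative times."""

import math
import warnings

import numpy as np
import pytest

from relclock import rrf, simulate, treeio
from relclock.treeio import ROOT, read_newick

from conftest import clock_tree


def _rate_of(tree, rates, label):
    return rates.rate[tree.tip_id(label)]


class TestLineageDepths:
    def test_clock_tree(self, balanced4):
        dep = rrf.lineage_depths(balanced4)
        internal = balanced4.internal_ids
        assert dep.H[ROOT] == 2.0
        assert all(dep.H[v] == 1.0 for v in internal if v != ROOT)

    def test_hand_recursion(self, uneven4):
        dep = rrf.lineage_depths(uneven4)
        ab = uneven4.parent[uneven4.tip_id("A")]
        assert dep.H[ab] == 1.5
        assert dep.H[ROOT] == 2.25

    def test_variance_recursion(self, uneven4):
        dep = rrf.lineage_depths(uneven4, L=10)
        a = uneven4.tip_id("A")
        ab = uneven4.parent[a]
        assert dep.var_D[a] == pytest.approx(0.2)
        assert dep.var_H[ab] == pytest.approx(0.075)


class TestAssignRelativeRates:
    def test_hand_oracle_infinite_L(self, uneven4):
        t = uneven4
        rates = rrf.assign_relative_rates(t)  # L = inf, exact-equality merge
        assert _rate_of(t, rates, "A") == pytest.approx(5 / 3, abs=1e-12)
        assert _rate_of(t, rates, "B") == pytest.approx(5 / 6, abs=1e-12)
        assert _rate_of(t, rates, "C") == pytest.approx(1.0, abs=1e-12)
        assert _rate_of(t, rates, "D") == pytest.approx(1.0, abs=1e-12)
        ab = t.parent[t.tip_id("A")]
        assert rates.rate[ab] == pytest.approx(1.25, abs=1e-12)
        assert rates.median == pytest.approx(8 / 9, abs=1e-12)
        # only the exactly clock-like C/D cherry merges at infinite L
        assert not rates.merged[uneven4.tip_id("A")]
        assert not rates.merged[uneven4.tip_id("B")]
        assert rates.merged[uneven4.tip_id("C")]
        assert rates.merged[uneven4.tip_id("D")]

    def test_full_merge_at_small_L(self, uneven4):
        # every z statistic falls below 2 (e.g. the A lineage:
        # 0.5/sqrt(0.275) ~ 0.95), so the whole tree collapses to a clock
        rates = rrf.assign_relative_rates(uneven4, L=10, z_merge=2.0)
        np.testing.assert_allclose(rates.rate[1:], 1.0)
        assert rates.merged[1:].all()

    def test_clock_tree_rates_one(self, balanced4):
        rates = rrf.assign_relative_rates(balanced4)
        np.testing.assert_allclose(rates.rate[1:], 1.0)

    def test_median_is_one(self):
        for seed in range(10):
            cfg = simulate.SimulationConfig(n_tips=12, seed=seed, L=200,
                                            noise="poisson")
            truth = simulate.simulate_dataset(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rates = rrf.assign_relative_rates(truth.observed, L=200)
            assert np.median(rates.rate[1:]) == pytest.approx(1.0, abs=1e-12)

    def test_merged_rate_equals_parent(self):
        cfg = simulate.SimulationConfig(n_tips=20, seed=4, L=500,
                                        noise="poisson")
        truth = simulate.simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rates = rrf.assign_relative_rates(truth.observed, L=500)
        tree = truth.observed
        for v in range(1, tree.n_nodes):
            if rates.merged[v]:
                p = tree.parent[v]
                # merged child carries its parent's branch rate exactly
                # (virtual pre-normalization rate 1 above the root)
                expected = (rates.rate[p] if p != ROOT
                            else 1.0 / rates.median)
                assert rates.rate[v] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_zero_subtree_warns(self):
        t = read_newick("((A:0,B:0):1,(C:1,D:1):1);")
        with pytest.warns(RuntimeWarning, match="zero"):
            rates = rrf.assign_relative_rates(t, L=100)
        a = t.tip_id("A")
        assert rates.merged[a]


class TestMergeBehaviour:
    def test_collapse_monotone_in_L(self):
        cfg = simulate.SimulationConfig(n_tips=32, seed=2, noise="none")
        truth = simulate.simulate_dataset(cfg)
        tree = truth.observed
        merged_counts = []
        for L in (10**7, 10**5, 10**3, 10**1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rates = rrf.assign_relative_rates(tree, L=L)
            merged_counts.append(int(rates.merged.sum()))
        assert all(a <= b for a, b in zip(merged_counts, merged_counts[1:]))
        # at tiny L the whole tree is a strict clock
        assert merged_counts[-1] == tree.n_nodes - 1

    def test_infinite_L_merges_only_exact_equality(self, uneven4, balanced4):
        merged = rrf.assign_relative_rates(uneven4).merged
        # unequal depths never merge without sampling error...
        for lab in ("A", "B"):
            assert not merged[uneven4.tip_id(lab)]
        # ...while exactly equal depths always do
        for lab in ("C", "D"):
            assert merged[uneven4.tip_id(lab)]
        assert rrf.assign_relative_rates(balanced4).merged[1:].all()


class TestRateSE:
    def test_zero_at_infinite_L(self, uneven4):
        rates = rrf.assign_relative_rates(uneven4)
        assert np.all(rates.se[1:] == 0.0)

    def test_hand_delta_method(self, uneven4):
        rates = rrf.assign_relative_rates(uneven4, L=10)
        a = uneven4.tip_id("A")
        expected = (2 / 1.5) * math.sqrt(0.2 / 4 + 0.075 / 2.25)
        assert rates.se[a] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.385, abs=5e-4)

    def test_halving_L_scales_se_by_sqrt2(self, uneven4):
        se1 = rrf.assign_relative_rates(uneven4, L=20).se
        se2 = rrf.assign_relative_rates(uneven4, L=10).se
        np.testing.assert_allclose(se2[1:], se1[1:] * math.sqrt(2),
                                   rtol=1e-12)


class TestRelativeTimes:
    def test_hand_oracle_unmerged(self, uneven4):
        t = uneven4
        rates = rrf.assign_relative_rates(t)
        chron = rrf.relative_times(t, rates)
        ab = t.parent[t.tip_id("A")]
        cd = t.parent[t.tip_id("C")]
        assert chron.ages[ROOT] == 1.0
        assert chron.ages[ab] == pytest.approx(0.6, abs=1e-12)
        assert chron.ages[cd] == pytest.approx(0.5, abs=1e-12)

    def test_hand_oracle_fully_merged(self, uneven4):
        t = uneven4
        rates = rrf.assign_relative_rates(t, L=10)  # all rates 1
        chron = rrf.relative_times(t, rates)
        ab = t.parent[t.tip_id("A")]
        cd = t.parent[t.tip_id("C")]
        assert chron.ages[ab] == pytest.approx(1.5 / 2.25, abs=1e-12)
        assert chron.ages[cd] == pytest.approx(1.0 / 2.25, abs=1e-12)

    def test_clock_tree(self, balanced4):
        rates = rrf.assign_relative_rates(balanced4)
        chron = rrf.relative_times(balanced4, rates)
        internal = [v for v in balanced4.internal_ids if v != ROOT]
        np.testing.assert_allclose(chron.ages[internal], 0.5)

    def test_clock_identity_random_trees(self):
        # branch lengths exactly proportional to durations: the RRF must
        # return rates 1 and the true relative ages, for any rate constant
        for seed in range(50):
            tree, timetree = clock_tree(n_tips=6 + seed % 7, seed=seed,
                                        rate=0.37)
            rates = rrf.assign_relative_rates(tree)
            np.testing.assert_allclose(rates.rate[1:], 1.0, atol=1e-9)
            chron = rrf.relative_times(tree, rates)
            np.testing.assert_allclose(chron.ages, timetree.relative().ages,
                                       atol=1e-9)
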