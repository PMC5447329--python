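"""Comparison diagnostics: regressions, collapse metrics, SE profiles."""

import math
import warnings

import numpy as np
import pytest

from relclock import diagnostics, rrf, simulate, timeprior
from relclock.simulate import SimulationConfig
from relclock.treeio import ROOT, Calibration, CalibrationSet, Chronogram, \
    read_newick

from conftest import clock_tree


def chron_pair(values_x, values_y):
    """Build two chronograms on a ladder tree whose internal non-root ages
    are the given vectors."""
    n = len(values_x)
    s = "(T0:1,T1:1)"
    for i in range(2, n + 2):
        s = f"({s}:1,T{i}:1)"
    tree = read_newick(s + ";")
    internal = [v for v in tree.internal_ids if v != ROOT]
    assert len(internal) == n
    # deepest node gets the smallest x; each y stays paired with its x
    order = np.argsort(values_x)
    nodes = sorted(internal, reverse=True)

    def build(vals):
        ages = np.zeros(tree.n_nodes)
        ages[ROOT] = 1.0
        for v, i in zip(nodes, order):
            ages[v] = vals[i]
        return Chronogram(tree, ages)

    return build(values_x), build(values_y)


class TestCompareRelativeAges:
    def test_identity(self):
        x, y = chron_pair([0.2, 0.4, 0.6, 0.8], [0.2, 0.4, 0.6, 0.8])
        reg = diagnostics.compare_relative_ages(x, y)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine(self):
        x, y = chron_pair([0.2, 0.4, 0.6, 0.8],
                          [0.5 * v + 0.1 for v in (0.2, 0.4, 0.6, 0.8)])
        reg = diagnostics.compare_relative_ages(x, y)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.slope == pytest.approx(0.5)

    def test_hand_ols_oracle(self):
        # r = 0.14 / sqrt(0.2 * 0.125) -> r^2 = 0.784
        x, y = chron_pair([0.2, 0.4, 0.6, 0.8], [0.3, 0.35, 0.7, 0.65])
        reg = diagnostics.compare_relative_ages(x, y)
        assert reg.r2 == pytest.approx(0.784, abs=1e-9)

    def test_symmetric_r2(self):
        x, y = chron_pair([0.2, 0.4, 0.6, 0.8], [0.3, 0.35, 0.7, 0.65])
        assert (diagnostics.compare_relative_ages(x, y).r2
                == pytest.approx(diagnostics.compare_relative_ages(y, x).r2))

    def test_too_few_nodes(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        c = Chronogram(tree, np.array([1.0, 0.5, 0, 0, 0]))
        with pytest.raises(ValueError, match="3"):
            diagnostics.compare_relative_ages(c, c)

    def test_zero_variance_flagged(self):
        x, y = chron_pair([0.5, 0.5, 0.5, 0.5], [0.3, 0.35, 0.7, 0.65])
        reg = diagnostics.compare_relative_ages(x, y)
        assert reg.degenerate and reg.r2 is None

    def test_strict_clock_truth_gives_r2_one(self):
        # both methods recover the same truth under a strict clock, so the
        # RRF and Bayesian relative ages can only disagree when rates vary
        tree, timetree = clock_tree(n_tips=10, seed=3)
        rates, chron = rrf.reltime(tree)
        reg = diagnostics.compare_relative_ages(chron, timetree.relative())
        assert reg.r2 == pytest.approx(1.0, abs=1e-9)


class TestCollapseMetrics:
    def _assignment(self, tree, rate_vec):
        return rrf.RateAssignment(
            tree, np.array(rate_vec, float), np.zeros(len(rate_vec)),
            np.zeros(len(rate_vec), bool), np.full(len(rate_vec), np.nan),
            1.0, math.inf, 2.0)

    def test_full_collapse(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        rates = self._assignment(tree, [np.nan, 1, 1, 1, 1, 1, 1])
        idx, depth = diagnostics.collapse_metrics(rates, ages)
        assert idx == 1.0 and depth == 0.0

    def test_no_collapse(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        rates = self._assignment(tree, [np.nan, 1.3, 0.7, 1.1, 0.9, 1.2, 0.8])
        idx, depth = diagnostics.collapse_metrics(rates, ages)
        assert idx == 0.0 and depth is None

    def test_partial_collapse_depth(self):
        # deep internal branch at median, shallow internal branch off it
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        rates = self._assignment(tree, [np.nan, 1.0, 1.4, 0.9, 1.1, 1.2, 0.8])
        idx, depth = diagnostics.collapse_metrics(rates, ages)
        assert idx == pytest.approx(0.5)
        assert depth == pytest.approx(1.0 / 3.0)  # relative age of off node

    def test_tolerance_monotone(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        rates = self._assignment(tree, [np.nan, 1.0, 1.01, 1, 1, 1, 1])
        i0, _ = diagnostics.collapse_metrics(rates, ages, tol=0.0)
        i1, _ = diagnostics.collapse_metrics(rates, ages, tol=0.05)
        assert i0 <= i1


class TestSeProfile:
    def test_infinite_L_all_zero(self, ):
        tree = read_newick("((A:2,B:1):1,(C:1,D:1):1);")
        rates, chron = rrf.reltime(tree)
        prof = diagnostics.se_profile(rates, chron)
        assert np.all(prof["pairs"][:, 1] == 0.0)
        assert prof["slope"] == 0.0

    def test_linear_se_gives_r2_one(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        rel = ages.relative().ages
        se = 0.1 + 0.5 * rel  # exactly linear in subtending node age
        rates = rrf.RateAssignment(tree, np.ones(7), se, np.zeros(7, bool),
                                   np.full(7, np.nan), 1.0, 100.0, 2.0)
        prof = diagnostics.se_profile(rates, ages)
        assert prof["r2"] == pytest.approx(1.0)

    def test_infinite_se_excluded(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ages = Chronogram(tree, np.array([3, 2, 1, 0, 0, 0, 0], float))
        se = np.array([np.nan, 0.1, 0.2, np.inf, 0.1, 0.2, 0.3])
        rates = rrf.RateAssignment(tree, np.ones(7), se, np.zeros(7, bool),
                                   np.full(7, np.nan), 1.0, 100.0, 2.0)
        prof = diagnostics.se_profile(rates, ages)
        assert prof["n_excluded_infinite"] == 1

    def test_rate_ratio_se_shrinks_with_depth_on_clock_replicates(self):
        # Under independent Poisson branch noise, depth averaging makes the
        # *relative* error of deep lineage depths saturate while the depths
        # themselves grow, so the delta-method SE of the local rate ratio is
        # largest on short tipward branches and smallest rootward (the
        # 4-taxon worked example shows the same ordering: tip SEs ~ 0.39,
        # deep branch SEs ~ 0.21-0.23).  Deep merging is driven by the
        # shrinking depth-contrast signal, not by growing SEs.
        deep_minus_shallow = []
        for seed in range(50):
            cfg = SimulationConfig(n_tips=16, clock="strict", L=500,
                                   noise="poisson", seed=seed)
            truth = simulate.simulate_dataset(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rates, chron = rrf.reltime(truth.observed, L=500)
            prof = diagnostics.se_profile(rates, chron)
            age, se = prof["pairs"][:, 0], prof["pairs"][:, 1]
            finite = np.isfinite(se)
            age, se = age[finite], se[finite]
            qs = np.quantile(age, [0.25, 0.75])
            deep_minus_shallow.append(
                se[age >= qs[1]].mean() - se[age <= qs[0]].mean())
        assert np.mean(deep_minus_shallow) < 0

    def test_collapse_index_rises_as_information_falls(self):
        # fewer sites -> larger depth SEs -> more merges -> a larger
        # fraction of nonterminal branches pinned at the median rate
        cfg = SimulationConfig(n_tips=32, seed=6, noise="none")
        truth = simulate.simulate_dataset(cfg)
        idx = {}
        for L in (100, 100000):
            obs, _, _ = simulate.add_branch_noise(
                truth.timetree, truth.branch_rates, "poisson", L, seed=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rates, chron = rrf.reltime(obs, L=L)
            idx[L], _ = diagnostics.collapse_metrics(rates, chron)
        assert idx[100] > idx[100000]


class TestPriorShiftReport:
    def test_no_calibrations_no_shift(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        spec = timeprior.TimePriorSpec(timeprior.ExponentialRoot(1000.0))
        marg = timeprior.sample_marginal_priors(tree, spec, n_samples=8000,
                                                seed=3)
        df = diagnostics.prior_shift_report(spec, marg)
        root_row = df[df.node_id == ROOT].iloc[0]
        assert abs(root_row["shift"]) < 50.0

    def test_truncation_shift_matches_oracle(self):
        # 3-tip hard-bound construction: root shift ~ +1237 Myr
        from relclock.experiments import (toy_truncation_exact_mean,
                                          toy_truncation_mcmc)
        marg = toy_truncation_mcmc(n_samples=20000, seed=4)
        df = diagnostics.prior_shift_report(marg.spec, marg)
        root_row = df[df.node_id == ROOT].iloc[0]
        expected = toy_truncation_exact_mean() - 1000.0
        assert root_row["shift"] == pytest.approx(expected, abs=60.0)

    def test_low_mass_flag(self):
        from relclock.experiments import toy_truncation_mcmc
        marg = toy_truncation_mcmc(n_samples=8000, seed=5)
        # the young interval [0, 500] has essentially no effective root mass
        df = diagnostics.prior_shift_report(marg.spec, marg,
                                            query_interval=(0.0, 500.0))
        assert bool(df[df.node_id == ROOT].iloc[0]["flag_low_mass"])
        # a broad interval is not flagged
        df2 = diagnostics.prior_shift_report(marg.spec, marg,
                                             query_interval=(500.0, 10000.0))
        assert not bool(df2[df2.node_id == ROOT].iloc[0]["flag_low_mass"])
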