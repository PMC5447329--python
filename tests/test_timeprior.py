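"""Joint time prior: soft bounds, truncation, prior-only MCMC."""

import math

import numpy as np
import pytest
from scipy import stats

from relclock import timeprior
from relclock.timeprior import (ExponentialRoot, FixedRoot, GammaRoot,
                                TimePriorSpec, calibration_logfactor,
                                joint_prior_logdensity,
                                sample_marginal_priors)
from relclock.treeio import ROOT, Calibration, CalibrationSet, read_newick

TREE3 = "((A:1,B:1):1,C:2);"


def spec_with(root, cals=()):
    return TimePriorSpec(root, CalibrationSet(list(cals)))


class TestCalibrationLogfactor:
    def test_inside_bound_is_one(self):
        cal = Calibration(clade=("A", "B"), kind="min", t_min=800.0)
        assert calibration_logfactor(900.0, cal) == 0.0

    def test_continuity_at_min_bound(self):
        cal = Calibration(clade=("A", "B"), kind="min", t_min=800.0,
                          tail_mass=0.05)
        just_below = math.exp(calibration_logfactor(800.0 - 1e-9, cal))
        assert just_below == pytest.approx(0.05, rel=1e-6)

    def test_max_bound_decay(self):
        cal = Calibration(clade=("A", "B"), kind="max", t_max=500.0,
                          tail_mass=0.05)
        assert calibration_logfactor(400.0, cal) == 0.0
        lf = calibration_logfactor(550.0, cal)
        assert lf == pytest.approx(math.log(0.05) + (500 - 550) / 50.0)

    def test_min_max_half_tails(self):
        cal = Calibration(clade=("A", "B"), kind="min_max", t_min=100.0,
                          t_max=200.0, tail_mass=0.05)
        below = math.exp(calibration_logfactor(100.0 - 1e-12, cal))
        assert below == pytest.approx(0.025, rel=1e-6)

    def test_hard_bound(self):
        cal = Calibration(clade=("A", "B"), kind="min", t_min=800.0,
                          tail_mass=0.0)
        assert calibration_logfactor(799.0, cal) == -math.inf
        assert calibration_logfactor(801.0, cal) == 0.0


class TestRootDensities:
    def test_exponential_quantiles_closed_form(self):
        root = ExponentialRoot(1000.0)
        lo, hi = root.interval(0.95)
        assert lo == pytest.approx(-1000 * math.log(0.975))
        assert hi == pytest.approx(-1000 * math.log(0.025))
        assert root.logpdf(1000.0) == pytest.approx(math.log(math.e**-1 / 1000))

    def test_gamma_mean_sd_parameterization(self):
        root = GammaRoot(1000.0, 100.0)
        x = np.linspace(1, 4000, 2000)
        pdf = np.exp([root.logpdf(v) for v in x])
        mean = np.trapezoid(pdf * x, x)
        assert mean == pytest.approx(1000.0, rel=1e-3)

    def test_gamma_shape_one_is_exponential(self):
        # gamma with sd == mean has shape 1, i.e. the diffuse exponential
        g = GammaRoot(1000.0, 1000.0)
        e = ExponentialRoot(1000.0)
        for t in (10.0, 500.0, 3000.0):
            assert g.logpdf(t) == pytest.approx(e.logpdf(t), rel=1e-9)


class TestJointPrior:
    def test_constant_on_feasible_region(self):
        tree = read_newick(TREE3)
        spec = spec_with(FixedRoot(1.0)).bind(tree)
        interior = [v for v in tree.internal_ids if v != ROOT][0]
        vals = []
        for u in (0.2, 0.5, 0.9):
            ages = np.zeros(tree.n_nodes)
            ages[ROOT] = 1.0
            ages[interior] = u
            vals.append(joint_prior_logdensity(ages, tree, spec))
        assert len(set(vals)) == 1

    def test_min_bound_factor_only_below(self):
        tree = read_newick(TREE3)
        interior = [v for v in tree.internal_ids if v != ROOT][0]
        cal = Calibration(clade=("A", "B"), kind="min", t_min=0.8)
        spec = spec_with(FixedRoot(1.0), [cal]).bind(tree)
        base = spec_with(FixedRoot(1.0)).bind(tree)

        def lp(s, u):
            ages = np.zeros(tree.n_nodes)
            ages[ROOT], ages[interior] = 1.0, u
            return joint_prior_logdensity(ages, tree, s)

        assert lp(spec, 0.9) == lp(base, 0.9)
        assert lp(spec, 0.5) == pytest.approx(
            lp(base, 0.5) + math.log(0.05) + (0.5 - 0.8) / 0.08)

    def test_ordering_violation_is_minus_inf(self):
        tree = read_newick(TREE3)
        spec = spec_with(FixedRoot(1.0)).bind(tree)
        ages = np.zeros(tree.n_nodes)
        ages[ROOT] = 1.0
        interior = [v for v in tree.internal_ids if v != ROOT][0]
        ages[interior] = 1.5
        assert joint_prior_logdensity(ages, tree, spec) == -math.inf


class TestMarginalPriors:
    def test_fixed_root_interior_uniform(self):
        tree = read_newick(TREE3)
        spec = spec_with(FixedRoot(1.0))
        marg = sample_marginal_priors(tree, spec, n_samples=8000, seed=1)
        interior = [v for v in tree.internal_ids if v != ROOT][0]
        x = marg.samples[:, interior]
        assert x.mean() == pytest.approx(0.5, abs=0.02)
        assert stats.kstest(x, "uniform").statistic < 0.02

    def test_no_truncation_identity(self):
        # uncalibrated root marginal equals the specified density
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        spec = spec_with(ExponentialRoot(1000.0))
        marg = sample_marginal_priors(tree, spec, n_samples=10000, seed=2)
        x = marg.samples[:, ROOT]
        assert stats.kstest(x, "expon", args=(0, 1000.0)).statistic < 0.02
        assert abs(marg.root_report()["shift"]) < 40.0

    def test_truncation_shifts_root_upward(self):
        # minimum-age bounds on non-root nodes push the effective root
        # prior toward older ages, for any placement
        rng = np.random.default_rng(10)
        from conftest import random_timetrees
        for chron in random_timetrees(20, (4, 7), seed=33):
            tree = chron.tree
            internal = [v for v in tree.internal_ids if v != ROOT]
            v = internal[rng.integers(len(internal))]
            tips = sorted(tree.clade_tips(v))[:2]
            t_min = float(rng.uniform(600, 1500))
            cal = Calibration(clade=(tips[0], tips[1]), kind="min",
                              t_min=t_min, tail_mass=0.0)
            spec = spec_with(ExponentialRoot(1000.0), [cal])
            marg = sample_marginal_priors(tree, spec, n_samples=4000,
                                          seed=int(rng.integers(2**31)),
                                          check=False)
            assert marg.root_report()["shift"] > 0.0

    def test_rejection_sampling_oracle_small_trees(self):
        # hard-bound marginals on a 4-tip tree vs direct rejection sampling
        tree = read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        ab = [v for v in tree.internal_ids
              if sorted(tree.clade_tips(v)) == ["A", "B"]][0]
        abc = [v for v in tree.internal_ids
               if sorted(tree.clade_tips(v)) == ["A", "B", "C"]][0]
        cal = Calibration(clade=("A", "B"), kind="min", t_min=700.0,
                          tail_mass=0.0)
        spec = spec_with(ExponentialRoot(1000.0), [cal])
        marg = sample_marginal_priors(tree, spec, n_samples=20000, seed=5)

        rng = np.random.default_rng(6)
        keep = []
        while len(keep) < 20000:
            t_root = rng.exponential(1000.0)
            u = np.sort(rng.uniform(0, t_root, size=2))
            t_ab, t_abc = u[0], u[1]   # ladder tree: ab below abc below root
            if t_ab >= 700.0:
                keep.append((t_root, t_abc, t_ab))
        keep = np.array(keep)
        for idx, node in ((0, ROOT), (1, abc), (2, ab)):
            mc = keep[:, idx]
            se = math.sqrt(mc.var() / len(mc) +
                           marg.samples[:, node].var() / 2000)
            assert abs(marg.samples[:, node].mean() - mc.mean()) < 4 * se

    def test_soft_bound_containment(self):
        # tail_mass 5% leaves at most ~10% marginal mass below a lone min
        tree = read_newick(TREE3)
        cal = Calibration(clade=("A", "B"), kind="min", t_min=800.0,
                          tail_mass=0.05)
        spec = spec_with(ExponentialRoot(1000.0), [cal])
        marg = sample_marginal_priors(tree, spec, n_samples=10000, seed=7)
        ab = [v for v in tree.internal_ids
              if sorted(tree.clade_tips(v)) == ["A", "B"]][0]
        below = np.mean(marg.samples[:, ab] < 800.0)
        assert below <= 0.10

    def test_hpd_not_wider_than_equal_tail(self):
        tree = read_newick(TREE3)
        spec = spec_with(ExponentialRoot(1000.0))
        marg = sample_marginal_priors(tree, spec, n_samples=5000, seed=8)
        for _, row in marg.table.iterrows():
            assert row.hpd_hi - row.hpd_lo <= row["q97.5"] - row["q2.5"] + 1e-9
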