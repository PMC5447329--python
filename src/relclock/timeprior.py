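"""Joint prior on node ages and prior-only MCMC ("marginal prior" runs).

The joint time prior is built from three ingredients:

* a base density on the internal node ages given the root age — by default
  the uniform-order-statistics prior (non-root internal ages i.i.d.
  U(0, t_root) restricted to the ancestor-older-than-descendant ordering,
  i.e. proportional to t_root^-(n-1) on the feasible region);
* a calibration density on the root age (gamma, exponential, or a point
  mass for "root fixed to 1" relative dating);
* soft-bounded fossil calibrations on internal nodes: inside the bound the
  factor is 1; outside, an exponential tail starting at the stated tail
  mass (default 5%) with decay scale 0.1 x bound, so the factor is
  continuous at the bound and a small, explicit probability is allowed
  outside it.  tail_mass = 0 makes a bound hard.

Because ancestors must be older than descendants, internal calibrations
truncate the prior that other nodes — the root in particular — actually
receive.  The marginal ("effective") prior of each node is therefore
computed by sampling, with MCMC run on the prior alone (no data), exactly
as one obtains it by running a dating chain with the likelihood switched
off.  The root is updated with a rescale-all independence move (a fresh
root age from the calibration density, all interior ages scaled along),
which mixes the root instantly in the absence of truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import ROOT, Calibration, CalibrationSet, Phylogeny
from .mcmc_utils import hpd


# ---------------------------------------------------------------------------
# Root densities
# ---------------------------------------------------------------------------

class RootDensity:
    """Calibration density on the root age."""

    name = "none"

    def logpdf(self, t: float) -> float:
        raise NotImplementedError

    def rvs(self, rng, size=None):
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def interval(self, mass: float = 0.95) -> tuple:
        raise NotImplementedError

    @property
    def fixed(self) -> bool:
        return False


@dataclass(frozen=True)
class GammaRoot(RootDensity):
    """Gamma root density parameterized by mean and sd (Myr)."""

    mean_age: float
    sd: float
    name = "gamma"

    @property
    def shape(self):
        return (self.mean_age / self.sd) ** 2

    @property
    def scale(self):
        return self.sd**2 / self.mean_age

    def logpdf(self, t):
        return stats.gamma.logpdf(t, self.shape, scale=self.scale)

    def rvs(self, rng, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def mean(self):
        return self.mean_age

    def interval(self, mass=0.95):
        a = (1 - mass) / 2
        return tuple(stats.gamma.ppf([a, 1 - a], self.shape, scale=self.scale))


@dataclass(frozen=True)
class ExponentialRoot(RootDensity):
    """Exponential root density (a gamma with shape 1: very diffuse)."""

    mean_age: float
    name = "exponential"

    def logpdf(self, t):
        if t <= 0:
            return -math.inf
        return -math.log(self.mean_age) - t / self.mean_age

    def rvs(self, rng, size=None):
        return rng.exponential(self.mean_age, size=size)

    def mean(self):
        return self.mean_age

    def interval(self, mass=0.95):
        a = (1 - mass) / 2
        return (-self.mean_age * math.log(1 - a),
                -self.mean_age * math.log(a))


@dataclass(frozen=True)
class FixedRoot(RootDensity):
    """Point mass: the relative-dating device "root fixed to age 1"."""

    age: float = 1.0
    name = "fixed"

    def logpdf(self, t):
        return 0.0 if t == self.age else -math.inf

    def rvs(self, rng, size=None):
        return self.age if size is None else np.full(size, self.age)

    def mean(self):
        return self.age

    def interval(self, mass=0.95):
        return (self.age, self.age)

    @property
    def fixed(self):
        return True


def root_density_from(density: tuple | None, fixed_age: float | None = None
                      ) -> RootDensity:
    """Build a RootDensity from a ("gamma", mean, sd) / ("exponential", mean)
    tuple (as parsed from calibration tables) or a fixed age."""
    if fixed_age is not None:
        return FixedRoot(fixed_age)
    if density is None:
        raise ValueError("a root density (or fixed age) is required")
    if density[0] == "gamma":
        return GammaRoot(density[1], density[2])
    if density[0] == "exponential":
        return ExponentialRoot(density[1])
    raise ValueError(f"unknown density {density!r}")


# ---------------------------------------------------------------------------
# Spec and densities
# ---------------------------------------------------------------------------

@dataclass
class TimePriorSpec:
    """Base prior + root density + bound calibrations for one tree."""

    root: RootDensity
    calibrations: CalibrationSet = field(default_factory=CalibrationSet)
    base: str = "uniform-order"

    def bind(self, tree: Phylogeny) -> "TimePriorSpec":
        return TimePriorSpec(self.root, self.calibrations.bind(tree), self.base)

    def bound_calibrations(self) -> list:
        return [c for c in self.calibrations.bound()]


def calibration_logfactor(age: float, cal: Calibration) -> float:
    """Log soft-bound factor at a node age.

    Inside the bound the factor is 1 (log 0).  Below a minimum bound the
    factor decays from ``tail_mass`` at the bound with scale 0.1*t_min;
    above a maximum bound symmetrically with scale 0.1*t_max.  min_max
    carries tail_mass/2 per side; tail_mass = 0 gives a hard bound.
    """
    if cal.kind == "root_density":
        raise ValueError("root_density rows are handled by the root density")
    lp = 0.0
    half = cal.kind == "min_max"
    if cal.kind in ("min", "min_max") and age < cal.t_min:
        mass = cal.tail_mass / 2 if half else cal.tail_mass
        if mass == 0.0:
            return -math.inf
        lp += math.log(mass) + (age - cal.t_min) / (0.1 * cal.t_min)
    if cal.kind in ("max", "min_max") and age > cal.t_max:
        mass = cal.tail_mass / 2 if half else cal.tail_mass
        if mass == 0.0:
            return -math.inf
        lp += math.log(mass) + (cal.t_max - age) / (0.1 * cal.t_max)
    return lp


def joint_prior_logdensity(ages: np.ndarray, tree: Phylogeny,
                           spec: TimePriorSpec) -> float:
    """Unnormalized log joint prior of a full age vector.

    Returns -inf for any ordering violation or non-positive root age.
    """
    t_root = ages[ROOT]
    if not t_root > 0:
        return -math.inf
    for v in range(1, tree.n_nodes):
        if not ages[tree.parent[v]] > ages[v]:
            return -math.inf
        if tree.is_tip(v) and ages[v] != 0.0:
            return -math.inf
    lp = spec.root.logpdf(t_root) if not spec.root.fixed else 0.0
    n_interior = len(tree.internal_ids) - 1
    lp += -n_interior * math.log(t_root)        # uniform-order base
    for cal in spec.bound_calibrations():
        lp += calibration_logfactor(ages[cal.node], cal)
    return lp


# ---------------------------------------------------------------------------
# Prior-only MCMC
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    def __init__(self, msg, report=None):
        super().__init__(msg)
        self.report = report


def _initial_ages(tree: Phylogeny, t_root: float) -> np.ndarray:
    """Feasible starting ages: node height proportional to levels-above-tips."""
    n = tree.n_nodes
    depth_below = np.zeros(n)
    for v in tree.postorder():
        if not tree.is_tip(v):
            depth_below[v] = 1 + max(depth_below[c] for c in tree.children[v])
    ages = t_root * depth_below / depth_below[ROOT]
    ages[ROOT] = t_root
    return ages


def _prior_sweep(tree, spec, ages, cal_by_node, rng, fixed_root):
    """One Metropolis-within-Gibbs sweep over node ages; mutates ``ages``."""
    internal = [v for v in tree.internal_ids if v != ROOT]
    n_int = len(tree.internal_ids)
    # node-age slides
    for v in internal:
        lo = max((ages[c] for c in tree.children[v]), default=0.0)
        hi = ages[tree.parent[v]]
        new = rng.uniform(lo, hi)
        dlp = 0.0
        cal = cal_by_node.get(v)
        if cal is not None:
            dlp = (calibration_logfactor(new, cal)
                   - calibration_logfactor(ages[v], cal))
        if dlp >= 0 or math.log(rng.random()) < dlp:
            ages[v] = new
    if fixed_root:
        return
    # root independence rescale: fresh root age from the calibration
    # density, interior ages scaled along; the root density, base term and
    # Jacobian cancel exactly, leaving only the calibration factors
    t_old = ages[ROOT]
    t_new = float(spec.root.rvs(rng))
    if t_new > 0:
        s = t_new / t_old
        dlp = 0.0
        for v, cal in cal_by_node.items():
            dlp += (calibration_logfactor(ages[v] * s, cal)
                    - calibration_logfactor(ages[v], cal))
        if dlp >= 0 or math.log(rng.random()) < dlp:
            ages *= s
    # root scale random walk (helps under strong truncation)
    s = math.exp(0.3 * (rng.random() - 0.5))
    new_ages = ages * s
    dlp = (spec.root.logpdf(new_ages[ROOT]) - spec.root.logpdf(ages[ROOT])
           + (1 - n_int) * math.log(s)         # base term t_root^-(n-1)
           + n_int * math.log(s))              # Jacobian of the scale map
    for v, cal in cal_by_node.items():
        dlp += (calibration_logfactor(new_ages[v], cal)
                - calibration_logfactor(ages[v], cal))
    if dlp >= 0 or math.log(rng.random()) < dlp:
        ages[:] = new_ages


@dataclass
class MarginalPriorSummary:
    """Per-node effective (marginal) prior summaries from prior-only MCMC."""

    table: pd.DataFrame        # node_id, mean, q2.5, q97.5, hpd_lo, hpd_hi
    samples: np.ndarray        # (n_samples, n_nodes) pooled post-burn-in ages
    spec: TimePriorSpec
    tree: Phylogeny

    def node_mean(self, v: int) -> float:
        return float(self.table.loc[self.table.node_id == v, "mean"].iloc[0])

    def root_report(self) -> dict:
        """Specified vs effective root prior: the truncation headline."""
        spec_mean = self.spec.root.mean()
        lo, hi = self.spec.root.interval(0.95)
        eff = self.samples[:, ROOT]
        return {
            "specified_mean": spec_mean,
            "specified_interval": (lo, hi),
            "effective_mean": float(np.mean(eff)),
            "effective_interval": (float(np.quantile(eff, 0.025)),
                                   float(np.quantile(eff, 0.975))),
            "shift": float(np.mean(eff)) - spec_mean,
        }


def sample_marginal_priors(tree: Phylogeny, spec: TimePriorSpec,
                           n_samples: int = 20000, chains: int = 2,
                           burn_frac: float = 0.25, seed: int = 0,
                           check: bool = True, maxdiff: float = 0.1,
                           ess_floor: float = 100.0) -> MarginalPriorSummary:
    """Sample the joint time prior ("MCMC with no data") and summarize.

    Runs ``chains`` independent chains of ``n_samples`` sweeps each, drops
    ``burn_frac`` of each, pools the rest.  With ``check=True`` a
    tracecomp-style comparison of chain means (relative difference below
    ``maxdiff``, ESS above ``ess_floor``) must pass or ConvergenceError is
    raised with the diagnostics attached.
    """
    spec = spec.bind(tree)
    cal_by_node = {c.node: c for c in spec.bound_calibrations()}
    fixed_root = spec.root.fixed
    internal = list(tree.internal_ids)
    keep = []
    for ch in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ch]))
        t0 = spec.root.mean() if fixed_root else float(spec.root.rvs(rng))
        ages = _initial_ages(tree, max(t0, 1e-12))
        burn = int(burn_frac * n_samples)
        chain = np.empty((n_samples, tree.n_nodes))
        for it in range(n_samples):
            _prior_sweep(tree, spec, ages, cal_by_node, rng, fixed_root)
            chain[it] = ages
        keep.append(chain[burn:])
    if check and chains >= 2:
        from .mcmc_utils import convergence_check
        monitored = [
            {f"age_{v}": k[:, v] for v in internal
             if not (fixed_root and v == ROOT)} for k in keep
        ]
        report = convergence_check(monitored, maxdiff_threshold=maxdiff,
                                   ess_floor=ess_floor)
        if not report.passed:
            raise ConvergenceError("prior-only MCMC did not converge",
                                   report)
    pooled = np.concatenate(keep, axis=0)
    rows = []
    for v in internal:
        x = pooled[:, v]
        lo, hi = hpd(x, 0.95)
        rows.append({"node_id": v, "mean": float(np.mean(x)),
                     "q2.5": float(np.quantile(x, 0.025)),
                     "q97.5": float(np.quantile(x, 0.975)),
                     "hpd_lo": lo, "hpd_hi": hi})
    return MarginalPriorSummary(pd.DataFrame(rows), pooled, spec, tree)
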