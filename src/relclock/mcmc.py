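"""Bayesian divergence-time MCMC under the autocorrelated CIR clock.

The posterior is proportional to

    likelihood(data | ages, rates)
    x CIR process density of the node rates (root rate from the stationary
      Gamma law, each child node rate from the CIR transition density over
      the branch duration; branch rate entering the likelihood = arithmetic
      mean of endpoint node rates)
    x joint time prior (root calibration density, uniform-order base,
      soft-bounded internal calibrations)
    x hyperpriors theta ~ Exp(1), sigma2 ~ Exp(1) truncated to the Feller
      region 2*theta*mu >= sigma2.

Relative dating fixes the root age to 1 and omits all calibrations;
absolute dating samples the root age under its calibration density.  The
proposal mixture follows the conventional design for this model family:
node-age slides within the (oldest child, parent) window, root scale moves
with all-ages rescale, single-rate lognormal multipliers, log-scale
random walks on the hyperparameters, and (absolute mode) a joint
rate <-> time trade-off scale move.  Prior-only sampling (no data) uses the
same machinery with the likelihood switched off, which is how marginal
("effective") priors are obtained.

Convergence across >= 2 chains is assessed tracecomp-style: relative
difference of chain means below a threshold and ESS above a floor for
every monitored scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ive

from . import cir
from .likelihood import PoissonData, jc_pruning_loglik
from .mcmc_utils import ConvergenceReport, convergence_check, hpd
from .timeprior import TimePriorSpec, calibration_logfactor
from .treeio import ROOT, Alignment, Phylogeny
from .rrf import reltime


@dataclass
class McmcTrace:
    """One chain: per-sample node ages, node rates and hyperparameters."""

    ages: np.ndarray        # (S, n_nodes)
    rates: np.ndarray       # (S, n_nodes)
    theta: np.ndarray       # (S,)
    sigma2: np.ndarray      # (S,)
    logpost: np.ndarray     # (S,) unnormalized
    seed: int
    burn: int               # first retained sample index

    def monitored(self, tree: Phylogeny) -> dict:
        out = {}
        for v in tree.internal_ids:
            out[f"age_{v}"] = self.ages[self.burn:, v]
        out["theta"] = self.theta[self.burn:]
        out["sigma2"] = self.sigma2[self.burn:]
        out["mean_rate"] = self.rates[self.burn:, 1:].mean(axis=1)
        return out


# ---------------------------------------------------------------------------
# scalar CIR edge density (hot path)
# ---------------------------------------------------------------------------

def _edge_lp(rc, rp, dt, th, s2, q, lgq):
    """log CIR transition density, scalar, overflow-safe."""
    if rc <= 0.0 or rp <= 0.0:
        return -math.inf
    e = math.exp(-th * dt)
    c = 2.0 * th / (s2 * (1.0 - e))
    u = c * rp * e
    v = c * rc
    z = 2.0 * math.sqrt(u * v)
    if z >= 1e-8:
        iv = ive(q, z)
        if iv > 0.0 and math.isfinite(iv):
            return math.log(c) - u - v + 0.5 * q * math.log(v / u) \
                + math.log(iv) + z
    # leading Bessel series term (also the u -> 0 / ergodic limit)
    return (q + 1.0) * math.log(c) + q * math.log(rc) - u - v - lgq


def _stat_lp(r, th, s2, mu):
    if r <= 0:
        return -math.inf
    a = 2.0 * th * mu / s2
    b = 2.0 * th / s2
    return a * math.log(b) - gammaln(a) + (a - 1.0) * math.log(r) - b * r


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class HyperPrior:
    """Exponential hyperpriors on theta and sigma2 (Feller-truncated)."""

    theta_mean: float = 1.0
    sigma2_mean: float = 1.0

    def logpdf(self, th, s2, mu):
        if th <= 0 or s2 <= 0 or 2 * th * mu < s2:
            return -math.inf
        return -th / self.theta_mean - s2 / self.sigma2_mean


class _Sampler:
    """One-chain sampler state with cached per-branch terms."""

    def __init__(self, observed: Phylogeny, spec: TimePriorSpec, mode: str,
                 L, alignment, clock0: cir.CIRParams, hyper: HyperPrior,
                 sample_hypers: bool, rng: np.random.Generator,
                 gamma_alpha=None):
        self.tree = observed
        self.spec = spec
        self.mode = mode
        self.alignment = alignment
        self.gamma_alpha = gamma_alpha
        self.rng = rng
        self.hyper = hyper
        self.sample_hypers = sample_hypers
        t = observed
        self.n = t.n_nodes
        self.parent = t.parent
        self.internal = [v for v in t.internal_ids if v != ROOT]
        self.n_int = len(t.internal_ids)
        self.cal_by_node = {c.node: c for c in spec.bound_calibrations()}
        self.fixed_root = spec.root.fixed

        self.mu = clock0.mu
        self.theta = clock0.theta
        self.sigma2 = clock0.sigma2

        if mode == "poisson":
            if L is None:
                raise ValueError("poisson mode needs L")
            pdat = PoissonData.from_tree(observed, L)
            self.K = pdat.counts
            self.L = float(L)
            self.lgK = gammaln(self.K + 1.0)
        elif mode == "alignment":
            if alignment is None:
                raise ValueError("alignment mode needs an alignment")
        elif mode != "none":
            raise ValueError(f"unknown mode {mode}")

        # static descendant lists for the compensatory move
        self.descendants = [[] for _ in range(self.n)]
        for w in range(self.n - 1, 0, -1):
            self.descendants[self.parent[w]].append(w)
            self.descendants[self.parent[w]].extend(self.descendants[w])
        for lst in self.descendants:
            lst.sort()          # ascending ids = parents before children

        self._init_state()
        # adaptive proposal scales (frozen after burn-in)
        self.rate_scale = 0.6
        self.hyper_scale = 0.5
        self.age_scale = 0.3        # local slide, as a fraction of the window
        self.comp_scale = 0.2       # compensatory move, fraction of window
        self.adapting = True
        self.shift_scale = 0.3
        self.stretch_scale = 0.1
        self.sub_scale = 0.2
        self._acc = {"rate": [0, 0], "hyper": [0, 0], "age": [0, 0],
                     "comp": [0, 0], "shift": [0, 0], "stretch": [0, 0],
                     "sub": [0, 0]}

    # -- state initialization ---------------------------------------------
    def _init_state(self):
        t, rng = self.tree, self.rng
        root0 = (self.spec.root.mean() if self.fixed_root
                 else max(float(self.spec.root.rvs(rng)), 1e-9))
        if self.mode in ("poisson", "alignment") and np.nansum(
                t.branch_length) > 0:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, chron = reltime(t)
            ages = chron.ages * root0
        else:
            from .timeprior import _initial_ages
            ages = _initial_ages(t, root0)
        # jitter interior ages within their windows for chain dispersion
        for v in self.internal:
            lo = max((ages[c] for c in t.children[v]), default=0.0)
            hi = ages[self.parent[v]]
            ages[v] = lo + (hi - lo) * np.clip(
                (ages[v] - lo) / (hi - lo) + 0.1 * (rng.random() - 0.5),
                0.05, 0.95)
        self.ages = ages
        d = ages[self.parent] - ages
        d[ROOT] = np.nan
        rates = np.full(self.n, self.mu)
        if self.mode in ("poisson", "alignment"):
            with np.errstate(invalid="ignore", divide="ignore"):
                est = t.branch_length / d
            est = np.clip(est, 0.2 * self.mu, 5 * self.mu)
            rates[1:] = np.where(np.isfinite(est[1:]), est[1:], self.mu)
        self.rates = rates
        self._recache()

    # -- cached terms ------------------------------------------------------
    def _durations(self):
        d = self.ages[self.parent] - self.ages
        d[ROOT] = np.nan
        return d

    def _branch_rates(self):
        br = np.full(self.n, np.nan)
        br[1:] = 0.5 * (self.rates[1:] + self.rates[self.parent[1:]])
        return br

    def _lik_term(self, v, lam):
        return self.K[v] * math.log(lam) - lam - self.lgK[v]

    def _lam(self, v, d=None):
        dd = (self.ages[self.parent[v]] - self.ages[v]) if d is None else d
        rbar = 0.5 * (self.rates[v] + self.rates[self.parent[v]])
        return max(rbar * dd * self.L, 1e-300)

    def _full_lik(self) -> float:
        if self.mode == "none":
            return 0.0
        d = self._durations()
        if np.any(d[1:] <= 0):
            return -math.inf
        br = self._branch_rates()
        if self.mode == "poisson":
            lam = np.maximum(br[1:] * d[1:] * self.L, 1e-300)
            return float(np.sum(self.K[1:] * np.log(lam) - lam - self.lgK[1:]))
        return jc_pruning_loglik(self.tree, br * d, self.alignment,
                                 gamma_alpha=self.gamma_alpha)

    def _full_cir(self):
        d = self._durations()
        lp = cir.transition_logdensity(
            self.rates[1:], self.rates[self.parent[1:]], d[1:],
            cir.CIRParams(self.theta, self.sigma2, self.mu))
        return lp, float(cir.stationary_logdensity(
            self.rates[ROOT], cir.CIRParams(self.theta, self.sigma2, self.mu)))

    def _recache(self):
        self.q = 2 * self.theta * self.mu / self.sigma2 - 1.0
        self.lgq = float(gammaln(self.q + 1.0))
        cir_lp, stat = self._full_cir()
        self.cir_lp = np.concatenate([[0.0], cir_lp])
        self.stat_lp = stat
        if self.mode == "poisson":
            d = self._durations()
            br = self._branch_rates()
            lam = np.maximum(br[1:] * d[1:] * self.L, 1e-300)
            self.lik = np.concatenate(
                [[0.0], self.K[1:] * np.log(lam) - lam - self.lgK[1:]])
        elif self.mode == "alignment":
            self.aln_lik = self._full_lik()

    def _edge(self, v, rc=None, rp=None, dt=None):
        rc = self.rates[v] if rc is None else rc
        rp = self.rates[self.parent[v]] if rp is None else rp
        dt = (self.ages[self.parent[v]] - self.ages[v]) if dt is None else dt
        if dt <= 0:
            return -math.inf
        return _edge_lp(rc, rp, dt, self.theta, self.sigma2, self.q, self.lgq)

    # -- prior pieces ------------------------------------------------------
    def _root_prior(self, t_root=None):
        t_root = self.ages[ROOT] if t_root is None else t_root
        lp = 0.0 if self.fixed_root else self.spec.root.logpdf(t_root)
        lp += -(self.n_int - 1) * math.log(t_root)
        return lp

    def _cal(self, v, age=None):
        cal = self.cal_by_node.get(v)
        if cal is None:
            return 0.0
        return calibration_logfactor(self.ages[v] if age is None else age, cal)

    # -- moves -------------------------------------------------------------
    def _metropolis(self, dlp) -> bool:
        return dlp >= 0 or math.log(self.rng.random()) < dlp

    def _age_move(self, v):
        # alternates a window-uniform slide (prior-friendly, large steps)
        # with an adaptive local slide (likelihood-friendly, small steps);
        # both are symmetric within the fixed (oldest child, parent) window
        t = self.tree
        lo = max((self.ages[c] for c in t.children[v]), default=0.0)
        hi = self.ages[self.parent[v]]
        local = self.rng.random() < 0.5
        if local:
            new = self.ages[v] + (hi - lo) * self.age_scale * (
                self.rng.random() - 0.5)
            if not (lo < new < hi):
                self._acc["age"][1] += 1
                return
        else:
            new = self.rng.uniform(lo, hi)
        edges = [v] + list(t.children[v])
        old_age = self.ages[v]
        old_terms = sum(self.cir_lp[e] for e in edges) + self._cal(v)
        if self.mode == "poisson":
            old_terms += sum(self.lik[e] for e in edges)
        elif self.mode == "alignment":
            old_terms += self.aln_lik
        self.ages[v] = new
        new_cir = {e: self._edge(e) for e in edges}
        new_terms = sum(new_cir.values()) + self._cal(v)
        new_lik = {}
        if self.mode == "poisson":
            for e in edges:
                new_lik[e] = self._lik_term(e, self._lam(e))
            new_terms += sum(new_lik.values())
        elif self.mode == "alignment":
            aln_new = self._full_lik()
            new_terms += aln_new
        acc = self._metropolis(new_terms - old_terms)
        if local:
            self._acc["age"][0] += acc
            self._acc["age"][1] += 1
        if acc:
            for e in edges:
                self.cir_lp[e] = new_cir[e]
                if self.mode == "poisson":
                    self.lik[e] = new_lik[e]
            if self.mode == "alignment":
                self.aln_lik = aln_new
        else:
            self.ages[v] = old_age

    def _rate_move(self, v):
        t = self.tree
        old = self.rates[v]
        s = math.exp(self.rate_scale * (self.rng.random() - 0.5))
        new = old * s
        edges = list(t.children[v]) + ([v] if v != ROOT else [])
        old_terms = sum(self.cir_lp[e] for e in edges)
        if v == ROOT:
            old_terms += self.stat_lp
        if self.mode == "poisson":
            lik_edges = [e for e in edges]
            old_terms += sum(self.lik[e] for e in lik_edges)
        elif self.mode == "alignment":
            old_terms += self.aln_lik
        self.rates[v] = new
        new_cir = {e: self._edge(e) for e in edges}
        new_terms = sum(new_cir.values())
        new_stat = None
        if v == ROOT:
            new_stat = _stat_lp(new, self.theta, self.sigma2, self.mu)
            new_terms += new_stat
        new_lik = {}
        if self.mode == "poisson":
            for e in edges:
                new_lik[e] = self._lik_term(e, self._lam(e))
            new_terms += sum(new_lik.values())
        elif self.mode == "alignment":
            aln_new = self._full_lik()
            new_terms += aln_new
        # lognormal multiplier Hastings term
        dlp = new_terms - old_terms + math.log(s)
        acc = self._metropolis(dlp)
        self._acc["rate"][0] += acc
        self._acc["rate"][1] += 1
        if acc:
            for e in edges:
                self.cir_lp[e] = new_cir[e]
                if self.mode == "poisson":
                    self.lik[e] = new_lik[e]
            if new_stat is not None:
                self.stat_lp = new_stat
            if self.mode == "alignment":
                self.aln_lik = aln_new
        else:
            self.rates[v] = old

    def _comp_move(self, v):
        """Compensatory age-rate move: shift t_v and rescale node rates in
        the subtree so that every branch length r_bar * d — and hence the
        branch-length likelihood — is preserved exactly.

        The branch above v fixes r'_v; each deeper node w then satisfies
        (r'_w + r'_pa(w)) d'_w = (r_w + r_pa(w)) d_w, a cascade that
        terminates at the tips.  The Jacobian is the product of the
        duration ratios of the three branches adjacent to v.  Only the CIR
        prior terms over the affected edges enter the acceptance ratio.
        """
        t = self.tree
        lo = max((self.ages[c] for c in t.children[v]), default=0.0)
        hi = self.ages[self.parent[v]]
        delta = (hi - lo) * self.comp_scale * (self.rng.random() - 0.5)
        new_age = self.ages[v] + delta
        self._acc["comp"][1] += 1
        if not (lo < new_age < hi):
            return
        rp = self.rates[self.parent[v]]
        d_a = hi - self.ages[v]
        d_a2 = hi - new_age
        r_new = {v: (self.rates[v] + rp) * d_a / d_a2 - rp}
        if r_new[v] <= 0:
            return
        logj = math.log(d_a / d_a2)
        for c in t.children[v]:
            d_c = self.ages[v] - self.ages[c]
            d_c2 = new_age - self.ages[c]
            r_new[c] = (self.rates[c] + self.rates[v]) * d_c / d_c2 - r_new[v]
            if r_new[c] <= 0:
                return
            logj += math.log(d_c / d_c2)
        for w in self.descendants[v]:
            if w in r_new:
                continue
            pw = self.parent[w]
            r_new[w] = self.rates[w] + (self.rates[pw] - r_new[pw])
            if r_new[w] <= 0:
                return
        # CIR terms on the edge above v and every edge inside the subtree
        affected = [v] + self.descendants[v]
        old_cir = sum(self.cir_lp[w] for w in affected)
        old_ages_v = self.ages[v]
        old_rates = {w: self.rates[w] for w in r_new}
        self.ages[v] = new_age
        for w, r in r_new.items():
            self.rates[w] = r
        new_cir = {w: self._edge(w) for w in affected}
        dlp = sum(new_cir.values()) - old_cir + logj
        if self._metropolis(dlp):
            self._acc["comp"][0] += 1
            for w in affected:
                self.cir_lp[w] = new_cir[w]
        else:
            self.ages[v] = old_ages_v
            for w, r in old_rates.items():
                self.rates[w] = r

    def _stretch_move(self):
        """Coherent age-field move: t' = t_root (t/t_root)^gamma for every
        internal non-root node, with rates re-solved top-down so every
        branch length is preserved exactly.  This targets the global
        rate-time ridge (all deep ages shift together against the deep
        rates) that single-node moves traverse only diffusively.
        """
        self._acc["stretch"][1] += 1
        gamma = math.exp(self.stretch_scale * (self.rng.random() - 0.5))
        t_root = self.ages[ROOT]
        old_ages = self.ages
        old_rates = self.rates
        with np.errstate(divide="ignore", invalid="ignore"):
            x = old_ages / t_root
            new_ages = np.where(old_ages > 0, t_root * x**gamma, 0.0)
        new_ages[ROOT] = t_root
        free = [v for v in self.internal]
        logj = sum(math.log(gamma) + (gamma - 1.0) * math.log(x[v])
                   for v in free)
        d_old = (old_ages[self.parent] - old_ages)[1:]
        d_new = (new_ages[self.parent] - new_ages)[1:]
        if np.any(d_new <= 0):
            return
        # smooth per-branch rate rescale: r' = r d/d' keeps each branch's
        # length nearly fixed (exactly, were branch rates child-local);
        # the residual likelihood change is recomputed exactly below
        new_rates = old_rates.copy()
        new_rates[1:] = old_rates[1:] * d_old / d_new
        logj += float(np.sum(np.log(d_old / d_new)))
        old_terms = (float(np.sum(self.cir_lp[1:]))
                     + (float(np.sum(self.lik[1:]))
                        if self.mode == "poisson" else self.aln_lik
                        if self.mode == "alignment" else 0.0))
        self.ages = new_ages
        self.rates = new_rates
        new_cir = cir.transition_logdensity(
            new_rates[1:], new_rates[self.parent[1:]], d_new,
            cir.CIRParams(self.theta, self.sigma2, self.mu))
        new_lik_arr = None
        if self.mode == "poisson":
            br = 0.5 * (new_rates[1:] + new_rates[self.parent[1:]])
            lam = np.maximum(br * d_new * self.L, 1e-300)
            new_lik_arr = self.K[1:] * np.log(lam) - lam - self.lgK[1:]
            new_lik_total = float(np.sum(new_lik_arr))
        elif self.mode == "alignment":
            new_lik_total = self._full_lik()
        else:
            new_lik_total = 0.0
        dlp = (float(np.sum(new_cir)) + new_lik_total - old_terms + logj)
        for v, cal in self.cal_by_node.items():
            dlp += (calibration_logfactor(new_ages[v], cal)
                    - calibration_logfactor(old_ages[v], cal))
        if math.isfinite(dlp) and self._metropolis(dlp):
            self._acc["stretch"][0] += 1
            self.cir_lp = np.concatenate([[0.0], new_cir])
            if self.mode == "poisson":
                self.lik = np.concatenate([[0.0], new_lik_arr])
            elif self.mode == "alignment":
                self.aln_lik = new_lik_total
        else:
            self.ages = old_ages
            self.rates = old_rates

    def _subtree_scale_move(self, v):
        """Scale all node ages in the subtree of v by s and all node rates
        in the subtree by 1/s.  Every branch inside the subtree keeps both
        its duration x s and its mean rate / s, so its length — and
        likelihood term — is exactly preserved; only the branch above v
        (duration change) and the CIR terms are re-evaluated.  This is the
        principal mixing move along the subtree-block rate-time ridge.
        """
        self._acc["sub"][1] += 1
        s = math.exp(self.sub_scale * (self.rng.random() - 0.5))
        hi = self.ages[self.parent[v]]
        if not self.ages[v] * s < hi:
            return
        nodes = [v] + self.descendants[v]
        n_tips_sub = sum(1 for w in nodes if self.tree.is_tip(w))
        old_ages = self.ages[nodes].copy()
        old_rates = self.rates[nodes].copy()
        edges = nodes                    # edge above each node in subtree
        old_terms = sum(self.cir_lp[e] for e in edges) + self._cal_sub(nodes)
        if self.mode == "poisson":
            old_terms += self.lik[v]
        elif self.mode == "alignment":
            old_terms += self.aln_lik
        self.ages[nodes] = old_ages * s
        self.rates[nodes] = old_rates / s
        new_cir = {e: self._edge(e) for e in edges}
        new_terms = sum(new_cir.values()) + self._cal_sub(nodes)
        new_lik_v = None
        if self.mode == "poisson":
            new_lik_v = self._lik_term(v, self._lam(v))
            new_terms += new_lik_v
        elif self.mode == "alignment":
            aln_new = self._full_lik()
            new_terms += aln_new
        n_int_sub = len(nodes) - n_tips_sub
        logj = (n_int_sub - len(nodes)) * math.log(s)
        dlp = new_terms - old_terms + logj
        if math.isfinite(dlp) and self._metropolis(dlp):
            self._acc["sub"][0] += 1
            for e in edges:
                self.cir_lp[e] = new_cir[e]
            if new_lik_v is not None:
                self.lik[v] = new_lik_v
            if self.mode == "alignment":
                self.aln_lik = aln_new
        else:
            self.ages[nodes] = old_ages
            self.rates[nodes] = old_rates

    def _cal_sub(self, nodes):
        if not self.cal_by_node:
            return 0.0
        return sum(self._cal(v) for v in nodes if v in self.cal_by_node)

    def _rate_shift_move(self, v):
        """Transfer rate between the endpoints of the branch above v
        (r_v + eps, r_parent - eps): the shared branch's mean rate — and
        its likelihood term — are untouched; only the other branches that
        touch either endpoint, and the adjacent CIR terms, change."""
        p = int(self.parent[v])
        eps = self.shift_scale * (self.rates[v] + self.rates[p]) * (
            self.rng.random() - 0.5)
        new_v, new_p = self.rates[v] + eps, self.rates[p] - eps
        self._acc["shift"][1] += 1
        if new_v <= 0 or new_p <= 0:
            return
        t = self.tree
        # edges whose CIR term involves v or p (the v-p edge itself too:
        # its transition density depends on both endpoint rates)
        edges = {v} | set(t.children[v]) | set(t.children[p])
        if p != ROOT:
            edges.add(p)
        # likelihood terms: every branch touching v or p except v-p itself
        lik_edges = (set(t.children[v]) | set(t.children[p]) |
                     ({p} if p != ROOT else set())) - {v}
        old_terms = sum(self.cir_lp[e] for e in edges)
        if p == ROOT:
            old_terms += self.stat_lp
        if self.mode == "poisson":
            old_terms += sum(self.lik[e] for e in lik_edges)
        elif self.mode == "alignment":
            old_terms += self.aln_lik
        old_v, old_p = self.rates[v], self.rates[p]
        self.rates[v], self.rates[p] = new_v, new_p
        new_cir = {e: self._edge(e) for e in edges}
        new_terms = sum(new_cir.values())
        new_stat = None
        if p == ROOT:
            new_stat = _stat_lp(new_p, self.theta, self.sigma2, self.mu)
            new_terms += new_stat
        new_lik = {}
        if self.mode == "poisson":
            for e in lik_edges:
                new_lik[e] = self._lik_term(e, self._lam(e))
            new_terms += sum(new_lik.values())
        elif self.mode == "alignment":
            aln_new = self._full_lik()
            new_terms += aln_new
        acc = self._metropolis(new_terms - old_terms)
        self._acc["shift"][0] += acc
        if acc:
            for e in edges:
                self.cir_lp[e] = new_cir[e]
            for e in new_lik:
                self.lik[e] = new_lik[e]
            if new_stat is not None:
                self.stat_lp = new_stat
            if self.mode == "alignment":
                self.aln_lik = aln_new
        else:
            self.rates[v], self.rates[p] = old_v, old_p

    def _hyper_move(self):
        for name in ("theta", "sigma2"):
            old = getattr(self, name)
            s = math.exp(self.hyper_scale * (self.rng.random() - 0.5))
            new = old * s
            th = new if name == "theta" else self.theta
            s2 = new if name == "sigma2" else self.sigma2
            lp_old = self.hyper.logpdf(self.theta, self.sigma2, self.mu)
            lp_new = self.hyper.logpdf(th, s2, self.mu)
            acc = False
            if math.isfinite(lp_new):
                try:
                    params = cir.CIRParams(th, s2, self.mu)
                except ValueError:
                    params = None
                if params is not None:
                    d = self._durations()
                    cir_new = cir.transition_logdensity(
                        self.rates[1:], self.rates[self.parent[1:]],
                        d[1:], params)
                    stat_new = float(cir.stationary_logdensity(
                        self.rates[ROOT], params))
                    dlp = (np.sum(cir_new) + stat_new + lp_new
                           - np.sum(self.cir_lp[1:]) - self.stat_lp - lp_old
                           + math.log(s))
                    if self._metropolis(dlp):
                        setattr(self, name, new)
                        self.q = 2 * self.theta * self.mu / self.sigma2 - 1.0
                        self.lgq = float(gammaln(self.q + 1.0))
                        self.cir_lp = np.concatenate([[0.0], cir_new])
                        self.stat_lp = stat_new
                        acc = True
            self._acc["hyper"][0] += acc
            self._acc["hyper"][1] += 1

    def _root_moves(self):
        """Absolute mode: scale-all move + independence rescale."""
        # scale-all random walk
        s = math.exp(0.2 * (self.rng.random() - 0.5))
        self._try_rescale(s, hastings=self.n_int * math.log(s))
        # independence rescale from the root density
        t_new = float(self.spec.root.rvs(self.rng))
        if t_new > 0:
            s = t_new / self.ages[ROOT]
            # root density and its own Jacobian slot cancel against the
            # proposal; remaining Hastings covers the other n_int-1 ages
            self._try_rescale(s, hastings=(self.n_int - 1) * math.log(s),
                              independence=True)

    def _try_rescale(self, s, hastings, independence=False):
        old_ages = self.ages.copy()
        new_ages = old_ages * s
        old_lp = self._root_prior() + sum(
            self._cal(v) for v in self.cal_by_node)
        if independence:
            old_lp -= self.spec.root.logpdf(old_ages[ROOT])
        old_lik = (self.aln_lik if self.mode == "alignment"
                   else (float(np.sum(self.lik[1:]))
                         if self.mode == "poisson" else 0.0))
        old_cir = float(np.sum(self.cir_lp[1:]))
        self.ages = new_ages
        new_lp = self._root_prior() + sum(
            self._cal(v) for v in self.cal_by_node)
        if independence:
            new_lp -= self.spec.root.logpdf(new_ages[ROOT])
        new_lik = self._full_lik()
        d = self._durations()
        params = cir.CIRParams(self.theta, self.sigma2, self.mu)
        cir_new = cir.transition_logdensity(
            self.rates[1:], self.rates[self.parent[1:]], d[1:], params)
        dlp = (new_lp + new_lik + float(np.sum(cir_new))
               - old_lp - old_lik - old_cir + hastings)
        if math.isfinite(dlp) and self._metropolis(dlp):
            self.cir_lp = np.concatenate([[0.0], cir_new])
            if self.mode == "poisson":
                br = self._branch_rates()
                lam = np.maximum(br[1:] * d[1:] * self.L, 1e-300)
                self.lik = np.concatenate(
                    [[0.0], self.K[1:] * np.log(lam) - lam - self.lgK[1:]])
            elif self.mode == "alignment":
                self.aln_lik = new_lik
        else:
            self.ages = old_ages

    def _tradeoff_move(self):
        """Absolute mode: ages x s, rates / s keeps branch lengths fixed."""
        s = math.exp(0.2 * (self.rng.random() - 0.5))
        old_ages, old_rates = self.ages.copy(), self.rates.copy()
        old_lp = (self._root_prior()
                  + sum(self._cal(v) for v in self.cal_by_node)
                  + float(np.sum(self.cir_lp[1:])) + self.stat_lp)
        self.ages = old_ages * s
        self.rates = old_rates / s
        d = self._durations()
        params = cir.CIRParams(self.theta, self.sigma2, self.mu)
        cir_new = cir.transition_logdensity(
            self.rates[1:], self.rates[self.parent[1:]], d[1:], params)
        stat_new = float(cir.stationary_logdensity(self.rates[ROOT], params))
        new_lp = (self._root_prior()
                  + sum(self._cal(v) for v in self.cal_by_node)
                  + float(np.sum(cir_new)) + stat_new)
        hastings = self.n_int * math.log(s) - self.n * math.log(s)
        dlp = new_lp - old_lp + hastings
        if math.isfinite(dlp) and self._metropolis(dlp):
            self.cir_lp = np.concatenate([[0.0], cir_new])
            self.stat_lp = stat_new
        else:
            self.ages, self.rates = old_ages, old_rates

    # -- sweep -------------------------------------------------------------
    def sweep(self):
        for v in self.internal:
            self._age_move(v)
        if self.mode in ("poisson", "alignment"):
            for v in self.internal:
                self._comp_move(v)
                self._subtree_scale_move(v)
            for v in range(1, self.n):
                self._rate_shift_move(v)
            for _ in range(4):
                self._stretch_move()
        if not self.fixed_root:
            self._root_moves()
            self._tradeoff_move()
        for v in range(self.n):
            self._rate_move(v)
        if self.sample_hypers:
            self._hyper_move()

    def adapt(self):
        for key, attr in (("rate", "rate_scale"), ("hyper", "hyper_scale"),
                          ("age", "age_scale"), ("comp", "comp_scale"),
                          ("shift", "shift_scale"),
                          ("stretch", "stretch_scale"),
                          ("sub", "sub_scale")):
            acc, tot = self._acc[key]
            if tot >= 50:
                rate = acc / tot
                hi = 1.0 if key == "age" else 3.0
                setattr(self, attr, float(np.clip(
                    getattr(self, attr) * math.exp(rate - 0.3), 1e-4, hi)))
                self._acc[key] = [0, 0]

    def logpost(self):
        lp = self._root_prior() + sum(self._cal(v) for v in self.cal_by_node)
        lp += float(np.sum(self.cir_lp[1:])) + self.stat_lp
        lp += self.hyper.logpdf(self.theta, self.sigma2, self.mu)
        if self.mode == "poisson":
            lp += float(np.sum(self.lik[1:]))
        elif self.mode == "alignment":
            lp += self.aln_lik
        return lp


# ---------------------------------------------------------------------------
# Public driver
# ---------------------------------------------------------------------------

@dataclass
class McmcResult:
    traces: list
    tree: Phylogeny
    report: ConvergenceReport | None = None

    def pooled_ages(self) -> np.ndarray:
        return np.concatenate([t.ages[t.burn:] for t in self.traces], axis=0)

    def pooled_rates(self) -> np.ndarray:
        return np.concatenate([t.rates[t.burn:] for t in self.traces], axis=0)

    def summary(self) -> pd.DataFrame:
        return summarize(self.traces, self.tree)


def _run_chain_compiled(s: _Sampler, observed: Phylogeny,
                        spec: TimePriorSpec, n_samples: int, burn: int,
                        chain_seed: int):
    """Drive one chain through the numba core, reusing the Python
    sampler's initialization."""
    from . import _engine
    t = observed
    n = t.n_nodes
    child1 = np.full(n, -1, dtype=np.int64)
    child2 = np.full(n, -1, dtype=np.int64)
    for v, ch in enumerate(t.children):
        if ch:
            child1[v], child2[v] = ch
    internal = np.array(s.internal, dtype=np.int64)
    desc_start = np.zeros(n, dtype=np.int64)
    desc_len = np.zeros(n, dtype=np.int64)
    flat = []
    for v in range(n):
        desc_start[v] = len(flat)
        desc_len[v] = len(s.descendants[v])
        flat.extend(s.descendants[v])
    desc_flat = np.array(flat, dtype=np.int64)
    if s.mode == "poisson":
        K, lgK, L, use_lik = s.K.astype(float), s.lgK, s.L, 1
    else:
        K = np.zeros(n)
        lgK = np.zeros(n)
        L, use_lik = 1.0, 0
    cal_kind = np.zeros(n, dtype=np.int64)
    cal_tmin = np.zeros(n)
    cal_tmax = np.zeros(n)
    cal_tail = np.zeros(n)
    kind_code = {"min": 1, "max": 2, "min_max": 3}
    for node, cal in s.cal_by_node.items():
        cal_kind[node] = kind_code[cal.kind]
        cal_tmin[node] = cal.t_min if cal.t_min is not None else 0.0
        cal_tmax[node] = cal.t_max if cal.t_max is not None else 0.0
        cal_tail[node] = cal.tail_mass
    root = spec.root
    if root.fixed:
        root_kind, root_a, root_b = 0, 0.0, 0.0
    elif root.name == "exponential":
        root_kind, root_a, root_b = 1, root.mean_age, 0.0
    elif root.name == "gamma":
        root_kind, root_a, root_b = 2, root.shape, root.scale
    else:  # pragma: no cover
        raise ValueError(f"engine does not support root density {root.name}")
    A = np.empty((n_samples, n))
    R = np.empty((n_samples, n))
    TH = np.empty(n_samples)
    S2 = np.empty(n_samples)
    LP = np.empty(n_samples)
    _engine.run_chain(
        t.parent.astype(np.int64), child1, child2, internal,
        desc_flat, desc_start, desc_len,
        K, lgK, float(L), use_lik,
        cal_kind, cal_tmin, cal_tmax, cal_tail,
        np.array(sorted(s.cal_by_node), dtype=np.int64),
        root_kind, root_a, root_b,
        s.mu, s.theta, s.sigma2, s.hyper.theta_mean, s.hyper.sigma2_mean,
        1 if s.sample_hypers else 0,
        s.ages.copy(), s.rates.copy(), n_samples, burn,
        chain_seed % 2**32,
        A, R, TH, S2, LP)
    return A, R, TH, S2, LP


def run_mcmc(observed: Phylogeny, spec: TimePriorSpec, mode: str = "poisson",
             L: float | None = None, alignment: Alignment | None = None,
             clock_init: cir.CIRParams | None = None,
             hyper: HyperPrior | None = None, sample_hypers: bool = True,
             chains: int = 2, n_samples: int = 2000,
             burn_frac: float = 0.2, seed: int = 0,
             gamma_alpha: float | None = None,
             check: bool = False, maxdiff: float = 0.1,
             ess_floor: float = 100.0, engine: str = "auto") -> McmcResult:
    """Posterior (or, with ``mode="none"``, prior-only) MCMC.

    Runs ``chains`` chains with per-chain seeds derived from ``seed``;
    ``burn_frac`` of each chain is discarded in summaries (full traces are
    kept).  With ``check=True`` a failed tracecomp comparison is reported
    via ``result.report`` (never an exception: the caller decides).

    ``engine``: "compiled" uses the numba core (Poisson / prior-only
    modes), "python" the reference implementation; "auto" picks compiled
    where available.
    """
    if chains < 2:
        raise ValueError("at least two chains are required")
    spec = spec.bind(observed)
    clock0 = clock_init or cir.CIRParams(1.0, 0.5, 1.0)
    hyper = hyper or HyperPrior()
    if engine == "auto":
        engine = "compiled" if mode in ("poisson", "none") else "python"
    if engine == "compiled" and mode not in ("poisson", "none"):
        raise ValueError("compiled engine supports poisson/none modes only")
    traces = []
    for ch in range(chains):
        seq = np.random.SeedSequence([seed, ch])
        rng = np.random.default_rng(seq)
        s = _Sampler(observed, spec, mode, L, alignment, clock0, hyper,
                     sample_hypers, rng, gamma_alpha)
        burn = int(burn_frac * n_samples)
        if engine == "compiled":
            chain_seed = int(seq.generate_state(1)[0])
            A, R, TH, S2, LP = _run_chain_compiled(
                s, observed, spec, n_samples, burn, chain_seed)
        else:
            A = np.empty((n_samples, s.n))
            R = np.empty((n_samples, s.n))
            TH = np.empty(n_samples)
            S2 = np.empty(n_samples)
            LP = np.empty(n_samples)
            for it in range(n_samples):
                s.sweep()
                if it < burn and it % 25 == 24:
                    s.adapt()
                if it % 500 == 499:
                    s._recache()  # guard against float drift in caches
                A[it] = s.ages
                R[it] = s.rates
                TH[it] = s.theta
                S2[it] = s.sigma2
                LP[it] = s.logpost()
        traces.append(McmcTrace(A, R, TH, S2, LP, seed=seed + ch, burn=burn))
    report = None
    if check:
        report = convergence_check([t.monitored(observed) for t in traces],
                                   maxdiff_threshold=maxdiff,
                                   ess_floor=ess_floor)
    return McmcResult(traces, observed, report)


def log_posterior(observed: Phylogeny, spec: TimePriorSpec,
                  ages: np.ndarray, rates: np.ndarray,
                  theta: float, sigma2: float, mode: str = "poisson",
                  L: float | None = None, alignment: Alignment | None = None,
                  mu: float = 1.0, hyper: HyperPrior | None = None) -> float:
    """Unnormalized log posterior of one full state, computed from scratch
    (no caches); used to cross-validate sampler engines."""
    spec = spec.bind(observed)
    s = _Sampler(observed, spec, mode, L, alignment,
                 cir.CIRParams(theta, sigma2, mu), hyper or HyperPrior(),
                 True, np.random.default_rng(0))
    s.ages = np.asarray(ages, float).copy()
    s.rates = np.asarray(rates, float).copy()
    s.theta, s.sigma2 = float(theta), float(sigma2)
    s._recache()
    return s.logpost()


def summarize(traces, tree: Phylogeny, mass: float = 0.95) -> pd.DataFrame:
    """Per-node age mean and 95% HPD from pooled post-burn-in samples."""
    pooled = np.concatenate([t.ages[t.burn:] for t in traces], axis=0)
    if pooled.shape[0] < 100:
        raise ValueError("need >= 100 post-burn-in samples")
    rows = []
    for v in tree.internal_ids:
        x = pooled[:, v]
        lo, hi = hpd(x, mass)
        rows.append({"node_id": int(v), "mean": float(np.mean(x)),
                     "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows)
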