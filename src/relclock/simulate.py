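"""Synthetic timetrees, rate histories, noisy branch lengths and alignments.

The generator emulates the kind of dataset the dating analyses are built
for: a rooted binary timetree of extant taxa (birth-death, conditioned on
tip count by rejection and rescaled to a chosen root age), branch rates
evolving under an autocorrelated CIR process (so rates vary along the whole
tree, with occasional tipward accelerations), and finite-alignment sampling
noise on branch lengths — Poisson substitution counts at alignment length L,
so that Var(b_hat) = b/L, the same variance model the relative-rate
framework uses for its standard errors.

Default configuration: 16 tips, relative time scale (root age 1),
CIR(theta=1, sigma2=0.5, mu=1) — stationary rate CV of 50%, autocorrelation
time equal to the root age — and L = 5000 sites of Poisson noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import cir
from .treeio import ROOT, Alignment, Chronogram, Phylogeny, PhyloError


@dataclass(frozen=True)
class LognormalIID:
    """Independent lognormal branch rates with mean 1 and log-sd ``sd``."""

    sd: float


@dataclass
class SimulationConfig:
    n_tips: int = 16
    root_age: float = 1.0
    birth_rate: float = 1.0
    death_rate: float = 0.0
    clock: object = field(default_factory=lambda: cir.CIRParams(1.0, 0.5, 1.0))
    L: int = 5000
    noise: str = "poisson"  # none | poisson | alignment
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if not self.root_age > 0:
            raise ValueError("root_age must be > 0")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.L < 1:
            raise ValueError("alignment length must be >= 1")
        if self.noise not in ("none", "poisson", "alignment"):
            raise ValueError(f"unknown noise mode {self.noise}")


@dataclass
class SimulatedTruth:
    """Ground truth for recovery tests: timetree, rates, observed lengths."""

    timetree: Chronogram
    node_rates: np.ndarray      # rate at each node (nan where undefined)
    branch_rates: np.ndarray    # rate of the branch above each node
    true_lengths: np.ndarray    # rate x duration
    observed: Phylogeny         # branch lengths with sampling noise
    alignment: Alignment | None = None


# ---------------------------------------------------------------------------
# Birth-death timetree, conditioned on tip count by rejection
# ---------------------------------------------------------------------------

class SimulationError(RuntimeError):
    pass


def _forward_birth_death(n_tips, birth, death, rng):
    """One forward simulation; returns (parent, time, alive) event records or
    None if the process dies before reaching n_tips extant lineages.

    Lineage records: parent index (-1 for the two root children's parent),
    birth time; the present is set at the end of the waiting interval during
    which the extant count first equals n_tips.
    """
    parent = [-1, 0, 0]          # node 0 = root, splits at t=0
    btime = [0.0, 0.0, 0.0]
    alive = [False, True, True]
    t = 0.0
    while True:
        n_alive = sum(alive)
        if n_alive == 0:
            return None
        total = n_alive * (birth + death)
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if n_alive == n_tips:
            # cut the tree just before the next event
            return parent, btime, alive, t + wait
        if not math.isfinite(wait):
            return None
        t += wait
        idx = [i for i, a in enumerate(alive) if a]
        v = idx[rng.integers(len(idx))]
        if rng.random() < birth / (birth + death):
            alive[v] = False
            for _ in range(2):
                parent.append(v)
                btime.append(t)
                alive.append(True)
        else:
            alive[v] = False


def _prune_to_phylogeny(parent, btime, alive, present, root_age):
    """Drop extinct lineages, suppress unary nodes, rescale root to
    root_age; returns (Phylogeny with nan lengths, ages array)."""
    n = len(parent)
    children = [[] for _ in range(n)]
    for v in range(1, n):
        children[parent[v]].append(v)
    # surv[v]: representative of v's surviving subtree (a binary node or an
    # extant tip), with unary pass-throughs suppressed; None if extinct
    surv = [None] * n
    for v in range(n - 1, -1, -1):
        if not children[v]:
            surv[v] = v if alive[v] else None
        else:
            kids = [surv[c] for c in children[v] if surv[c] is not None]
            if len(kids) == 0:
                surv[v] = None
            elif len(kids) == 1:
                surv[v] = kids[0]       # unary: pass through
            else:
                surv[v] = v
    new_root = surv[0]
    if new_root is None or not children[new_root]:
        return None                     # extinct, or a single surviving tip

    # rebuild in preorder from new_root
    def surviving_children(v):
        out = []
        for c in children[v]:
            if surv[c] is not None:
                out.append(surv[c])
        return out

    order, stack = [], [new_root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(surviving_children(v)))
    index = {v: i for i, v in enumerate(order)}
    m = len(order)
    new_parent = np.full(m, -1, dtype=int)
    new_children = [[] for _ in range(m)]
    ages = np.zeros(m)
    labels = [None] * m
    tip_no = 0
    for v in order:
        i = index[v]
        kids = surviving_children(v)
        if kids:
            # v's original children share one birth time: the split event
            ages[i] = present - btime[children[v][0]]
            for c in kids:
                j = index[c]
                new_parent[j] = i
                new_children[i].append(j)
        else:
            ages[i] = 0.0
            tip_no += 1
            labels[i] = f"t{tip_no}"
    scale = root_age / ages[0]
    ages *= scale
    tree = Phylogeny(new_parent, [tuple(c) for c in new_children],
                     np.full(m, np.nan), labels)
    return tree, ages


def simulate_timetree(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      max_attempts: int = 10000) -> Chronogram:
    """Birth-death timetree with exactly ``n_tips`` extant tips.

    Simulated forward from the root split; runs that go extinct (or lose
    tips to pruning) are rejected and re-drawn; node ages are rescaled so
    the root sits at ``config.root_age`` and all tips at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(max_attempts):
        res = _forward_birth_death(config.n_tips, config.birth_rate,
                                   config.death_rate, rng)
        if res is None:
            continue
        built = _prune_to_phylogeny(*res, config.root_age)
        if built is None:
            continue
        tree, ages = built
        if tree.n_tips != config.n_tips:
            continue
        chron = Chronogram(tree, ages)
        chron.validate(tip_tol=0.0)
        return chron
    raise SimulationError(
        f"no {config.n_tips}-tip tree in {max_attempts} attempts; "
        "check birth/death rates")


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def simulate_rates(timetree: Chronogram, clock,
                   rng: np.random.Generator | None = None,
                   seed: int = 0) -> tuple:
    """Draw (node_rates, branch_rates) under a clock model.

    strict: all rates 1.  CIRParams: root node rate from the stationary
    Gamma, child node rates by the exact CIR transition along each branch;
    branch rate = arithmetic mean of its endpoint node rates.  LognormalIID:
    i.i.d. mean-1 lognormal branch rates (node rates undefined).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = timetree.tree
    n = tree.n_nodes
    node_rates = np.full(n, np.nan)
    branch_rates = np.full(n, np.nan)
    if clock == "strict":
        node_rates[:] = 1.0
        branch_rates[1:] = 1.0
    elif isinstance(clock, cir.CIRParams):
        d = timetree.durations()
        node_rates[ROOT] = cir.sample_stationary(clock, rng)
        for v in range(1, n):
            node_rates[v] = cir.simulate_transition(
                node_rates[tree.parent[v]], d[v], clock, rng)
        branch_rates[1:] = 0.5 * (node_rates[1:] + node_rates[tree.parent[1:]])
    elif isinstance(clock, LognormalIID):
        mu_log = -0.5 * clock.sd**2   # mean-1 lognormal
        branch_rates[1:] = rng.lognormal(mu_log, clock.sd, size=n - 1)
    else:
        raise ValueError(f"unknown clock model {clock!r}")
    return node_rates, branch_rates


# ---------------------------------------------------------------------------
# Branch-length noise
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _simulate_jc_alignment(tree: Phylogeny, lengths: np.ndarray, L: int,
                           rng: np.random.Generator):
    """Simulate JC sequences at every node; returns (states array, Alignment)."""
    states = np.empty((tree.n_nodes, L), dtype=np.int8)
    states[ROOT] = rng.integers(4, size=L)
    for v in range(1, tree.n_nodes):
        b = lengths[v]
        p_change = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
        parent_state = states[tree.parent[v]]
        hit = rng.random(L) < p_change
        shift = rng.integers(1, 4, size=L)
        states[v] = np.where(hit, (parent_state + shift) % 4, parent_state)
    tips = tree.tip_ids
    aln = Alignment(
        [tree.labels[t] for t in tips],
        ["".join(_BASES[s] for s in states[t]) for t in tips])
    return states, aln


def jc_distance(p_mismatch: float) -> float:
    """Jukes-Cantor distance from a mismatch fraction (capped near 0.75)."""
    arg = 1.0 - 4.0 * p_mismatch / 3.0
    if arg <= 1e-9:
        arg = 1e-9
    return max(0.0, -0.75 * math.log(arg))


def add_branch_noise(timetree: Chronogram, branch_rates: np.ndarray,
                     noise: str, L: int,
                     rng: np.random.Generator | None = None,
                     seed: int = 0):
    """Observed branch lengths from true lengths b = rate x duration.

    poisson: b_hat = K/L with K ~ Poisson(bL) per branch (Var = b/L).
    alignment: simulate JC sequences on the true tree and set b_hat to the
    per-branch JC maximum-likelihood estimate between the (simulated)
    endpoint sequences on the true topology.
    none: b_hat = b.

    Returns (observed Phylogeny, true_lengths, alignment-or-None).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = timetree.tree
    d = timetree.durations()
    true_b = branch_rates * d
    true_b[ROOT] = np.nan
    obs = true_b.copy()
    aln = None
    if noise == "poisson":
        k = rng.poisson(true_b[1:] * L)
        obs[1:] = k / L
    elif noise == "alignment":
        states, aln = _simulate_jc_alignment(tree, true_b, L, rng)
        for v in range(1, tree.n_nodes):
            p_hat = np.mean(states[v] != states[tree.parent[v]])
            obs[v] = jc_distance(p_hat)
    elif noise != "none":
        raise ValueError(f"unknown noise mode {noise}")
    observed = tree.with_lengths(np.where(np.isnan(obs), 0.0, obs))
    observed.branch_length[ROOT] = np.nan
    return observed, true_b, aln


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedTruth:
    """Full pipeline: timetree -> rates -> noisy branch lengths (seeded)."""
    rng = np.random.default_rng(config.seed)
    timetree = simulate_timetree(config, rng)
    node_rates, branch_rates = simulate_rates(timetree, config.clock, rng)
    observed, true_b, aln = add_branch_noise(
        timetree, branch_rates, config.noise, config.L, rng)
    return SimulatedTruth(timetree, node_rates, branch_rates, true_b,
                          observed, aln)
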