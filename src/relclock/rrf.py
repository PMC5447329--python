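"""Relative-rate framework (RRF): RelTime-style rates, SEs and relative times.

The scheme is deterministic and fully documented here; it is a
tip-averaged-depth variant of the relative rate framework, not a re-import
of any particular program's internals:

1.  Lineage depths.  For each node the expected tip-to-node path length H
    is the average of its two children's lineage depths D(c) = b(c) + H(c),
    with tip depth 0.  Branch-length sampling variance Var(b) = b/L
    (Poisson substitution counts at alignment length L) propagates through
    the same recursion.

2.  Rates, top-down.  Each child lineage gets a raw rate factor
    rho(c) = D(c)/H(v) relative to its parent; the branch rate is the
    running product down from a virtual rate 1 above the root.

3.  SE-driven merging.  Parent and child are given the *same* rate when
    their depths are statistically indistinguishable:
    |D(c) - H(v)| / sqrt(Var D(c) + Var H(v)) < z_merge (default 2).  With
    infinite L the test degenerates to exact equality.  This is the
    mechanism by which finite data collapse deep branches onto a single
    strict-clock rate: the absolute depth difference carries the rate
    signal while its standard error grows with depth.

4.  Median normalization.  All branch rates are divided by their median, so
    a fully merged tree has every rate exactly 1.

Relative node times then follow by averaging child ages plus rate-corrected
branch durations, normalized to a root age of 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .treeio import ROOT, Chronogram, Phylogeny


@dataclass
class LineageDepths:
    """Tip-averaged path lengths H (per node) and lineage depths
    D = b + H(child) (per non-root node), with propagated variances."""

    H: np.ndarray
    var_H: np.ndarray
    D: np.ndarray
    var_D: np.ndarray


@dataclass
class RateAssignment:
    """Per-branch relative rates (median-normalized), SEs and provenance.

    ``rate[v]`` is the rate of the branch above node v (nan at the root);
    ``se[v]`` is the delta-method SE of the local rate ratio D(v)/H(parent);
    ``merged[v]`` marks branches whose rate was set equal to the parent's.
    """

    tree: Phylogeny
    rate: np.ndarray
    se: np.ndarray
    merged: np.ndarray
    rho: np.ndarray
    median: float
    L: float
    z_merge: float

    @property
    def branch_ids(self) -> np.ndarray:
        return np.arange(1, self.tree.n_nodes)

    def internal_branch_ids(self) -> np.ndarray:
        """Branches whose child node is internal (nonterminal branches)."""
        return np.array([v for v in range(1, self.tree.n_nodes)
                         if not self.tree.is_tip(v)], dtype=int)


def lineage_depths(tree: Phylogeny, L: float = math.inf) -> LineageDepths:
    """Bottom-up expected depths and variances.

    H(tip) = 0; D(c) = b(c) + H(c); H(v) = (D(x) + D(y))/2;
    Var D(c) = b(c)/L + Var H(c); Var H(v) = (Var D(x) + Var D(y))/4.
    """
    n = tree.n_nodes
    H = np.zeros(n)
    var_H = np.zeros(n)
    D = np.full(n, np.nan)
    var_D = np.full(n, np.nan)
    for v in tree.postorder():
        if tree.is_tip(v):
            H[v] = 0.0
            var_H[v] = 0.0
        else:
            x, y = tree.children[v]
            H[v] = 0.5 * (D[x] + D[y])
            var_H[v] = 0.25 * (var_D[x] + var_D[y])
        if v != ROOT:
            b = tree.branch_length[v]
            D[v] = b + H[v]
            var_D[v] = (b / L if math.isfinite(L) else 0.0) + var_H[v]
    return LineageDepths(H, var_H, D, var_D)


def assign_relative_rates(tree: Phylogeny, L: float = math.inf,
                          z_merge: float = 2.0,
                          geometric_parent: bool = False) -> RateAssignment:
    """Top-down rate assignment with SE-based parent/child merging.

    ``geometric_parent`` switches the implicit parent-rate convention from
    the arithmetic to the geometric mean of the sister rate factors (the
    rho's are renormalized so their product, rather than their sum, is
    neutral); the default matches the documented arithmetic convention.
    """
    dep = lineage_depths(tree, L)
    n = tree.n_nodes
    rate = np.full(n, np.nan)
    se = np.full(n, np.nan)
    rho = np.full(n, np.nan)
    merged = np.zeros(n, dtype=bool)
    parent_rate = np.ones(n)  # rate of the branch above v's parent (virtual 1 at root)

    for v in tree.preorder():
        if tree.is_tip(v):
            continue
        Hv, varHv = dep.H[v], dep.var_H[v]
        kids = tree.children[v]
        r_parent = 1.0 if v == ROOT else rate[v]
        raw = []
        for c in kids:
            Dc, varDc = dep.D[c], dep.var_D[c]
            if Hv == 0.0:
                warnings.warn(
                    f"zero-depth subtree at node {v}; child {c} merged to "
                    "parent rate", RuntimeWarning)
                rho[c], merged[c] = 1.0, True
                se[c] = np.inf if math.isfinite(L) else 0.0
                raw.append(1.0)
                continue
            if Dc == 0.0:
                # degenerate zero-depth lineage: no signal, inherit parent
                warnings.warn(f"zero lineage depth at branch {c}; merged to "
                              "parent rate", RuntimeWarning)
                rho[c], merged[c] = 1.0, True
                se[c] = math.inf if math.isfinite(L) else 0.0
                raw.append(1.0)
                continue
            ratio = Dc / Hv
            denom = math.sqrt(varDc + varHv)
            if denom == 0.0:
                do_merge = (Dc == Hv)
            else:
                do_merge = abs(Dc - Hv) / denom < z_merge
            rho[c] = 1.0 if do_merge else ratio
            merged[c] = do_merge
            se[c] = ratio * math.sqrt(varDc / Dc**2 + varHv / Hv**2)
            raw.append(ratio)
        if geometric_parent and len(kids) == 2 and min(raw) > 0:
            g = math.sqrt(raw[0] * raw[1])
            for c in kids:
                if not merged[c]:
                    rho[c] = rho[c] / g
        for c in kids:
            rate[c] = r_parent * rho[c]

    branch = np.arange(1, n)
    med = float(np.median(rate[branch]))
    if med <= 0:
        raise ValueError("non-positive median rate; degenerate tree")
    rate[branch] = rate[branch] / med
    return RateAssignment(tree, rate, se, merged, rho, med, L, z_merge)


def relative_times(tree: Phylogeny, rates: RateAssignment) -> Chronogram:
    """Relative chronogram from rate-corrected branch lengths.

    t(tip) = 0; t(v) = mean over children c of (t(c) + b(c)/r(c)); ages are
    then divided by the root age so root = 1 exactly.  With all rates 1
    this returns H(v)/H(root).
    """
    n = tree.n_nodes
    t = np.zeros(n)
    for v in tree.postorder():
        if tree.is_tip(v):
            continue
        vals = []
        for c in tree.children[v]:
            r = rates.rate[c]
            if not (r > 0):
                raise ValueError(f"non-positive rate on branch {c}")
            vals.append(t[c] + tree.branch_length[c] / r)
        t[v] = float(np.mean(vals))
    if t[ROOT] <= 0:
        raise ValueError("zero root age; all branch lengths zero?")
    t /= t[ROOT]
    chron = Chronogram(tree, t)
    return chron


def reltime(tree: Phylogeny, L: float = math.inf,
            z_merge: float = 2.0) -> tuple:
    """Convenience wrapper: (RateAssignment, relative Chronogram)."""
    rates = assign_relative_rates(tree, L=L, z_merge=z_merge)
    return rates, relative_times(tree, rates)
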