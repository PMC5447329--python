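"""Comparison statistics between dating methods.

Regressions between relative chronograms, rate-vs-depth and SE-vs-depth
profiles, strict-clock collapse quantification, and specified-vs-effective
prior (truncation) reports.  Regressions exclude the root and the tips:
both are pinned by construction (1 and 0) in every relative chronogram, so
including them only inflates agreement artificially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rrf import RateAssignment
from .timeprior import MarginalPriorSummary, TimePriorSpec
from .treeio import ROOT, Chronogram


@dataclass
class Regression:
    r2: float | None
    slope: float | None
    intercept: float | None
    pairs: np.ndarray          # (n, 2) columns x, y
    degenerate: bool = False   # zero variance in either vector


def compare_relative_ages(x: Chronogram, y: Chronogram) -> Regression:
    """OLS (with intercept) of y's relative ages on x's over shared
    internal non-root nodes; R^2 is the squared Pearson correlation."""
    if x.tree.n_nodes != y.tree.n_nodes:
        raise ValueError("chronograms must share a tree")
    nodes = [v for v in x.tree.internal_ids if v != ROOT]
    if len(nodes) < 3:
        raise ValueError("need at least 3 shared internal nodes")
    xv = x.relative().ages[nodes]
    yv = y.relative().ages[nodes]
    pairs = np.column_stack([xv, yv])
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return Regression(None, None, None, pairs, degenerate=True)
    fit = stats.linregress(xv, yv)
    return Regression(float(fit.rvalue**2), float(fit.slope),
                      float(fit.intercept), pairs)


def collapse_metrics(rates: RateAssignment, ages: Chronogram,
                     tol: float = 1e-6) -> tuple:
    """(collapse_index, collapse_depth) of a median-normalized assignment.

    collapse_index: fraction of nonterminal branches whose rate equals the
    median rate (1 after normalization) within ``tol`` — the strict-clock
    collapse produced by SE-driven merging is exact, so the default
    tolerance is tight.  collapse_depth: smallest relative age tau such
    that every branch subtending a node older than tau carries the median
    rate; None when no branch does.
    """
    internal = rates.internal_branch_ids()
    if len(internal) == 0:
        return 0.0, None
    rel = ages.relative().ages
    at_median = np.abs(rates.rate[internal] - 1.0) <= tol
    index = float(np.mean(at_median))
    if not np.any(at_median):
        return index, None
    off = internal[~at_median]
    if len(off) == 0:
        return index, 0.0
    # all nodes older than the oldest off-median child node are collapsed
    return index, float(np.max(rel[off]))


def se_profile(rates: RateAssignment, ages: Chronogram) -> dict:
    """Per-branch (subtending node age, SE) pairs with an OLS fit.

    Branches with infinite SE are excluded (their count is reported).
    """
    rel = ages.relative().ages
    branch = rates.branch_ids
    se = rates.se[branch]
    finite = np.isfinite(se)
    x = rel[branch][finite]
    y = se[finite]
    out = {"pairs": np.column_stack([x, y]),
           "n_excluded_infinite": int(np.sum(~finite))}
    if len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        fit = stats.linregress(x, y)
        out.update(slope=float(fit.slope), intercept=float(fit.intercept),
                   r2=float(fit.rvalue**2))
    else:
        out.update(slope=0.0 if np.ptp(y) == 0 else None,
                   intercept=None, r2=None)
    return out


def prior_shift_report(spec: TimePriorSpec, marginal: MarginalPriorSummary,
                       query_interval: tuple | None = None,
                       query_node: int = ROOT,
                       flag_level: float = 0.025) -> pd.DataFrame:
    """Specified vs effective prior for the root and each calibrated node.

    For the root the specified side is analytic (mean and central 95%
    interval of the calibration density); for bound calibrations the
    specified column records the bounds.  ``query_interval`` asks whether
    the effective marginal of ``query_node`` gives that age interval at
    least ``flag_level`` cumulative probability; the flag fires when it
    does not (the device for "vanishingly small prior probability").
    """
    rows = []
    root_rep = marginal.root_report()
    row = {"node_id": ROOT, "kind": "root_density",
           "specified_mean": root_rep["specified_mean"],
           "specified_lo": root_rep["specified_interval"][0],
           "specified_hi": root_rep["specified_interval"][1],
           "effective_mean": root_rep["effective_mean"],
           "effective_lo": root_rep["effective_interval"][0],
           "effective_hi": root_rep["effective_interval"][1],
           "shift": root_rep["shift"], "flag_low_mass": False}
    rows.append(row)
    for cal in marginal.spec.bound_calibrations():
        x = marginal.samples[:, cal.node]
        eff_mean = float(np.mean(x))
        spec_mid = np.nanmean([v for v in (cal.t_min, cal.t_max)
                               if v is not None])
        rows.append({
            "node_id": cal.node, "kind": cal.kind,
            "specified_mean": float(spec_mid),
            "specified_lo": cal.t_min if cal.t_min is not None else math.nan,
            "specified_hi": cal.t_max if cal.t_max is not None else math.nan,
            "effective_mean": eff_mean,
            "effective_lo": float(np.quantile(x, 0.025)),
            "effective_hi": float(np.quantile(x, 0.975)),
            "shift": eff_mean - float(spec_mid), "flag_low_mass": False})
    df = pd.DataFrame(rows)
    if query_interval is not None:
        lo, hi = query_interval
        x = marginal.samples[:, query_node]
        mass = float(np.mean((x >= lo) & (x <= hi)))
        df.loc[df.node_id == query_node, "flag_low_mass"] = mass < flag_level
        df.attrs["query_mass"] = mass
    return df


def plot_rate_profile(rates: RateAssignment, ages: Chronogram, path=None):
    """Scatter of relative node age vs branch rate (rate-collapse panel)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    rel = ages.relative().ages
    branch = rates.branch_ids
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(rel[branch], rates.rate[branch], s=12)
    ax.axhline(1.0, color="red", lw=0.8)
    ax.set_xlabel("relative node age")
    ax.set_ylabel("relative branch rate")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
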