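"""Branch-length likelihoods for the dating sampler.

Three desk-scale data models connect node ages and rates to observations
(the branch length implied by the model is rate x duration, with the
branch rate the arithmetic mean of the endpoint node rates):

* ``poisson`` — the observed branch lengths b_hat derive from Poisson
  substitution counts K = b_hat * L at alignment length L; the
  log-likelihood is the Poisson log-pmf of K with mean r * d * L per
  branch.  This matches the synthetic generator's noise model exactly.
* ``alignment`` — Felsenstein pruning under Jukes-Cantor with optional
  discrete-gamma rate heterogeneity (4 categories).
* ``exact`` — a delta function at b_hat = r * d, for likelihood-level
  testing only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist

from .treeio import ROOT, Alignment, Chronogram, Phylogeny


@dataclass
class PoissonData:
    """Substitution counts recovered from observed branch lengths."""

    counts: np.ndarray  # K per node (branch above); 0 at root
    L: float

    @classmethod
    def from_tree(cls, observed: Phylogeny, L: float) -> "PoissonData":
        k = np.rint(np.nan_to_num(observed.branch_length) * L)
        k[ROOT] = 0.0
        return cls(k, float(L))


def poisson_branch_loglik(counts: np.ndarray, L: float, durations: np.ndarray,
                          branch_rates: np.ndarray) -> float:
    """Sum of Poisson log-pmfs over branches (full pmf, K! included)."""
    d = durations[1:]
    if np.any(d <= 0):
        return -math.inf
    lam = branch_rates[1:] * d * L
    lam = np.maximum(lam, 1e-300)
    k = counts[1:]
    return float(np.sum(k * np.log(lam) - lam - gammaln(k + 1.0)))


# ---------------------------------------------------------------------------
# Jukes-Cantor pruning
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ncat equal-probability gamma(alpha, alpha) categories."""
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), alpha, scale=1 / alpha)
    # category mean via the standard incomplete-gamma identity
    cdf_ap1 = gamma_dist.cdf(edges, alpha + 1, scale=1 / alpha)
    means = ncat * np.diff(cdf_ap1)
    return means


def _jc_pmatrix(b: float) -> np.ndarray:
    same = 0.25 + 0.75 * math.exp(-4.0 * b / 3.0)
    diff = (1.0 - same) / 3.0
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def jc_pruning_loglik(tree: Phylogeny, branch_lengths: np.ndarray,
                      alignment: Alignment, gamma_alpha: float | None = None,
                      ncat: int = 4) -> float:
    """Felsenstein pruning log-likelihood under JC (optionally +Gamma).

    Gaps/ambiguities get a flat partial likelihood.  Site patterns are not
    compressed (desk-scale alignments).
    """
    L = alignment.length
    tip_partials = {}
    for lab, seq in zip(alignment.labels, alignment.seqs):
        p = np.ones((L, 4))
        for i, ch in enumerate(seq):
            c = _CODE.get(ch)
            if c is not None:
                p[i] = 0.0
                p[i, c] = 1.0
        tip_partials[lab] = p
    cats = (np.array([1.0]) if gamma_alpha is None
            else discrete_gamma_rates(gamma_alpha, ncat))
    site_lik = np.zeros(L)
    for r in cats:
        partial = [None] * tree.n_nodes
        for v in tree.postorder():
            if tree.is_tip(v):
                partial[v] = tip_partials[tree.labels[v]]
            else:
                p = np.ones((L, 4))
                for c in tree.children[v]:
                    pm = _jc_pmatrix(branch_lengths[c] * r)
                    p = p * (partial[c] @ pm.T)
                partial[v] = p
        site_lik += 0.25 * partial[ROOT].sum(axis=1) / len(cats)
    if np.any(site_lik <= 0):
        return -math.inf
    return float(np.sum(np.log(site_lik)))


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def branch_loglikelihood(observed: Phylogeny, ages: Chronogram | np.ndarray,
                         node_rates: np.ndarray, mode: str,
                         L: float | None = None,
                         alignment: Alignment | None = None,
                         gamma_alpha: float | None = None) -> float:
    """Log-likelihood of the observation under (ages, node rates).

    ``mode``: poisson | alignment | exact | none.  Branch rate is the mean
    of endpoint node rates; negative durations give -inf.
    """
    tree = observed
    age = ages.ages if isinstance(ages, Chronogram) else np.asarray(ages, float)
    dur = age[tree.parent] - age
    dur[ROOT] = np.nan
    if np.any(dur[1:] <= 0):
        return -math.inf
    br = np.full(tree.n_nodes, np.nan)
    br[1:] = 0.5 * (node_rates[1:] + node_rates[tree.parent[1:]])
    if mode == "none":
        return 0.0
    if mode == "poisson":
        if L is None:
            raise ValueError("poisson mode needs L")
        data = PoissonData.from_tree(observed, L)
        return poisson_branch_loglik(data.counts, data.L, dur, br)
    if mode == "exact":
        model_b = br[1:] * dur[1:]
        obs_b = observed.branch_length[1:]
        return 0.0 if np.allclose(model_b, obs_b, rtol=0, atol=1e-12) else -math.inf
    if mode == "alignment":
        if alignment is None:
            raise ValueError("alignment mode needs an alignment")
        return jc_pruning_loglik(tree, br * dur, alignment,
                                 gamma_alpha=gamma_alpha)
    raise ValueError(f"unknown likelihood mode {mode}")
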