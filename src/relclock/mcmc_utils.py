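"""Trace summaries and convergence diagnostics shared by the samplers."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


def hpd(samples, mass: float = 0.95) -> tuple:
    """Shortest single interval containing ``mass`` of the samples
    (highest posterior density), by sorted-window minimization."""
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = max(1, int(math.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def ess(x) -> float:
    """Effective sample size by Geyer's initial monotone positive sequence
    on the FFT autocovariance."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        return float(n)
    v = np.var(x)
    if v == 0:
        return float(n)
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sums of adjacent pairs; stop at the first negative, enforce monotone
    m = (n - 1) // 2
    pair = rho[1 : 2 * m + 1 : 2] + rho[2 : 2 * m + 1 : 2]
    s = 0.0
    prev = np.inf
    for p in pair:
        if p < 0:
            break
        p = min(p, prev)
        prev = p
        s += p
    tau = 1.0 + 2.0 * s
    return float(n / max(tau, 1.0 / n))


@dataclass
class ConvergenceReport:
    """Tracecomp-style chain comparison: per-scalar relative difference of
    chain means (|m1 - m2| / pooled sd) and minimum per-chain ESS."""

    table: pd.DataFrame
    passed: bool
    maxdiff_threshold: float
    ess_floor: float

    @property
    def maxdiff(self) -> float:
        return float(self.table["reldiff"].max())

    @property
    def min_ess(self) -> float:
        return float(self.table["ess"].min())


def convergence_check(traces, maxdiff_threshold: float = 0.1,
                      ess_floor: float = 100.0) -> ConvergenceReport:
    """Compare >= 2 chains scalar by scalar.

    ``traces`` is a list of dicts mapping scalar name -> 1-D sample array;
    unequal lengths are truncated to the shortest.  Pass requires every
    relative mean difference below the threshold and every pooled ESS above
    the floor.
    """
    if len(traces) < 2:
        raise ValueError("need at least two chains")
    names = list(traces[0].keys())
    for t in traces[1:]:
        if set(t.keys()) != set(names):
            raise ValueError("chains monitor different scalar sets")
    n = min(len(t[names[0]]) for t in traces)
    rows = []
    ok = True
    for name in names:
        xs = [np.asarray(t[name], float)[:n] for t in traces]
        pooled = np.concatenate(xs)
        sd = float(np.std(pooled))
        means = [float(np.mean(x)) for x in xs]
        if sd == 0:
            reldiff = 0.0
        else:
            reldiff = max(abs(a - b) for a in means for b in means) / sd
        e = sum(ess(x) for x in xs)
        rows.append({"scalar": name, "reldiff": reldiff, "ess": e})
        if reldiff >= maxdiff_threshold or e <= ess_floor:
            ok = False
    return ConvergenceReport(pd.DataFrame(rows), ok,
                             maxdiff_threshold, ess_floor)
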