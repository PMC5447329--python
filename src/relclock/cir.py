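"""Cox–Ingersoll–Ross (CIR) rate process: densities, moments, exact sampling.

The CIR process is the mean-reverting positive diffusion
``dr = theta (mu - r) dt + sqrt(sigma2 r) dW`` used as an autocorrelated
relaxed-clock model: node rates evolve along the tree, and the rate of a
branch is the arithmetic mean of its endpoint node rates.  Its stationary
law is Gamma(2 theta mu / sigma2, rate 2 theta / sigma2) and its transition
law is a scaled noncentral chi-square, which gives exact (discretization
free) simulation and closed-form transition densities.

All densities are computed in log space with the exponentially scaled
Bessel function; naive evaluation of I_q overflows for small time steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ive


@dataclass(frozen=True)
class CIRParams:
    """CIR parameters.

    theta : mean-reversion rate (1/time; time is Myr in absolute mode,
        dimensionless in relative mode).
    sigma2 : diffusion variance parameter.
    mu : stationary mean rate (fixed to 1 in relative-rate analyses).

    The Feller condition ``2 theta mu >= sigma2`` keeps the process strictly
    positive and is enforced.
    """

    theta: float
    sigma2: float
    mu: float = 1.0

    def __post_init__(self):
        if not (self.theta > 0 and self.sigma2 > 0 and self.mu > 0):
            raise ValueError("CIR parameters must be positive")
        if 2 * self.theta * self.mu < self.sigma2:
            raise ValueError("Feller condition 2*theta*mu >= sigma2 violated")

    @property
    def stationary_shape(self) -> float:
        return 2 * self.theta * self.mu / self.sigma2

    @property
    def stationary_rate(self) -> float:
        return 2 * self.theta / self.sigma2


def stationary_moments(params: CIRParams) -> tuple:
    """(mean, variance) of the stationary Gamma law."""
    return params.mu, params.sigma2 * params.mu / (2 * params.theta)


def stationary_logdensity(r, params: CIRParams):
    """Log stationary density (Gamma); -inf for r <= 0. Vectorized."""
    r = np.asarray(r, dtype=float)
    a, b = params.stationary_shape, params.stationary_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = a * math.log(b) - gammaln(a) + (a - 1) * np.log(r) - b * r
    lp = np.where(r > 0, lp, -np.inf)
    return lp if lp.ndim else float(lp)


def sample_stationary(params: CIRParams, rng: np.random.Generator, size=None):
    return rng.gamma(params.stationary_shape, 1.0 / params.stationary_rate, size=size)


def _cuq(dt: float, params: CIRParams) -> tuple:
    e = math.exp(-params.theta * dt)
    c = 2 * params.theta / (params.sigma2 * (1.0 - e))
    q = params.stationary_shape - 1.0
    return c, e, q


def transition_mean_var(r_parent, dt, params: CIRParams) -> tuple:
    """Closed-form conditional mean and variance after time dt."""
    th, s2, mu = params.theta, params.sigma2, params.mu
    e = np.exp(-th * np.asarray(dt, float))
    mean = mu + (np.asarray(r_parent, float) - mu) * e
    var = (np.asarray(r_parent, float) * s2 * (e - e**2) / th
           + mu * s2 * (1.0 - e) ** 2 / (2 * th))
    return mean, var


def transition_logdensity(r_child, r_parent, dt, params: CIRParams):
    """Log transition density p(r_child | r_parent, dt). Vectorized.

    Assembled in log space from the noncentral chi-square form:
    ``log c - u - v + (q/2) log(v/u) + log I_q(2 sqrt(uv))`` with the
    exponentially scaled Bessel ``ive``; a series branch covers u*v
    underflow and the dt -> inf (ergodic) limit falls back to the
    stationary density.
    """
    rc = np.asarray(r_child, dtype=float)
    rp = np.asarray(r_parent, dtype=float)
    dt_arr = np.asarray(dt, dtype=float)
    if np.any(dt_arr <= 0):
        raise ValueError("dt must be > 0")
    rc, rp, dt_b = np.broadcast_arrays(rc, rp, dt_arr)
    out = np.full(rc.shape, -np.inf)
    ok = rc > 0
    if np.any(ok):
        th, s2 = params.theta, params.sigma2
        e = np.exp(-th * dt_b[ok])
        c = 2 * th / (s2 * (1.0 - e))
        q = params.stationary_shape - 1.0
        u = c * rp[ok] * e
        v = c * rc[ok]
        z = 2.0 * np.sqrt(u * v)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            # main branch: scaled Bessel
            log_bessel = np.log(ive(q, z)) + z
            lp = np.log(c) - u - v + 0.5 * q * np.log(v / u) + log_bessel
            # series branch for tiny z: I_q(z) ~ (z/2)^q / Gamma(q+1);
            # combined with (q/2)log(v/u) this is exactly the stationary
            # Gamma at u -> 0
            lp_small = ((q + 1) * np.log(c) + q * np.log(rc[ok])
                        - u - v - gammaln(q + 1.0))
        small = (z < 1e-8) | ~np.isfinite(log_bessel)
        lp = np.where(small, lp_small, lp)
        out[ok] = lp
    return out if out.ndim else float(out)


def simulate_transition(r_parent, dt, params: CIRParams,
                        rng: np.random.Generator, size=None):
    """Exact draw of r(t+dt) | r(t) via the noncentral chi-square law."""
    if np.any(np.asarray(dt) <= 0):
        raise ValueError("dt must be > 0")
    c, e, q = _cuq(float(dt), params)
    df = 2.0 * (q + 1.0)
    nc = 2.0 * c * np.asarray(r_parent, float) * e
    y = rng.noncentral_chisquare(df, nc, size=size)
    return y / (2.0 * c)
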