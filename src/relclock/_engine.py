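"""numba-compiled MCMC core for the CIR dating sampler.

This is a faithful port of the move set in :mod:`relclock.mcmc` for the
Poisson branch-count likelihood (and the likelihood-free prior-only mode):
node-age slides, likelihood-preserving compensatory and subtree-scale
moves, edge rate-shifts, global stretch moves, single-rate multipliers,
hyperparameter random walks, and (absolute mode) root scale/independence
rescales and the rate-time trade-off move.  The Python-level class in
``mcmc.py`` remains the reference implementation and serves the alignment
likelihood; tests compare the two engines distributionally.

Layout: per-node arrays indexed by preorder id; ``child1/child2`` are -1
at tips; calibration arrays carry kind 0 (none), 1 (min), 2 (max),
3 (min_max); the root density kind is 0 (fixed), 1 (exponential(mean)),
2 (gamma(shape, scale)).
"""

from __future__ import annotations

import math

import numba
import numpy as np

from ._bessel import log_iv

ROOT = 0


@numba.njit(cache=True)
def _edge_lp(rc, rp, dt, th, s2, q, lgq):
    if rc <= 0.0 or rp <= 0.0 or dt <= 0.0:
        return -math.inf
    e = math.exp(-th * dt)
    c = 2.0 * th / (s2 * (1.0 - e))
    u = c * rp * e
    v = c * rc
    z = 2.0 * math.sqrt(u * v)
    if u < 1e-300 or z < 1e-8:
        return (q + 1.0) * math.log(c) + q * math.log(rc) - u - v - lgq
    return (math.log(c) - u - v + 0.5 * q * math.log(v / u)
            + log_iv(q, z))


@numba.njit(cache=True)
def _stat_lp(r, th, s2, mu):
    if r <= 0.0:
        return -math.inf
    a = 2.0 * th * mu / s2
    b = 2.0 * th / s2
    return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(r) - b * r


@numba.njit(cache=True)
def _cal_lf(age, kind, tmin, tmax, tail):
    if kind == 0:
        return 0.0
    lp = 0.0
    half = kind == 3
    if (kind == 1 or kind == 3) and age < tmin:
        mass = tail * 0.5 if half else tail
        if mass == 0.0:
            return -math.inf
        lp += math.log(mass) + (age - tmin) / (0.1 * tmin)
    if (kind == 2 or kind == 3) and age > tmax:
        mass = tail * 0.5 if half else tail
        if mass == 0.0:
            return -math.inf
        lp += math.log(mass) + (tmax - age) / (0.1 * tmax)
    return lp


@numba.njit(cache=True)
def _root_logpdf(t, kind, a, b):
    if kind == 0:
        return 0.0
    if t <= 0.0:
        return -math.inf
    if kind == 1:      # exponential with mean a
        return -math.log(a) - t / a
    # gamma with shape a, scale b
    return ((a - 1.0) * math.log(t) - t / b - a * math.log(b)
            - math.lgamma(a))


@numba.njit(cache=True)
def _root_rvs(kind, a, b):
    if kind == 1:
        return np.random.exponential(a)
    return np.random.gamma(a, b)


@numba.njit(cache=True)
def _lik_term(k, lgk, lam):
    if lam < 1e-300:
        lam = 1e-300
    return k * math.log(lam) - lam - lgk


@numba.njit(cache=True)
def run_chain(parent, child1, child2, internal,
              desc_flat, desc_start, desc_len,
              K, lgK, L, use_lik,
              cal_kind, cal_tmin, cal_tmax, cal_tail, cal_nodes,
              root_kind, root_a, root_b,
              mu, theta0, sigma20, hyp_th_mean, hyp_s2_mean, sample_hypers,
              ages_init, rates_init, n_samples, burn, seed,
              out_ages, out_rates, out_theta, out_sigma2, out_logpost):
    np.random.seed(seed)
    n = parent.shape[0]
    n_int = internal.shape[0] + 1           # internal nodes incl. root
    fixed_root = root_kind == 0
    ages = ages_init.copy()
    rates = rates_init.copy()
    theta = theta0
    sigma2 = sigma20
    q = 2.0 * theta * mu / sigma2 - 1.0
    lgq = math.lgamma(q + 1.0)

    cir_lp = np.zeros(n)
    lik = np.zeros(n)
    for v in range(1, n):
        dt = ages[parent[v]] - ages[v]
        cir_lp[v] = _edge_lp(rates[v], rates[parent[v]], dt, theta, sigma2,
                             q, lgq)
        if use_lik == 1:
            rbar = 0.5 * (rates[v] + rates[parent[v]])
            lik[v] = _lik_term(K[v], lgK[v], rbar * dt * L)
    stat = _stat_lp(rates[ROOT], theta, sigma2, mu)

    # proposal scales + acceptance counters (adapted during burn-in)
    rate_scale, hyper_scale, age_scale = 0.6, 0.5, 0.3
    comp_scale, shift_scale, stretch_scale, sub_scale = 0.2, 0.3, 0.1, 0.2
    acc = np.zeros((7, 2))   # rate, hyper, age, comp, shift, stretch, sub

    new_r = np.zeros(n)
    new_a = np.zeros(n)

    for it in range(n_samples):
        # ---------------- age slides -------------------------------------
        for ii in range(internal.shape[0]):
            v = internal[ii]
            lo = max(ages[child1[v]], ages[child2[v]])
            hi = ages[parent[v]]
            local = np.random.random() < 0.5
            if local:
                new = ages[v] + (hi - lo) * age_scale * (
                    np.random.random() - 0.5)
                acc[2, 1] += 1
                if not (lo < new < hi):
                    continue
            else:
                new = lo + (hi - lo) * np.random.random()
            old_age = ages[v]
            d_old = 0.0
            d_old += cir_lp[v] + cir_lp[child1[v]] + cir_lp[child2[v]]
            if use_lik == 1:
                d_old += lik[v] + lik[child1[v]] + lik[child2[v]]
            d_old += _cal_lf(old_age, cal_kind[v], cal_tmin[v], cal_tmax[v],
                             cal_tail[v])
            ages[v] = new
            c1 = _edge_lp(rates[v], rates[parent[v]], hi - new, theta,
                          sigma2, q, lgq)
            c2 = _edge_lp(rates[child1[v]], rates[v], new - ages[child1[v]],
                          theta, sigma2, q, lgq)
            c3 = _edge_lp(rates[child2[v]], rates[v], new - ages[child2[v]],
                          theta, sigma2, q, lgq)
            d_new = c1 + c2 + c3
            l1 = l2 = l3 = 0.0
            if use_lik == 1:
                l1 = _lik_term(K[v], lgK[v],
                               0.5 * (rates[v] + rates[parent[v]])
                               * (hi - new) * L)
                l2 = _lik_term(K[child1[v]], lgK[child1[v]],
                               0.5 * (rates[child1[v]] + rates[v])
                               * (new - ages[child1[v]]) * L)
                l3 = _lik_term(K[child2[v]], lgK[child2[v]],
                               0.5 * (rates[child2[v]] + rates[v])
                               * (new - ages[child2[v]]) * L)
                d_new += l1 + l2 + l3
            d_new += _cal_lf(new, cal_kind[v], cal_tmin[v], cal_tmax[v],
                             cal_tail[v])
            dlp = d_new - d_old
            ok = dlp >= 0.0 or math.log(np.random.random()) < dlp
            if local and ok:
                acc[2, 0] += 1
            if ok:
                cir_lp[v], cir_lp[child1[v]], cir_lp[child2[v]] = c1, c2, c3
                if use_lik == 1:
                    lik[v], lik[child1[v]], lik[child2[v]] = l1, l2, l3
            else:
                ages[v] = old_age

        if use_lik == 1:
            # ------------- compensatory + subtree-scale moves ------------
            for ii in range(internal.shape[0]):
                v = internal[ii]
                # compensatory: shift t_v, cascade exact rate compensation
                acc[3, 1] += 1
                lo = max(ages[child1[v]], ages[child2[v]])
                hi = ages[parent[v]]
                delta = (hi - lo) * comp_scale * (np.random.random() - 0.5)
                new = ages[v] + delta
                if lo < new < hi:
                    rp = rates[parent[v]]
                    d_a = hi - ages[v]
                    d_a2 = hi - new
                    ok_pos = True
                    rv_new = (rates[v] + rp) * d_a / d_a2 - rp
                    if rv_new <= 0.0:
                        ok_pos = False
                    logj = math.log(d_a / d_a2)
                    if ok_pos:
                        new_r[v] = rv_new
                        for cc in range(2):
                            c = child1[v] if cc == 0 else child2[v]
                            d_c = ages[v] - ages[c]
                            d_c2 = new - ages[c]
                            rc_new = ((rates[c] + rates[v]) * d_c / d_c2
                                      - rv_new)
                            if rc_new <= 0.0:
                                ok_pos = False
                                break
                            new_r[c] = rc_new
                            logj += math.log(d_c / d_c2)
                    if ok_pos:
                        s0 = desc_start[v]
                        for k in range(desc_len[v]):
                            w = desc_flat[s0 + k]
                            if w == child1[v] or w == child2[v]:
                                continue
                            pw = parent[w]
                            rw = rates[w] + (rates[pw] - new_r[pw])
                            if rw <= 0.0:
                                ok_pos = False
                                break
                            new_r[w] = rw
                    if ok_pos:
                        old_cir = cir_lp[v]
                        s0 = desc_start[v]
                        for k in range(desc_len[v]):
                            old_cir += cir_lp[desc_flat[s0 + k]]
                        old_age_v = ages[v]
                        ages[v] = new
                        new_cir_v = _edge_lp(new_r[v], rates[parent[v]],
                                             hi - new, theta, sigma2, q, lgq)
                        d_new_cir = new_cir_v
                        # pw is always v or inside the subtree, so new_r
                        # holds both endpoint rates; store edge terms in
                        # new_a for reuse on acceptance
                        for k in range(desc_len[v]):
                            w = desc_flat[s0 + k]
                            pw = parent[w]
                            dtw = ages[pw] - ages[w]
                            new_a[w] = _edge_lp(new_r[w], new_r[pw], dtw,
                                                theta, sigma2, q, lgq)
                            d_new_cir += new_a[w]
                        dlp = d_new_cir - old_cir + logj
                        if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                            acc[3, 0] += 1
                            rates[v] = new_r[v]
                            cir_lp[v] = new_cir_v
                            for k in range(desc_len[v]):
                                w = desc_flat[s0 + k]
                                rates[w] = new_r[w]
                                cir_lp[w] = new_a[w]
                        else:
                            ages[v] = old_age_v

                # subtree scale: ages * s, rates / s inside the subtree
                acc[6, 1] += 1
                s = math.exp(sub_scale * (np.random.random() - 0.5))
                hi = ages[parent[v]]
                if ages[v] * s < hi:
                    s0 = desc_start[v]
                    m = desc_len[v]
                    old_terms = cir_lp[v]
                    n_tips_sub = 0
                    for k in range(m):
                        w = desc_flat[s0 + k]
                        old_terms += cir_lp[w]
                        if child1[w] < 0:
                            n_tips_sub += 1
                    old_terms += _cal_lf(ages[v], cal_kind[v], cal_tmin[v],
                                         cal_tmax[v], cal_tail[v])
                    for k in range(m):
                        w = desc_flat[s0 + k]
                        old_terms += _cal_lf(ages[w], cal_kind[w],
                                             cal_tmin[w], cal_tmax[w],
                                             cal_tail[w])
                    old_terms += lik[v]
                    old_av = ages[v]
                    ages[v] *= s
                    rates[v] /= s
                    for k in range(m):
                        w = desc_flat[s0 + k]
                        ages[w] *= s
                        rates[w] /= s
                    new_cir_v = _edge_lp(rates[v], rates[parent[v]],
                                         hi - ages[v], theta, sigma2, q, lgq)
                    new_terms = new_cir_v
                    for k in range(m):
                        w = desc_flat[s0 + k]
                        pw = parent[w]
                        new_a[w] = _edge_lp(rates[w], rates[pw],
                                            ages[pw] - ages[w], theta,
                                            sigma2, q, lgq)
                        new_terms += new_a[w]
                    new_terms += _cal_lf(ages[v], cal_kind[v], cal_tmin[v],
                                         cal_tmax[v], cal_tail[v])
                    for k in range(m):
                        w = desc_flat[s0 + k]
                        new_terms += _cal_lf(ages[w], cal_kind[w],
                                             cal_tmin[w], cal_tmax[w],
                                             cal_tail[w])
                    lik_v = _lik_term(K[v], lgK[v],
                                      0.5 * (rates[v] + rates[parent[v]])
                                      * (hi - ages[v]) * L)
                    new_terms += lik_v
                    n_int_sub = 1 + m - n_tips_sub
                    logj = (n_int_sub - (1 + m)) * math.log(s)
                    dlp = new_terms - old_terms + logj
                    if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                        acc[6, 0] += 1
                        cir_lp[v] = new_cir_v
                        lik[v] = lik_v
                        for k in range(m):
                            w = desc_flat[s0 + k]
                            cir_lp[w] = new_a[w]
                    else:
                        ages[v] = old_av
                        rates[v] *= s
                        for k in range(m):
                            w = desc_flat[s0 + k]
                            ages[w] /= s
                            rates[w] *= s

            # ---------------- edge rate shifts ---------------------------
            for v in range(1, n):
                p = parent[v]
                acc[4, 1] += 1
                eps = shift_scale * (rates[v] + rates[p]) * (
                    np.random.random() - 0.5)
                nv = rates[v] + eps
                npp = rates[p] - eps
                if nv <= 0.0 or npp <= 0.0:
                    continue
                # affected edges: v, children(v), children(p), p
                d_old = cir_lp[v]
                if child1[v] >= 0:
                    d_old += cir_lp[child1[v]] + cir_lp[child2[v]]
                    d_old += lik[child1[v]] + lik[child2[v]]
                for cc in range(2):
                    c = child1[p] if cc == 0 else child2[p]
                    if c != v:
                        d_old += cir_lp[c] + lik[c]
                if p != ROOT:
                    d_old += cir_lp[p] + lik[p]
                else:
                    d_old += stat
                old_rv, old_rp = rates[v], rates[p]
                rates[v], rates[p] = nv, npp
                dt_v = ages[p] - ages[v]
                c_v = _edge_lp(nv, npp, dt_v, theta, sigma2, q, lgq)
                d_new = c_v
                cv1 = cv2 = 0.0
                lv1 = lv2 = 0.0
                if child1[v] >= 0:
                    dt1 = ages[v] - ages[child1[v]]
                    dt2 = ages[v] - ages[child2[v]]
                    cv1 = _edge_lp(rates[child1[v]], nv, dt1, theta, sigma2,
                                   q, lgq)
                    cv2 = _edge_lp(rates[child2[v]], nv, dt2, theta, sigma2,
                                   q, lgq)
                    lv1 = _lik_term(K[child1[v]], lgK[child1[v]],
                                    0.5 * (rates[child1[v]] + nv) * dt1 * L)
                    lv2 = _lik_term(K[child2[v]], lgK[child2[v]],
                                    0.5 * (rates[child2[v]] + nv) * dt2 * L)
                    d_new += cv1 + cv2 + lv1 + lv2
                cp1 = cp2 = lp1 = lp2 = 0.0
                sib = -1
                for cc in range(2):
                    c = child1[p] if cc == 0 else child2[p]
                    if c != v:
                        sib = c
                        dts = ages[p] - ages[c]
                        cp1 = _edge_lp(rates[c], npp, dts, theta, sigma2,
                                       q, lgq)
                        lp1 = _lik_term(K[c], lgK[c],
                                        0.5 * (rates[c] + npp) * dts * L)
                        d_new += cp1 + lp1
                c_p = l_p = 0.0
                new_stat = stat
                if p != ROOT:
                    dtp = ages[parent[p]] - ages[p]
                    c_p = _edge_lp(npp, rates[parent[p]], dtp, theta, sigma2,
                                   q, lgq)
                    l_p = _lik_term(K[p], lgK[p],
                                    0.5 * (npp + rates[parent[p]]) * dtp * L)
                    d_new += c_p + l_p
                else:
                    new_stat = _stat_lp(npp, theta, sigma2, mu)
                    d_new += new_stat
                dlp = d_new - d_old
                if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                    acc[4, 0] += 1
                    cir_lp[v] = c_v
                    if child1[v] >= 0:
                        cir_lp[child1[v]], cir_lp[child2[v]] = cv1, cv2
                        lik[child1[v]], lik[child2[v]] = lv1, lv2
                    if sib >= 0:
                        cir_lp[sib] = cp1
                        lik[sib] = lp1
                    if p != ROOT:
                        cir_lp[p] = c_p
                        lik[p] = l_p
                    else:
                        stat = new_stat
                else:
                    rates[v], rates[p] = old_rv, old_rp

            # ---------------- global stretch moves ------------------------
            for _rep in range(4):
                acc[5, 1] += 1
                gamma = math.exp(stretch_scale * (np.random.random() - 0.5))
                t_root = ages[ROOT]
                logj = 0.0
                ok = True
                for ii in range(internal.shape[0]):
                    v = internal[ii]
                    x = ages[v] / t_root
                    new_a[v] = t_root * x**gamma
                    logj += math.log(gamma) + (gamma - 1.0) * math.log(x)
                new_a[ROOT] = t_root
                for v in range(n):
                    if child1[v] < 0:
                        new_a[v] = 0.0
                for v in range(1, n):
                    d_oldv = ages[parent[v]] - ages[v]
                    d_newv = new_a[parent[v]] - new_a[v]
                    if d_newv <= 0.0:
                        ok = False
                        break
                    new_r[v] = rates[v] * d_oldv / d_newv
                    logj += math.log(d_oldv / d_newv)
                if ok:
                    new_r[ROOT] = rates[ROOT]
                    d_old_total = 0.0
                    d_new_total = 0.0
                    for v in range(1, n):
                        d_old_total += cir_lp[v] + lik[v]
                        d_old_total += _cal_lf(ages[v], cal_kind[v],
                                               cal_tmin[v], cal_tmax[v],
                                               cal_tail[v])
                        dtv = new_a[parent[v]] - new_a[v]
                        cn = _edge_lp(new_r[v], new_r[parent[v]], dtv,
                                      theta, sigma2, q, lgq)
                        ln = _lik_term(K[v], lgK[v],
                                       0.5 * (new_r[v] + new_r[parent[v]])
                                       * dtv * L)
                        d_new_total += cn + ln
                        d_new_total += _cal_lf(new_a[v], cal_kind[v],
                                               cal_tmin[v], cal_tmax[v],
                                               cal_tail[v])
                    dlp = d_new_total - d_old_total + logj
                    if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                        acc[5, 0] += 1
                        for v in range(n):
                            ages[v] = new_a[v]
                            rates[v] = new_r[v]
                        for v in range(1, n):
                            dtv = ages[parent[v]] - ages[v]
                            cir_lp[v] = _edge_lp(rates[v], rates[parent[v]],
                                                 dtv, theta, sigma2, q, lgq)
                            lik[v] = _lik_term(
                                K[v], lgK[v],
                                0.5 * (rates[v] + rates[parent[v]])
                                * dtv * L)

        # ---------------- absolute-mode root moves ------------------------
        if not fixed_root:
            for mode_i in range(3):
                # 0: scale-all RW; 1: independence rescale; 2: trade-off
                if mode_i == 0:
                    s = math.exp(0.2 * (np.random.random() - 0.5))
                    hast = n_int * math.log(s)
                    indep = False
                    trade = False
                elif mode_i == 1:
                    t_new = _root_rvs(root_kind, root_a, root_b)
                    if t_new <= 0.0:
                        continue
                    s = t_new / ages[ROOT]
                    hast = (n_int - 1) * math.log(s)
                    indep = True
                    trade = False
                else:
                    s = math.exp(0.2 * (np.random.random() - 0.5))
                    hast = (n_int - n) * math.log(s)
                    indep = False
                    trade = True
                old_lp = _root_logpdf(ages[ROOT], root_kind, root_a, root_b)
                old_lp += -(n_int - 1) * math.log(ages[ROOT])
                for v in range(n):
                    old_lp += _cal_lf(ages[v], cal_kind[v], cal_tmin[v],
                                      cal_tmax[v], cal_tail[v])
                if indep:
                    old_lp -= _root_logpdf(ages[ROOT], root_kind, root_a,
                                           root_b)
                d_old = old_lp + stat
                for v in range(1, n):
                    d_old += cir_lp[v]
                    if use_lik == 1 and not trade:
                        d_old += lik[v]
                # propose: scale internal ages (tips stay at 0)
                for v in range(n):
                    new_a[v] = 0.0 if child1[v] < 0 else ages[v] * s
                if trade:
                    for v in range(n):
                        new_r[v] = rates[v] / s
                else:
                    for v in range(n):
                        new_r[v] = rates[v]
                new_lp = _root_logpdf(new_a[ROOT], root_kind, root_a, root_b)
                new_lp += -(n_int - 1) * math.log(new_a[ROOT])
                for v in range(n):
                    new_lp += _cal_lf(new_a[v], cal_kind[v], cal_tmin[v],
                                      cal_tmax[v], cal_tail[v])
                if indep:
                    new_lp -= _root_logpdf(new_a[ROOT], root_kind, root_a,
                                           root_b)
                new_stat2 = _stat_lp(new_r[ROOT], theta, sigma2, mu)
                d_new = new_lp + new_stat2
                for v in range(1, n):
                    dtv = new_a[parent[v]] - new_a[v]
                    new_a_cir = _edge_lp(new_r[v], new_r[parent[v]], dtv,
                                         theta, sigma2, q, lgq)
                    d_new += new_a_cir
                    if use_lik == 1 and not trade:
                        d_new += _lik_term(
                            K[v], lgK[v],
                            0.5 * (new_r[v] + new_r[parent[v]]) * dtv * L)
                dlp = d_new - d_old + hast
                if math.isfinite(dlp) and (
                        dlp >= 0.0 or math.log(np.random.random()) < dlp):
                    for v in range(n):
                        ages[v] = new_a[v]
                        rates[v] = new_r[v]
                    stat = new_stat2
                    for v in range(1, n):
                        dtv = ages[parent[v]] - ages[v]
                        cir_lp[v] = _edge_lp(rates[v], rates[parent[v]], dtv,
                                             theta, sigma2, q, lgq)
                        if use_lik == 1:
                            lik[v] = _lik_term(
                                K[v], lgK[v],
                                0.5 * (rates[v] + rates[parent[v]])
                                * dtv * L)

        # ---------------- single-rate multipliers -------------------------
        for v in range(n):
            acc[0, 1] += 1
            s = math.exp(rate_scale * (np.random.random() - 0.5))
            new = rates[v] * s
            d_old = 0.0
            d_new = 0.0
            if v != ROOT:
                d_old += cir_lp[v]
                if use_lik == 1:
                    d_old += lik[v]
            else:
                d_old += stat
            if child1[v] >= 0:
                d_old += cir_lp[child1[v]] + cir_lp[child2[v]]
                if use_lik == 1:
                    d_old += lik[child1[v]] + lik[child2[v]]
            old_rv = rates[v]
            rates[v] = new
            c_v = l_v = 0.0
            new_stat3 = stat
            if v != ROOT:
                dtv = ages[parent[v]] - ages[v]
                c_v = _edge_lp(new, rates[parent[v]], dtv, theta, sigma2,
                               q, lgq)
                d_new += c_v
                if use_lik == 1:
                    l_v = _lik_term(K[v], lgK[v],
                                    0.5 * (new + rates[parent[v]]) * dtv * L)
                    d_new += l_v
            else:
                new_stat3 = _stat_lp(new, theta, sigma2, mu)
                d_new += new_stat3
            cc1 = cc2 = ll1 = ll2 = 0.0
            if child1[v] >= 0:
                dt1 = ages[v] - ages[child1[v]]
                dt2 = ages[v] - ages[child2[v]]
                cc1 = _edge_lp(rates[child1[v]], new, dt1, theta, sigma2,
                               q, lgq)
                cc2 = _edge_lp(rates[child2[v]], new, dt2, theta, sigma2,
                               q, lgq)
                d_new += cc1 + cc2
                if use_lik == 1:
                    ll1 = _lik_term(K[child1[v]], lgK[child1[v]],
                                    0.5 * (rates[child1[v]] + new) * dt1 * L)
                    ll2 = _lik_term(K[child2[v]], lgK[child2[v]],
                                    0.5 * (rates[child2[v]] + new) * dt2 * L)
                    d_new += ll1 + ll2
            dlp = d_new - d_old + math.log(s)
            if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                acc[0, 0] += 1
                if v != ROOT:
                    cir_lp[v] = c_v
                    if use_lik == 1:
                        lik[v] = l_v
                else:
                    stat = new_stat3
                if child1[v] >= 0:
                    cir_lp[child1[v]], cir_lp[child2[v]] = cc1, cc2
                    if use_lik == 1:
                        lik[child1[v]], lik[child2[v]] = ll1, ll2
            else:
                rates[v] = old_rv

        # ---------------- hyperparameters ---------------------------------
        if sample_hypers == 1:
            for which in range(2):
                acc[1, 1] += 1
                s = math.exp(hyper_scale * (np.random.random() - 0.5))
                th_new = theta * s if which == 0 else theta
                s2_new = sigma2 * s if which == 1 else sigma2
                if 2.0 * th_new * mu < s2_new:
                    continue
                q_new = 2.0 * th_new * mu / s2_new - 1.0
                lgq_new = math.lgamma(q_new + 1.0)
                d_old = stat - theta / hyp_th_mean - sigma2 / hyp_s2_mean
                d_new = (_stat_lp(rates[ROOT], th_new, s2_new, mu)
                         - th_new / hyp_th_mean - s2_new / hyp_s2_mean)
                for v in range(1, n):
                    d_old += cir_lp[v]
                    dtv = ages[parent[v]] - ages[v]
                    new_a[v] = _edge_lp(rates[v], rates[parent[v]], dtv,
                                        th_new, s2_new, q_new, lgq_new)
                    d_new += new_a[v]
                dlp = d_new - d_old + math.log(s)
                if dlp >= 0.0 or math.log(np.random.random()) < dlp:
                    acc[1, 0] += 1
                    theta, sigma2, q, lgq = th_new, s2_new, q_new, lgq_new
                    for v in range(1, n):
                        cir_lp[v] = new_a[v]
                    stat = _stat_lp(rates[ROOT], theta, sigma2, mu)

        # ---------------- adaptation (burn-in only) ------------------------
        if it < burn and it % 25 == 24:
            for j in range(7):
                if acc[j, 1] >= 50:
                    r = acc[j, 0] / acc[j, 1]
                    f = math.exp(r - 0.3)
                    if j == 0:
                        rate_scale = min(max(rate_scale * f, 1e-4), 3.0)
                    elif j == 1:
                        hyper_scale = min(max(hyper_scale * f, 1e-4), 3.0)
                    elif j == 2:
                        age_scale = min(max(age_scale * f, 1e-4), 1.0)
                    elif j == 3:
                        comp_scale = min(max(comp_scale * f, 1e-4), 1.0)
                    elif j == 4:
                        shift_scale = min(max(shift_scale * f, 1e-4), 3.0)
                    elif j == 5:
                        stretch_scale = min(max(stretch_scale * f, 1e-4), 3.0)
                    else:
                        sub_scale = min(max(sub_scale * f, 1e-4), 3.0)
                    acc[j, 0] = 0.0
                    acc[j, 1] = 0.0

        # ---------------- refresh caches against float drift ---------------
        if it % 500 == 499:
            for v in range(1, n):
                dtv = ages[parent[v]] - ages[v]
                cir_lp[v] = _edge_lp(rates[v], rates[parent[v]], dtv, theta,
                                     sigma2, q, lgq)
                if use_lik == 1:
                    rbar = 0.5 * (rates[v] + rates[parent[v]])
                    lik[v] = _lik_term(K[v], lgK[v], rbar * dtv * L)
            stat = _stat_lp(rates[ROOT], theta, sigma2, mu)

        # ---------------- record -------------------------------------------
        lp_tot = (stat - theta / hyp_th_mean - sigma2 / hyp_s2_mean
                  + _root_logpdf(ages[ROOT], root_kind, root_a, root_b)
                  - (n_int - 1) * math.log(ages[ROOT]))
        for v in range(n):
            lp_tot += _cal_lf(ages[v], cal_kind[v], cal_tmin[v], cal_tmax[v],
                              cal_tail[v])
        for v in range(1, n):
            lp_tot += cir_lp[v]
            if use_lik == 1:
                lp_tot += lik[v]
        out_logpost[it] = lp_tot
        out_theta[it] = theta
        out_sigma2[it] = sigma2
        for v in range(n):
            out_ages[it, v] = ages[v]
            out_rates[it, v] = rates[v]

    return 0
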