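"""Numba kernel for the Metropolis-within-Gibbs MSOM sampler.

One call runs one chain.  Latent indicators (z, w) and Omega use their exact
full conditionals; species-level effects and community means/SDs use
adaptive Gaussian random-walk Metropolis, with SDs proposed on the log scale
and adaptation (Robbins-Monro on the log proposal scale, target acceptance
0.44) frozen at the end of burn-in.

Likelihood terms run over observed cells only, collapsed into per-site
binomial groups: replicate slots that share one detection-covariate row
(e.g. the five inflorescences of one visit) enter as a success count and a
trial count, which is exactly equivalent to the cell-wise Bernoulli product.
Species with no occupied site contribute no likelihood and are Gibbs-drawn
from the community prior.  Stable identities used throughout:
``log sigmoid(L) = L - softplus(L)`` and ``log(1 - sigmoid(L)) =
-softplus(L)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain"]

_TARGET_ACC = 0.44


@njit(cache=True, inline="always")
def _softplus(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _logistic_logpdf(x):
    # density of logit(U), U ~ Uniform(0, 1): standard logistic
    return -x - 2.0 * _softplus(-x)


@njit(cache=True, inline="always")
def _logcond_mu(m, ssum, ssq, n, sd, kind, coef_mean_var):
    # log p(mu | effects, sd): normal likelihood + hyperprior
    ll = -(ssq - 2.0 * m * ssum + n * m * m) / (2.0 * sd * sd)
    if kind == 0:
        return ll + _logistic_logpdf(m)
    return ll - m * m / (2.0 * coef_mean_var)


@njit(cache=True, inline="always")
def _logcond_logsd(t, ss, n, log_bound):
    # log p(log sd | effects, mu): Uniform(0, bound) prior + Jacobian
    if t >= log_bound:
        return -1.0e300
    return (1.0 - n) * t - ss / (2.0 * np.exp(2.0 * t))


@njit(cache=True)
def _slice_mu(m0, ssum, ssq, n, sd, kind, coef_mean_var):
    """Stepping-out/shrinkage slice update for a community mean."""
    logy = _logcond_mu(m0, ssum, ssq, n, sd, kind, coef_mean_var) + np.log(
        np.random.random()
    )
    w = 1.0
    left = m0 - w * np.random.random()
    right = left + w
    for _ in range(50):
        if _logcond_mu(left, ssum, ssq, n, sd, kind, coef_mean_var) <= logy:
            break
        left -= w
    for _ in range(50):
        if _logcond_mu(right, ssum, ssq, n, sd, kind, coef_mean_var) <= logy:
            break
        right += w
    for _ in range(100):
        x = left + np.random.random() * (right - left)
        if _logcond_mu(x, ssum, ssq, n, sd, kind, coef_mean_var) > logy:
            return x
        if x < m0:
            left = x
        else:
            right = x
    return m0


@njit(cache=True)
def _slice_logsd(sd0, ss, n, bound):
    """Slice update for a community SD, on the log scale."""
    log_bound = np.log(bound)
    t0 = np.log(sd0)
    logy = _logcond_logsd(t0, ss, n, log_bound) + np.log(np.random.random())
    w = 1.0
    left = t0 - w * np.random.random()
    right = left + w
    for _ in range(50):
        if _logcond_logsd(left, ss, n, log_bound) <= logy:
            break
        left -= w
    for _ in range(50):
        if _logcond_logsd(right, ss, n, log_bound) <= logy:
            break
        right += w
    for _ in range(100):
        t = left + np.random.random() * (right - left)
        if _logcond_logsd(t, ss, n, log_bound) > logy:
            return np.exp(t)
        if t < t0:
            left = t
        else:
            right = t
    return sd0


@njit(cache=True)
def run_chain(
    y,              # (M, G) int16  per-group detection counts
    ntrials,        # (G,) int16    replicate slots per group
    group_site,     # (G,) int64
    site_ptr,       # (J + 1,) int64  group ranges per site
    Xdet,           # (G, Td) f8
    Xocc,           # (J, To) f8
    det_kind,       # (Td,) int8   0 = intercept, 1 = coefficient
    occ_kind,       # (To,) int8
    det_bound,      # (Td,) f8     Uniform upper bound on community SD
    occ_bound,      # (To,) f8
    coef_mean_var,  # f8           variance of Normal hyperprior on coef means
    omega_a,        # f8
    omega_b,        # f8
    hyper_fixed,    # bool
    n_iter,         # int64
    n_burn,         # int64
    thin,           # int64
    seed,           # int64
    store_z,        # bool
    do_gof,         # bool
    w0, z0, Adet0, Aocc0, mu_det0, sd_det0, mu_occ0, sd_occ0, omega0,
):
    M, G = y.shape
    J = site_ptr.shape[0] - 1
    Td = Xdet.shape[1]
    To = Xocc.shape[1]
    R = (n_iter - n_burn) // thin

    np.random.seed(seed)

    w = w0.copy()
    z = z0.copy()
    Adet = Adet0.copy()
    Aocc = Aocc0.copy()
    mu_det = mu_det0.copy()
    sd_det = sd_det0.copy()
    mu_occ = mu_occ0.copy()
    sd_occ = sd_occ0.copy()
    omega = omega0

    Ldet = Adet @ Xdet.T
    Locc = Aocc @ Xocc.T

    det_any = np.zeros((M, J), dtype=np.bool_)
    for i in range(M):
        for g in range(G):
            if y[i, g] > 0:
                det_any[i, group_site[g]] = True

    # proposal scales (log-adapted during burn-in)
    s_Adet = np.full((M, Td), 0.5)
    s_Aocc = np.full((M, To), 0.5)
    s_mud = np.full(Td, 0.3)
    s_sdd = np.full(Td, 0.3)
    s_muo = np.full(To, 0.3)
    s_sdo = np.full(To, 0.3)

    # post-burn-in acceptance tallies
    acc_Adet = np.zeros((M, Td))
    acc_Aocc = np.zeros((M, To))
    att_Adet = np.zeros((M, Td))
    att_Aocc = np.zeros((M, To))
    acc_mud = np.zeros(Td)
    acc_sdd = np.zeros(Td)
    acc_muo = np.zeros(To)
    acc_sdo = np.zeros(To)

    # retained traces
    t_omega = np.zeros(R)
    t_mu_det = np.zeros((R, Td))
    t_sd_det = np.zeros((R, Td))
    t_mu_occ = np.zeros((R, To))
    t_sd_occ = np.zeros((R, To))
    t_Adet = np.zeros((R, M, Td))
    t_Aocc = np.zeros((R, M, To))
    t_w = np.zeros((R, M), dtype=np.int8)
    t_zrow = np.zeros((R, M), dtype=np.int32)
    t_zcol = np.zeros((R, J), dtype=np.int32)
    t_z = np.zeros((R if store_z else 0, M, J), dtype=np.int8)
    t_dobs = np.zeros(R if do_gof else 0)
    t_drep = np.zeros(R if do_gof else 0)
    site_dev = np.zeros(J)
    taxon_dev = np.zeros(M)

    for t in range(n_iter):
        adapting = t < n_burn
        gamma = 1.0 / (1.0 + t) ** 0.6 if adapting else 0.0

        # ---- (w, z) blocked Gibbs ---------------------------------------
        # Detected taxa have w = 1; their z follows its full conditional.
        # For undetected taxa, w is drawn with z integrated out (marginal
        # conditional), then z | w — avoiding the slow w <-> z tunnelling
        # of one-at-a-time updates for augmented taxa.
        lomega = np.log(omega) - np.log1p(-omega)
        for i in range(M):
            detected = False
            for j in range(J):
                if det_any[i, j]:
                    detected = True
                    break
            if detected:
                w[i] = 1
                for j in range(J):
                    if det_any[i, j]:
                        z[i, j] = 1
                    else:
                        lq = 0.0
                        for g in range(site_ptr[j], site_ptr[j + 1]):
                            lq -= ntrials[g] * _softplus(Ldet[i, g])
                        pz = _sigmoid(Locc[i, j] + lq)
                        z[i, j] = 1 if np.random.random() < pz else 0
            else:
                # log P(no detections at site j | w = 1)
                #   = log(1 - psi + psi * prod_k (1 - p))
                s = 0.0
                for j in range(J):
                    lq = 0.0
                    for g in range(site_ptr[j], site_ptr[j + 1]):
                        lq -= ntrials[g] * _softplus(Ldet[i, g])
                    s += np.log(
                        _sigmoid(-Locc[i, j])
                        + _sigmoid(Locc[i, j]) * np.exp(lq)
                    )
                w[i] = 1 if np.random.random() < _sigmoid(lomega + s) else 0
                if w[i] == 1:
                    for j in range(J):
                        lq = 0.0
                        for g in range(site_ptr[j], site_ptr[j + 1]):
                            lq -= ntrials[g] * _softplus(Ldet[i, g])
                        pz = _sigmoid(Locc[i, j] + lq)
                        z[i, j] = 1 if np.random.random() < pz else 0
                else:
                    for j in range(J):
                        z[i, j] = 0

        # ---- Omega | w (conjugate Beta) ---------------------------------
        sw = 0.0
        for i in range(M):
            sw += w[i]
        ga = np.random.gamma(omega_a + sw, 1.0)
        gb = np.random.gamma(omega_b + M - sw, 1.0)
        omega = ga / (ga + gb)
        if omega < 1e-12:
            omega = 1e-12
        elif omega > 1.0 - 1e-12:
            omega = 1.0 - 1e-12

        # ---- species occupancy effects ----------------------------------
        # w = 0 taxa contribute no occupancy likelihood: their conditional
        # is the community prior, drawn exactly (Gibbs).  Others use RWM.
        for col in range(To):
            mu = mu_occ[col]
            sd = sd_occ[col]
            for i in range(M):
                a = Aocc[i, col]
                if w[i] == 0:
                    an = mu + sd * np.random.standard_normal()
                    delta = an - a
                    Aocc[i, col] = an
                    for j in range(J):
                        Locc[i, j] += delta * Xocc[j, col]
                    continue
                delta = s_Aocc[i, col] * np.random.standard_normal()
                an = a + delta
                dll = ((a - mu) ** 2 - (an - mu) ** 2) / (2.0 * sd * sd)
                for j in range(J):
                    L = Locc[i, j]
                    Ln = L + delta * Xocc[j, col]
                    dll += z[i, j] * (Ln - L) - _softplus(Ln) + _softplus(L)
                accept = np.log(np.random.random()) < dll
                if accept:
                    Aocc[i, col] = an
                    for j in range(J):
                        Locc[i, j] += delta * Xocc[j, col]
                if adapting:
                    s_Aocc[i, col] *= np.exp(
                        gamma * ((1.0 if accept else 0.0) - _TARGET_ACC)
                    )
                else:
                    att_Aocc[i, col] += 1.0
                    if accept:
                        acc_Aocc[i, col] += 1.0

        # ---- species detection effects ----------------------------------
        # taxa occupying no site contribute no detection likelihood: exact
        # prior (Gibbs) draw; occupied taxa use RWM over their cells.
        for col in range(Td):
            mu = mu_det[col]
            sd = sd_det[col]
            for i in range(M):
                hasz = False
                for j in range(J):
                    if z[i, j] == 1:
                        hasz = True
                        break
                a = Adet[i, col]
                if not hasz:
                    an = mu + sd * np.random.standard_normal()
                    delta = an - a
                    Adet[i, col] = an
                    for g in range(G):
                        Ldet[i, g] += delta * Xdet[g, col]
                    continue
                delta = s_Adet[i, col] * np.random.standard_normal()
                an = a + delta
                dll = ((a - mu) ** 2 - (an - mu) ** 2) / (2.0 * sd * sd)
                for g in range(G):
                    if z[i, group_site[g]] == 1:
                        L = Ldet[i, g]
                        Ln = L + delta * Xdet[g, col]
                        dll += y[i, g] * (Ln - L) - ntrials[g] * (
                            _softplus(Ln) - _softplus(L)
                        )
                accept = np.log(np.random.random()) < dll
                if accept:
                    Adet[i, col] = an
                    for g in range(G):
                        Ldet[i, g] += delta * Xdet[g, col]
                if adapting:
                    s_Adet[i, col] *= np.exp(
                        gamma * ((1.0 if accept else 0.0) - _TARGET_ACC)
                    )
                else:
                    att_Adet[i, col] += 1.0
                    if accept:
                        acc_Adet[i, col] += 1.0

        # ---- community means / SDs (slice updates, tuning-free) ---------
        if not hyper_fixed:
            for col in range(To):
                ssum = 0.0
                ssq = 0.0
                for i in range(M):
                    a = Aocc[i, col]
                    ssum += a
                    ssq += a * a
                mu_occ[col] = _slice_mu(
                    mu_occ[col], ssum, ssq, float(M), sd_occ[col],
                    occ_kind[col], coef_mean_var,
                )
                ss = ssq - 2.0 * mu_occ[col] * ssum + M * mu_occ[col] ** 2
                sd_occ[col] = _slice_logsd(sd_occ[col], ss, float(M), occ_bound[col])

            for col in range(Td):
                ssum = 0.0
                ssq = 0.0
                for i in range(M):
                    a = Adet[i, col]
                    ssum += a
                    ssq += a * a
                mu_det[col] = _slice_mu(
                    mu_det[col], ssum, ssq, float(M), sd_det[col],
                    det_kind[col], coef_mean_var,
                )
                ss = ssq - 2.0 * mu_det[col] * ssum + M * mu_det[col] ** 2
                sd_det[col] = _slice_logsd(sd_det[col], ss, float(M), det_bound[col])

        # ---- record ------------------------------------------------------
        if t >= n_burn and (t - n_burn) % thin == thin - 1:
            m = (t - n_burn) // thin
            t_omega[m] = omega
            for col in range(Td):
                t_mu_det[m, col] = mu_det[col]
                t_sd_det[m, col] = sd_det[col]
            for col in range(To):
                t_mu_occ[m, col] = mu_occ[col]
                t_sd_occ[m, col] = sd_occ[col]
            for i in range(M):
                t_w[m, i] = w[i]
                for col in range(Td):
                    t_Adet[m, i, col] = Adet[i, col]
                for col in range(To):
                    t_Aocc[m, i, col] = Aocc[i, col]
                nrow = 0
                for j in range(J):
                    if z[i, j] == 1:
                        nrow += 1
                        t_zcol[m, j] += 1
                t_zrow[m, i] = nrow
            if store_z:
                for i in range(M):
                    for j in range(J):
                        t_z[m, i, j] = z[i, j]
            if do_gof:
                dobs = 0.0
                drep = 0.0
                for i in range(M):
                    for g in range(G):
                        if z[i, group_site[g]] == 1:
                            L = Ldet[i, g]
                            n_g = ntrials[g]
                            co = -2.0 * (y[i, g] * L - n_g * _softplus(L))
                            dobs += co
                            site_dev[group_site[g]] += co
                            taxon_dev[i] += co
                            kr = np.random.binomial(n_g, _sigmoid(L))
                            drep += -2.0 * (kr * L - n_g * _softplus(L))
                t_dobs[m] = dobs
                t_drep[m] = drep

    for i in range(M):
        for col in range(Td):
            if att_Adet[i, col] > 0:
                acc_Adet[i, col] /= att_Adet[i, col]
            else:
                acc_Adet[i, col] = np.nan
        for col in range(To):
            if att_Aocc[i, col] > 0:
                acc_Aocc[i, col] /= att_Aocc[i, col]
            else:
                acc_Aocc[i, col] = np.nan
    if do_gof and R > 0:
        site_dev /= R
        taxon_dev /= R

    return (
        t_omega, t_mu_det, t_sd_det, t_mu_occ, t_sd_occ,
        t_Adet, t_Aocc, t_w, t_zrow, t_zcol, t_z, t_dobs, t_drep,
        site_dev, taxon_dev,
        acc_Adet, acc_Aocc, acc_mud, acc_sdd, acc_muo, acc_sdo,
    )
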