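"""Exact posterior for tiny occupancy instances, by brute-force enumeration.

Independent validation oracle for the MCMC sampler: on instances with at
most 3 taxa, 4 sites and 3 replicate slots, enumerate every latent
configuration (w, z), sum exact Bernoulli likelihoods, and integrate the
continuous parameters (Omega and the per-species occupancy/detection
intercepts on the logit scale) over user-supplied quadrature grids.  The
model here is intercept-only on both sides — enough to exercise every
update family of the sampler — and each parameter may instead be fixed at a
scalar.

Nothing in this module shares code with the sampler kernel; probabilities
are plain products so the arithmetic stays transparently checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import inv_logit

__all__ = ["exact_posterior_tiny", "normal_grid", "beta_grid", "TinyPosterior"]

_MAX_TAXA, _MAX_SITES, _MAX_SLOTS, _MAX_GRID = 3, 4, 3, 801


def normal_grid(mean: float, sd: float, n: int = 201, half_width: float = 6.0):
    """Trapezoid quadrature grid for a Normal(mean, sd^2) prior."""
    x = np.linspace(mean - half_width * sd, mean + half_width * sd, n)
    w = np.exp(-0.5 * ((x - mean) / sd) ** 2)
    return x, w / w.sum()


def beta_grid(a: float, b: float, n: int = 401):
    """Midpoint quadrature grid on (0, 1) for a Beta(a, b) prior."""
    edges = np.linspace(0.0, 1.0, n + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    w = x ** (a - 1.0) * (1.0 - x) ** (b - 1.0)
    return x, w / w.sum()


def _as_grid(param) -> tuple[np.ndarray, np.ndarray]:
    if np.isscalar(param):
        return np.array([float(param)]), np.array([1.0])
    values, weights = param
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size > _MAX_GRID:
        raise ValueError(f"grid larger than {_MAX_GRID} points")
    return values, weights / weights.sum()


@dataclass(frozen=True)
class TinyPosterior:
    """Exact posterior summaries for a tiny instance."""

    omega_mean: float
    p_w: np.ndarray          # (M,) Pr(w_i = 1 | y)
    p_z: np.ndarray          # (M, J) Pr(z_ij = 1 | y)
    lpsi_mean: np.ndarray    # (M,) E[lpsi_i | y]
    lp_mean: np.ndarray      # (M,) E[lp_i | y]
    config_posterior: list   # per taxon: dict (w, z-config tuple) -> prob
    log_evidence: float


def exact_posterior_tiny(y, mask, *, omega, lpsi, lp) -> TinyPosterior:
    """Enumerate the exact posterior of a tiny intercept-only MSOM.

    Parameters
    ----------
    y
        (M, J, K) binary detections.
    mask
        (J, K) True where surveyed.
    omega, lpsi, lp
        Scalar (fixed value) or ``(values, weights)`` quadrature grid.
        ``omega`` is on the probability scale; ``lpsi``/``lp`` are logit-scale
        species intercept grids shared by all species (species are a priori
        exchangeable).
    """
    y = np.asarray(y)
    mask = np.asarray(mask, dtype=bool)
    M, J, K = y.shape
    if M > _MAX_TAXA or J > _MAX_SITES or K > _MAX_SLOTS:
        raise ValueError(
            f"instance {M}x{J}x{K} too large for exact enumeration "
            f"(max {_MAX_TAXA}x{_MAX_SITES}x{_MAX_SLOTS})"
        )
    og, ow = _as_grid(omega)
    lg, lw = _as_grid(lpsi)
    pg, pw = _as_grid(lp)
    psi_g = inv_logit(lg)
    p_g = inv_logit(pg)

    cfgs = np.array(
        [[(cfg >> j) & 1 for j in range(J)] for cfg in range(2**J)], dtype=float
    )  # (2^J, J)

    # per-taxon tables
    f1 = np.zeros(M)                 # marginal lik of y_i given w=1
    f0 = np.zeros(M)                 # given w=0 (y must be all zero)
    m1_cfg = np.zeros((M, 2**J))     # per z-config contribution to f1
    num_l = np.zeros(M)              # like f1 but with lpsi weight replaced by l * weight
    num_p = np.zeros(M)
    for i in range(M):
        # detection likelihood per site given z_j = 1, over the lp grid
        a1 = np.ones((pg.size, J))
        a0 = np.ones(J)
        for j in range(J):
            for k in range(K):
                if not mask[j, k]:
                    continue
                if y[i, j, k] == 1:
                    a1[:, j] *= p_g
                    a0[j] = 0.0
                else:
                    a1[:, j] *= 1.0 - p_g
        # site-product likelihood per z configuration: (Gp, 2^J)
        det = np.prod(
            cfgs[None, :, :] * a1[:, None, :] + (1 - cfgs[None, :, :]) * a0[None, None, :],
            axis=2,
        )
        det_w = pw @ det                      # (2^J,)
        det_wp = (pw * pg) @ det              # weighted by lp value
        # occupancy prior of each z configuration given w = 1: (Gl, 2^J)
        occ = np.prod(
            cfgs[None, :, :] * psi_g[:, None, None]
            + (1 - cfgs[None, :, :]) * (1 - psi_g[:, None, None]),
            axis=2,
        )
        occ_w = lw @ occ
        occ_wl = (lw * lg) @ occ
        m1_cfg[i] = occ_w * det_w
        f1[i] = m1_cfg[i].sum()
        f0[i] = float(a0.prod())
        num_l[i] = float((occ_wl * det_w).sum())
        num_p[i] = float((occ_w * det_wp).sum())

    # posterior over the Omega grid
    log_marg = np.zeros(og.size)
    m_io = np.empty((M, og.size))
    with np.errstate(divide="ignore"):
        for oi, o in enumerate(og):
            m_io[:, oi] = o * f1 + (1.0 - o) * f0
            log_marg[oi] = np.log(ow[oi]) + np.log(m_io[:, oi]).sum()
    if not np.isfinite(log_marg).any():
        raise ValueError("data impossible under every grid point")
    shift = log_marg.max()
    post_o = np.exp(log_marg - shift)
    evidence = post_o.sum()
    post_o /= evidence
    log_evidence = float(shift + np.log(evidence))

    prior_l_mean = float(lw @ lg)
    prior_p_mean = float(pw @ pg)

    p_w = np.zeros(M)
    p_z = np.zeros((M, J))
    lpsi_mean = np.zeros(M)
    lp_mean = np.zeros(M)
    config_post = [dict() for _ in range(M)]
    z1_mask = cfgs.astype(bool)  # (2^J, J)
    for i in range(M):
        for oi, o in enumerate(og):
            if post_o[oi] == 0.0:
                continue
            scale = post_o[oi] / m_io[i, oi]
            p_w[i] += scale * o * f1[i]
            p_z[i] += scale * o * (m1_cfg[i] @ z1_mask.astype(float))
            lpsi_mean[i] += scale * (
                o * num_l[i] + (1.0 - o) * f0[i] * prior_l_mean
            )
            lp_mean[i] += scale * (
                o * num_p[i] + (1.0 - o) * f0[i] * prior_p_mean
            )
        live = post_o > 0.0
        ratio = post_o[live] / m_io[i, live]
        for cfg in range(2**J):
            prob = float(np.sum(ratio * og[live]) * m1_cfg[i, cfg])
            if prob > 0.0:
                config_post[i][(1, tuple(int(b) for b in cfgs[cfg]))] = prob
        prob0 = float(np.sum(ratio * (1.0 - og[live])) * f0[i])
        if prob0 > 0.0:
            config_post[i][(0, (0,) * J)] = prob0

    omega_mean = float(post_o @ og)
    return TinyPosterior(
        omega_mean=omega_mean,
        p_w=p_w,
        p_z=p_z,
        lpsi_mean=lpsi_mean,
        lp_mean=lp_mean,
        config_posterior=config_post,
        log_evidence=log_evidence,
    )
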