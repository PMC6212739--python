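"""Compiled per-cycle marker sweeps for the Gibbs samplers.

All randomness is pre-drawn by the caller (one uniform / normal per marker and
branch), so draws are consumed positionally regardless of which branch runs:
chains are bit-reproducible and variants that disable a sub-update consume an
identical stream.

The residual vector r = y - X beta - Z g is maintained incrementally; the
engine refreshes it from scratch periodically to bound accumulation error.
"""

import numpy as np
from numba import njit

# products of |t| below this are treated as zero when propagating effects
# downstream; with |t| typically < 1 this truncates the O(m) tail quickly
DECAY_TOL = 1e-12


@njit(cache=True)
def _dot(a, b):
    s = 0.0
    for i in range(a.shape[0]):
        s += a[i] * b[i]
    return s


@njit(cache=True)
def cpi_sweep(Zt, zsq, r, effects, indicators, pi, slab_var, sigma_e2, u, eps):
    """One sweep of collapsed indicator + effect draws for the non-ante models.

    For each marker j the inclusion indicator is drawn with the effect
    integrated out:
      odds(in/out) = (1-pi)/pi * sqrt(se2 / (z'z s2 + se2))
                     * exp(rhs^2 s2 / (2 se2 (z'z s2 + se2)))
    with rhs = z_j' r_j and r_j the residual with marker j's contribution
    restored; a non-null effect is then drawn from its normal FCD.
    Returns (number of non-null markers, sum of squared non-null effects).
    """
    m, n = Zt.shape
    m1 = 0
    ssq = 0.0
    log_prior_odds = np.log(1.0 - pi) - np.log(pi)
    for j in range(m):
        zj = Zt[j]
        gj = effects[j]
        if gj != 0.0:
            for i in range(n):
                r[i] += zj[i] * gj
        rhs = _dot(zj, r)
        vt = zsq[j] * slab_var + sigma_e2
        log_odds = (
            log_prior_odds
            + 0.5 * (np.log(sigma_e2) - np.log(vt))
            + 0.5 * rhs * rhs * slab_var / (sigma_e2 * vt)
        )
        if log_odds > 0.0:
            p1 = 1.0 / (1.0 + np.exp(-log_odds))
        else:
            e = np.exp(log_odds)
            p1 = e / (1.0 + e)
        if u[j] < p1:
            mean = rhs * slab_var / vt
            sd = np.sqrt(sigma_e2 * slab_var / vt)
            gnew = mean + sd * eps[j]
            indicators[j] = 1
            effects[j] = gnew
            m1 += 1
            ssq += gnew * gnew
            for i in range(n):
                r[i] -= zj[i] * gnew
        else:
            indicators[j] = 0
            effects[j] = 0.0
    return m1, ssq


@njit(cache=True)
def _downstream_w(Zt, t, seg_id, j, w):
    """Fill w with Z L[:, j] (truncating once the t-product decays to zero)."""
    m, n = Zt.shape
    for i in range(n):
        w[i] = Zt[j, i]
    coef = 1.0
    k = j + 1
    while k < m and seg_id[k] == seg_id[j]:
        coef *= t[k - 1]
        if abs(coef) < DECAY_TOL:
            break
        for i in range(n):
            w[i] += coef * Zt[k, i]
        k += 1


@njit(cache=True)
def _propagate(g, t, seg_id, j, change):
    """Add `change` to g_j and its downstream images within the segment."""
    m = g.shape[0]
    g[j] += change
    coef = 1.0
    k = j + 1
    while k < m and seg_id[k] == seg_id[j]:
        coef *= t[k - 1]
        if abs(coef) < DECAY_TOL:
            break
        g[k] += coef * change
        k += 1


@njit(cache=True)
def ante_sweep(
    Zt,
    r,
    delta,
    g,
    t,
    indicators,
    seg_id,
    pi,
    slab_shared,
    locus_vars,
    method_kind,
    sigma_e2,
    u_t,
    sigma_t2,
    do_update_t,
    u_ind,
    eps_delta,
    eps_t,
    v_d,
    s_d2,
    u_prop,
    chi_prop,
    u_acc,
):
    """One sweep over markers for the antedependence samplers.

    method_kind: 0 = shared slab with indicator (ante-BayesCpi family),
                 1 = per-locus variance, no indicator (ante-BayesA),
                 2 = per-locus variance with fixed-pi indicator and
                     Metropolis inner cycles on (indicator, variance)
                     (ante-BayesB); proposals come from the prior, accepted
                     against the delta-integrated marginal likelihood.

    delta enters the model linearly with effective covariate w_j = Z L[:, j];
    the interval coefficient t_{j,j-1} is drawn right after delta_j from its
    normal FCD with covariate g_{j-1} * w_j.  Returns (m1, sum delta^2 over
    non-null loci).
    """
    m, n = Zt.shape
    w = np.empty(n)
    m1 = 0
    ssq = 0.0
    log_prior_odds = np.log(1.0 - pi) - np.log(pi)
    n_inner = u_prop.shape[1]
    for j in range(m):
        _downstream_w(Zt, t, seg_id, j, w)
        ww = _dot(w, w)
        dj = delta[j]
        if dj != 0.0:
            for i in range(n):
                r[i] += w[i] * dj
        rhs = _dot(w, r)

        include = True
        if method_kind == 0:
            s2j = slab_shared
            vt = ww * s2j + sigma_e2
            log_odds = (
                log_prior_odds
                + 0.5 * (np.log(sigma_e2) - np.log(vt))
                + 0.5 * rhs * rhs * s2j / (sigma_e2 * vt)
            )
            if log_odds > 0.0:
                p1 = 1.0 / (1.0 + np.exp(-log_odds))
            else:
                e = np.exp(log_odds)
                p1 = e / (1.0 + e)
            include = u_ind[j] < p1
        elif method_kind == 1:
            s2j = locus_vars[j]
        else:
            # joint (indicator, variance) Metropolis move, prior proposals
            cur_s2 = locus_vars[j] if indicators[j] == 1 else 0.0
            vt = ww * cur_s2 + sigma_e2
            cur_ml = 0.5 * (np.log(sigma_e2) - np.log(vt)) + (
                0.5 * rhs * rhs * cur_s2 / (sigma_e2 * vt)
            )
            for c in range(n_inner):
                if u_prop[j, c] < 1.0 - pi:
                    prop_s2 = v_d * s_d2 / chi_prop[j, c]
                else:
                    prop_s2 = 0.0
                vtp = ww * prop_s2 + sigma_e2
                prop_ml = 0.5 * (np.log(sigma_e2) - np.log(vtp)) + (
                    0.5 * rhs * rhs * prop_s2 / (sigma_e2 * vtp)
                )
                if np.log(u_acc[j, c]) < prop_ml - cur_ml:
                    cur_s2 = prop_s2
                    cur_ml = prop_ml
            locus_vars[j] = cur_s2
            include = cur_s2 > 0.0
            s2j = cur_s2

        if include:
            vt = ww * s2j + sigma_e2
            mean = rhs * s2j / vt
            sd = np.sqrt(sigma_e2 * s2j / vt)
            dnew = mean + sd * eps_delta[j]
            indicators[j] = 1
            m1 += 1
            ssq += dnew * dnew
        else:
            indicators[j] = 0
            dnew = 0.0
        delta[j] = dnew
        if dnew != 0.0:
            for i in range(n):
                r[i] -= w[i] * dnew
        change = dnew - dj
        if change != 0.0:
            _propagate(g, t, seg_id, j, change)

        # interval coefficient t_{j,j-1}, drawn immediately after delta_j;
        # its covariate g_{j-1} * w_j reuses the already-computed w
        if do_update_t and j > 0 and seg_id[j] == seg_id[j - 1]:
            gprev = g[j - 1]
            told = t[j - 1]
            if gprev == 0.0:
                tnew = u_t + np.sqrt(sigma_t2) * eps_t[j]
            else:
                a2 = gprev * gprev * ww
                atr = gprev * rhs_after_t(w, r) + a2 * told
                prec = a2 / sigma_e2 + 1.0 / sigma_t2
                mean = (atr / sigma_e2 + u_t / sigma_t2) / prec
                tnew = mean + eps_t[j] / np.sqrt(prec)
            dt = tnew - told
            t[j - 1] = tnew
            if dt != 0.0 and gprev != 0.0:
                dg = dt * gprev
                for i in range(n):
                    r[i] -= w[i] * dg
                _propagate(g, t, seg_id, j, dg)
    return m1, ssq


@njit(cache=True)
def rhs_after_t(w, r):
    return _dot(w, r)
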