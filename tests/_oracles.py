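"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (grids, enumeration, dense matrices) and
shares no code path with the sampler kernels it checks.
"""

from itertools import product

import numpy as np


def inclusion_prob_quadrature(Z, y, pi, slab_var, sigma_e2, n_grid=601, width=12.0):
    """Posterior P(indicator_j = 1 | y) for the fixed-hyperparameter
    spike-and-slab model y = Z g + e, by enumerating indicator configurations
    and integrating each non-null effect on a trapezoid grid."""
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = Z.shape
    assert m <= 2, "oracle is for tiny problems only"
    L = width * np.sqrt(slab_var)
    grid = np.linspace(-L, L, n_grid)
    post = np.zeros(m)
    total = 0.0

    def loglik(mean):
        return -0.5 * np.sum((y[:, None] - mean) ** 2, axis=0) / sigma_e2

    for gamma in product((0, 1), repeat=m):
        k = sum(gamma)
        logw = k * np.log1p(-pi) + (m - k) * np.log(pi)
        if k == 0:
            ml = np.exp(-0.5 * np.sum(y**2) / sigma_e2)
        elif k == 1:
            j = gamma.index(1)
            mean = Z[:, [j]] * grid[None, :]
            dens = np.exp(loglik(mean) - 0.5 * grid**2 / slab_var)
            ml = np.trapezoid(dens, grid) / np.sqrt(2 * np.pi * slab_var)
        else:
            g1, g2 = np.meshgrid(grid, grid, indexing="ij")
            mean = (
                Z[:, 0][:, None, None] * g1[None] + Z[:, 1][:, None, None] * g2[None]
            )
            ll = -0.5 * np.sum((y[:, None, None] - mean) ** 2, axis=0) / sigma_e2
            dens = np.exp(ll - 0.5 * (g1**2 + g2**2) / slab_var)
            ml = np.trapezoid(np.trapezoid(dens, grid, axis=1), grid) / (
                2 * np.pi * slab_var
            )
        w = np.exp(logw) * ml
        total += w
        for j in range(m):
            if gamma[j]:
                post[j] += w
    return post / total


def t_fcd_quadrature(residual_restored, a, sigma_e2, u_t, sigma_t2, n_grid=4001, width=10.0):
    """Mean/variance of p(t | rest) ∝ N(r_restored; a t, se2 I) N(t; u_t, st2)
    by normalizing the product density on a grid.  ``residual_restored`` has
    the t contribution added back; ``a`` is the effective covariate."""
    sd = np.sqrt(sigma_t2)
    grid = np.linspace(u_t - width * sd, u_t + width * sd, n_grid)
    r = np.asarray(residual_restored, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    ll = -0.5 * np.sum((r[:, None] - a[:, None] * grid[None, :]) ** 2, axis=0) / sigma_e2
    lp = ll - 0.5 * (grid - u_t) ** 2 / sigma_t2
    w = np.exp(lp - lp.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(grid * w, grid)
    var = np.trapezoid((grid - mean) ** 2 * w, grid)
    return mean, var


def expand_recursion_bruteforce(delta, t, starts):
    """Reference antedependence recursion written independently."""
    delta = np.asarray(delta, dtype=float)
    g = []
    for j in range(delta.size):
        if j in starts:
            g.append(delta[j])
        else:
            g.append(t[j - 1] * g[-1] + delta[j])
    return np.array(g)


def vg_target_grid(s_g2, variances, vmin=2.0, vmax=80.0, n_grid=20001):
    """Grid-normalized FCD of the slab degrees of freedom given variances."""
    from scipy.special import gammaln

    v = np.linspace(vmin + 1e-6, vmax, n_grid)
    logp = -2.0 * np.log(v + 1.0)
    for s2 in np.atleast_1d(variances):
        half = v / 2.0
        logp += half * np.log(half * s_g2) - gammaln(half) - (half + 1) * np.log(s2) - half * s_g2 / s2
    w = np.exp(logp - logp.max())
    norm = np.trapezoid(w, v)
    pdf = w / norm
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(v))])
    cdf /= cdf[-1]
    return v, pdf, cdf
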