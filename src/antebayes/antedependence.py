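"""First-order antedependence structure on SNP effects.

Within each chromosome the composite SNP effect follows the recursion
g_1 = delta_1 and g_j = t_{j,j-1} * g_{j-1} + delta_j, so effects of
physically adjacent markers are serially correlated with interval-specific
coefficients t.  Across chromosome boundaries t is pinned at zero.  In matrix
form g = L(t) * delta with L unit-lower-triangular whose (j,k) entry is the
product of the t's on the path from k to j.

This module holds the transform, the per-interval coefficient update, and the
conjugate updates of the coefficient hyperpriors (u_t, sigma_t2).  The MCMC
engine inlines the same algebra in its compiled sweep; these reference
implementations are the readable (and independently testable) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .priors import AnteHyperPrior, sample_scaled_inv_chisq

__all__ = [
    "AnteParams",
    "boundary_interval_mask",
    "expand_effects",
    "transform_matrix",
    "downstream_design",
    "t_full_conditional",
    "update_t",
    "update_t_hyperpriors",
]


@dataclass
class AnteParams:
    """Antedependence state: interval coefficients, residual effects, hyperpriors."""

    t: np.ndarray  # m-1 interval coefficients, 0 at chromosome boundaries
    delta: np.ndarray  # m residual SNP effects
    sigma_d2: float | np.ndarray = 1.0  # shared slab variance, or per-locus vector
    v_d: float = 4.2
    s_d2: float = 1.0
    u_t: float = 0.0
    sigma_t2: float = 0.1
    hyper: AnteHyperPrior = field(default_factory=AnteHyperPrior)


def boundary_interval_mask(m: int, boundaries) -> np.ndarray:
    """Boolean mask over the m-1 intervals; True where t is pinned at zero.

    Interval i joins markers i and i+1; it crosses a boundary iff marker i+1
    starts a new chromosome.
    """
    mask = np.zeros(m - 1, dtype=bool)
    for b in np.asarray(boundaries)[1:]:
        mask[b - 1] = True
    return mask


def _check_lengths(delta, t):
    delta = np.asarray(delta, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if t.size != delta.size - 1:
        raise ValueError(f"need {delta.size - 1} interval coefficients, got {t.size}")
    return delta, t


def expand_effects(delta, t, boundaries) -> np.ndarray:
    """Composite effects g from residual effects delta via the recursion."""
    delta, t = _check_lengths(delta, t)
    m = delta.size
    starts = set(int(b) for b in np.asarray(boundaries))
    g = np.empty(m)
    for j in range(m):
        if j in starts:
            g[j] = delta[j]
        else:
            g[j] = t[j - 1] * g[j - 1] + delta[j]
    return g


def transform_matrix(t, boundaries, m: Optional[int] = None) -> np.ndarray:
    """Dense unit-lower-triangular L with g = L @ delta.

    L[j, k] = prod_{i=k+1..j} t_{i,i-1} for k <= j within a chromosome
    segment, zero across segments.
    """
    t = np.asarray(t, dtype=np.float64)
    if m is None:
        m = t.size + 1
    starts = set(int(b) for b in np.asarray(boundaries))
    L = np.zeros((m, m))
    for k in range(m):
        L[k, k] = 1.0
        coef = 1.0
        for j in range(k + 1, m):
            if j in starts:
                break
            coef *= t[j - 1]
            L[j, k] = coef
    return L


def downstream_design(Z, t, boundaries, j: int) -> np.ndarray:
    """Effective covariate of delta_j: w_j = Z @ L[:, j] (n-vector).

    w_j accumulates marker column j plus every downstream column of the same
    chromosome weighted by the running product of t's.
    """
    Z = np.asarray(Z, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    m = Z.shape[1]
    starts = set(int(b) for b in np.asarray(boundaries))
    w = Z[:, j].copy()
    coef = 1.0
    for k in range(j + 1, m):
        if k in starts:
            break
        coef *= t[k - 1]
        w += coef * Z[:, k]
    return w


def t_full_conditional(
    i: int,
    residual: np.ndarray,
    w_next: np.ndarray,
    g_prev: float,
    t_cur: float,
    sigma_e2: float,
    u_t: float,
    sigma_t2: float,
):
    """Normal FCD (mean, variance) of interval coefficient t_i = t_{i+1,i}.

    The coefficient scales g_prev = g_i into marker i+1 and, through the
    recursion, into every downstream marker; its effective covariate is
    a = g_prev * w_next where w_next is the downstream design of marker i+1.
    ``residual`` is the current full residual (with t_i at t_cur).
    """
    if sigma_t2 <= 0:
        raise ValueError("sigma_t2 must be positive")
    a = g_prev * np.asarray(w_next, dtype=np.float64)
    ata = float(a @ a)
    # restore the t_i contribution: residual + a * t_cur
    atr = float(a @ residual) + ata * t_cur
    prec = ata / sigma_e2 + 1.0 / sigma_t2
    mean = (atr / sigma_e2 + u_t / sigma_t2) / prec
    return mean, 1.0 / prec


def update_t(
    i: int,
    residual: np.ndarray,
    w_next: np.ndarray,
    g_prev: float,
    t_cur: float,
    sigma_e2: float,
    u_t: float,
    sigma_t2: float,
    rng: np.random.Generator,
    boundary_mask: Optional[np.ndarray] = None,
) -> float:
    """Gibbs draw of one interval coefficient from its normal FCD."""
    if boundary_mask is not None and boundary_mask[i]:
        raise ValueError(f"interval {i} crosses a chromosome boundary; t is pinned at 0")
    mean, var = t_full_conditional(
        i, residual, w_next, g_prev, t_cur, sigma_e2, u_t, sigma_t2
    )
    return mean + np.sqrt(var) * rng.standard_normal()


def update_t_hyperpriors(
    t, boundaries, hyper: AnteHyperPrior, sigma_t2: float, rng: np.random.Generator
):
    """Conjugate draws of (u_t, sigma_t2) from the non-boundary coefficients.

    u_t | t ~ normal-normal update against N(u_t0, sigma_t02);
    sigma_t2 | t, u_t ~ chi^-2(v_t + q, (v_t s_t2 + sum (t - u_t)^2)/(v_t + q)).
    Boundary intervals (t pinned at 0) are excluded from both.
    """
    t = np.asarray(t, dtype=np.float64)
    mask = boundary_interval_mask(t.size + 1, boundaries)
    tt = t[~mask]
    q = tt.size
    if q == 0:
        raise ValueError("no free interval coefficients")
    prec = q / sigma_t2 + 1.0 / hyper.sigma_t02
    mean = (tt.sum() / sigma_t2 + hyper.u_t0 / hyper.sigma_t02) / prec
    u_t = mean + np.sqrt(1.0 / prec) * rng.standard_normal()
    df = hyper.v_t + q
    scale = (hyper.v_t * hyper.s_t2 + float(np.sum((tt - u_t) ** 2))) / df
    sigma_t2_new = sample_scaled_inv_chisq(df, scale, rng)
    return u_t, sigma_t2_new
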