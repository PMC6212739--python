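"""Prior elicitation and hyperparameter updates for the spike-and-slab samplers.

The slab variance of a non-null SNP effect follows a scaled inverse chi-square
distribution chi^-2(v_g, s_g^2) with density proportional to
x^-(v/2+1) * exp(-v s^2 / 2x); its mean is v s^2 / (v - 2) for v > 2.  The
scale s_g^2 is either elicited from a guess of the total additive variance
(splitting it over the expected number of non-null SNPs) or, in the "hyper"
variants, learned: s_g^2 gets a conjugate Gamma(alpha_s, beta_s) prior with a
Gibbs update, and v_g gets the heavy-tailed prior p(v) ∝ (v+1)^-2 with a
random-walk Metropolis-Hastings update on log(v - v_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MixturePrior",
    "HyperPriorConfig",
    "ResidualPrior",
    "AnteHyperPrior",
    "Priors",
    "scale_from_genetic_variance",
    "sample_scaled_inv_chisq",
    "scaled_inv_chisq_logpdf",
    "log_prior_vg",
    "sample_prior_vg",
    "mh_update_vg",
    "gibbs_update_s2",
]

DEFAULT_VG = 4.2  # slab degrees of freedom used throughout unless learned


@dataclass
class MixturePrior:
    """Spike-and-slab mixture prior state: pi, (v_g, s_g2) and the slab draw."""

    pi: float = 0.5
    v_g: float = DEFAULT_VG
    s_g2: float = 1.0
    sigma_g2: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.s_g2 <= 0:
            raise ValueError("s_g2 must be positive")
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be non-negative")


@dataclass
class HyperPriorConfig:
    """Hyperpriors for (v_g, s_g2) learning in the hyper variants.

    alpha_s, beta_s : shape and rate of the Gamma prior on s_g2 (both 1.0)
    vg_proposal_sd : sd of the random walk on log(v_g - vg_min)
    vg_min, vg_max : support of the (v+1)^-2 prior on v_g; vg_min > 2 keeps the
        slab prior mean finite, vg_max=None leaves the tail untruncated
    """

    alpha_s: float = 1.0
    beta_s: float = 1.0
    vg_proposal_sd: float = 0.3
    learn_vg: bool = True
    learn_s2: bool = True
    vg_min: float = 2.0
    vg_max: Optional[float] = None

    def __post_init__(self):
        if self.alpha_s <= 0 or self.beta_s <= 0:
            raise ValueError("Gamma hyperprior parameters must be positive")
        if self.vg_proposal_sd <= 0:
            raise ValueError("vg_proposal_sd must be positive")
        if self.vg_max is not None and self.vg_max <= self.vg_min:
            raise ValueError("vg_max must exceed vg_min")


@dataclass
class ResidualPrior:
    """Scaled-inv-chi-square prior on the residual variance.

    The default chi^-2(-1, 0) is the improper flat prior on sigma_e^2; any
    proper (nu_e > 0, s_e2 > 0) override is accepted.
    """

    nu_e: float = -1.0
    s_e2: float = 0.0


@dataclass
class AnteHyperPrior:
    """Fixed hyper-hyperparameters of the antedependence coefficients.

    t_{j,j-1} ~ N(u_t, sigma_t2) with u_t ~ N(u_t0, sigma_t02) and
    sigma_t2 ~ chi^-2(v_t, s_t2).  The source model leaves these four constants
    unspecified; the defaults are weakly informative around zero correlation.
    """

    u_t0: float = 0.0
    sigma_t02: float = 1.0
    v_t: float = 5.0
    s_t2: float = 0.1


@dataclass
class Priors:
    """Bundle of every prior constant a sampler needs."""

    mixture: MixturePrior = field(default_factory=MixturePrior)
    hyper: HyperPriorConfig = field(default_factory=HyperPriorConfig)
    residual: ResidualPrior = field(default_factory=ResidualPrior)
    ante: AnteHyperPrior = field(default_factory=AnteHyperPrior)
    genetic_variance: Optional[float] = None  # additive-variance guess for elicitation
    beta_prior_var: Optional[float] = None  # None = flat prior on fixed effects


# ---------------------------------------------------------------------------
# elicitation and densities
# ---------------------------------------------------------------------------

def scale_from_genetic_variance(
    sigma_a2_total: float, pi: float, freqs: np.ndarray, v_g: float = DEFAULT_VG
) -> float:
    """Elicit the slab scale s_g2 from a total additive-variance guess.

    The per-SNP slab variance share is
    sigma_g2_tilde = sigma_a2_total / ((1 - pi) * sum_k 2 p_k (1 - p_k)),
    and s_g2 = sigma_g2_tilde * (v_g - 2) / v_g so that the chi^-2(v_g, s_g2)
    prior mean equals sigma_g2_tilde.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must lie in [0, 1) for elicitation")
    if v_g <= 2.0:
        raise ValueError("v_g must exceed 2 for a finite slab prior mean")
    if sigma_a2_total <= 0:
        raise ValueError("additive variance guess must be positive")
    freqs = np.asarray(freqs, dtype=np.float64)
    het = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if het <= 0:
        raise ValueError("all markers monomorphic: cannot elicit s_g2")
    sigma_g2_tilde = sigma_a2_total / ((1.0 - pi) * het)
    return sigma_g2_tilde * (v_g - 2.0) / v_g


def sample_scaled_inv_chisq(v: float, s2: float, rng: np.random.Generator, size=None):
    """Draw from chi^-2(v, s2) via the identity draw = v*s2 / chisq_v."""
    if v <= 0:
        raise ValueError("degrees of freedom must be positive")
    if s2 < 0:
        raise ValueError("scale must be non-negative")
    return v * s2 / rng.chisquare(v, size=size)


def scaled_inv_chisq_logpdf(x, v: float, s2: float):
    """Log density of chi^-2(v, s2), normalized."""
    x = np.asarray(x, dtype=np.float64)
    half_v = v / 2.0
    return (
        half_v * np.log(half_v * s2)
        - math.lgamma(half_v)
        - (half_v + 1.0) * np.log(x)
        - half_v * s2 / x
    )


def log_prior_vg(v) -> float:
    """Log of the (v+1)^-2 prior on the slab degrees of freedom, up to a constant."""
    v = np.asarray(v, dtype=np.float64)
    if np.any(v <= 0):
        raise ValueError("v must be positive")
    out = -2.0 * np.log(v + 1.0)
    return float(out) if out.ndim == 0 else out


def sample_prior_vg(
    rng: np.random.Generator, vg_min: float = 2.0, vg_max: Optional[float] = None, size=None
):
    """Draw v_g from p(v) ∝ (v+1)^-2 on (vg_min, vg_max] by inverse CDF."""
    a = 1.0 / (vg_min + 1.0)
    b = 0.0 if vg_max is None else 1.0 / (vg_max + 1.0)
    u = rng.random(size)
    return 1.0 / (a - u * (a - b)) - 1.0


def _log_target_vg(v: float, s_g2: float, variances: np.ndarray) -> float:
    """Unnormalized log FCD of v_g given s_g2 and the current slab variance(s)."""
    return float(log_prior_vg(v) + np.sum(scaled_inv_chisq_logpdf(variances, v, s_g2)))


def mh_update_vg(
    v_g: float,
    s_g2: float,
    variances,
    cfg: HyperPriorConfig,
    rng: np.random.Generator,
):
    """One random-walk MH step for v_g on the log(v - vg_min) scale.

    Returns (new v_g, accepted flag).  The Jacobian of the log transform is
    included in the acceptance ratio; proposals outside (vg_min, vg_max] are
    rejected outright (zero prior mass).
    """
    variances = np.atleast_1d(np.asarray(variances, dtype=np.float64))
    if np.any(variances <= 0):
        raise ValueError("slab variances must be positive for the v_g update")
    lo = cfg.vg_min
    z = math.log(v_g - lo) + cfg.vg_proposal_sd * rng.standard_normal()
    v_prop = lo + math.exp(z)
    u = rng.random()  # always consumed: keeps the draw stream path-independent
    if cfg.vg_max is not None and v_prop > cfg.vg_max:
        return v_g, False
    log_ratio = (
        _log_target_vg(v_prop, s_g2, variances)
        - _log_target_vg(v_g, s_g2, variances)
        + math.log(v_prop - lo)
        - math.log(v_g - lo)
    )
    if math.log(u) < log_ratio:
        return v_prop, True
    return v_g, False


def gibbs_update_s2(
    v_g: float, variances, cfg: HyperPriorConfig, rng: np.random.Generator
) -> float:
    """Conjugate Gamma Gibbs draw for the slab scale s_g2.

    Each supplied variance contributes a chi^-2(v_g, s_g2) likelihood term
    (s_g2)^{v_g/2} exp(-v_g s_g2 / (2 sigma^2)), so with a Gamma(alpha_s,
    beta_s) prior the FCD is Gamma(alpha_s + q v_g/2,
    beta_s + (v_g/2) sum 1/sigma^2).  q = 0 recovers the prior.
    """
    variances = np.atleast_1d(np.asarray(variances, dtype=np.float64))
    if np.any(variances <= 0):
        raise ValueError("slab variances must be positive for the s_g2 update")
    q = variances.size
    shape = cfg.alpha_s + 0.5 * q * v_g
    rate = cfg.beta_s + 0.5 * v_g * float(np.sum(1.0 / variances)) if q else cfg.beta_s
    return rng.gamma(shape, 1.0 / rate)
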