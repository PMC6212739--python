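"""Getting-it-right (joint-distribution) validation of the Gibbs samplers.

Two simulators of the joint distribution p(parameters, data) must agree if the
sampler's full-conditional updates are correct:

* marginal-conditional: draw parameters from the prior, data from the model —
  i.i.d. draws whose parameter marginals are exactly the prior;
* successive-conditional: alternate one full Gibbs cycle (parameters | data)
  with a fresh draw of data | parameters — a Markov chain whose stationary
  parameter marginals are again the prior, *only if every update targets the
  right full conditional*.

Moments of selected parameters from the two simulators are compared by
z-score.  All priors must be proper here, so the harness expects a proper
scaled-inv-chi-square residual prior, a normal prior on fixed effects, and —
for the hyper variants — an upper-truncated (v+1)^-2 prior on v_g (the
untruncated prior has no finite moments).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .antedependence import boundary_interval_mask
from .data_model import GenotypeData, PhenotypeData, chromosome_boundaries
from .engine import MethodSpec, Sampler, SamplerOptions, batch_means_mcse
from .priors import Priors, sample_prior_vg

__all__ = ["forward_draws", "geweke_test"]


def forward_draws(
    geno: GenotypeData, method: MethodSpec, priors: Priors,
    n_draws: int, rng: np.random.Generator,
) -> dict:
    """I.i.d. parameter draws from the prior (marginal-conditional simulator)."""
    m = geno.n_markers
    mix, hp, ante = priors.mixture, priors.hyper, priors.ante
    if method.is_hyper:
        if hp.vg_max is None:
            raise ValueError("geweke validation needs a truncated v_g prior (vg_max)")
        v_g = sample_prior_vg(rng, hp.vg_min, hp.vg_max, n_draws)
        s_g2 = rng.gamma(hp.alpha_s, 1.0 / hp.beta_s, n_draws)
    else:
        v_g = np.full(n_draws, mix.v_g)
        s_g2 = np.full(n_draws, mix.s_g2)
    slab = v_g * s_g2 / rng.chisquare(v_g, n_draws)
    pi = rng.random(n_draws)
    ind = rng.random((n_draws, m)) < (1.0 - pi)[:, None]
    delta = rng.standard_normal((n_draws, m)) * np.sqrt(slab)[:, None] * ind
    out = {"pi": pi, "slab": slab}
    if method.is_ante:
        u_t = ante.u_t0 + np.sqrt(ante.sigma_t02) * rng.standard_normal(n_draws)
        sigma_t2 = ante.v_t * ante.s_t2 / rng.chisquare(ante.v_t, n_draws)
        t = u_t[:, None] + np.sqrt(sigma_t2)[:, None] * rng.standard_normal((n_draws, m - 1))
        bmask = boundary_interval_mask(m, chromosome_boundaries(geno))
        t[:, bmask] = 0.0
        starts = set(chromosome_boundaries(geno).tolist())
        g = np.empty_like(delta)
        for j in range(m):
            if j in starts:
                g[:, j] = delta[:, j]
            else:
                g[:, j] = t[:, j - 1] * g[:, j - 1] + delta[:, j]
        out["t0"] = t[:, int(np.flatnonzero(~bmask)[0])]
    else:
        g = delta
    out["effect"] = g[:, min(1, m - 1)]
    return out


def _successive_draws(
    geno: GenotypeData, method: MethodSpec, priors: Priors,
    n_cycles: int, burn: int, rng: np.random.Generator,
) -> dict:
    pheno = PhenotypeData(y=np.zeros(geno.n_animals))
    sampler = Sampler(
        geno, pheno, method,
        options=SamplerOptions(refresh_every=500),
        priors=priors,
    )
    if priors.beta_prior_var is None:
        raise ValueError("geweke validation needs a proper fixed-effect prior")
    if priors.residual.nu_e <= 0 or priors.residual.s_e2 <= 0:
        raise ValueError("geweke validation needs a proper residual prior")
    sampler.simulate_response(rng)
    m = geno.n_markers
    idx = min(1, m - 1)
    bmask = boundary_interval_mask(m, sampler.boundaries)
    t_idx = int(np.flatnonzero(~bmask)[0]) if method.is_ante else None
    keep = n_cycles - burn
    out = {"pi": np.empty(keep), "slab": np.empty(keep), "effect": np.empty(keep)}
    if method.is_ante:
        out["t0"] = np.empty(keep)
    for it in range(n_cycles):
        sampler.cycle(rng)
        if (it + 1) % 500 == 0:
            sampler.refresh_residual()
        sampler.simulate_response(rng)
        if it >= burn:
            k = it - burn
            st = sampler.state
            out["pi"][k] = st.pi
            out["slab"][k] = st.sigma_g2
            out["effect"][k] = st.effects[idx]
            if method.is_ante:
                out["t0"][k] = st.t[t_idx]
    return out


def geweke_test(
    geno: GenotypeData,
    method: MethodSpec,
    priors: Priors,
    n_forward: int = 200_000,
    n_cycles: int = 100_000,
    burn: int = 2_000,
    seed: int = 0,
    moments: int = 2,
) -> pd.DataFrame:
    """z-scores comparing prior moments between the two joint simulators.

    |z| values beyond ~4 indicate an incorrect full-conditional update.
    """
    rng_f = np.random.default_rng([seed, 1])
    rng_s = np.random.default_rng([seed, 2])
    fwd = forward_draws(geno, method, priors, n_forward, rng_f)
    suc = _successive_draws(geno, method, priors, n_cycles, burn, rng_s)
    rows = []
    for name in fwd:
        for p in range(1, moments + 1):
            xf = fwd[name] ** p
            xs = suc[name] ** p
            se_f = np.std(xf, ddof=1) / np.sqrt(xf.size)
            se_s = batch_means_mcse(xs)
            z = (np.mean(xf) - np.mean(xs)) / np.hypot(se_f, se_s)
            rows.append(
                {"parameter": name, "moment": p, "forward_mean": float(np.mean(xf)),
                 "chain_mean": float(np.mean(xs)), "z": float(z)}
            )
    return pd.DataFrame(rows)
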