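"""Gibbs/Metropolis samplers for the six whole-genome regression methods.

The data model is y = X beta + Z g + e with g the vector of SNP effects and
e ~ N(0, I sigma_e^2).  The six methods differ in the prior on g:

==================  =========================================================
bayesCpi            spike-and-slab on g with shared slab variance sigma_g^2
                    ~ chi^-2(v_g, s_g^2) and pi ~ U(0,1)
hyperBayesCpi       bayesCpi + learned hyperparameters: s_g^2 ~ Gamma(1,1)
                    (Gibbs) and v_g ~ (v+1)^-2 (random-walk MH)
anteBayesCpi        spike-and-slab on the antedependence residual effects
                    delta, g = L(t) delta, shared slab sigma_delta^2
anteHyperBayesCpi   anteBayesCpi + learned (v, s^2) for the delta slab
anteBayesA          antedependence with per-locus slab variances, no spike
anteBayesB          antedependence, per-locus variances, fixed pi, joint
                    (indicator, variance) Metropolis inner cycles per locus
==================  =========================================================

Every cycle follows a fixed schedule: fixed effects -> markers in physical
order (interval coefficients t drawn immediately after each delta in the ante
methods) -> pi -> variance structure -> hyperparameters -> residual variance.
A fixed seed yields a bit-identical chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .antedependence import expand_effects, update_t_hyperpriors
from .data_model import GenotypeData, PhenotypeData, allele_frequencies, chromosome_boundaries
from .priors import (
    Priors,
    sample_scaled_inv_chisq,
    scale_from_genetic_variance,
    mh_update_vg,
    gibbs_update_s2,
)

__all__ = [
    "METHODS",
    "MethodSpec",
    "ChainConfig",
    "SamplerOptions",
    "ChainState",
    "PosteriorChain",
    "Sampler",
    "run_chain",
    "posterior_summary",
    "batch_means_mcse",
]

METHODS = (
    "bayesCpi",
    "hyperBayesCpi",
    "anteBayesCpi",
    "anteHyperBayesCpi",
    "anteBayesA",
    "anteBayesB",
)

_ANTE = {"anteBayesCpi", "anteHyperBayesCpi", "anteBayesA", "anteBayesB"}
_HYPER = {"hyperBayesCpi", "anteHyperBayesCpi"}
_PER_LOCUS = {"anteBayesA", "anteBayesB"}


@dataclass
class MethodSpec:
    """Sampler selection.  fixed_pi is required by (and only by) anteBayesB."""

    method: str
    fixed_pi: Optional[float] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method == "anteBayesB":
            if self.fixed_pi is None:
                raise ValueError("anteBayesB requires fixed_pi")
            if not 0.0 <= self.fixed_pi < 1.0:
                raise ValueError("fixed_pi must lie in [0, 1)")
        elif self.fixed_pi is not None:
            raise ValueError(f"fixed_pi is only valid for anteBayesB, not {self.method}")

    @property
    def is_ante(self) -> bool:
        return self.method in _ANTE

    @property
    def is_hyper(self) -> bool:
        return self.method in _HYPER

    @property
    def per_locus_variance(self) -> bool:
        return self.method in _PER_LOCUS

    @property
    def has_indicator(self) -> bool:
        return self.method != "anteBayesA"


@dataclass
class ChainConfig:
    """MCMC protocol: 350,000 cycles, 50,000 burn-in, save every 10th draw."""

    n_iter: int = 350_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    bayesb_inner_mh: int = 100

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.bayesb_inner_mh < 1:
            raise ValueError("bayesb_inner_mh must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class SamplerOptions:
    """Knobs that restrict or instrument the sampler (validation, nesting)."""

    fixed_pi: Optional[float] = None  # pin pi for any method
    fix_sigma_g2: bool = False
    fix_sigma_e2: bool = False
    update_beta: bool = True
    freeze_t: bool = False  # pin all interval coefficients at their initial value
    beta_init: Optional[np.ndarray] = None
    pi_init: float = 0.5
    refresh_every: int = 1000


@dataclass
class ChainState:
    """Full parameter state of one Gibbs cycle."""

    beta: np.ndarray
    effects: np.ndarray  # composite g (equals delta for non-ante methods)
    indicators: np.ndarray
    pi: float
    sigma_g2: float  # shared slab variance (Cpi family)
    locus_vars: Optional[np.ndarray]  # per-locus variances (A/B family)
    v_g: float
    s_g2: float
    sigma_e2: float
    delta: Optional[np.ndarray] = None
    t: Optional[np.ndarray] = None
    u_t: float = 0.0
    sigma_t2: float = 0.1
    residual: np.ndarray = None


@dataclass
class PosteriorChain:
    """Thinned scalar traces plus running posterior means of the marker-level
    quantities (accumulated at saved cycles only, bounding memory at O(m))."""

    method: str
    config: ChainConfig
    marker_ids: np.ndarray
    traces: dict
    effect_mean: np.ndarray
    indicator_mean: np.ndarray
    delta_mean: Optional[np.ndarray] = None
    t_mean: Optional[np.ndarray] = None
    vg_accept_rate: Optional[float] = None
    n_saved: int = 0

    def effects_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "effect_mean": self.effect_mean,
                "inclusion_prob": self.indicator_mean,
            }
        )
        if self.delta_mean is not None:
            df["delta_mean"] = self.delta_mean
            df["t_mean"] = np.concatenate([[np.nan], self.t_mean])
        return df


class Sampler:
    """Stateful Gibbs sampler; ``cycle`` advances one full update schedule."""

    def __init__(
        self,
        geno: GenotypeData,
        pheno: PhenotypeData,
        method: MethodSpec,
        config: Optional[ChainConfig] = None,
        priors: Optional[Priors] = None,
        options: Optional[SamplerOptions] = None,
    ):
        self.geno = geno
        self.method = method
        self.config = config or ChainConfig()
        self.priors = priors or Priors()
        self.options = options or SamplerOptions()

        if pheno.n_animals != geno.n_animals:
            raise ValueError("genotypes and phenotypes disagree on animal count")
        self.y = pheno.y.copy()
        self.X = np.ascontiguousarray(pheno.fixed_design, dtype=np.float64)
        self.xtx = np.einsum("ij,ij->j", self.X, self.X)
        if np.any(self.xtx == 0):
            raise ValueError("fixed-effect design contains an all-zero column")
        self.Zt = np.ascontiguousarray(geno.markers.T, dtype=np.float64)
        self.zsq = np.einsum("ji,ji->j", self.Zt, self.Zt)
        self.n = geno.n_animals
        self.m = geno.n_markers
        boundaries = chromosome_boundaries(geno)
        seg = np.zeros(self.m, dtype=np.int64)
        for s in boundaries[1:]:
            seg[s:] += 1
        self.seg_id = seg
        self.boundaries = boundaries

        self._init_hyper()
        self._init_state()
        self.vg_proposed = 0
        self.vg_accepted = 0

    # -- initialization ---------------------------------------------------
    def _init_hyper(self):
        pr = self.priors
        self.learn_vg = self.method.is_hyper and pr.hyper.learn_vg
        self.learn_s2 = self.method.is_hyper and pr.hyper.learn_s2
        self.v_g = pr.mixture.v_g
        if pr.genetic_variance is not None:
            freqs = allele_frequencies(self.geno)
            self.s_g2 = scale_from_genetic_variance(
                pr.genetic_variance, self.options.pi_init, freqs, self.v_g
            )
        elif self.method.is_hyper:
            self.s_g2 = pr.hyper.alpha_s / pr.hyper.beta_s
        else:
            self.s_g2 = pr.mixture.s_g2

    def _init_state(self):
        opts = self.options
        pr = self.priors
        beta = np.zeros(self.X.shape[1])
        if opts.beta_init is not None:
            beta[:] = np.asarray(opts.beta_init, dtype=np.float64)
        else:
            beta[0] = float(np.mean(self.y))
        pi = self._effective_fixed_pi()
        if pi is None:
            pi = opts.pi_init
        slab0 = (
            self.v_g * self.s_g2 / (self.v_g - 2.0) if self.v_g > 2.0 else self.s_g2
        )
        vary = float(np.var(self.y))
        self.state = ChainState(
            beta=beta,
            effects=np.zeros(self.m),
            indicators=np.zeros(self.m, dtype=np.int64),
            pi=float(pi),
            sigma_g2=slab0,
            locus_vars=(np.full(self.m, slab0) if self.method.per_locus_variance else None),
            v_g=self.v_g,
            s_g2=self.s_g2,
            sigma_e2=max(0.5 * vary, 1e-8),
            delta=(np.zeros(self.m) if self.method.is_ante else None),
            t=(np.zeros(self.m - 1) if self.method.is_ante else None),
            u_t=pr.ante.u_t0,
            sigma_t2=pr.ante.v_t * pr.ante.s_t2 / (pr.ante.v_t - 2.0),
        )
        self.state.residual = self.y - self.X @ self.state.beta

    def _effective_fixed_pi(self) -> Optional[float]:
        if self.options.fixed_pi is not None:
            return self.options.fixed_pi
        return self.method.fixed_pi

    # -- updates ----------------------------------------------------------
    def _update_fixed_effects(self, rng: np.random.Generator):
        st = self.state
        tau2 = self.priors.beta_prior_var
        eps = rng.standard_normal(self.X.shape[1])
        for k in range(self.X.shape[1]):
            x = self.X[:, k]
            st.residual += x * st.beta[k]
            xtr = float(x @ st.residual)
            if tau2 is None:
                mean = xtr / self.xtx[k]
                var = st.sigma_e2 / self.xtx[k]
            else:
                prec = self.xtx[k] / st.sigma_e2 + 1.0 / tau2
                mean = (xtr / st.sigma_e2) / prec
                var = 1.0 / prec
            st.beta[k] = mean + np.sqrt(var) * eps[k]
            st.residual -= x * st.beta[k]

    def _sweep_markers(self, rng: np.random.Generator):
        st = self.state
        m = self.m
        method = self.method
        if not method.is_ante:
            u = rng.random(m)
            eps = rng.standard_normal(m)
            m1, ssq = _kernels.cpi_sweep(
                self.Zt, self.zsq, st.residual, st.effects, st.indicators,
                st.pi, st.sigma_g2, st.sigma_e2, u, eps,
            )
            return m1, ssq
        update_t = not self.options.freeze_t
        u_ind = rng.random(m)
        eps_delta = rng.standard_normal(m)
        eps_t = rng.standard_normal(m) if update_t else np.zeros(m)
        if method.method == "anteBayesB":
            k_inner = self.config.bayesb_inner_mh
            u_prop = rng.random((m, k_inner))
            chi_prop = rng.chisquare(self.v_g, (m, k_inner))
            u_acc = rng.random((m, k_inner))
            kind = 2
        else:
            u_prop = np.empty((m, 0))
            chi_prop = np.empty((m, 0))
            u_acc = np.empty((m, 0))
            kind = 1 if method.method == "anteBayesA" else 0
        m1, ssq = _kernels.ante_sweep(
            self.Zt, st.residual, st.delta, st.effects, st.t, st.indicators,
            self.seg_id, st.pi, st.sigma_g2, st.locus_vars
            if st.locus_vars is not None else np.empty(0),
            kind, st.sigma_e2, st.u_t, st.sigma_t2, update_t,
            u_ind, eps_delta, eps_t, st.v_g, st.s_g2, u_prop, chi_prop, u_acc,
        )
        return m1, ssq

    def _update_pi(self, m1: int, rng: np.random.Generator):
        st = self.state
        fixed = self._effective_fixed_pi()
        if fixed is not None:
            st.pi = fixed
            return
        if not self.method.has_indicator:
            return  # anteBayesA has no spike; pi plays no role
        st.pi = rng.beta(self.m - m1 + 1, m1 + 1)

    def _update_variances(self, m1: int, ssq: float, rng: np.random.Generator):
        st = self.state
        method = self.method
        if not method.per_locus_variance:
            if not self.options.fix_sigma_g2:
                df = st.v_g + m1
                scale = (st.v_g * st.s_g2 + ssq) / df
                st.sigma_g2 = sample_scaled_inv_chisq(df, scale, rng)
        elif method.method == "anteBayesA":
            # conjugate per-locus update chi^-2(v+1, (v s^2 + delta_j^2)/(v+1))
            chis = rng.chisquare(st.v_g + 1.0, self.m)
            st.locus_vars = (st.v_g * st.s_g2 + st.delta**2) / chis
        # anteBayesB updated its locus variances jointly during the sweep
        if method.is_ante and not self.options.freeze_t:
            st.u_t, st.sigma_t2 = update_t_hyperpriors(
                st.t, self.boundaries, self.priors.ante, st.sigma_t2, rng
            )

    def _update_hyperparameters(self, rng: np.random.Generator):
        st = self.state
        if not (self.learn_vg or self.learn_s2):
            return
        variances = np.array([st.sigma_g2])
        if self.learn_vg:
            st.v_g, accepted = mh_update_vg(
                st.v_g, st.s_g2, variances, self.priors.hyper, rng
            )
            self.vg_proposed += 1
            self.vg_accepted += int(accepted)
        if self.learn_s2:
            st.s_g2 = gibbs_update_s2(st.v_g, variances, self.priors.hyper, rng)

    def _update_residual_variance(self, rng: np.random.Generator):
        if self.options.fix_sigma_e2:
            return
        st = self.state
        sse = float(st.residual @ st.residual)
        if sse == 0.0:
            raise FloatingPointError("degenerate fit: residual sum of squares is 0")
        nu0 = self.priors.residual.nu_e
        df = self.n + nu0
        scale = (sse + nu0 * self.priors.residual.s_e2) / df
        st.sigma_e2 = sample_scaled_inv_chisq(df, scale, rng)

    # -- cycle / run ------------------------------------------------------
    def cycle(self, rng: np.random.Generator):
        if self.options.update_beta:
            self._update_fixed_effects(rng)
        m1, ssq = self._sweep_markers(rng)
        self._update_pi(m1, rng)
        self._update_variances(m1, ssq, rng)
        self._update_hyperparameters(rng)
        self._update_residual_variance(rng)
        return m1, ssq

    def genetic_values(self) -> np.ndarray:
        """Z g for the current state (recomputed, not cached)."""
        return self.state.effects @ self.Zt

    def refresh_residual(self) -> float:
        """Recompute g (ante) and the residual from scratch; return the drift."""
        st = self.state
        if self.method.is_ante:
            st.effects = expand_effects(st.delta, st.t, self.boundaries)
        fresh = self.y - self.X @ st.beta - st.effects @ self.Zt
        drift = float(np.max(np.abs(fresh - st.residual))) if self.n else 0.0
        st.residual = fresh
        return drift

    def set_response(self, y: np.ndarray):
        """Replace the response vector (validation harness use)."""
        self.y = np.asarray(y, dtype=np.float64).copy()
        st = self.state
        st.residual = self.y - self.X @ st.beta - st.effects @ self.Zt

    def simulate_response(self, rng: np.random.Generator) -> np.ndarray:
        """Draw y | current state (used by the getting-it-right harness)."""
        st = self.state
        mean = self.X @ st.beta + st.effects @ self.Zt
        y = mean + np.sqrt(st.sigma_e2) * rng.standard_normal(self.n)
        self.set_response(y)
        return y

    def _check_finite(self, cycle_idx: int):
        st = self.state
        ok = (
            np.isfinite(st.sigma_e2)
            and np.isfinite(st.sigma_g2)
            and np.isfinite(st.pi)
            and np.all(np.isfinite(st.effects))
            and np.all(np.isfinite(st.beta))
        )
        if not ok:
            raise FloatingPointError(f"non-finite sampler state at cycle {cycle_idx}")

    def run(self, rng: Optional[np.random.Generator] = None) -> PosteriorChain:
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        m = self.m
        n_saved = cfg.n_saved
        scalars = ["pi", "sigma_e2", "sigma_g2", "v_g", "s_g2", "genetic_variance"]
        if self.method.is_ante:
            scalars += ["u_t", "sigma_t2"]
        traces = {k: np.empty(n_saved) for k in scalars}
        effect_sum = np.zeros(m)
        ind_sum = np.zeros(m)
        delta_sum = np.zeros(m) if self.method.is_ante else None
        t_sum = np.zeros(m - 1) if self.method.is_ante else None
        saved = 0
        for it in range(1, cfg.n_iter + 1):
            self.cycle(rng)
            self._check_finite(it)
            if it % self.options.refresh_every == 0:
                self.refresh_residual()
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and saved < n_saved:
                st = self.state
                traces["pi"][saved] = st.pi
                traces["sigma_e2"][saved] = st.sigma_e2
                traces["sigma_g2"][saved] = (
                    st.sigma_g2 if st.locus_vars is None else float(np.mean(st.locus_vars))
                )
                traces["v_g"][saved] = st.v_g
                traces["s_g2"][saved] = st.s_g2
                traces["genetic_variance"][saved] = float(np.var(self.genetic_values()))
                if self.method.is_ante:
                    traces["u_t"][saved] = st.u_t
                    traces["sigma_t2"][saved] = st.sigma_t2
                    delta_sum += st.delta
                    t_sum += st.t
                effect_sum += st.effects
                ind_sum += st.indicators
                saved += 1
        denom = max(saved, 1)
        return PosteriorChain(
            method=self.method.method,
            config=cfg,
            marker_ids=self.geno.marker_ids,
            traces={k: v[:saved] for k, v in traces.items()},
            effect_mean=effect_sum / denom,
            indicator_mean=ind_sum / denom,
            delta_mean=None if delta_sum is None else delta_sum / denom,
            t_mean=None if t_sum is None else t_sum / denom,
            vg_accept_rate=(
                self.vg_accepted / self.vg_proposed if self.vg_proposed else None
            ),
            n_saved=saved,
        )


def run_chain(
    geno: GenotypeData,
    pheno: PhenotypeData,
    method: MethodSpec,
    config: Optional[ChainConfig] = None,
    priors: Optional[Priors] = None,
    options: Optional[SamplerOptions] = None,
) -> PosteriorChain:
    """Build a sampler and run the full chain (seeded from ``config.seed``)."""
    sampler = Sampler(geno, pheno, method, config, priors, options)
    return sampler.run()


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def batch_means_mcse(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the mean by non-overlapping batch means."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 4:
        return float("nan")
    nb = int(np.floor(np.sqrt(n)))
    size = n // nb
    means = x[: nb * size].reshape(nb, size).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(nb))


@dataclass
class PosteriorSummary:
    effects: pd.DataFrame
    scalars: pd.DataFrame


def posterior_summary(chain: PosteriorChain) -> PosteriorSummary:
    """Posterior means of marker effects/indicators and scalar traces +- MCSE."""
    if chain.n_saved == 0:
        raise ValueError("chain holds no saved cycles after burn-in")
    rows = []
    for name, trace in chain.traces.items():
        rows.append(
            {"parameter": name, "mean": float(np.mean(trace)),
             "mcse": batch_means_mcse(trace)}
        )
    return PosteriorSummary(effects=chain.effects_frame(), scalars=pd.DataFrame(rows))
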