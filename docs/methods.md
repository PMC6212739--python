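# Methods

## Model and samplers

All six methods share the linear model y = Xβ + Zg + e with e ~ N(0, I σ²_e)
and differ only in the prior on the SNP effects g. One Gibbs cycle always
follows the same schedule, which the model itself does not dictate but which
makes runs reproducible and matches common spike-and-slab implementations:

1. fixed effects β, coefficient by coefficient, flat prior by default
   (an optional N(0, τ²) prior exists for validation, see below);
2. all markers in physical order — for each marker: inclusion indicator with
   the effect integrated out (collapsed draw), then the effect from its
   normal full conditional; in the antedependence methods the interval
   coefficient t_{j,j−1} is drawn immediately after δ_j;
3. π from its Beta conjugate full conditional Beta(m − m₁ + 1, m₁ + 1),
   unless fixed (ante-BayesB);
4. the variance structure: shared slab σ²_g ~ χ⁻²(v_g + m₁,
   (v_g s²_g + Σ g²)/(v_g + m₁)) for the Cπ family, the conjugate per-locus
   update for ante-BayesA (ante-BayesB updates its locus variances jointly
   with the indicators inside step 2, since that move is necessarily
   per-locus), plus the (u_t, σ²_t) conjugate updates in ante methods;
5. hyperparameters in the hyper variants: random-walk MH for v_g on
   log(v_g − 2) (proposal sd 0.3, Jacobian included), then the conjugate
   Gamma Gibbs draw for s²_g;
6. residual variance from χ⁻²(n + ν_e, (SSE + ν_e s²_e)/(n + ν_e)); the
   default ν_e = −1, s²_e = 0 is the flat prior on σ²_e.

The collapsed indicator odds are computed in log space; any non-finite state
aborts the chain with its cycle index rather than continuing silently.

Scaled-inverse-chi-square convention: χ⁻²(v, s²) has density
∝ x^−(v/2+1) exp(−v s²/2x) and mean v s²/(v − 2) for v > 2.

### Antedependence bookkeeping

With g = L(t) δ (L unit-lower-triangular, entries the running products of t
within a chromosome segment), δ_j enters the likelihood linearly through the
effective covariate w_j = Z L[:,j]. The sweep computes w_j on the fly,
truncating the downstream accumulation once the running |t| product falls
below 1e−12; the residual cache and the composite g are updated
incrementally and refreshed from scratch every `refresh_every` cycles
(default 1000; relative drift is checked in tests to stay below 1e−8).
t for an excluded marker (δ_j = 0) is still defined and updated, since the
recursion can propagate signal through a null marker. DGVs for ante methods
use the posterior mean of the *transformed* draws g (accumulated per cycle),
not the transform of the posterior means, because g is nonlinear in (t, δ)
jointly.

## Tunable parameters, defaults, and why

| parameter | default | meaning / rationale |
|---|---|---|
| v_g | 4.2 | slab degrees of freedom (Bayesian-alphabet convention) |
| s²_g | elicited | σ̃²_g (v_g−2)/v_g with σ̃²_g = σ̃²_a/[(1−π₀) Σ 2p(1−p)] |
| π₀ (`pi_init`) | 0.5 | π used in the elicitation before π is estimated |
| α_s, β_s | 1, 1 | Gamma prior on s²_g in the hyper variants |
| v_g proposal sd | 0.3 | random walk on log(v_g − 2); keeps v_g > 2 so the slab mean exists |
| ν_e, s²_e | −1, 0 | flat prior on σ²_e |
| u_t0, σ²_t0, v_t, s²_t | 0, 1, 5, 0.1 | hyper-hyperpriors of the interval coefficients; weakly informative around zero correlation, all overridable |
| n_iter / burn-in / thin | 350000 / 50000 / 10 | standard long protocol; scale down for experiments |
| `bayesb_inner_mh` | 100 | inner MH cycles per locus per iteration in ante-BayesB (read as per-locus; configurable) |

The elicitation divides the additive-variance guess by the expected
heterozygosity of the expected (1−π₀)·m non-null markers — the standard
partition of additive variance; the alternative reading (multiplication)
would make the slab grow with panel size, which is not meaningful.
Hyper variants start s²_g from the elicitation when a variance guess is
supplied, else from the Gamma prior mean (= 1).

## Synthetic data

The generator reproduces the statistical structure the samplers are
sensitive to, not a population history. Haplotypes follow a first-order
copying process (allele copied from the left neighbour with probability ρ,
else redrawn at the marker's base frequency ~U(0.05, 0.95)); ρ is calibrated
against the realized mean adjacent-marker r² by a brute-force table
(`RHO_R2_TABLE`, measured at n = 2000, m = 1000, 5 seeds) so the three
benchmark LD levels 0.33 / 0.22 / 0.14 can be dialed in. Defaults: 500
reference + 500 candidate animals, 1000 SNPs on 5 chromosomes, 30 QTL with
MAF > 0.05 and i.i.d. standard-normal effects, heritability 0.5 with noise
sized from the *realized* genetic variance.

What it does **not** emulate: pedigree/family transmission (the half-sib
flag only labels ids), mutation–drift equilibrium, and long-range LD. In
particular, correlation decays geometrically with marker distance (≈ ρ^d),
so a panel thinned by 10 is essentially LD-free — faster decay than
coalescent-like data, where thinned panels retain r² ≈ 0.22/0.14. The
thinning experiments therefore reproduce the qualitative accuracy ordering
across marker densities, not the quantitative accuracies at the two thinned
levels; to study a given LD level directly, simulate with
`rho_for_adjacent_r2(target)` instead of thinning. Passing tests on this
generator show the samplers are correct and recover sparse additive
architectures under serial-correlation LD; they do not certify performance
on real livestock data.

## Validation strategy and numerical choices

* Collapsed-indicator correctness is checked against direct numerical
  integration of the two-component marginal likelihood on 4-animal toys.
* Every sampler in the Cπ family passes a getting-it-right (Geweke) joint
  test: the prior-only moments from a forward simulator match a
  successive-conditional chain (Gibbs cycle + data redraw) at |z| < 4.
  This requires fully proper priors, so the engine supports a normal prior
  on β, a proper residual χ⁻², and an upper truncation `vg_max` for the
  (v+1)⁻² prior on v_g, whose untruncated form has no finite mean. These
  knobs exist for validation and stay off by default.
* Nesting identities: ante variants with t frozen at 0 reproduce the plain
  sampler (identical draw streams by construction — randoms are pre-drawn
  per marker and consumed positionally); hyper variants with learning
  disabled reproduce the plain chains draw for draw; ante-BayesB at π = 0
  matches ante-BayesA in distribution.
* Reference/candidate splitting rounds the reference size to
  floor(fraction·n + 0.5); positions are 1-based and only their order
  matters; the `matrix` genotype dialect forbids missing values while the
  PLINK `.raw` dialect mean-imputes NA per SNP (rounded to 0/1/2) with a
  logged count.
* Bias is reported as the regression of DGV on truth, as that is how the
  evaluation is usually worded; posterior-mean shrinkage pushes this slope
  below 1 even for a well-calibrated model, while the conventional
  truth-on-DGV slope (available via `direction="truth_on_dgv"` or
  `--bias-direction`) sits near 1. Both are reported to be near-unity only
  for highly accurate predictors.

Problem sizes in the test suite and acceptance script (20,000-cycle chains
on 500-animal, 1000-marker replicates; 6,000-cycle chains for the ante
demonstrations) are scaled-down choices that keep full validation runs in
the minutes range while leaving all acceptance bands comfortably testable;
the library defaults remain the long protocol.

## Known limitations

* Plain (non-ante) BayesA/BayesB and GBLUP are out of scope, as are multi-
  trait models, VCF/BGEN input, genotype QC and pedigree handling.
* The antedependence sweep costs O(n · m · w̄) per cycle (w̄ = mean effective
  downstream window), noticeably slower than the O(n · m) plain sweep at
  high density — the same ordering reported for the original implementations.
* π in ante-BayesCπ counts markers with no *residual* effect, which is not
  the same quantity as BayesCπ's π; compare across methods with care.
* MCSEs use non-overlapping batch means; no further convergence diagnostics
  are built in.
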