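# Methods

`snailselect` estimates natural selection on land-snail shell colour from
monthly mark–recapture surveys with dead recovery, separating mortality from
mouse predation from mortality by other causes.  This note documents the
models, the numerical choices, and what the synthetic-data tests do and do
not show.

## Colour trait

Shell colour is the luminance `Y = 0.299 R + 0.587 G + 0.114 B` of pixels
sampled (uniformly, with replacement, under a mandatory seed) from a cropped
shell photograph, divided by the luminance `Y'` of a grey card photographed
in the same shot to cancel lighting differences.  The corrected ratio
`Y/Y'` is z-standardised (sample SD, denominator `n − 1`) over the dataset
being fitted — one site at a time — before entering any model; this is both
a numerical-stability device for the sampler and the convention that makes
selection gradients comparable across fits.  Image decoding, cropping and
white balance are out of scope: the API takes pixel arrays or per-individual
channel means.

Population comparisons use the two-sided Wilcoxon rank-sum test (exact for
group sizes ≤ 20, tie-corrected normal approximation with continuity
correction above) and a two-sided variance-ratio F test.

## Encounter histories

Each individual contributes one observation code per monthly occasion:
live juvenile (1), juvenile carcass other-cause (2), juvenile carcass
predated (3), the adult analogues (4–6), or not seen (7).  Carcass codes are
assigned to the occasion of recovery; the death itself is attributed to the
preceding inter-occasion interval.  Occasions map to calendar months so that
month effects are shared across survey years.  Multiple captures within one
survey window collapse to the first event.  Validation rejects stage
reversal (adult → juvenile) and any event after a dead recovery.

## The state-space model

Latent states are the 12 combinations of {juvenile, adult} × {alive, dead
other, dead predated} × {inside, outside the study site}, plus an internal
13th absorbing "long dead" state.  The 13th state exists so that a carcass
is recoverable only at the occasion immediately after death; it is
bookkeeping, and outputs use the 12-state vocabulary.

Within one interval, events compose in the order **predation → other-cause
survival → fidelity → stage transition**.  For an in-site juvenile with
predation probability `m_J`, survival `S_J`, fidelity `F` and transition
probability `ψ_t`, the transition row is:

* predated in site: `m_J`
* dead other cause in site: `(1 − m_J)(1 − S_J)`
* alive in site as adult: `(1 − m_J) S_J F ψ_t`, as juvenile with `1 − ψ_t`
* alive outside (emigrated): `(1 − m_J) S_J (1 − F)` split by `ψ_t`

This composition makes `S` survival *conditional on escaping predation*, the
quantity on which "selection excluding predation" is defined.  Emigration is
permanent (no return flow), outside-site and long-dead states are
unobservable, and newly dead in-site states emit their recovery code with
probability `r`, else 7.

Survival on the logit scale is, per stage,

* quadratic: `logit S_i,t = μ + β col_i + ½ γ col_i² + ε_i + B_t`
  (Lande–Arnold convention: `β` directional, `γ` < 0 stabilising, > 0
  disruptive selection), or
* P-spline: `logit S_i,t = μ + Σ_p β_p col_i^p + Σ_k b_k (col_i − κ_k)₊³ +
  ε_i + B_t` with cubic degree `P = 3`, `K = min(⌊I/4⌋, 35)` knots at the
  `k/(K+1)` empirical quantiles (linear-interpolation/type-7 quantiles;
  duplicated knots are an error), and shrinkage `b_k ~ N(0, σ_b²)`.

Heterogeneity is per individual and per stage: `ε_{i,s} ~ N(0, σ_s²)`.  The
published summaries report a separate heterogeneity variance per growth
stage, so the implementation carries independent juvenile and adult draws
rather than a single shared `ε_i`.  Month effects `B_t` (calendar-indexed,
1–12) are modelled as random, `B_t ~ N(0, σ_B²)`, which keeps them
identifiable against `μ`.  Predation rates (one per stage) are constant over
colour and month; fidelity is constant; transition rates have
`logit ψ_t ~ N(μ_ψ, σ_ψ²)`.  Recapture `p` and recovery `r` share month
intercepts structure (`a_t`, `g_t`), separate colour slopes (`d_p`, `d_r` —
the shared-slope variant is the special case `d_p = d_r`), and one shared
per-individual heterogeneity `ε_rp,i ~ N(0, σ_rp²)` entering both.

The likelihood conditions on first capture (state then known: alive, in
site, observed stage) and marginalises latent paths with the forward
algorithm.  A readable matrix-based implementation backs a numba-compiled
batch version that hand-codes the sparse transition structure; the two are
tested to agree to 1e−10, and the forward values are tested against
exhaustive path enumeration on small instances.

## Priors and MCMC

Priors: `N(0, 10²)` on all logit-scale location parameters, `U(0, 10)` on
all SDs, and `U(0, 1)` on the predation and fidelity probabilities.  The
last is a deliberate deviation from putting `N(0, 10²)` on their logits,
which concentrates mass near 0 and 1 and destabilises early chain
behaviour; these are rates, not regression locations.  All priors are
overridable through `PriorConfig`.

The sampler is adaptive Metropolis-within-Gibbs: random-walk blocks for
(μ, β, γ) per stage (or (μ, β₁..β₃) and the `b` vector for the spline), the
two month-effect vectors, (logit m_J, logit m_A, logit F), the `ψ` logits,
the `a` and `g` intercept vectors and (d_p, d_r); vectorised elementwise
Metropolis for the three per-individual heterogeneity vectors (exact,
because the likelihood factorises over individuals given the globals);
variance components updated against their conditional densities, which do
not involve the encounter likelihood; and a conjugate Gibbs step for `μ_ψ`.
Each SD additionally gets a joint rescaling move `(σ, v) → (cσ, cv)` with
lognormal `c`, whose acceptance ratio reduces to the likelihood ratio plus
`log c`; without it the centred parameterisation makes the variance
components the slowest-mixing block by far.  Month-indexed parameters
(`B_t`, `ψ_t`, `a_t`, `g_t`) are estimated only for calendar months that
actually index an interval in the data; the rest carry no likelihood
information and are pinned at zero rather than left to wander over the
prior and pollute the convergence diagnostic.
Proposal scales adapt (Robbins–Monro toward 23.4% block / 44% scalar
acceptance) during burn-in only and are frozen afterwards, preserving the
stationary distribution.  All randomness derives from the config seed via
`SeedSequence` spawning; identical seeds give bit-identical draws.

The default protocol follows the study: 3 chains, 1,000 burn-in sweeps,
2,000 retained-phase sweeps thinned by 5 (2,500 for spline visualisation
fits).  Convergence is monitored with the Gelman–Rubin split-chain R-hat;
fits warn, and set `converged=False`, when any key parameter exceeds 1.1.
Summaries report median, SD, the 2.5/97.5% quantiles (95% BCI) and the
fraction of draws below zero (the "X% of γ draws were negative" statistic).
Survival-vs-colour curves are evaluated at `ε = 0` and `B = 0`
(population-average logit at the reference month), pointwise median and 95%
band over draws.

## Synthetic data

The generator runs the exact state-space process the model assumes:
staggered entry, mixture-distributed colour, stage transitions, constant
predation, permanent emigration, and emission through the recapture/recovery
model, retaining latent paths and the truth parameters.  The default
scenario mirrors the mainland survey: N = 1,700 over T = 13 occasions
(February start), first captures over the first 10 occasions, unimodal
bright colour (ratio ≈ 1.07 ± 0.23), survival intercepts at logit(0.88)
(juveniles) and logit(0.69) (adults), gradients (β, γ) = (−0.16, −0.34) and
(0.01, −1.05), stage predation 0.02/0.06 per month, fidelity 0.95, and
detection sparse enough to yield roughly two hundred re-encountered
individuals out of 1,700 — the regime of the field data.  The island-like
profile is a two-component mixture (ratio 0.50/1.05, SD 0.15) chosen to
reproduce the darker median and roughly doubled variance of the island
population; its component parameters are qualitative configuration, not
measured quantities.

A second preset (`recovery_scenario`) defines the parameter-recovery
conditions used by the tests: N = 400, T = 10, (β, γ) = (0, −1) in both
stages, heterogeneity SD 0.4, predation 0.03/0.05, fidelity 0.95, recapture
≈ 0.5 and recovery ≈ 0.4 per occasion.  Detection is deliberately moderate
rather than field-sparse: recovery tests measure whether the estimator finds
truth when the data carry signal, not whether a particular field effort was
adequate.  The microhabitat layer draws arboreal use from a logit model with
month and individual random effects, overridden by hibernation in a
configurable winter-month set.

What the generator does **not** emulate: spatial structure and GPS
locations, weather covariates, time-varying colour, colour-measurement
error, between-year demographic trends, and predator behaviour.  Passing
recovery tests therefore show correctness of the estimation machinery under
the model's own assumptions — not robustness to their violation in real
field data.

## Problem sizes and numerics

The test suite runs reduced problem sizes chosen as the smallest that leave
the checks informative: the acceptance recovery study uses 20 replicates of
N = 400, T = 10 with 3 chains × (500 burn-in + 750 sweeps, thin 3); unit
fits are smaller still.  Forward-algorithm probabilities are normalised per
occasion (log-scaling), so underflow is not a concern at these lengths.
Degenerate inputs fail loudly: zero-variance colour, invalid probabilities,
histories with events after death, too few individuals for the knot rule
(I < 8), and grids outside the observed colour range (extrapolation
warning).  GLMMs fit by Laplace approximation with a damped inner Newton
solver (tolerance 1e−10) and L-BFGS-B outer optimisation; complete
separation is flagged at |coefficient| > 10 on the logit scale, and a
single-level grouping factor is dropped with a warning.

## Known limitations

* The Laplace GLMM slightly underestimates random-effect variances with
  many small binary groups (the usual Laplace bias); fixed-effect estimates
  and SEs match lme4 closely and are the reported quantities.
* Random-walk MCMC mixes slowly for weakly identified variance components
  (σ_ε, σ_rp) when detection is sparse; their R-hats are the usual
  offenders, and longer chains are the remedy.
* The spline model's `b` block is updated jointly; with K = 35 knots its
  effective exploration is slower than the quadratic model's, matching the
  study's need for extra iterations in visualisation fits.
* No model comparison (WAIC/LOO), time-varying covariates, multi-site joint
  fits, or continuous-time formulation.
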