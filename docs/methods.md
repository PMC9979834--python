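# Methods

`panelcomp` implements two complementary analyses of removal experiments on
settlement-panel fouling communities containing jellyfish polyps
(*Aurelia aurita* scyphistomae): a phenomenological hierarchical
compositional MANOVA of final community composition, and a mechanistic
family of ODE models of competition for space fitted to weekly point-count
time series. This note records the models, their assumptions, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Experimental design assumed throughout

60 panels in 10 blocks; within each block, 3 panels at 1 m and 3 at 3 m,
one panel per depth assigned to each treatment: control (C), weekly removal
of half the *A. aurita* polyps (A), weekly removal of every second
potential-competitor individual or colony (O). Weekly photographs for 8
weeks, before and after treatment; percent cover estimated by 100
randomly placed points per photograph over nine categories (*A. aurita* on
panel, *A. aurita* on competitors, bare panel, *Botrylloides* spp.,
*Bugula* spp., *Molgula tubifera*, *Ascidiella aspersa*, *Botryllus
schlosseri*, other). When no treatment was applied to a panel in a week,
the pre- and post-treatment records are the same photograph. Paired
environmental measurements (dissolved oxygen, temperature, salinity) are
taken weekly at both depths; salinity is missing in week 5. Weeks are
indexed 1–8 from deployment (deployment = week 0, no observation).

A recorded mistake — one A-type application to a control panel — is
handled as in the study: the panel stays a control for the
final-composition analysis, but the extra event enters its schedule for
the dynamics track. Schedules therefore store (week, kind) pairs rather
than weeks alone.

## Environmental intervals

Between-depth differences in weekly pairs are assumed i.i.d. normal.
Under a noninformative uniform prior on the mean and log standard
deviation, the central 95% credible interval for the mean difference is
the classical one-sample t-interval, mean ± t₀.₉₇₅,ₙ₋₁·s/√n. Pairs with a
missing member are dropped listwise. Normality is checked by QQ points at
plotting positions (i − 0.5)/n (a common convention; nothing downstream
depends on it). A simulation test verifies 95% ± 1.5% coverage at n = 8.

## Compositional MANOVA

Final-week pre-treatment counts are restricted to the five parts that
dominate cover: *A. aurita* on panel, bare panel, and every named taxon
reaching ≥ 20 points on at least one panel (a data-driven rule, not a
hard-coded list). Subcompositional coherence makes the exclusion of rare
parts harmless: results about retained parts do not depend on excluded
ones.

The model, for the panel at depth j, treatment k, block l:

    y_jkl   ~ multinomial(n_jkl, ρ_jkl)
    ρ_jkl   = ilr⁻¹(μ + α_j + β_k + γ_jk + δ_l + ε_jkl)
    δ_l     ~ N(0, Z),    ε_jkl ~ N(0, Σ)

in the 4-dimensional ilr space of the 5-part simplex. Sum-to-zero effect
coding identifies the fixed effects (α over 2 depths, β over 3
treatments, γ doubly centered). Variants drop the interaction, the
treatment effect, or the depth effect.

**Basis.** The orthonormal contrast matrix comes from the sequential
binary partition ((*A. aurita*, bare) | competitors; *A. aurita* | bare;
*Botrylloides* | (*Bugula*, *Molgula*); *Bugula* | *Molgula*). All fitted
compositions and logit contrasts are invariant to this choice (tested
against a second basis); the choice makes the two ternary display
projections exact coordinate blocks: ilr of the competitor subcomposition
equals coordinates 3–4, and ilr of the (aurita, bare, gm(competitors))
projection equals coordinates 1–2 up to the factor 3/√5 on the first
coordinate. Zero replacement by 1/2 is applied only when plotting
observed counts, never in likelihoods.

**Priors.** N(0, 2.5²) per ilr component on μ, α, β, γ; inverse-Wishart
(ν₀ = 6, S₀ = 0.5·I) on Z and Σ. The inverse-Wishart form was chosen over
a scale-times-correlation decomposition because it admits exact conjugate
Gibbs updates, which the sampler exploits; both are weakly informative
and the reported contrasts are insensitive to the difference at the
precision reported.

**Sampler.** Blocked adaptive Metropolis-within-Gibbs, 4 chains × 1000
post-warmup draws by default:

* Gaussian random-walk updates for each fixed-effect vector and for the
  conditionally independent block and panel effects (vectorized across
  blocks/panels), with per-block proposal scales Robbins–Monro-adapted
  toward 25–30% acceptance during warmup only (so the post-warmup chain
  is a fixed Markov kernel).
* Exact conjugate inverse-Wishart Gibbs draws for Z | δ and Σ | ε.
* Interweaving moves: each fixed-effect vector θ enters every panel's
  linear predictor with a known coefficient c_i, so the transformation
  (θ + v, ε_i − c_i v) leaves the likelihood unchanged and v has a
  Gaussian full conditional determined by the priors. Sampling v exactly
  (for each fixed effect against ε, each δ_l against its panels' ε, and μ
  against δ) removes the funnel between fixed and latent effects that
  otherwise dominates the autocorrelation time.

Convergence is summarized by rank-normalized R-hat and bulk ESS (arviz);
`fit` warns when any reported scalar has R-hat > 1.01. The default test
and acceptance runs use shorter chains than a production analysis would;
the quantities they assert (contrast coverage, cross-validation ordering)
are robust to the residual autocorrelation, but tail quantiles of single
parameters from short runs should not be over-read.

**Summaries.** Treatment-cell compositions set random effects to zero:
ρ'_jk = ilr⁻¹(μ + α_j + β_k [+ γ_jk]). Logit contrasts report
logit(share) differences between treatments at a depth, for the
*A. aurita* share and the summed competitor share. 95% HPD credible
regions for ternary displays use a Gaussian KDE (scipy's plug-in
bandwidth) in the 2-D ilr coordinates; the boundary is the density
contour at the 5th percentile of the sample densities, extracted on a
200×200 grid and mapped back to the simplex. Whether random effects
should instead be marginalized in the contrasts is a genuine modelling
choice; zeroing them reports the effect for a typical (median) block and
panel, which is the package's convention.

**Model comparison (LOCO).** New observations are new blocks, so models
are compared by leave-one-block-out cross-validation with *marginal*
likelihoods: for each held-out block, the predictive density averages the
multinomial likelihood over posterior draws and over fresh δ ~ N(0, Z),
ε ~ N(0, Σ) replicates (100 per draw by default, shared δ within a
block). Δelpd is reported against the best model with the standard error
√B × sd(per-block differences). The Monte-Carlo weight ESS is recorded
and a warning emitted when it falls below 50.

## Dynamic models of competition for space

State: proportion of substrate x covered by potential competitors and
polyp density y₁ (numbers per squared length), with δ the area per polyp;
free space is 1 − x − δy₁. The basic model is preemptive competition
(settlement and growth claim only free space; occupants are not
displaced):

    dx/dt  = a₀(1 − x − δy₁) + a₁x(1 − x − δy₁) + a₂x
    dy₁/dt = b₀(1 − x − δy₁) + b₁y₁(1 − x − δy₁) + b₂y₁

with settlement rates a₀ (T⁻¹) and b₀ (numbers·L⁻²·T⁻¹), growth/budding
rates a₁, b₁ (T⁻¹), death rates a₂, b₂ < 0 (T⁻¹). The time unit is one
week. Four one-parameter extensions allow a positive effect of polyps on
competitors:

* settlement facilitation: a₀ → a₀ + m₀δy₁
* growth facilitation: a₁ → a₁ + m₁δy₁
* overgrowth: +a₁,ᵧ₁·x·y₁ in dx/dt and −(a₁,ᵧ₁/δ)·x·y₁ in dy₁/dt, so the
  exchanged space cancels exactly in d(x + δy₁)/dt
* protection from predation: a₂ → a₂e^(−m₂δy₁) (m₂ dimensionless,
  absorbing the product of the affected-space proportionality and the
  deterrence rate)

Setting the extra parameter to zero recovers the basic model exactly, and
the flow points inward on the boundary of {x ≥ 0, y₁ ≥ 0, x + δy₁ ≤ 1}
under the sign constraints, so trajectories stay in the region (property
tested on random parameters and schedules).

**Interaction strengths.** The community matrix holds partial derivatives
of proportional rates of change of relative abundances u = (x, δy₁) with
respect to u. Analytic expressions per variant are verified against
central finite differences; in the basic model all four entries are
negative at interior states. The polyp-on-competitor effect field
evaluates entry (1,2) on a simplex grid with boundary margin ε = 10⁻³.

**Removal events.** An application is an instantaneous proportional
reduction at the sampling instant, between the pre- and post-treatment
photographs: y₁ → (1 − r_A)y₁ or x → (1 − r_O)x, with r_A, r_O estimated,
shared across panels, weeks and depths.

**Reparameterization.** Point counts observe only relative abundances,
so δ and y₁ are not separately identifiable. The fitted system uses
y₁* = δy₁, which is closed in (x, y₁*) with parameters a₀, a₁, a₂,
δb₀, b₁, b₂ and (for overgrowth) a₁,ᵧ₁/δ. Reported polyp settlement is
therefore δb₀ and the reported overgrowth rate is per unit of covered
proportion.

**Likelihood.** Panels sharing a depth and application schedule share one
deterministic trajectory (no panel random effects — a deliberate
simplification whose documented consequence is underdispersion relative
to real panels). Each observation contributes a multinomial likelihood
over (polyps, bare, competitors) with probabilities (u₂, 1 − u₁ − u₂, u₁)
at the pre- or post-event state; probabilities are floored at 10⁻⁹ and
renormalized because early weeks produce exact zeros. Points on polyps
growing on competitors are excluded from all three categories (they are
negligible in this design) so totals can fall slightly below 100.
Control panel-weeks enter once (pre ≡ post is the same photograph).

**Priors and sampling.** Half-normal(scale 1 per week) with mode zero on
all rate magnitudes, signs imposed structurally; uniform(0, 1) on r_A and
r_O. Per-depth parameters are a priori independent; r_A, r_O are shared
across depths. The posterior (14–16 dimensions) is sampled with the emcee
affine-invariant ensemble sampler using differential-evolution moves
(80% DEMove, 20% DESnookerMove), which mix far better than the stretch
move on this correlated posterior; walkers are initialized in a 5% ball
around the posterior mode found by L-BFGS-B with a batched
central-difference gradient. Walkers play the role of chains in R-hat and
ESS.

**Integration.** The reference solver is LSODA with rtol 10⁻⁸ /
atol 10⁻¹⁰ and stop-update-restart event handling. Inside likelihood
evaluations, all distinct (depth, schedule) trajectories for the whole
walker batch are integrated in a single vectorized fixed-step RK4 pass at
10 steps per week; against the reference solver this is accurate to ~10⁻⁷
in the states, four orders of magnitude below the multinomial sampling
noise at 100 points. Tests pin the agreement.

**Model comparison.** PSIS-LOO on the pointwise log-likelihood (arviz),
reporting Δelpd from the best model, the paired-difference standard error
√N × sd, and Pareto-k diagnostics (warning when > 10% of observations
exceed k = 0.7). A brute-force oracle refits the model without each
observation on small instances; PSIS carries a small, well-documented
finite-sample optimism for influential observations, so agreement is
asserted on the scale of the elpd estimate's own standard error.

**Recovery harness.** `recovery_study` simulates experiments from known
parameters, refits, and tallies 95% HPD coverage per parameter. At the
default scenario, coverage is reliable for the parameters the data inform
well — competitor settlement/growth at the depth with high competitor
cover, polyp settlement/budding at the depth with visible polyps, and
r_O — while death rates and the weakly expressed rates at the other depth
are prior-dominated, mirroring the behaviour expected of this design.

## Synthetic data

The generator is first-class, tested code. It reproduces the full design
(blocks, depths, treatments, schedules, the optional mistaken
application) and draws counts in two ways: multinomial point counts along
deterministic trajectories for the dynamics track (the competitor total
split across named taxa by a per-panel Dirichlet weight vector, with the
'other' category capped at 7 points as on real panels, so the ≥20-point
inclusion rule is exercised), and the full hierarchical MANOVA generative
process for the composition track. Environmental tables emulate the
study's measurement pattern, including the missing salinity week.

The default scenario (versioned in `presets/default.json`) reproduces the
study's qualitative pattern: heavy competitor cover at 1 m, more polyps
and bare space at 3 m, low polyp cover overall, overgrowth dynamics, and
removal targets of 0.5. Default MANOVA covariances are isotropic
(Z = 0.05·I, Σ = 0.08·I — block variation somewhat smaller than panel
variation).

Not emulated: photograph noise, taxon misidentification, spatial point
placement, stochastic settlement variation among panels, and polyps
growing on competitors (kept at zero). Passing tests therefore establish
the correctness and calibration of the estimators under the stated
models, not the adequacy of those models for any particular real
community.

## Problem sizes in the test and acceptance runs

The test suite runs reduced problem sizes chosen as the package's default
quick-check configuration: MANOVA fits with 2 chains × (600–1200 warmup,
300–800 draws); dynamics fits with ~34 walkers × (400–700 warmup,
300–600 steps); LOCO on 5 blocks; the recovery harness at the full
60-panel design with 10 replicate experiments; the PSIS-vs-exact oracle
on a 20-observation single-depth instance. A production analysis should
scale these up (4 chains × 1000+ draws; full 10-block LOCO).

## Known limitations

* Deterministic shared trajectories underestimate among-panel variance;
  posterior-predictive spread from the dynamics track is narrower than
  real panel-to-panel variation.
* The Metropolis-within-Gibbs MANOVA sampler has modest ESS per sweep;
  very tight interval estimates require long runs.
* r_A is weakly identified when polyp cover is low (its information comes
  only from post/pre contrasts of a scarce category).
* HPD regions depend mildly on the KDE bandwidth; only the display is
  affected.
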