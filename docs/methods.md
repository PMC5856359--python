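# Methods

## Model

Each arm k = 0, …, K (0 = control) yields i.i.d. normal endpoints
X_k,t ~ N(μ_k, σ²) with a common, known σ.  Outcomes are observed
immediately after allocation (fully sequential recruitment), except under
the batched rules, where allocation probabilities are frozen within blocks.
Each μ_k carries an improper uniform prior, so after n observations with
sample mean x̄ the posterior is N(x̄, σ²/n) and (x̄, n) is a sufficient
statistic.  No historical data, covariates, delayed outcomes or
unknown-variance modelling enter anywhere; that is exactly the setting the
simulations are meant to isolate.

## Gittins indices

For geometric discounting d ∈ [0, 1) the Gittins index of a normal arm with
known variance separates as ν(x̄, n; σ², d) = x̄ + σ·ν(0, n; 1, d), so only
the standardized sequence ν(0, n; 1, d) is ever computed.  We use the
calibration (retirement-option) formulation: ν(0, n) is the standing reward
λ at which sampling the arm once more (and then continuing optimally, with
the option to retire to λ at every later time) is exactly as valuable as
retiring immediately for λ/(1 − d).

Numerics: backward induction over a uniform grid of posterior means,
half-width 6 posterior standard deviations (6/√n), default 201 grid points
(801 for the bundled tables); horizon H chosen so d^H < 10⁻⁶; λ located by
bisection to 10⁻⁴.  The one-step expectation of the value function is *not*
quadrature: the piecewise-linear value interpolant is convolved with the
exact Gaussian kernel of the posterior-mean increment (sd 1/√(n(n+1)))
using closed-form hat-function overlaps, and the retirement kink —
where the value switches from the constant λ/(1 − d) to the continuation
branch — is integrated analytically (a Bachelier-type closed form) rather
than interpolated.  Residual error is the grid's interpolation bias of the
smoothed value function; at 801 points it is ≈ +3·10⁻³ absolute at n = 1
(d = 0.995) and the *profile* error across n, which is what allocation
dynamics respond to, is ≈ 10⁻³.  `compute_gittins_table(..., check=True)`
re-solves a subset of entries at double resolution and horizon and fails
loudly if any entry moves by more than the check tolerance.

Tables for d ∈ {0.9, 0.95, 0.99, 0.995} are bundled as plain text
(n_max = 400, dense in n up to 30, progressively sparser above) and looked
up log-linearly in n between grid entries; beyond n_max the last value is
carried forward (it is below 0.01 there).

**Index state-count convention.**  The reference studies this package
reproduces read their index values off printed tables and, in doing so,
counted the flat prior as one observation of the index state: their GI
score is x̄_k + σ·ν(0, n_k + 1; 1, d).  We verified this by simulation —
the n_k convention gives a two-arm null 95th percentile ≈ 2.05 and H1 power
≈ 0.33, while the n_k + 1 convention reproduces the published calibration
(≈ 1.95), null SD (1.37), null ECDF at 1.645 (0.89), power (0.24), patient-
benefit and bias figures simultaneously.  The package therefore defaults to
`index_offset = 1` for GI/RGI/CG, with `index_offset = 0` available.

## Allocation rules

All thirteen rules sit behind one allocator interface; t counts patients
already allocated (the patient being placed is t + 1, 1-based).

- **FR**: each arm with probability 1/(K+1).
- **TS**: P(arm k best | data) estimated from 1000 joint posterior draws
  per decision, sharpened as p_k^c with c = t/(2T) and renormalized.  The
  printed source is ambiguous about the exponent ("t2T"); t/(2T) is the
  stabilising choice consistent with its description and with the cited
  tuning literature.
- **TSB / TPB**: probabilities recomputed at t ∈ {0, b, 2b, …} (b = 20 by
  default) from all outcomes observed so far, frozen in between; the final
  partial block keeps the last vector; at t = 0 the vector is uniform (the
  analytic limit of both rules as their exponents vanish).
- **UCB**: x̄_k + σ·√(2·ln t / n_k); **KLU**: x̄_k + σ·√(2·(ln t + 3·ln ln t)/n_k).
  The typeset sources are ambiguous about the constant; these are the
  canonical forms of the cited algorithms, and a `log_factor` tuning key
  exposes the literal no-factor-2 reading.
- **CB**: argmax of the posterior mean — the myopic d = 0 limit of GI.
- **GI / RGI / RBI**: Gittins score as above; the semi-randomised variants
  add an arm-wise perturbation ((K+1)/n_k)·Y with Y ~ Exp(mean 1/(K+1)),
  drawn fresh per arm per patient.
- **TP**: experimental arms weighted by P(μ_k > μ₀ | data)^{γ_t} (closed
  form, a univariate normal tail), γ_t = 3(t/T)^1.75; control weight
  (1/K)·exp((max_k n_k − n₀)·η_t), η_t = 0.25(t/T); all renormalized.
- **CG / CUC**: with probability 1/(K+1) the patient receives the control;
  otherwise the GI (resp. UCB) argmax — taken over *all* arms, control
  included.  The experimental-only variant and the 1/K control probability
  exist as tuning keys, but the published four-arm operating
  characteristics (control-arm share ≈ 0.46 for CG and ≈ 0.34 for CUC under
  the null) single out the all-arms, 1/(K+1) reading.  The control
  assignment is randomised, not systematic (one in every K+1), because a
  deterministic schedule invites selection bias in practice.

Initialization: scores and posterior probabilities are undefined while any
arm has n = 0, so every rule except FR forces one observation per arm
first — UCB/KLU/CUC in arm-id order (patient t gets arm t−1), all others
uniformly at random among the empty arms.  Ties in any score are broken
uniformly at random.  Within a patient, allocation randomness is consumed
before the outcome draw, and each replicate runs on its own child RNG
stream spawned from the master seed, so studies are reproducible and
independent of execution order.

## Testing and calibration

Superiority is tested one-sided via Z_k = (x̄_k − x̄₀)/(σ√(1/n_k + 1/n₀)),
rejecting when Z_k exceeds a critical value; for K ≥ 2 the global test uses
max_k Z_k, controlling the family-wise error rate.  Under equal fixed
randomisation (Z_1, …, Z_K) is multivariate normal with unit variances and
pairwise correlation 1/2 (the shared control), so the FWER critical value
solves E[Φ(U + c√2)^K] = 1 − α over a standard normal U; K = 1 reduces to
the normal quantile (1.645 at α = 0.05; 2.0621 for K = 3).

Sample sizes come from the marginal (per-comparison) power requirement:
per-arm n = 2σ²(C_α + z_β)²/δ², total T = (K+1)·n, rounded up to the next
integer.  Effect sizes derive from outcome-superiority probabilities:
δ = √2·σ·Φ⁻¹(p), giving δ⁽¹⁾ = 0.545 at p = 0.65 and δ⁽⁰⁾ = 0.178 at
p = 0.55 (σ = 1).

Adaptive allocation makes the null Z distribution non-normal (heavy,
bimodal tails: whichever arm is dropped early retains a negatively biased
mean).  Critical values for adaptive rules are therefore calibrated: the
trial is simulated 10⁴ times under the global null, the per-replicate Z
(or max-Z) recorded, and the empirical 95th percentile (inverse-ECDF order
statistic) used as the test cutoff.  Replicates whose statistic is
undefined (a never-sampled reported arm) are excluded and counted; above 1%
exclusions a warning is raised.  At 10⁴ replicates the quantile's
Monte-Carlo standard error is ≈ 0.01–0.02 for the index rules.

## Operating characteristics

A study aggregates per replicate: the test decision at a supplied critical
value, p* (share of patients on the designated best arm — the control under
the null, the truly best experimental arm otherwise), and the mean patient
outcome.  Under an alternative the headline power is the *best-arm*
rejection rate P(Z_best > C); the global rejection rate is always reported
alongside, since published power columns could in principle follow either
convention — the best-arm reading is the one our reproduction matches.
Bias trajectories average x̄_k(t) − μ_k across replicates at every t,
carrying a frozen arm's last running mean forward and averaging only over
replicates where the arm has data (a flag switches to excluding them).

## What the simulations do and do not show

The generator implements exactly the idealised trial the designs assume:
immediately observable, exactly normal outcomes with known common variance,
no covariates, no drift, no selection bias by clinicians, and a correctly
guessed trial size T.  Passing tests therefore demonstrate properties of
the *designs* under their own assumptions — not robustness to delayed or
non-normal endpoints, variance misestimation, or the behavioural biases
that deterministic allocation invites in real trials (the methods
literature discusses these at length; the semi-randomised and batched
variants exist precisely to soften them).

## Default problem sizes

Defaults mirror the reference studies: α = 0.05, β = 0.10, σ² = 1,
δ⁽¹⁾ = 0.545, δ⁽⁰⁾ = 0.178, d = 0.995, batch b = 20, 10⁴ replicates for
calibration and studies.  The four-arm alternative is the least favourable
configuration (0, δ⁽⁰⁾, δ⁽⁰⁾, δ⁽¹⁾).  The test suite runs its end-to-end
checks at 10⁴ replicates, except the four-arm TS/TP-family power rows
(2×10³, with a correspondingly wider tolerance) and the per-rule
calibrate-then-retest self-consistency checks (2.5×10³ at reduced trial
sizes), keeping the whole suite within a desk-scale run.

## Known limitations

- The DP value at very small n carries a ≈ 3·10⁻³ absolute upward bias at
  the bundled resolution (the smoothed retirement boundary converges slowly
  in the grid); differences across n, which drive allocation, are accurate
  to ≈ 10⁻³.
- Calibrated critical values are themselves Monte-Carlo estimates; studies
  run against a stale or low-replicate calibration inherit that noise.
- The unknown-variance index and finite-horizon (Whittle-type) indices are
  out of scope, as are Bernoulli endpoints and covariate-adjusted designs.
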