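# Methods

## The mechanistic model

`spherofit` models an avascular tumour spheroid as a sphere of outer radius
R (µm) containing two concentric interfaces: the inhibited region, where
cells are viable but cell-cycle arrested, of relative radius φ = Ri/R, and
the necrotic core of relative radius η = Rn/R, with 0 ≤ η ≤ φ < 1. Following
Greenspan's reduction, nutrient and a growth-inhibiting metabolic waste are
taken to be at diffusive equilibrium, with hard concentration thresholds for
arrest and death. The thresholds' consequences are summarised by two
parameters:

* **Q** (dimensionless, 0 < Q < 1) — the balance of nutrient
  consumption/diffusion against inhibitor production/clearance,
  Q² = [ω_cons / (ω_diff (ω∞ − ω_crit))]·[β_crit β_diff / β_prod]. The
  regime Q < 1 corresponds to the inhibited region forming before the
  necrotic core; the seven dimensional rates are not separately identifiable
  from structure data, only their composite Q.
* **Rc** (µm) — the critical outer radius at which necrosis first occurs.

Growth has three phases. Phase 1 (R ≤ Q·Rc): all cells cycle, φ = η = 0.
Phase 2 (Q·Rc < R ≤ Rc): an inhibited region with φ = √(1 − Q²Rc²/R²),
no necrosis. Phase 3 (R > Rc): φ and η solve the coupled cubic system

    2R²η³ − 3R²η² + R² − Rc² = 0
    R²φ³ + (Q²Rc² − R²(1+2η³))φ + 2η³R² = 0.

The first cubic factorises as (1−η)²(1+2η) = Rc²/R², whose left side is
strictly decreasing on (0,1), so η is unique; given η, the second cubic has
exactly one root in (η, 1) because g(η) = ηRc²(Q²−1) < 0 and g(1) = Q²Rc² > 0.
Both are solved by bracketed Brent iteration (argument tolerance 1e−12), and
the map R ↦ (φ, η) is continuous across both phase boundaries. At the exact
boundaries the lower phase is assigned (R = Q·Rc → phase 1, R = Rc →
phase 2); continuity makes the convention observationally irrelevant.

The outer radius evolves by a mass balance between proliferation in the
cycling rim and loss of necrotic debris,

    dR/dt = (s/3)(1 − φ³)R − (s/3)γη³R,

with per-volume proliferation rate s (1/d) and loss/growth ratio γ = λ/s > 0.
Trajectories are integrated with an adaptive explicit Runge–Kutta scheme
(relative tolerance 1e−8); the structural system is re-solved at every
right-hand-side evaluation rather than cached, favouring correctness over
speed (a full trajectory costs ~10 ms).

### Steady state and its inversion

Setting dR/dt = 0 and imposing the structural system yields the limiting
structure m(θ) = (R̄, φ̄, η̄) for θ = (Q, Rc, γ). Parameterising by
ρ = η̄/φ̄ ∈ (0, 1) reduces the system to one scalar equation: from the mass
balance φ̄ = (1 + γρ³)^(−1/3) and η̄ = ρφ̄, and eliminating R̄ through the
first structural cubic leaves

    Q²(1−η̄)²(1+2η̄) = 1 − φ̄² − 2η̄³(1−φ̄)/φ̄,

after which R̄ = Rc / ((1−η̄)√(1+2η̄)). The residual is positive as ρ → 0
and negative as ρ → 1 for every valid (Q, γ), so a bracketed root always
exists; a 1000-point pre-scan logs any additional sign changes (none have
been observed) and the smallest root is taken with a warning if several
appear. The returned state satisfies both steady-state equations to ≤ 1e−10
(relative to R̄² for the structural components, which carry that scale).

The map m is invertible in closed form, which anchors both testing and
optimization:

    Rc = R̄ √((1−η̄)²(1+2η̄)),   γ = (1−φ̄³)/η̄³,
    Q² = R̄²[(1+2η̄³)φ̄ − φ̄³ − 2η̄³] / (Rc² φ̄).

With η̄ = 0 the inversion is degenerate (γ unidentifiable): all three
components of the limiting structure must be observed to identify θ.

Sensitivities ∂m/∂θ are computed by implicit differentiation of the
steady-state residuals with analytic partial derivatives
(dy/dθ = −J_y⁻¹ J_θ); central finite differences are retained as a
cross-check in the tests, agreeing to better than 1e−4 relative.

## Statistical model and inference

A measured spheroid contributes x = (R, φ, η), modelled as multivariate
normal, x ~ N(μ, Σ). The *statistical model* leaves μ free; the *mechanistic
model* substitutes μ = m(θ). Σ is a plug-in estimate — the unbiased (n−1)
sample covariance of the relevant (density, day) group, or the pooled
covariance Σ_g (n_g−1)S_g / Σ_g (n_g−1) across seeding densities for
steady-state analysis — and is never co-estimated with θ. Groups where a
coordinate has exactly zero variance (e.g. φ = η = 0 at early days) drop
that coordinate from the likelihood with a logged warning.

Maximum-likelihood estimation uses a bounded Nelder–Mead search, multi-start
(Latin hypercube) when requested; because the mechanistic model has three
parameters and a three-dimensional mean, the MLE coincides with the
closed-form inversion of the sample mean whenever that inversion is feasible,
and the optimizer is verified against it to 1e−6. The chain-rule gradient
∇_θ ℓ = J_m(θ)ᵀ [nΣ⁻¹(x̄ − m(θ))] is available for polish and for region
tracing.

Confidence sets come from Wilks' theorem: the α-level region is
{θ : ℓ(θ) ≥ ℓ(θ̂) − Δ_{ν,α}/2} with Δ the χ²(ν) quantile (1.92 at
α = 0.95, ν = 1). Profile likelihoods are computed on a grid spanning the
MLE ± 4 plug-in standard errors (from the observed information), 41 points
by default, extended outward until the profile crosses the threshold;
nuisance optimizations are warm-started from the adjacent grid point and CI
endpoints refined by bisection on the profile itself. For the free-mean
model the profile is exactly quadratic and the CI equals x̄ ± 1.96·se, used
as an analytic regression test.

Group comparisons use the likelihood-ratio statistic
T = 2(−ℓ(θ̂*) + Σ_N ℓ(θ̂_N)) with ν equal to the number of additional
parameters under the alternative ((G−1)·dim θ for full equivalence; G−1 when
only one indexed parameter is shared and the rest are group-specific, the
shared value being found by maximizing the sum of per-group profile
likelihoods). Statistics in (−1e−6, 0) from optimizer noise are clipped to
zero with a warning; more negative values raise. With known plug-in Σ the
full-equivalence statistic for the saturated mechanistic model is exactly
χ²-distributed, which the calibration tests exploit.

Two-dimensional confidence-region boundaries are traced by first bisecting
along a ray from the MLE to a point θ0 on the target contour, then
integrating the likelihood-annihilating (rotated-gradient) field with RK4
and re-projecting onto the contour by a Newton correction along the gradient
after every step (drift tolerance 1e−9). Tracing is performed in
standardized coordinates (θ − θ̂)/se so anisotropic parameter scales do not
force tiny steps; closure is detected by the swept angle around the MLE
returning to within 1.5 steps of θ0 after ≥ 1.75π. Contours that exit the
parameter bounds are returned open with a flag. Three-dimensional regions
are a stack of two-dimensional slices at the χ²(3) threshold, the slice
coordinate gridded over the MLE ± 4 standard errors; slices whose
conditional maximum falls below the threshold are returned empty.

## Phase-3 linear trajectory (total least squares)

Empirically, phase-3 structure follows a nearly linear path
(R, φ, η) = (Rc_emp, φ_c, 0) + τ·q̂ with a latent progression variable τ per
observation (τ = 0 at necrosis onset). All three coordinates, including τ,
are noisy, so the fit is errors-in-variables: the exact MLE of the
latent-variable normal model is the leading principal axis of the
Σ-whitened centred data, de-whitened back to measurement space. The anchor
is the point on the fitted line with η = 0, the direction is canonically
signed so τ increases with η, and negative fitted τ are reported, not
clipped (clipping would bias the line). Degenerate fits (whitened data
isotropic) raise.

When Σ is not supplied it is estimated from residuals about the line,
iterated twice (fit → residual covariance → refit). TLS residuals are
Σ-orthogonal to the line, so the residual covariance is rank-deficient along
it; the missing eigenvalue is floored at the smallest substantial residual
eigenvalue to keep the metric positive definite. The iteration starts from
per-coordinate variances only — whitening with the full raw covariance would
erase the line direction itself.

The shared-trajectory test applies the likelihood-ratio statistic with a
common plug-in Σ for null (one line) and alternative (one line per group)
fits; a line on the η = 0 plane has 4 free parameters (2 anchor components
+ 2 direction degrees of freedom on the unit sphere), so ν = 4(G−1). Type-I
calibration at 5% ± 2% is verified by simulation with line-generated groups.

## Synthetic cohorts

The generator emulates the cross-sectional design of the reference
experiments: each spheroid is observed once (destructively), at one of the
panel days 3–24, with 10 spheroids per (density, day) condition and seeding
densities 2500/5000/10000 cells. Defaults, chosen once as study-condition
stand-ins: true θ = (0.75, 149 µm, 0.737); s = 1.0 /d, calibrated so
trajectories plateau by day 18–21 as observed for the reference cell line;
initial radius lognormal with median 4 µm·(density)^(1/3) (aggregate volume
proportional to cell count; day-3 cohorts then span all three phases) and
coefficient of variation 0.05; measurement noise Σ = diag(20², 0.02², 0.1²)
(µm, –, –), an illustrative calibration to the reported interval widths, not
a data-derived covariance. Noise is independent across days; per-spheroid
RNG substreams are derived from (seed, cell line, density, replicate) so a
condition's draws do not depend on cohort composition.

Noise vectors violating R > 0 or 0 ≤ η ≤ φ < 1 are resampled (up to 100
attempts) rather than clipped, avoiding boundary point masses; in the
degenerate phase-1 corner (mean φ = η = 0) where resampling can fail, the
draw is projected onto the valid set with a logged warning.

**What the generator does not emulate.** Real image-derived measurements of
a spheroid without a necrotic core read essentially zero; the generator's
truncated-normal η instead leaves small positive values, so the generic
phase-3 selection threshold (η > 0.01) over-selects on synthetic cohorts —
the analysis drivers select at twice the η noise sd instead. Real data are
also reported to follow a near-linear size–structure relation, whereas the
generator's mean is the curved Greenspan map, so the shared-line TLS test on
synthetic cohorts is approximate in a way it is not for truly linear data.
Passing tests therefore validate the inferential machinery under its own
assumptions, not the biological adequacy of the structural model. Late-time
decay below the limiting size, reported for real spheroids, is not modelled:
the growth law cannot produce decay from below-steady initial conditions.

## Numerical conventions and limitations

* Units are fixed: µm and days; no unit-conversion layer.
* Covariances use the unbiased n−1 denominator (convention choice; affects
  only small-n behaviour).
* All root finding is bracketed (Brent) on intervals with proven sign
  changes; no derivative-based root polishing is needed.
* p-values are reported to 3 significant figures in pipeline reports.
* Problem sizes in the test suite (cohorts of 10–20 observations per group,
  200 coverage replicates, 500 test-calibration replicates, 120–150² contour
  grids) are chosen to make Monte-Carlo bands tight enough to detect
  miscalibration while keeping the full suite interactive.
* The equivalence of the single-shared-parameter test's constraint structure
  to the reference analysis is a modelling choice (the reference tabulates
  per-parameter p-values without printing the constraint); the implementation
  shares only the indexed parameter and leaves the others free per group.
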