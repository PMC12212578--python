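# Methods

## Model

The package estimates the spatial single-index varying-coefficient
autoregressive model

    yᵢ = g(uᵢᵀα) Σⱼ wᵢⱼ yⱼ + xᵢᵀβ + εᵢ,        i = 1…n,

in matrix form Y = GWY + Xβ + ε with G = diag{g(u₁ᵀα), …, g(u_nᵀα)}.
W is a known n×n spatial weight matrix with zero diagonal (row-standardized
in all default designs, so WY is a neighbour average); α ∈ ℝᵐ is a unit-norm
index direction with α₁ ≥ 0 for sign identification; g is an unknown smooth
function; ε is i.i.d. N(0, σ²). When I − GW is invertible the reduced form
is Y = (I − GW)⁻¹(Xβ + ε); a sufficient condition under row-standardized W
is sup|g| < 1, which all shipped designs satisfy.

Because WY appears on the right-hand side and depends on ε through the
reduced form, WY is endogenous: E[(WY)ᵀε] = σ²·E[tr{W(I−GW)⁻¹}] ≠ 0 in
general. On the default lattice designs this correlation is numerically
mild (the relevant trace is small), which informs several choices below.

## Estimation

**Spline approximation.** g is approximated on the observed index range by a
p-th order truncated power basis
B(t) = (1, t, …, tᵖ, (t−k₁)₊ᵖ, …, (t−k_l)₊ᵖ), default p = 3. Knots are the
every-`step`-th order statistics of the current index values t = Uα (default
step 10), with knots equal to the sample minimum or maximum dropped — a
truncated term at the maximum is identically zero on the sample and one at
the minimum duplicates the monomial span — and duplicates collapsed. The
basis is ill-conditioned by construction, so every solve goes through an
orthogonal-decomposition least-squares path (LAPACK gelsd); normal equations
are never formed.

**Concentrated (profile) fit.** Given a lag vector s (see below) and a
candidate ϕ, α(ϕ) = (√(1−‖ϕ‖²), ϕ), t = Uα, knots and basis are rebuilt, and
(δ, β) solve the joint linear least-squares problem on [diag(s)·B, X]. The
joint solve is the exact fixed point of alternating the two closed-form
single-block updates (each conditionally minimizes the same convex
quadratic), which a test verifies. The profile loss L(ϕ) is the resulting
residual sum of squares.

**Index stage.** For m = 2 the scalar ϕ is initialized by a grid search over
41 equispaced points in [−1, 1] (ties to the smaller ϕ); for m > 2, by the
best of 20 seeded random unit directions. A trust-region minimizer
(`scipy.optimize` trust-constr) then refines ϕ inside the ball
‖ϕ‖ ≤ 1 − 1e−8, which keeps α₁ real and gradients finite. Because knots are
reselected at every evaluation, L is piecewise smooth with shallow
micro-minima at ~1e−3 spacing; the implementation therefore keeps the best
*evaluated* point rather than the optimizer's final iterate and finishes
with a bounded golden-section polish of the best bracket. The outer loop
(re-optimize, test ‖Δα‖∞ < 1e−4, default max 50 iterations) typically
converges in two passes since the objective does not change between them.

The index stage evaluates the profile loss with the **observed** lag
s = WY. The direction α is identified by the shape of g's variation across
units; replacing WY by a first-stage projection at this point only adds
projection noise that flattens the profile and inflates the sampling spread
of α̂, while the level distortions endogeneity causes are absorbed by the
concentrated (δ, β) and corrected afterwards. Simulation confirms the
observed-lag profile yields a markedly tighter α̂ than any projected-lag
variant, at identical bias.

Two degenerate-direction guards make the profile well-posed. First,
configurations where the index values collapse onto fewer than twice the
spline dimension of resolvable locations are rejected (loss +∞): on a
lattice, directions aligned with a grid axis collapse t onto h distinct
levels that a ~26-dimensional spline can interpolate, creating spurious
global minima at the ϕ-boundary. Second, a fit whose ĝ has range below 0.01
triggers a weak-identification warning (α is then barely identified and the
model degenerates toward homogeneous SAR).

**Coefficient stage (2SLS).** At α̂ the final (δ, β) are re-estimated with an
instrumented lag s = ŴY, the least-squares projection of WY on an exogenous
instrument block. The base block is [X, WX, W²X, WU, W²U] with collinear
columns dropped greedily left-to-right at relative tolerance 1e−10 and each
kept column rescaled to unit norm. Two augmentations make the first stage
track the conditional mean E[WY | X, U] = WXβ + Wdiag(g)WXβ + …, which plain
powers of W cannot reach when g varies:

* spline-interacted columns W(Bⱼ ∘ WXₖ), the first-order terms of that
  series, with B built at α̂;
* one model-implied mean-lag column W(I − Ĝ₀W)⁻¹Xβ̂₀ from a pilot
  observed-lag fit, which sums the series exactly at the pilot estimates
  (the pilot ĝ is clipped to ±0.95 so the solve is a contraction).

With these instruments the substitution estimator is exact on noise-free
spline-representable data (a test asserts recovery to 1e−4; machine
precision is achieved in practice) and nearly unbiased at realistic noise,
and the instrumented fit recovers g with lower mean squared error than the
uninstrumented regression — the point of the instrumental correction.
`FitOptions(instruments="basic")` restricts to the base block for
comparison.

**Residual variance.** The default σ̂² is the *structural* residual
Y − Ĝ·WY − Xβ̂ evaluated with the observed lag, divided by n − p with
p = dim δ + dim β + (m−1). The 2SLS coefficients do not minimize this
criterion, so it carries no least-squares deflation, and the
degrees-of-freedom divisor removes the remaining downward bias from the
fitted mean parameters; in the shipped Monte Carlo designs its mean tracks
the true σ² within a few percent at every noise level from 1.0 down to
0.01. `sigma2_mode="fitted"` instead uses the first-stage lag and divisor n
(that residual also contains the first-stage noise Ĝ(WY − ŴY) and
over-states σ² by ~30% on the default design; it is provided for
comparison). Fitted values Ŷ and `predict` are consistent with whichever
definition was used. Only in-sample prediction is defined: the fitted lag is
built from the observed response.

**Bootstrap (extension).** `bootstrap_se` resamples centred residuals,
regenerates Y through the reduced form at the fitted (Ĝ, β̂), and refits;
the across-replicate standard deviations are practical standard errors for
(α̂, β̂). This is an add-on — the Monte Carlo experiments quantify dispersion
by replication, not by asymptotics.

## Synthetic data designs

`SimulationDesign` defaults reproduce the regular-grid study: a 15×15
half-unit lattice (n = 225, coordinates uᵢ = 0.5·((i−1) mod 15, ⌊(i−1)/15⌋)),
row-standardized Rook contiguity, α = (1/2, √3/2), β = (1, 2), covariates
i.i.d. U(−1, 1), g = sin, ε ~ N(0, σ²) with σ² ∈ {1, 0.64, 0.25, 0.01} as
experiment presets. The irregular variant draws n points area-uniformly on a
disk (default radius 1) with k-nearest-neighbour weights; k = 6 by default,
chosen to match the Rook-scale average degree since no canonical value
exists. Covariate laws U(−1,1), U(0,1), N(0,1), χ²(2) and Beta(2,2) are
supported. Y is obtained by a dense linear solve of (I−GW)Y = Xβ + ε — never
an explicit inverse — preceded by a cheap row-sum bound on the spectral
radius of GW (eigenvalues computed only if the bound is inconclusive), and
every draw is verified against the defining equation to 1e−9.

The heterogeneous-ρ process Y = diag(ρ)WY + Xβ + ε with
ρᵢ = a·sin(ω(uᵢ₁+uᵢ₂)) (defaults a = 0.8, ω = 1, exposed as parameters)
drives the misspecification experiment: the functional form of such a field
is a modelling choice, so only the qualitative failure of the homogeneous
fit — severalfold σ̂² inflation, large β bias relative to a correctly
specified control — is asserted, never particular numbers. The experiment
uses U(0,1) covariates, under which the failure is most dramatic because
the mean structure interacts with near-unit-root rows of the field.

What the generator deliberately does not emulate: real weight matrices from
administrative boundaries, non-Gaussian or heteroskedastic errors, covariate
dependence between X and U, and temporal dynamics. Passing tests therefore
certify the estimator under the model's own assumptions, not robustness to
their violation.

## Baseline and diagnostics

The homogeneous SAR baseline is fit by quasi-maximum likelihood —
concentrated log-likelihood with log|I−ρW| from the eigenvalues of W, ρ
searched on (1/λ_min, 1) by bounded scalar minimization to 1e−8 — or by
spatial 2SLS with instruments [X, WX, W²X]. The two agree within Monte Carlo
noise on well-specified simulations (tested).

Global Moran's I follows the standard cross-product form normalized by the
total weight S₀. Inference is by seeded random permutation of y (default 999
permutations, one-sided toward positive autocorrelation,
p = (1 + #{I_perm ≥ I_obs})/(n_perm + 1)); the reported variance and z-score
use the closed-form randomization (permutation) moments, chosen over the
normality variant because the headline inference is itself permutation
based. The Moran scatter assigns quadrants by the signs of the deviation and
its spatial lag, zeros counting as "high"; for row-standardized W the
lag-on-deviation slope equals Moran's I (tested to 1e−10). The LM-Lag and
LM-Error statistics are the canonical score tests built from OLS residuals
with the trace term tr(W² + WᵀW), referred to χ²₁.

## Monte Carlo conventions

Per-parameter metrics use the population-variance convention:
S.E. = √((1/n_mc)Σ(θ̂ᵢ−θ̄)²), Bias = |θ̄−θ|, MSE = (1/n_mc)Σ(θ̂ᵢ−θ)², so
MSE = S.E.² + Bias² holds as an identity (asserted to 1e−10). Replicate r
uses seed base_seed + r; experiments are pure functions of (design, n_mc,
base_seed). Replicates that fail or do not converge are excluded with a
logged warning up to a 5% cap, beyond which the experiment errors; in
practice the shipped designs produce no failures. Distribution summaries use
Freedman–Diaconis histogram bins and standardized normal Q-Q pairs;
rendering is left to the caller.

Problem sizes: the test suite runs the replication experiments at n_mc = 100
with mean tolerances widened by √3 relative to the 300-replicate study;
`scripts/acceptance.py` runs the full n_mc = 300. MSE comparisons against
reference values are treated as one-sided performance bounds (at most twice
the reference), since a smaller Monte Carlo error is an improvement, not a
discrepancy.

## Known limitations

* α̂'s sampling spread is ~10% wider than the tightest published
  replication of this design, which we attribute to unspecified details of
  the original initializer and trust-region configuration; the residual
  α-MSE gap is of that order.
* The profile loss is piecewise smooth; the optimizer guarantees a
  non-ascending step and basin-bottom accuracy ~1e−3 in ϕ, far below the
  sampling spread but short of smooth-problem precision.
* For m > 2 the multistart initializer is heuristic; the grid initializer
  covers only m = 2.
* Out-of-sample prediction is undefined by the model's in-sample lag
  construction and is not offered.
* Weight matrices are dense in memory; designs beyond a few thousand units
  would need a sparse path.
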