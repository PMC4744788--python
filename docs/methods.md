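# Methods

## Model

On the transformed scale z = log(y + c) (offset c = 1 by default, so exact
zero concentrations are admissible), the surface is

    z_i = m(s1_i, s2_i, t_i) + ε_i,   ε_i ~ N(0, σ²),
    m(s1, s2, t) = Σ_jkl α_jkl φ_j(s1) φ_k(s2) φ_l(t),

with marginal B-spline bases on equally spaced knots.  Each coordinate is
affinely rescaled to [0, 1] (B-spline values are invariant under this map;
it only improves conditioning), the knot grid extends `degree` uniform
steps beyond the data range so exactly n_basis functions are supported, and
the tensor design matrix is assembled by row-wise Kronecker products — at
most (degree+1)³ non-zeros per row.

Roughness is penalized by λ‖Dα‖², where D stacks the order-d difference
operator along each of the three coefficient dimensions (Kronecker-expanded
with identities).  A single global λ is used; differential smoothness
across dimensions is achieved by the basis counts instead (more basis
functions where the signal varies faster), which keeps the cheap
single-parameter profile.  "Second-order basis functions" means degree-2
(quadratic) B-splines here; both the degree and the penalty order are
configurable (defaults: degree 2, order 1 — order-1 penalties are less
prone to spurious linear extrapolation into data gaps than order-2).

## Smoothing-parameter posterior

With the conjugate prior α, σ² ~ NIG(0, (λD′D)⁻¹, a, b), the marginal
posterior of λ is, up to a λ-free constant,

    log f(λ|y) = (r/2)·log λ − ½·log|B′B + λD′D|
                 − (a + n/2)·log(2b + RSSλ) + log f(λ),

where r = rank(D′D) and RSSλ = y′(I − B(B′B+λD′D)⁻¹B′)y is the *minimized
penalized objective* (residual sum of squares plus λ‖Dα̂‖²).  Defaults:
a = b = 10⁻⁴ (weak prior information on σ²) and a flat improper prior on λ
over an 81-point log-spaced grid on [10⁻⁶, 10⁸]; any other prior can be
supplied as a callable.  MAP selection takes the grid argmax (ties broken
toward the smaller λ, boundary maxima warn, or raise in strict mode); model
averaging uses the normalized grid masses as discrete quadrature weights.

D is rank deficient (null dimension 1 for order 1; 2³ = 8 for order 2 —
the tensor products of per-dimension constant/linear-in-index vectors), so
the implied prior is partially improper.  The null-space component of α
carries a flat prior and the complement a proper Gaussian.  The determinant
in the kernel is evaluated on the penalized subspace after this split; the
convention is pinned by a ridge-limit identity verified in the tests: with
prior precision λD′D + εI, the normalized posterior converges to the
formula above as ε → 0.

Classical selectors are computed from the same profile using the plain
residual sum of squares ‖y − ŷ‖² and the effective degrees of freedom
edf(λ) = tr B(B′B+λD′D)⁻¹B′, in the Gaussian profile-likelihood forms
GCV = n·RSS/(n−edf)², AICc = n log(RSS/n) + 2edf + 2edf(edf+1)/(n−edf−1),
BIC = n log(RSS/n) + log(n)·edf.  k-fold cross-validation (default k = 10)
refits per fold with either shuffled observations or whole wells held out;
held-out predictions use the global basis domains.

## Computation

One decomposition serves the entire λ profile:

1. sparse cross-products B′B, D′D; orthonormal split [Z X] of coefficient
   space with Z spanning null(D);
2. thin QR of BZ projects the unpenalized fit out of the data (if BZ is
   rank deficient the penalized system is singular for every λ and the
   offending directions are reported);
3. whitening of S = X′(D′D)X by its eigendecomposition (penalty-only, so it
   is cached on the penalty object and shared across CV folds);
4. one dense symmetric eigendecomposition of the whitened projected
   cross-product — the only O(m³) step.

Afterwards RSS(λ), the penalized RSS, edf(λ), the generalized
log-determinant Σ log(s²_i + λ) and the log posterior are O(m) per λ;
coefficients and prediction variances cost one extra matrix–vector product.
Spectrum values below 10⁻¹² of the maximum are treated as exact zeros and
folded into the rank bookkeeping, so rank decisions are explicit.
Prediction intervals are Student-t with 2(a + n/2) degrees of freedom and
scale b_n/a_n times the posterior quadratic form, computed through the
block (Schur-complement) structure of the normal matrix; model-averaged
bounds are mixture quantiles found by vectorized bisection on the mixture
CDF.  A guardrail refuses m > 10⁴ coefficients (25 basis functions per
dimension would already mean a 15,625² cross-product matrix) unless
explicitly overridden.

Averaging over λ widens credible intervals through between-model spread;
with a diffuse λ posterior the mixture can nevertheless be locally slightly
narrower than the MAP-component interval, because components at larger λ
have smaller posterior scale.  The guaranteed statement is the
mixture-variance decomposition, not pointwise quantile ordering.

## Synthetic plume data

The generator provides a ground truth where none can be published: real
monitoring datasets (well coordinates, groundwater levels) are proprietary.

**Transport model.**  ∂y/∂t = D∇²y + ψ·∇y on the unit square, t ∈ [0, 1],
zero-flux boundaries.  With the advection term entering with a positive
sign the solute drifts along −ψ; ψ is the gradient of a groundwater-head
surface (tilted plane plus two smooth bumps, head high in the south-east),
so the plume drifts down-gradient toward the north-west at speed ≈ 0.5.
Defaults: diffusion D = 0.004, initial condition a Gaussian release of
amplitude 100 and sd 0.04 at (0.75, 0.25).  The initial plume is deliberately
narrower than the spline resolution of the default 14×8×5 basis: persistent
lack of fit concentrated near the source is what makes data-hungry
selectors undersmooth on sparse designs, the phenomenon the scenario
exists to exhibit.

**Solver.**  Explicit finite differences: conservative central diffusion
(ghost node equals edge value, which makes the pure-diffusion scheme
exactly mass-conserving) and first-order upwind advection, sub-stepping
under the CFL-style bound dt ≤ 0.8/(4D/h² + max|ψ₁|+|ψ₂|/h) with automatic
refinement and a blow-up check.  The solution is stored on a 100×100×100
regular grid and interpolated trilinearly.  Boundary conditions, scheme and
initial shape are configuration with these documented defaults.  Verified
against closed forms: mass conservation (machine precision), the spreading
heat kernel (≤1% interior error), and centroid drift at −ψ (within one
cell).

**Monitoring designs.**  One fixed reference network (the design seed is a
package constant), mirroring how a real site's network is fixed:

- scenario 1 — 29 wells (12 crowding the source, 8 along the plume track,
  9 jittered guard wells on the site perimeter, leaving large hull-interior
  areas unsupported), 1402 samples;
- scenario 2 — 280 uniformly placed wells, 1402 samples (statistically
  comfortable, economically unrealistic);
- scenario 3 — the scenario-1 wells with only 100 samples (~3.4 per well).

Sample dates follow 80 shared site-wide campaigns; each well is sampled on
its own irregular subset, so wells share dates the way real monitoring
rounds do.  The reference layout was chosen (from seeded draws of the same
clustered process) for a realization that genuinely exhibits the
sparse-design geometry scenario 1 represents; a draw that happens to cover
space uniformly would misrepresent the scenario.

**Noise.**  Multiplicative: raw = signal·exp(u_w + e_i), with the log-scale
standard deviation set to SD(log-signal)/SNR (SNR 10:1), split into a
shared per-well effect (fraction ρ = 0.05 of the variance; exchangeable, the
simplest structure consistent with a single stated correlation) and
independent error.  Exact zero concentrations stay exactly zero — the
log(y+1) offset exists for them.

**What the generator does not emulate.**  Censored/non-detect values,
laboratory changes and trends in measurement quality, seasonal water-table
movement (the flow field is static), vertical structure, and
sorption/degradation chemistry.  Passing tests therefore demonstrate the
selector behaviour under idealized transport with realistic sampling
geometry, not performance on any particular real site.

## Evaluation

Fitted surfaces are scored on the transformed scale by the integrated
squared error ∫∫∫ (m̂ − m)² over the convex hull of the wells crossed with
the sampled time range, computed as a trapezoid-weighted sum on a regular
grid (default 50×50×20 for the comparison pipeline; halving the spacing
changes smooth ISEs by well under 2%).  Hull membership uses the closed
hull (facet half-plane tests with tolerance).  In the replicate-level
comparison all selectors score the identical noisy dataset (checksummed),
with the truth field and design fixed and only measurement noise
re-drawn.

Validation studies in the test suite use 50 replicates for the selector
comparison and deletion-stability studies (evaluation grid 40×40×15) and
200 replicates of a 250-observation fit for interval coverage; these sizes
give stable Monte-Carlo estimates of the orderings while keeping a full
run to a couple of minutes.  On the reference sparse design, the MAP λ
exceeds the AICc choice in essentially every replicate, mean ISE under
AICc/GCV is roughly double that of the Bayesian selectors, MAP and full
model averaging agree within a couple of percent, well-based CV selects
larger λ than observation-based CV, and deleting four low-concentration
wells moves MAP predictions less than AICc predictions — the stability
that motivates the Bayesian selector.

## Limitations

- Gaussian responses on the transformed scale only; no censoring support
  (inputs with non-detects must be pre-imputed, and negative results are
  rejected at parsing).
- A single global smoothing parameter; strongly anisotropic smoothness
  beyond what basis-count ratios can absorb is out of scope, as are
  MCMC-based non-conjugate extensions.
- The dense eigendecomposition bounds practical model sizes to a few
  thousand coefficients; the guardrail reflects this.
- Scenario realism is qualitative: the reference design reproduces the
  geometry class (clustered wells, shared campaigns, unsupported hull
  regions), not any specific site.
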