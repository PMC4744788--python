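# plumespline

Fully automatic Bayesian P-spline smoothing for irregular spatiotemporal
monitoring data, built for groundwater-contamination surveillance: networks
of monitoring wells sampled at irregular dates, analysed by staff who need
robust concentration surfaces without hand-tuning a smoother.

## The problem and the model

Concentrations y_i measured at well locations (s1_i, s2_i) and times t_i are
modelled, on the log(y+1) scale, as

    y = B α + ε,        ε ~ N(0, σ² I_n)

where B is the tensor-product B-spline design matrix: row i holds the
products φ_j(s1_i) φ_k(s2_i) φ_l(t_i) of three marginal B-spline bases on
equally spaced knots (row-wise Kronecker product, so B is sparse).
Smoothness is imposed by a first-order (optionally second-order) difference
penalty λ‖Dα‖² on adjacent coefficients in each of the three dimensions.

The smoothing parameter λ is chosen automatically from its marginal
posterior under the conjugate normal–inverse-gamma prior
α, σ² ~ NIG(0, (λD′D)⁻¹, a, b):

    f(λ | y) ∝ λ^{rank(D′D)/2} |B′B + λD′D|^{-1/2}
               [2b + y′(I − B(B′B + λD′D)⁻¹B′)y]^{-(a + n/2)}

with a = b = 10⁻⁴ and a flat prior over λ on a log grid.  Either the MAP λ
is used, or λ is integrated out numerically (model averaging).  The rank
deficiency of D is handled by splitting α into a flat-prior null-space
component and a proper Gaussian component.

A one-time decomposition (sparse null-space split, penalty whitening, one
dense symmetric eigendecomposition) makes every subsequent λ evaluation —
RSS, effective degrees of freedom, generalized log-determinant, log
posterior, coefficients — an O(m) operation, so the whole λ profile is
essentially free after the first factorization.

The classical selectors AICc, GCV, BIC and k-fold cross-validation
(observation-based or leaving out whole wells) are provided on the same
profile for comparison: on sparse well networks they are prone to
"ballooning" — spurious surface extrema in regions without data support —
which the Bayesian selector avoids.

A synthetic-data module solves the 2-D advection–diffusion equation for a
drifting solute plume, samples it under three monitoring designs (29
clustered wells × 1402 samples; 280 random wells × 1402; 29 wells × 100)
with multiplicative log-scale noise (SNR 10:1, within-well correlation
0.05), and scores fitted surfaces by integrated squared error over the
convex hull of the wells.

## Worked example

```
plumespline simulate --scenario 1 --seed 42 --out-dir run/
plumespline fit --input run/monitoring.csv --selector map \
    --output run/pred.csv --summary run/summary.json
```

which logs

```
INFO plumespline: read 1402 observations from 29 wells
INFO plumespline: wrote run/pred.csv (MAP λ = 0.0004217, edf = 116.89)
```

The fit summary reports the model actually used: n = 1402 observations,
m = 14×8×5 = 560 tensor coefficients, MAP smoothing parameter
λ = 4.2·10⁻⁴ with 116.9 effective degrees of freedom (of a possible
rank(B) ≈ 145 on this clustered design — the posterior smooths away about a
fifth of the fittable complexity), and posterior variance parameters
a_n = a + n/2 = 701.0, b_n = 6.12.  `run/pred.csv` holds the predicted
surface with pointwise 95% credible bounds and a flag marking grid nodes
inside the convex hull of the wells:

```
s1,s2,t,mean,lower,upper,in_hull
0.0292,0.0547,0,-0.000254,-0.3945,0.3940,0
...
```

Means and bounds are on the log(y+1) scale (pass `--concentration-scale`
to back-transform).  The replicate-level selector comparison behind the
same scenario is available as

```
plumespline evaluate --replicates 50 --scenario 1 \
    --selectors map,average,aicc,bic --seed 0 --out table.csv
```

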