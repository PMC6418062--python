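# Methods

## Model

ARF0 is the probability of at least one hip fracture in (just under) one
year. With `n` mutually independent falls per year and per-fall fracture
probability `P`, `ARF0 = 1 − (1−P)^n`. `P` is an integral of the fracture
indicator `χ = 1[F ≥ S]` over the joint density of the fall variables
`(θ_i, θ_f, cHθ̇_i, cHθ̈_i, η_P, η_I)` and the impact orientation
`(α′, β′)`; the subject enters through mass `m`, height `H`, the BMI-derived
soft-tissue attenuation `η_ST`, and the strength surface `S(α′, β′)`.

The force chain is deterministic given a fall realisation:
kinetic energy per unit mass `e` (inverted-pendulum energy balance),
impact velocity `u = √(2(1−η_P)e)`, unattenuated peak force
`F* = k·2mu/Δt` with `k = 0.5`, and skeletal force
`F = (1−η_I)(1−η_ST)F*`. Because `F` does not depend on orientation, the
double integral factorises: the per-orientation fall-average of `χ` is the
fraction of simulated forces reaching that orientation's strength, and `P`
is its quadrature over the uniform orientation density. The implementation
exploits this (sort + binary search per subject) and a test asserts the
two integration orders agree to 1e-12.

Assumptions inherited from the model family: falls are independent and
identically distributed within and across subjects; the fall rate is the
same for everyone; fracture is a sharp threshold `F ≥ S` (the boundary case
counts as fracture; it has measure zero under continuous distributions);
joint torques, segment dynamics and the pelvis transient are not modelled —
their net effect is absorbed into `η_P`, `η_I`, `k` and `Δt`.

## Parameters

Fixed constants (all configurable through the YAML config):

| constant | default | meaning |
|---|---|---|
| `c` | 0.554 | centre-of-mass elevation / body height |
| `Δt` | 0.09 s | impact duration (triangular pulse) |
| `n` | 0.65 /yr | annual fall rate, all subjects |
| `g` | 9.81 m s⁻² | gravitational acceleration (value not prescribed by the source model; standard choice) |
| `k` | 0.5 | impact proportionality factor |

Stochastic fall parameters are normals truncated symmetrically at ±3 SD,
fully specified by their truncation limits `(a, b)` (mean `(a+b)/2`,
untruncated SD `(b−a)/6`): `θ_i ∈ [0°, 30°]`, `θ_f ∈ [60°, 120°]`,
`cHθ̇_i ∈ [0, 1.40] m/s`, `cHθ̈_i ∈ [0, 5.10] m/s²`,
`η_P ∈ [0.500, 0.800]`, `η_I ∈ [−2.55, 0.914]`. The angular-rate
parameters are represented as the linear quantities `cHθ̇_i`, `cHθ̈_i`
because their bounds are subject-independent in that form and the energy
equation only ever consumes them that way. Angles are degrees at every I/O
boundary and converted to radians inside trigonometric code.

`η_ST` is deterministic per subject (`0.0231·BMI − 0.330`, clamped at 0),
while `η_I` is drawn per fall. The intermediate regression of skeletal
force on soft-tissue thickness (7.2 kN − 0.71·STT, equivalent to
η_ST = 0.0986·STT) is kept only as a consistency check of the direct BMI
form, not in the runtime path. Note a structural consequence: the net mass
effect on skeletal force, `m·(1−η_ST(m/H²))`, peaks near 72 kg at
H = 1.58 m, so risk is not globally monotone in body mass.

Verified numerical defaults: `N = 10⁴` Latin-hypercube falls and `M = 33`
orientation points. At these settings the sampling moment errors are below
10⁻³, and on synthetic cohorts the median ARF0 difference to an `N = 10⁵`
reference run is a few hundredths of a percentage point (see
`examples/03_verification.py`, which prints the ladders).

## Sampling

Latin-hypercube sampling is inverse-transform based: each column gets one
uniform draw per probability stratum of width 1/N, jittered uniformly
within the stratum (midpoint placement would also satisfy the verified
error bounds; jitter keeps the sample unbiased) and mapped through the
truncated-normal quantile function. A single root seed spawns independent
per-column substreams, so adding a column never reshuffles the others.

Rank correlations are induced by the Iman–Conover method on van der
Waerden scores with a Cholesky adjustment; the target is Spearman
correlation, converted to the equivalent normal-score Pearson correlation
via `2·sin(πr/6)`. For very small samples the empirical score correlation
can be singular; it is then shrunk minimally toward the identity before
factorisation. Marginals are preserved exactly (the operation only
permutes within columns).

## Orientation grids and quadrature

Supported orientation counts are rectangular lattices over
`[−30°, 30°] × [0°, 30°]`: 2×2, 5×3, 11×3, 11×6 and 21×11 (M = 4, 15, 33,
66, 231), each triangulated deterministically along the lower-left to
upper-right cell diagonal. Quadrature of a nodal field integrates its
piecewise-linear interpolant exactly: Σ triangle-area × vertex-mean,
normalised by the domain area. Because this refinement family improves the
`β′` resolution only at M = 66 and 231, the ARF0 quadrature-error ladder
is guaranteed monotone only for surfaces whose orientation structure lies
along `α′`; the error sequence for a general surface is layout- and
subject-specific.

## Surrogate strength surfaces

The CT-based finite-element strength stage is out of scope; the generator
replaces it with `S(α′, β′) = ⟨S⟩ · f(α′, β′)`, where `f` is a positive
quadratic polynomial in the normalised angles with population-mean
coefficients plus per-subject Gaussian perturbations, rescaled to unit
grid mean so `⟨S⟩` is exactly the orientation-averaged strength.
`⟨S⟩` is drawn from a normal (mean 2800 N, SD 1000 N) truncated to
[390, 6330] N — the span of strengths plausible for an osteopenic referral
population, with the upper limit at the largest strength reported for such
a cohort. The default anisotropy amplitudes (shared coefficients of order
0.1, per-subject SD 0.05) were calibrated once so that the default cohort's
ARF0 spans roughly 2–82% with median near 36%, strength is normally
distributed across subjects at most orientations, and nearly all subjects'
surfaces correlate at r ≥ 0.5 with the population-mean surface. All of
these are config-exposed (`SurfaceGenParams`).

What the generator does **not** emulate: real inter-orientation strength
ratios (the quadratic shape family is a convenience), CT acquisition noise
(the ±3% strength uncertainty appears only as the `s̃_S` input to the
uncertainty band), and any dependence of bone quality on age or BMI beyond
the prescribed weak rank correlations. Tests passing on synthetic cohorts
therefore demonstrate correctness of the machinery and of the model's
internal structure, not clinical accuracy on real patients.

## Synthetic cohorts and labels

The cohort generator draws mass, height and age per group from ±3 SD
truncated normals matching the pair-matched case/control summary
statistics (49 + 49 subjects), induces the rank correlations
r(m,H) = 0.429, r(m,⟨S⟩) = 0.264, r(H,⟨S⟩) = 0.294, and builds a surface
per subject. Fracture labels are synthetic by construction: each subject's
label is Bernoulli in their own ARF0, then the case count is balanced to
exactly half the cohort (uniform demotion of excess cases, risk-weighted
promotion of controls). This guarantees an imperfect, tunable signal —
AUC < 1, increasing with the strength variance — which is what the
validation statistics need; the subject's `group` field mirrors the final
label. Real labels are clinical outcomes and carry information no
generator can reproduce.

## Sensitivity analysis and uncertainty bands

Independent-input first-order Sobol indices use the Saltelli radial
estimator, `S_i = mean(f_B·(f_ABi − f_A))/Var(Y)`, at (d+2)·N model
evaluations. Correlated-input indices use an Iman–Conover correlated
sample and the binned conditional-expectation estimator
`Var[E(Y|X_i)]/Var(Y)` (equal-count bins, default 50); with the identity
correlation this agrees with the Saltelli estimator within estimator
noise. A frequency-domain estimator for correlated inputs would be a
drop-in alternative; the binned estimator was chosen for transparency and
is validated against the analytic additive-model decomposition.

Screening keeps the smallest prefix of descending indices whose sum
reaches 80% (ties broken by name). For the skeletal-force screening the
soft-tissue attenuation is held at a fixed reference value (0.26): it is a
deterministic per-subject regression rather than a measured stochastic
input, and letting it track BMI over the wide screening mass range
cancels the mass effect entirely, contradicting the established result
that mass is a primary driver of hip impact force. With the fixed value
the screening reproduces the expected pattern (`η_I` dominant, then `m`).

The location-independent uncertainty band is
`s̃ = √(Σ s_X²) · (⟨Y⟩_max − ⟨Y⟩_min)/|X_max − X_min|`, with bin-mean
extrema over a 10×10 regular grid in the sensitive-input space and
extremum locations reported as bin centres. **All angle-valued quantities
enter in radians** — both the measurement uncertainties `s_X` and the
coordinates in the Euclidean distance; using degrees changes mixed-unit
bands by a few percent and is wrong on dimensional grounds.

## Numerical choices and degenerate inputs

- Truncated-normal variance uses the closed form
  `σ²·(1 − 6φ(3)/(Φ(3)−Φ(−3))) ≈ 0.97334·σ²`, cross-checked against an
  independent library implementation in tests.
- The kinetic-energy expression is clamped at zero with a warning; no
  parameter combination within the default ranges can reach it.
- Quantile inputs must lie strictly inside (0, 1); quantile outputs are
  clipped to the truncation limits to absorb floating-point overshoot.
- Monte-Carlo convergence reports use an independently seeded reference
  run (not a superset of the smaller samples).
- The Youden-optimal ROC threshold is searched over midpoints between
  adjacent observed scores, ties resolved toward higher specificity.
  AUC confidence intervals are stratified bootstrap percentiles (2000
  replicates, seeded); sensitivity/specificity use Wilson intervals. The
  calibration test fits a univariate logistic model by maximum likelihood
  and groups fitted probabilities into risk deciles (degenerate deciles
  merged with a warning).
- Hosmer–Lemeshow degrees of freedom are `groups − 2`, floored at 1.

## Problem sizes

Default analyses run at the verified settings: cohorts of 98 subjects at
N = 10⁴ falls and M = 33 orientations (seconds on one core, thanks to the
sort/search formulation); sensitivity screenings at N = 10⁵ Saltelli
samples; the correlated ARF0 analysis at 8192 virtual subjects sharing a
1024-fall sample and the population-mean surface shape, which keeps the
conditional-variance estimate stable while the whole analysis stays under
a minute.

## Known limitations

- The surrogate strength generator is calibrated to summary statistics,
  not to anatomy; cohort-level results are engineering mirrors of the
  published cohort, not reproductions (those require CT-derived surfaces).
- Fall parameters are independent across falls and of each other; in
  reality postural and muscular attenuation are likely coupled.
- The fall rate is population-level; subject-specific fall risk is not
  modelled.
- Only first-order sensitivity indices are computed; interaction effects
  are visible only as the gap between the index sum and 1.
- Multi-year risk (accounting for ageing and bone loss) is out of scope.
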