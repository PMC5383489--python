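# Methods

## Process model

The package models a planar track observed without appreciable
measurement error at a constant time step. Writing d_t = x_t − x_{t−1}
for the displacement (degrees longitude/latitude), the movement process
is a switching correlated random walk on first differences:

    d_t | b_t  ~  N₂( γ_{b_t} T(θ_{b_t}) d_{t−1} ,  Σ ),
    Σ = diag(σ_lon², σ_lat²),

with T(θ) the rotation matrix [[cos θ, −sin θ], [sin θ, cos θ]]. The
latent state b_t ∈ {1, 2} follows a first-order Markov chain with
transition matrix A = [[α₁₁, 1−α₁₁], [α₂₁, 1−α₂₁]] and initial
distribution δ. The cross-axis noise correlation is structurally zero:
the covariance is carried as two standard deviations and a full Σ is
never materialised.

Assumptions worth stating plainly:

- **Unprojected degrees.** Coordinates are raw lon/lat; a degree of
  longitude and a degree of latitude are different distances, which the
  separate σ_lon/σ_lat partially absorb. No projection is applied, and
  tracks crossing ±180° must be unwrapped upstream.
- **Negligible location error.** There is no observation equation. For
  error-prone data (e.g. raw light-based geolocation) a state-space
  filter must be applied before this model.
- **Two states, constant switching probabilities.** No covariates, no
  third state.

## Parameters

| parameter | meaning | domain | units | study value |
|---|---|---|---|---|
| γ₁, γ₂ | persistence of speed/heading per state | (0, 1) | — | 0.80, 0.05 |
| θ₁, θ₂ | mean turning angle per state | ℝ (reported mod 2π) | rad | 0, π |
| σ_lon, σ_lat | process noise SD per axis | (0, ∞) | degrees | 0.07, 0.05 |
| α₁₁ | P(stay directed) | (0, 1) | — | 0.89 |
| α₂₁ | P(tortuous → directed) | (0, 1) | — | 0.20 |
| δ | initial state distribution | simplex | — | stationary |

State 1 is the directed state by the labeling constraint γ₁ > γ₂,
applied by relabeling after optimization (the likelihood is invariant to
a label swap, so this costs nothing and removes label switching across
replicates).

## Likelihood

The marginal likelihood is the HMM product δ′ P A P ⋯ 1 with P the
diagonal matrix of state-conditional step densities. Each factor
conditions on the previous displacement, so the first displacement has
no evaluable factor; it is treated as fixed data. With n positions there
are n−1 displacements and n−2 factors, and δ applies to the state of the
first evaluated factor. This is the only indexing under which every
factor is well defined without inventing a displacement before the
track starts; the first factor's influence is O(1) in a likelihood of
O(n) terms.

δ is tied to the stationary distribution of A by default (δ′A = δ′,
i.e. δ₁ = α₂₁/(1−α₁₁+α₂₁)): it is what the chain looks like in
steady state and saves two boundary-prone free parameters. `delta_mode`
switches to a fixed uniform (½, ½) or free estimation (one extra logit
parameter).

Numerics: the forward recursion renormalizes at every step and
accumulates log constants, so tracks of thousands of steps cannot
underflow; emission log-densities are floored at −745 (the log of the
smallest positive normal double) so a single wild step cannot propagate
−∞. The floor is part of the likelihood's definition and is applied
identically in the test oracles.

## Estimation

Optimization runs on an unconstrained working scale — logit(γ),
logit(α), log(σ), θ as-is — with scipy's L-BFGS-B (finite-difference
gradients), iteration cap 1000, relative log-likelihood tolerance 1e-10
and projected-gradient tolerance 1e-5. Default starting values are
θ = (0, π), γ = (0.7, 0.2), σ = per-axis sample SDs of the
displacements, α = (0.8, 0.2); on reported non-convergence up to four
seeded randomized restarts perturb the start (SD 0.5 on angle/logit
coordinates, 0.3 on log-σ). A fit that fails every start raises,
carrying the best point found; study code records such replicates and
excludes them from aggregates, reporting the count.

Standard errors come from the inverse Hessian of the negative
log-likelihood at the optimum (numerical differentiation, statsmodels'
`approx_hess1`), mapped to the natural scale by the delta method.
95% intervals are Wald intervals on the working scale pushed through the
monotone inverse transforms, so probability and σ intervals respect
their domains by construction. Turning-angle intervals are plain Wald
intervals on the estimate's branch, unwrapped — when θ₂ is weakly
identified they are honestly wide rather than artificially clipped.
A non-invertible Hessian (it happens when γ₂ drifts toward 0 and θ₂
becomes flat) yields NaN standard errors and a warning, never a crash.

## Decoding

States are recovered by the Viterbi algorithm (the single jointly most
probable path), with exact ties broken toward state 1. The decoded
sequence has one state per likelihood factor (n−2 of them). For export,
the state of a displacement is attached to the position terminating it,
and leading positions inherit the first decoded state so every position
is labeled. Posterior (forward–backward) state probabilities are
deliberately out of scope: the workflow is global decoding after an ML
fit.

## Simulator

`simulate_track` draws the state chain from δ and A (one state per
displacement), the first displacement from N₂(0, Σ) — its stationary law
is intractable, the choice washes out within a few steps, and the first
displacement is conditioned on rather than modeled anyway — and
subsequent displacements from the process equation; positions are
cumulative sums from an arbitrary origin (inference only sees
differences). Each track uses its own `numpy` Generator seeded
explicitly, so output is bit-reproducible, and a study collection seeds
replicate i with base_seed + i so any replicate can be regenerated
alone.

Defaults emulate the reference setting of the recovery study: 1,227
positions at a 6-hour step with the parameter table above,
representative of a multi-month marine-mammal GPS deployment. What the
synthetic tracks do *not* contain: measurement error, irregular or
gappy sampling, tidal/diel covariate structure, or behavior that
violates the two-state Markov assumption. Passing the recovery study
therefore demonstrates correctness of the estimator under its own
generative model — not robustness to the ways real telemetry departs
from it; the preprocessing module (interpolation) addresses only the
sampling-regularity gap.

## Recovery study conventions

`run_study` simulates, fits, decodes and scores n_tracks replicates and
reports per-parameter RMSE against the generating values, averages of
estimates and interval endpoints, and the state error rate. Choices a
user should know:

- **Turning-angle deviations are unwrapped by default** (the raw
  difference on the estimate's branch); `wrap_theta_deviation=True`
  wraps them to (−π, π]. With starts on the principal branch the two
  coincide in practice.
- **The error rate is pooled** (total mismatches / total decoded states,
  over converged replicates); the per-replicate mean is also reported.
  With equal-length replicates the two are identical.
- **Interval averages** skip replicates whose Hessian was singular;
  estimate and RMSE aggregates use all converged replicates.

At the default 50 × 1,227 setting the study takes ~30 s on one CPU;
this size was chosen as the smallest giving Monte Carlo noise on each
RMSE of roughly 10% of its value (RMSE/√(2·50)).

## Preprocessing

Linear interpolation per axis onto a grid anchored at the first raw
timestamp (overridable), no extrapolation, duplicate timestamps
rejected rather than averaged (the ambiguity is the user's to resolve),
and no cap on gap length — a warning fires for gaps beyond 10× the step
since interpolating through long gaps manufactures straight-line
"directed" movement.

## Known limitations

- Degrees are anisotropic in metric distance; estimates of σ and γ are
  scale-consistent but not directly comparable across latitudes.
- θ₂ is weakly identified whenever γ₂ is small: its RMSE and intervals
  are dominated by likelihood flatness, not estimator defects.
- Wald intervals can undercover for parameters near their boundaries
  (γ₂ here); profile likelihood is not implemented.
- No model selection over the number of states.
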