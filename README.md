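# trackhmm

Behavioral-state estimation for animal telemetry tracks with negligible
measurement error, via a two-state hidden Markov model whose emission
process is a correlated random walk on first-differenced locations.

## Who this is for

Movement ecologists with accurate, regularly-sampled (or regularizable)
tracks — GPS, acoustic positioning arrays, state-space-filtered
geolocation — who want to segment a track into *directed* (transiting)
and *tortuous* (area-restricted / foraging) movement and to estimate the
movement parameters of each mode, in seconds rather than the hours an
MCMC treatment of the same process takes.

## The model

Let x_t be the position (lon, lat, degrees) at regular time steps and
d_t = x_t − x_{t−1} the displacement. Conditional on a latent behavioral
state b ∈ {1, 2} governing the step,

    d_t | b  ~  N₂( γ_b T(θ_b) d_{t−1} ,  Σ ),      Σ = diag(σ_lon², σ_lat²)

where T(θ) is the planar rotation matrix, γ_b ∈ (0, 1) is the persistence
of speed and heading, and θ_b is the mean turning angle. States follow a
first-order Markov chain with transition matrix

    A = [[α₁₁, 1−α₁₁],
         [α₂₁, 1−α₂₁]].

State 1 is the directed state (γ high, θ ≈ 0); state 2 the tortuous state
(γ low, θ ≈ π); the labeling is anchored by γ₁ > γ₂. The likelihood is the
standard HMM matrix product δ′ P(d) A P(d) ⋯ 1, evaluated by a scaled
forward recursion; parameters are estimated by maximum likelihood on an
unconstrained working scale (logit/log transforms), uncertainties come
from the observed information via the delta method, and states are
recovered by Viterbi (global) decoding. See `docs/methods.md` for the
full account.

## Worked example

```python
from trackhmm import MovementHMM, simulate_track, state_error_rate
from trackhmm.study import default_study_params

truth = default_study_params()            # γ=(0.8, 0.05), θ=(0, π), σ=(0.07, 0.05), α=(0.89, 0.20)
sim = simulate_track(truth, n_positions=1227, seed=1)

model = MovementHMM(sim.diffs)
res = model.fit(seed=1)
print(res.summary())
print("state error rate:", state_error_rate(res.decode(), sim.true_states))
```

Output:

```
Two-state switching random walk (ML fit)
========================================================
n factors: 1225    log-likelihood: 3248.9150
converged: True    iterations: 37    restarts: 0
initial distribution: stationary
--------------------------------------------------------
            estimate     std err     [0.025     0.975]
theta1    -0.0247831   0.0205451 -0.0650507  0.0154845
theta2       2.39487    0.371108    1.66751    3.12223
gamma1      0.789582   0.0205863    0.74641   0.827107
gamma2      0.101724   0.0396755  0.0461226   0.209623
sigma_lon  0.0701159  0.00152617  0.0671875  0.0731718
sigma_lat   0.051093  0.00111669  0.0489506  0.0533293
a11         0.899373   0.0186744   0.856417    0.93052
a21         0.187489   0.0336611   0.130166    0.26244
========================================================
state error rate: 0.1657142857142857
```

Every generating value sits inside its 95% interval except θ₂, whose
information content is tiny when γ₂ ≈ 0.05 (the rotation acts on an
almost-zero mean); its interval is correspondingly wide. About 17% of
the 1,225 decoded states disagree with the simulated truth — switching
steps are intrinsically hard to classify from a single displacement.

The same workflow is available from the shell:

```sh
trackhmm simulate --seed 1 --n-positions 1227 --out sim
trackhmm fit sim_track.csv --seed 1 --out sealfit      # writes params/states CSVs + metadata
trackhmm prep raw.csv --step 6h --out regular          # regularize irregular data first
trackhmm study --seed 0 --n-tracks 50 --out study      # full recovery study
```

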