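# Methods

## Model

### Sensory transduction

AFD activity is the linear convolution of a Hill-transformed temperature
signal with a response kernel over the trailing 100 s:
y₁(t) = Σₖ r(k·dt) · h(T(t − k·dt)) · dt at dt = 0.1 s.  The Hill stage
h(T) = (T − T_thr)ⁿ / (K_d + (T − T_thr)ⁿ) for T ≥ T_thr (0 below) sets
the operating range; T_thr ∈ [14, 26] °C, K_d ∈ [10, 1000] (the upper
bound is a configuration default; see *Parameter ranges*), n ∈ [1, 10].
The temperature history before the assay begins is back-filled with the
worm's initial temperature, so the convolution is defined from the first
step.

The default AFD-like kernel is a difference of two exponential lobes
(fast: amplitude 1, τ = 2 s; slow: amplitude 1, τ = 25 s), with the slow
lobe rescaled so the discrete quadrature of the kernel is exactly zero.
This makes AFD a differentiator: a constant temperature yields a response
below 10⁻¹⁰, while ramps produce sustained responses whose sign follows
dT/dt.  The AWC-like variant flips the slow lobe's sign (both lobes
positive), giving an integrator-like response.  These are parametric
stand-ins for empirically measured kernels, which are not distributed with
this package; their shape parameters are configuration values.

### Circuit dynamics

Nodes AIB, AIY, AIZ, DMN, VMN follow first-order nonlinear dynamics
(equation in the README) with τ = 1 s, fixed — the time constant is not
part of the evolved parameter set — and forward-Euler integration at
0.1 s.  β₇ (the CPG bias) is fixed at 0 since the CPG output already spans
[−1, 1]; the six evolved biases belong to AFD through VMN.  The default
wiring carries 10 chemical edges (AFD→AIB, AFD→AIY, AIB→AIY, AIY⇄AIZ,
AIB→AIZ, AIZ→DMN, AIZ→VMN, AIB→DMN, AIB→VMN) and 2 gap junctions
(AIB↔AIY, AIY↔AIZ): exactly 12 evolvable connection weights, plus the
shared CPG→motor weight and the neuromuscular weight.  The edge list is
configurable; the count is what the genome layout relies on.

Ablating a node clamps its potential to 0 and removes its outgoing
chemical and gap influence.  The oscillatory-noise perturbation injects an
additive sinusoid (configurable amplitude; period from t_OSC up to
10·t_OSC) into the input of AIY or DMN.

### Steering kinematics

The signed curving rate ψ (deg/s) from the motor pair is applied through
the worm's dorsoventral anatomy.  Internally the simulator advances the
*lab-frame* heading by dα = handedness · ψ · dt (handedness = ±1, fixed
per worm at initialization: a dorsal-ward bend turns left for a
dorsal-left worm).  For the unsigned gradient-relative direction θ this is
exactly dθ = DV·ψ·dt with DV = sign(handedness · sin θ_signed), i.e. DV =
+1 when the dorsal side faces the cold direction — the recorded DV uses
that convention (ties break to +1).  Formulating the update in the lab
frame makes mirror symmetry exact: flipping handedness under an identical
ψ sequence reflects the trajectory about the gradient axis.

Between turns the worm advances v·dt along its heading (v = 0.2 mm/s on
the 14–20 °C plate, 0.3 mm/s on 20–26 °C; evolvable in extended mode).
Plate borders reflect specularly (position overshoot and heading mirrored
about the violated wall; corners reflect in both axes).

## Synthetic data

The generator emulates the *structure* of empirical turning statistics,
not any particular dataset:

- **Turn rates** (per second, 4 turn classes) over 18 θ-bins × 3 plate
  regions (fractions 1–2, 3–6, 7–8) × 3 time bins (10-min thirds):
  base + amplitude · (1 − cos θ)/2, i.e. monotone increasing in θ for the
  positive mode.  Base rates (0.003, 0.004, 0.003, 0.002)/s and amplitudes
  (0.015, 0.010, 0.010, 0.005)/s give a turn every ~80 s when heading
  warm-ward and every ~19 s when heading away — klinokinesis-scale rates.
  Mild region/time factors and a seeded ±5% per-cell jitter provide index
  structure without breaking θ-monotonicity.
- **Exit directions** Φ per class: 10° bins with weights
  1 + κ·cos Φ (κ = 0.6, 0.3, 0.2, 0.4 per class), biased toward the
  destination; uniform in the gradient-free control.
- **Curving-bias profile** φ(θ) = 1.5·sin θ deg/s (positive mode).
- **Turn displacements** default to (0, 0) mm with a one-step turn
  duration; magnitudes are not derivable from anything shipped here and
  are exposed in the configuration.

Negative mode is the exact mirror under θ → 180° − θ (with the bias
profile negated); gradient-free mode is θ-independent.  The data-based
steering policy draws φ from the bias profile plus Gaussian noise
(sd 3 deg/s) — the spread keeps headings realistically diffuse.

What the generator does *not* emulate: temporal correlations between
events (events are sampled independently per step), turn-duration
kinematics, speed fluctuations, and worm–worm interactions.  Passing tests
therefore demonstrate that the pipeline recovers the structure the
generator encodes, not that it would reproduce any particular laboratory
dataset.

## Analysis

Positions are smoothed with a moving mean spanning exactly one undulation
period (4.2 s; at 0.1 s sampling the 42-sample boxcar nulls the body-wave
frequency exactly; the window shrinks at series ends rather than
discarding frames).  The moving direction θ(t) is the angle of
centroid(t)→centroid(t+1 s); steering curvature Ψ(t) is the unsigned angle
between the directions at t−1 s and t; curving bias φ is Ψ signed positive
when |θ| decreased.  Frames within ±4.2 s of a turn are excluded from
curvature statistics, as are frames within 0.3 cm of a plate wall —
specular reflections flip the heading and would otherwise dominate the
bias profile once worms accumulate at the warm border.

The thermotaxis index is Σₖ cₖ·(occupancy of fraction k) with
cₖ = (2k−9)/7: −1 for the coldest eighth, +1 for the warmest.  The exact
weighting used in plate assays varies between laboratories; this linear
antisymmetric form preserves the sign and normalization semantics the
fitness needs and is configurable.

## Evolutionary search

Real-coded generational GA: tournament selection (size 3), uniform
crossover (per-gene exchange probability 0.5), per-gene Gaussian mutation
(probability 0.1, sd 5% of the range), elitism 1, all genes clamped to
their boxes.  Fitness = F_ttx · F_bias with
F = max(0, 1 − mean|deviation|/S); S_ttx = 2 (the full index range) and
S_bias = 2·max|φ_ref|.  Only θ-bins actually visited by the model worms
enter the bias term.  Assays within one generation share a seed so
individuals face the same noise realization; the seed changes each
generation to prevent overfitting a single realization.  The per-
generation log records the generation best and the running best-so-far
(non-decreasing by construction).

Desk-scale defaults — population 16, 30 generations, fitness assays of 12
worms × 240 s, references from a 100-worm data-based assay of the same
duration — keep a full search around 20 s after JIT warm-up.  The
full-campaign scale (96 × 300, 100-worm 30-min assays, hundreds of
independent runs) uses the same code via `SearchConfig`.

## Decomposition and dependence

SSA embeds a motor-neuron series in a Hankel matrix with a 4 s window
(40 samples at dt = 0.1 s) and takes its SVD.  A spectrum with coefficient
of variation below 0.2 is classified "constant" (the threshold is a
configurable stand-in for visual classification); its magnitude series
carries the slow, non-oscillatory content.  Magnitude samples are
time-stamped at their window centers for pairing with y₁(t) and Ψ(t).
SSA is applied per channel (y₅, y₆ separately); no multichannel stacking.

Mutual information uses average shifted histograms on a 50-bin grid with
12 shifts applied to both dimensions in lockstep, which keeps
deterministic relations on the grid diagonal (an identity channel loses
nothing to smoothing).  The plug-in estimate carries a positive
small-sample bias, so a permutation baseline (mean plug-in MI after
shuffling one variable, symmetrized over both argument orders; 2
permutations, fixed seed) is subtracted and the result clipped at zero.
Setting `bias_permutations=0` recovers the plain plug-in estimator.
Measured behavior at n = 10⁴: independent uniforms < 0.01 bits, identity
channel within 2% of the marginal entropy, exact symmetry, ~1% drift
under monotone rescaling.  Units are bits by default (the logarithm base
is configurable).

## Numerical and engineering choices

- The circuit-policy assay loop is JIT-compiled (numba) with all random
  numbers pre-drawn from the numpy Generator, so results are a pure
  function of the seed; interpreted vectorized paths serve the data- and
  profile-policy assays.
- Every stage derives its randomness from one master seed through named
  SHA-256 substreams; manifests record seed, configuration, and a config
  hash, and replaying a manifest reproduces outputs bitwise.
- Event probabilities are per-second and rescaled by dt, keeping rates
  invariant across the 1 s (data/profile) and 0.1 s (circuit) cadences.
- Degenerate inputs: constant series return 0 mutual information and
  raise for Pearson correlation; trajectories shorter than the smoothing
  window yield empty analyses; off-plate temperature queries raise rather
  than extrapolate.

## Known limitations

- Worms are dimensionless points: no body mechanics, no collisions, no
  posture; turn displacement defaults of (0, 0) understate the spatial
  footprint of real turns.
- The TTX fraction weighting and the wall-exclusion margin are declared
  analysis choices, not measured properties.
- A single desk-scale evolution finds *a* well-fitting circuit, not the
  ensemble a 200-run campaign characterizes; qualitative properties of
  one evolved model (e.g. the ramp-response sign pattern) are reported
  rather than asserted.
- Isothermal tracking and chemotactic "surfing" are outside the model's
  scope.
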