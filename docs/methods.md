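# Methods

## Problem

When a gripper (or a texture-analyzer probe) compresses a ripe tomato by a
fixed amount and holds, the contact force decays over tens of seconds:
stress relaxation. The decay law depends on fruit size and on whether the
probe sits over a locule (seed cavity) or a septum (radial wall), which is
why a single classical constitutive fit generalises poorly across fruit.
This package provides (i) a synthetic-data generator emulating the standard
instrument protocol, (ii) two classical relaxation models with
least-squares calibration, (iii) a from-scratch stacked-LSTM sequence
regressor, and (iv) the evaluation harness that compares them.

## Constitutive models

Both models give the relaxation stress under a constant imposed strain
ε₀ = D/(2R), where D is the imposed deformation and R the fruit radius.

**Triple-element Maxwell** (two Maxwell arms in parallel with an
equilibrium spring):

σ(t) = [E₁·e^(−t/T₁) + E₂·e^(−t/T₂) + E₀]·ε₀

E₀ is the equilibrium modulus (MPa), E₁/E₂ decay moduli (MPa), T₁/T₂
relaxation times (s). Five free constants; σ(t→∞) = E₀·ε₀. Labels are
reported in the canonical order T₁ < T₂.

**Caputo fractional derivative** (one fractional viscous element):

σ(t) = χ_α/Γ(1−α) · t^(−α) · ε₀

χ_α is the relaxation modulus (MPa), α ∈ (0,1) the fractional order. Two
free constants; power-law decay, singular at t = 0 (all curve times are
strictly positive — the first sample sits one sampling interval into the
hold). σ(2t)/σ(t) = 2^(−α) for any t.

Default population values used by the generator (ripe tomato, literature
means ± SDs): E₀ = 0.222 ± 0.0168, E₁ = 0.0681 ± 0.00799,
E₂ = 0.0816 ± 0.0144 MPa, T₁ = 0.355 ± 0.0517, T₂ = 8.672 ± 0.353 s;
χ_α = 0.388 ± 0.025 MPa, α = 0.072 ± 0.0012.

### Calibration

`fit_maxwell`/`fit_caputo` minimise the pooled sum of squared stress
residuals (each curve with its own ε₀) with `scipy.optimize.least_squares`
(trust-region reflective, bounds: all Maxwell constants ≥ 1e−8,
T ≤ 10 × hold duration for identifiability on a finite window;
α ∈ [1e−4, 1−1e−4]). Starts are data-driven — E₀ from the tail mean and
log-linear fits of the residual for the exponential arms; the log–log
slope for α — with up to five seeded log-normal-jittered restarts.
Noiseless self-generated curves are recovered to ~1e−7 relative. Per-fruit
fits feed mean ± SD summary tables; a pooled global fit per family is what
enters the model comparison.

## Hertz contact conversion

Force is converted to stress via sphere-on-flat Hertz contact,

E = 3F(1−μ²)/(4·D^1.5·R^0.5),  ε = D/(2R),  σ = E·ε,

with F in N and D, R in mm so σ comes out in MPa (N/mm²). μ is Poisson's
ratio, default 0.49 (near-incompressible plant tissue). The generator uses
the exact algebraic inverse, F = 8σ·D^0.5·R^1.5/(3(1−μ²)), so the
round trip is exact to floating point.

## Synthetic-data generator

The generator emulates the instrument protocol: loading at 1 mm/s to a
1 mm deformation, a 60 s hold sampled at 20 Hz (1200 relaxation samples),
a 0.49 N contact trigger. Per fruit, ground-truth constitutive parameters
are drawn component-wise from normal laws around the population means with
the published SDs (scaled by `param_scale`; negative draws are resampled,
not clipped, to preserve the shape near the mean). Probe position enters
as one multiplicative factor on all elastic moduli (default 1.3 for the
septum — the radial wall reads stiffer than the seed cavity; the effect is
qualitative in the field, so a single configurable factor is the simplest
faithful encoding). Fruit radii are drawn uniformly within configurable
size bands (defaults: large 38–44, medium 32–38, small 26–32 mm —
plausible for a Provence-type tomato; only the ordering matters
downstream). Measurement noise is additive Gaussian on force with SD
defaulting to 0.5% of the fruit's initial relaxation force — small enough
to keep percentage errors meaningful, large enough that fits are not
trivially exact. The default population mixes the two constitutive
families half and half within each group: real fruit are neither exactly
exponential nor exactly power-law, and both families describe the same
measured curves in the literature, so a mixture is the least-committal
population. Loading and unloading segments are synthesized only so
trimming has something to remove; their shape (linear ramp from the
trigger, short exponential tail) is deliberately simple and non-physical.

What the generator does *not* emulate: probe-edge shearing, slippage,
ripeness heterogeneity, temperature effects, non-Gaussian instrument
noise, or any within-hold drift of material properties. Passing tests
therefore demonstrate correctness of the pipeline and the qualitative
model ordering under idealised conditions, not instrument-grade realism.

## Preprocessing

Stage trimming keeps the relaxation block and re-zeroes time so the hold
starts at 0 with the first retained sample one sampling interval later
(the fractional model is singular at 0; an on-grid time origin keeps every
retained sample strictly positive). Each feature (time t, force f, strain
ε, stress σ) is min–max normalised to [0,1] over the whole dataset by
convention (a train-only reference is available via `normalize_on:
train`); values outside the reference range pass through unclipped, and a
constant feature is stored as a passthrough. The 80/20 split is stratified
by (size class, probe position), so every cell appears in the test set.

## LSTM sequence regressor

Architecture: an affine input layer I₀ = W_in·[t,f,ε]ⁿᵒʳᵐ + b_in, two
stacked LSTM units (unit 1 consumes I₀; unit 2 consumes unit 1's hidden
state), and an affine output layer mapping unit 2's hidden state to the
normalised stress at every step. Cells use the standard
forget/input/output gates (sigmoid) and tanh candidate; hidden and cell
states start at zero each sequence. The loss is the MSE over (masked)
steps; gradients are exact backpropagation through time, written by hand
in numpy and validated against central finite differences (the module's
defining test: max relative deviation < 1e−5 on a seeded instance, which
is the finite-difference noise floor).

Training: mini-batches of whole sequences (batch size min(128, #sequences);
padding masked in the loss), one full shuffled pass per epoch, step-decay
schedule lr(e) = lr₀ · 0.9^⌊e/period⌋. Defaults are the tuned operating
point: 48 neurons, lr₀ = 0.008, drop period 90, 850 epochs.

Two optimisation choices matter and were made deliberately:

* **Forget-gate bias initialised to 1** (other biases 0, weights seeded
  uniform Glorot). The unit-forget-gate convention starts the cell in a
  remembering regime and is standard practice.
* **Classical momentum 0.9** in the update (v ← 0.9·v + g;
  w ← w − lr·v), the standard companion of step-decay SGD training.
  With whole-sequence batches there are only ~2 updates per epoch, and
  the readout problem on the gated states is badly conditioned (the
  states are small and collinear): plain first-order steps at lr ≤ 0.009
  stall at roughly the variance of the per-fruit stress levels, while
  momentum converges to a normalized MSE of ~1e−3 over 850 epochs.
  `momentum=0` in `LSTMConfig` recovers the plain update; `sgd_step`
  itself is the plain descent step.

All stochasticity (init, shuffling) flows through one seed; identical
configurations give bit-identical training histories.

Caveat on inputs: force f at prediction time is, through the Hertz
relation, an affine function of the target stress for the same fruit, so
the regression task contains an information leak by construction. The
package implements the stated inputs verbatim; the comparison with
classical models remains informative because those models cannot use f at
all once calibrated.

## Evaluation

RMSE (MPa) and MAPE (%) over pooled test points; MAPE is scale-free and
drives qualitative ordering, with RMSE reported alongside. The three-model
comparison scores the trained LSTM and the two globally fitted classical
models on exactly the same strided test grid; the per-fruit report breaks
the LSTM down by (size, position) cell, with absent cells marked
explicitly rather than zero-filled. Sweeps vary one hyperparameter at a
time around the base configuration (grids: neurons 40–60 step 4, lr
0.001–0.009 step 0.001, drop period 70–90 step 2, epochs 400–900 step 50)
and select by minimum test RMSE with MAPE as tie-break.

## Problem sizes

The standard experiment is 210 fruit (35 per size × position group), 60 s
holds at 20 Hz. For modelling, curves are strided in time by 10 (an
effective 2 Hz grid, 120 steps per sequence): both relaxation laws are
smooth and slow beyond the first second, so the stride preserves curve
shape while keeping the pure-numpy BPTT affordable on a single CPU; all
models are fitted and scored on the same strided grid, so comparisons are
unaffected. At this size the full pipeline (generation, classical fits,
850-epoch training, evaluation) takes a few minutes on one core.

## Numerical notes and limitations

* Sigmoid is evaluated in a branch-stable form (no overflow up to |x| ≈ 1e3).
* Maxwell label-switching (T₁↔T₂) is resolved after convergence by
  canonical reordering, not by constraints during optimisation.
* A constant curve drives the exponential arms to the lower bound (1e−8),
  recovering the pure-elastic limit.
* The split requires ≥ 5 fruit per stratum so the test stratum is nonempty.
* Degenerate normalisation (constant feature) warns and passes through.
* No gradient clipping by default (`clip_grad` exists for experiments);
  no early stopping — a fixed epoch count is part of the protocol.
* The comparison uses a single split, no cross-validation, and no
  significance testing between models; observed orderings are seeded,
  single-realisation results.
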