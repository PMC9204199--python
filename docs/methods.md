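# Methods

## The plant: a lumped-parameter rat cardiovascular model with baroreflex

The controlled system is a closed-loop circulation driven by a time-varying
elastance left ventricle:

* **Circulation.** Three volume compartments — left ventricle, systemic
  arterial compliance `C3`, venous compliance `C2` — connected in a ring:
  ventricle → aortic valve (`R3`, with outflow inertance `L`) → arteries →
  systemic resistance (`R1`, autonomically modulated) → veins → mitral valve
  (`R2`) → ventricle. Compartment pressures follow `P = E (V − V_d)`; flows
  follow `Q = ΔP/R` with ideal-diode valves; volumes follow the mass balance
  `dV/dt = Q_in − Q_out`, so total blood volume is conserved exactly.
* **Ventricular elastance.** The double-Hill shape
  `E(t_n) = E_min + a (E_max − E_min) · h₁(t_n/α₁T) · h₂(t_n/α₂T)` with
  `h₁(x) = xⁿ¹/(1+xⁿ¹)`, `h₂(x) = 1/(1+xⁿ²)`, shape constants
  α₁ = 0.3, α₂ = 0.5, n₁ = 1.9, n₂ = 21.9 and amplitude `a` normalised so
  the peak reaches `E_max`. `E(0) = E_min` exactly.
* **Baroreflex.** Arterial pressure is low-pass filtered (τ_p = 1 s) and
  mapped through a sigmoidal afferent firing curve (floor 2.52 Hz, ceiling
  47.78 Hz, width `k_a`). Sympathetic efferent firing decreases
  exponentially with afferent firing; vagal efferent firing increases
  sigmoidally. Three sympathetic effectors (heart-period contribution
  `T_es`, end-systolic elastance, systemic resistance) relax first-order
  (τ = 1 s, delay 0.3 s) toward `θ0 + G·ln(max(f_es − f_es,min, 1))`; the
  vagal heart-period contribution `T_ev` relaxes (τ = 0.5 s, delay 0.1 s)
  toward `T0 + G_Tev · f_ev`. The heart period combines additively,
  `T = T_ev + T_es − T0`, is clamped at 0.05 s, and updates at cycle
  boundaries.
* **Stimulation.** A command is (pulse width, pulse frequency) at three cuff
  locations. Recruitment saturates with pulse width,
  `F(Pw) = (Pw/k_w)²/(1+(Pw/k_w)²)` with `k_w = 0.2 ms`, and the induced
  rate change scales identically with frequency (`k_f = 20 Hz`). A 3×3
  concentration matrix `C` mixes locations into the three fiber types, and
  `Δf_j = (G_j/3) Σ_i δ_i C_ij F(Pw_i) ΔR(Pf_i)` adds to the baroreceptive
  afferent (j = 1), sympathetic efferent (j = 2) and vagal efferent (j = 3)
  firing. In the baseline plant `C` is the identity (each site recruits one
  fiber type) with gains `G = (30, 30, 30)` Hz.

Integration is fixed-step RK4 at `dt = 10⁻⁴ s` (deterministic and fast well
below every model time constant); transport delays are ring buffers sampled
at the integration step; per-cycle outputs are HR = 60/T of the completed
cycle and the time-averaged arterial pressure over that cycle. The stepping
kernel is numba-compiled and batched over independent trials.

### Calibration and the two printed operating points

The published parameter set fixes the circulation constants, efferent gains
and intrinsic heart period for the healthy and overactive-sympathetic
variants, but the upstream model's remaining constants (unstressed and
total volumes, baroreceptor and efferent-map shapes, time constants,
delays, minimum sympathetic firing) are not recoverable. These were fixed
once, at design time, by anchoring the model to its four printed resting
values: the healthy plant must rest at 409 bpm / 138 mmHg and, after the
diseased substitutions (and nothing else), at ≈452 bpm / ≈152 mmHg. Most
shape constants follow the classical baroreflex lineage; the afferent
sigmoid width `k_a = 140 mmHg` was selected by a one-dimensional sweep so
the diseased point emerges correctly, and `calibrate()` then refines only
(total blood volume, afferent midpoint pressure) against the healthy pair
by a two-dimensional root find (steady state simulated for 200 cycles per
evaluation).

Two caveats are worth recording. First, taken at face value the printed
resistances/compliances/elastances imply non-physiological absolute flows
and volumes (cardiac output in l/s for a rat); the model is therefore
treated as a dynamical system anchored to the printed HR/MAP operating
points, not as an anatomically faithful rat. Second, the resulting
baroreflex is deliberately shallow (wide afferent sigmoid): a steeper
afferent curve makes the pressure loop gain — which scales with the very
large cardiac output — oscillatory, and compresses the diseased pressure
shift far below the printed 152 mmHg.

## The surrogate: a small recurrent network

The surrogate maps the previous cycle's (HR, MAP) and the current command
6-vector to the next cycle's (HR, MAP), all in normalized units
`x̂ = (x − μ)/(x_max − x_min)` with statistics from the training split only.
The reference configuration is a single LSTM layer of hidden dimension 10
with tanh activations and a dense tanh output of dimension 2 (≈850
weights), trained with Adam on mean-squared error; simple-recurrent and GRU
cells and deeper/wider stacks are available for architecture comparison.
Cells, backpropagation through time and Adam are implemented directly in
numpy — at this size a framework would be slower than the array code.

Training data are open-loop trials: 100 cycles of constant stimulation from
the calibrated resting state, commands sampled uniformly (pulse width
0–0.5 ms, frequency 0–50 Hz, each location on with probability ½), split
40/20/40 by trial. Training has two phases:

1. **Teacher forcing** on one-step pairs, learning rate 3·10⁻³ decaying
   within the phase.
2. **Free-running fine-tuning**: the model's own predictions are fed back
   and gradients flow through the rollout. Batches alternate between full
   rollouts from the trial start (length ramped 24 → 49 → 99) and short
   12-cycle windows anchored at random mid-trial positions after a
   teacher-forced state warmup (gradient truncated at the anchor). The
   short windows match how the controller actually uses the model — a
   10-cycle prediction from a measured state — and measurably reduce
   steady-state prediction bias; the full rollouts maintain 99-step
   stability. Gradients are norm-clipped at 5.

Training commands are augmented with the device model's exact null set:
a site contributes nothing whenever its pulse width *or* its frequency is
zero, so a trial recorded with a site off at (0, 0) is re-labelled, for a
random half of such sites, with a random point on that null set
((0, pf) or (pw, 0)). The sampling protocol itself never visits these
lines, but the sparsity-promoting controller drives single components to
zero and will otherwise exploit the model's unconstrained (phantom)
sensitivity there.

Accuracy is reported as normalized mean absolute error (MAE) of recursive
99-cycle rollouts on held-out trials, against a persistence baseline that
repeats the initial value. Because the output layer saturates at ±1,
training refuses datasets whose normalized targets leave [−0.9, 0.9].

## The controllers

At each cardiac cycle the controller minimizes, over the next `N_c`
command 6-vectors (held constant beyond `N_c`, box bounds 0–0.5 ms /
0–50 Hz), a cost on the surrogate's `N_p`-cycle predicted trajectory, and
applies only the first optimized move. All optimization is in normalized
space: outputs through the surrogate's statistics, inputs scaled by the
per-channel training span so that "off" is exactly zero — this makes the
printed weights (λ = 10⁻³ etc.) commensurate between tracking and input
terms, and is required anyway because the network only sees normalized
quantities. Costs:

* **sparsity** — quadratic tracking + λ Σ‖u‖₁ (λ = 0.001, N_p = 10,
  N_c = 5); the L1 term drives unused sites to zero, a continuous stand-in
  for integer location selection. |x| is smoothed as √(x²+10⁻¹²) for the
  gradient-based solver.
* **min_energy** — tracking + λ Σ uᵀRu (identity Q, R).
* **min_overshoot** — sparsity cost + λ₂ Σ‖u − u(k−1)‖₁ (λ₁ = 0.001,
  λ₂ = 5·10⁻⁵), penalizing deviation from the previously applied action.
* **offset_free** — for plants that differ from the one the surrogate was
  trained on. The model is augmented with an integrating output
  disturbance, `f_aug = f_NN + d`, updated as `d ← d + L_d ∘ (y_meas −
  ŷ_aug)` (the standard innovation form; the estimate converges
  geometrically on a constant mismatch for 0 < L_d < 2, and `d(0) = 0`).
  The decision vector adds a steady-state pair (u_s, ŷ_s) — 68 variables at
  N_c = 10 — with the zero-offset terminal conditions `ŷ_s = r` and
  `r = f_NN(ŷ_s, u_s) + d` as equality constraints, and the cost tracks
  (ŷ_s, u_s) instead of r. Pinning `ŷ_s` to the target is essential with a
  neural model: with the one-step constraint alone the optimizer can
  satisfy it at out-of-distribution (ŷ_s, u_s) pairs where the network
  output is meaningless. Gains L_d = (0.06, 0.05) for the intra-patient
  plant and (0.06, 0.018) for the overactive-sympathetic plant.

Problems are solved with SLSQP (tolerance 10⁻⁵ / 50 iterations for healthy
scenarios, 10⁻⁴ / 500 for mismatch scenarios). Cost gradients are supplied
as batched forward differences — one batched rollout evaluates all
perturbed candidates simultaneously — which keeps a solve in the
millisecond range. Because the surrogate makes the cost landscape
non-convex, each solve is seeded by a global pre-screen: 64 constant move
sequences (four activation levels per location applied to both pulse
parameters) plus the shifted previous solution are costed in one batched
rollout and the cheapest seeds the local solve. Without the pre-screen the
warm-started continuation reliably gets trapped after set-point changes.
On solver non-convergence the best feasible iterate is applied and the
loop continues.

The reference trajectory is the **current** cycle's target held over the
horizon. Previewing the future schedule makes the controller manoeuvre
several cycles before each set-point change, which contradicts the
reference closed-loop responses (movement starts at the change) and
corrupts the last-10-cycle steady-state metric.

The controller's recurrent state is advanced once per cycle with the
measured output and applied command, so the hidden state tracks the
realized trajectory; rollouts inside the optimizer start from a copy.
The closed loop reads nothing from the plant but the two measured outputs.

## Scenarios and metrics

Five named scenarios: three healthy-plant designs (sparsity, min_energy,
min_overshoot) on the schedule HR 392→346→393 bpm / MAP 111→144→125 mmHg in
50-cycle segments from the resting point (409, 138); offset-free on the
intra-patient plant (recruitment matrix C perturbed, same dynamics) over
150-cycle segments with targets (356,150), (393,129), (377,143); and
offset-free on the overactive-sympathetic plant (same targets, 300-cycle
segments, initial (452, 152)). Performance is SS-MAE: per segment, mean
|HR error| + mean |MAP error| over the last 10 cycles, averaged over
segments ("combined" error is read as the channel sum; the magnitudes in
the reference table match raw-unit offsets). A horizon sweep re-runs
scenarios across (N_c, N_p) pairs with all λ fixed at 0.001 and reports
decision-variable counts (6·N_c, +8 offset-free) and per-cycle wall time;
timings are logged, never asserted.

## Problem sizes

Simulations are desk-scale by construction. The reproduction script and
the end-to-end tests use 3 000 open-loop trials (the full-scale study used
15 198) and 1 000 training epochs (600 free-running); with those sizes the
whole pipeline — calibration, data generation, training and two
closed-loop scenarios — runs in roughly ten minutes on one CPU core, and
the surrogate reaches a recursive test MAE of ≈0.005. The unit-test suite
trains smaller surrogates (60–100 trials) for mechanics checks and
reserves the full pipeline for the end-to-end tests.

## What the synthetic data do and do not show

The generator reproduces the study conditions exactly as stated — constant
commands, 100-cycle trials, uniform sampling, fixed resting start — and the
plant is deterministic and noise-free. Passing tests therefore demonstrate
the identification and control machinery, not robustness to measurement
noise, beat-to-beat variability, electrode drift, or varied initial
conditions, none of which the upstream study modelled either (observer
design under noise is explicitly future work). The intra-patient and
diseased variants probe structured model mismatch only.

## Known limitations

* The plant is an anchored dynamical system, not an anatomically faithful
  circulation (see calibration caveats above).
* The attainable steady-state set of the reconstructed plant does not cover
  every published set point: on the intra-patient variant the pair
  (393 bpm, 129 mmHg) is ≈3 mmHg outside it (at HR ≈ 393 the reachable MAP
  floor is ≈132). This is structural: the two printed resting heart rates
  force the baseline sympathetic drive to sit ≈0.27 ln-units above the
  effector logarithm's floor, and all three sympathetic effectors share a
  single ln(f_es) drive, making HR and MAP moves nearly collinear in that
  region. The offset-free controller converges to the closest reachable
  steady state instead, and the offset-free settling times on the
  mismatched plants run 60–75 cycles rather than 50 (set by the printed
  disturbance gains).
* Plain (non-offset-free) MPC retains steady-state offsets of order the
  surrogate's local prediction bias; only the offset-free formulation
  guarantees zero offset under convergent disturbance estimation.
* The ln(·) floor in the sympathetic effector makes the plant
  non-differentiable at one firing level; the surrogate smooths over it.
* L1 sparsity is a continuous relaxation; no mixed-integer formulation is
  provided.
* No stability or terminal-set certificates; horizons and weights follow
  the printed settings.
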