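# Methods

This note documents the models and procedures implemented in `gaitprop`,
the assumptions behind the synthetic data generator, the numerical choices,
and the known limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Problem

Paretic propulsion — the anterior (positive) portion of the
anterior–posterior ground reaction force (AP GRF) during stance — is a
clinically meaningful marker of post-stroke gait, normally measured with
instrumented treadmills. The package estimates AP GRF sample-by-sample from
two wearable modalities, a pressure insole (vertical loading, spatially
resolved) and segment IMUs (kinematics), with individualized per-leg neural
models, and derives per-stride clinical point metrics from the estimate:
peak propulsion (%BW), peak timing (% of stance), propulsion impulse
(%BW·s, trapezoidal integral of the positive AP GRF region), and
propulsion symmetry (paretic share of the two-limb impulse, %).

Errors are judged against minimal-detectable-change (MDC) constants for
treadmill walking post-stroke, taken as given: 0.80 %BW (peak),
0.24 %BW·s (impulse), 3.92 % (symmetry). A strict `<` comparison is used.

## 2. Synthetic gait sessions (`synthgait`)

No public dataset pairs insole + IMU + force plates for this protocol, so
the package generates sessions with exact ground truth. The generator is
intentionally parametric — simple lobe shapes with closed-form integrals —
so downstream code can be tested against analytic oracles, not a
biomechanical simulation.

**Protocol.** Clinical bouts: 240 s, first 120 s at a constant speed v₂
(a centre in {70…130} %CWS, 10 % steps), then ramps between
v₁ = v₂ − 20 %CWS and v₃ = v₂ + 20 %CWS, each v₂→extreme ramp lasting 30 s
and each extreme held 15 s. Healthy bouts: 600 s, 180 s constant, centres
{0.6…1.4} m/s in 0.2 m/s steps, ±0.2 m/s extremes held 60 s. Bout order is
randomized per session.

**Strides.** Stride period T(v) = 1.1·(v/1.0)^−0.4 s, clamped to
[0.8, 2.0] s, with multiplicative timing noise (CV 0.02 by default); stance
occupies 62 % of the stride; the right foot starts half a period after the
left. Belt speeds below 0.05 m/s produce no strides (standing).

**Kinetics (per stride, %BW).** AP GRF is a negative half-sine braking lobe
over the first half of stance followed by a positive half-sine propulsion
lobe over the second half; the true impulse is 2·A·d/π and the true peak
timing is 75 % of stance. Vertical GRF is an M-shaped
sin(πu)·(1 + 0.3·cos 2πu) hump, zero in swing, with amplitude
(100 + 10·v) %BW. Amplitude laws: propulsion A(v) = (4 + 8·v) %BW scaled by
(1 − impairment) on the paretic side; braking (3 + 7·v) %BW. Force plates
record Newtons and are treated as a noise-free gold standard (so the
swing-phase-zero invariant is exact); the %BW conversion happens during
preprocessing using the subject's body weight.

**Shared latent factors.** Each stride draws two standard-normal latents:
a *kinematic* latent z_k (visible in the IMU as a pitch-range multiplier
1 + 0.08·z_k) and a *loading* latent z_l (visible in the insole via the
vertical-GRF amplitude multiplier 1 + 0.08·z_l). Both load on the
propulsion amplitude (multiplier 1 + 0.08·z_k + 0.08·z_l). Consequently
neither modality alone can determine AP GRF — each is blind to one latent,
leaving an irreducible single-modality error of roughly 0.08·A per missing
latent — which makes the benefit of sensor fusion a *constructed, testable*
property of the data rather than an accident of training.

**Insole.** 233 sensels on a fixed foot-shaped mask inside a 31 × 11 grid
(the 233 highest-scoring cells of a smooth heel/arch/forefoot half-width
profile; exported via `layout_to_csv`). Frame pressure = 0.4 a.u. per %BW of
vertical load, spatially distributed as a heel→toe travelling Gaussian blob
(55 %) plus a static foot-shaped component (45 %); CoP is the exact
pressure-weighted centroid before noise. Per-sensel constant offsets
(U[0, 1.5] a.u.) and white noise (σ = 0.1 a.u.) are added, and frames are
clamped at zero. Pressure units are arbitrary: the real device's
calibration is unspecified, and the pipeline min-max normalizes anyway.
The noise default keeps per-sensel SNR of loaded sensels around 3–10,
matching the behaviour of commercial capacitive arrays better than heavier
noise would.

**IMU.** 21 channels per side: 3-axis accelerations (foot, shank), 3-axis
angular rates (foot, shank, thigh), pitch + roll angles (foot, shank,
thigh). Pitch is a two-harmonic function of stride phase with a speed- and
z_k-dependent range; the angular-rate channels are by construction the
central finite differences of the sampled noise-free angles; accelerations
are the gravity vector rotated through pitch/roll plus speed-proportional
motion harmonics, so a zero-speed extension returns ‖a‖ = g exactly.
Gaussian noise per channel class (0.05 m/s², 1 °/s, 0.2°).

**Clocks.** Streams carry constant clock offsets (defaults: insole 25 ms,
IMU 15 ms, configurable up to the tens-of-ms range typical of independently
started recorders). A stream sample stamped t was truly acquired at
t + offset; alignment must recover this.

**Perturbation hook.** `perturb_propulsion` shifts the propulsion amplitude
by δ %BW for strides inside a session-time window by moving both latents in
equal parts, so the change propagates consistently to the force plate, the
insole and the IMU; ground truth is recomputed and negative amplitudes are
clamped at zero. With δ = 0 the session is bit-identical.

**Determinism.** One seed per session; per-bout/side/stream sub-generators
derive from `SeedSequence((seed, bout, side, stream))`. Identical seeds give
bit-identical sessions (hash-checked in the tests).

## 3. Preprocessing (`preprocess`)

Per bout and side: (i) per-sensel zeroing over a detected foot-off window
(0.3 s with the lowest rolling total pressure; "foot off" requires a
sustained near-floor run, since sensel offsets keep even unloaded frames
above zero); (ii) zero-phase 2nd-order Butterworth low-pass, 10 Hz cutoff,
on insole, IMU and force-plate signals (DC gain 1; the forward–backward
pass squares the magnitude response, so a sine at the cutoff is attenuated
to 1/2); (iii) spatial Gaussian (σ = 0.5 grid units, kernel truncated at
radius 2) on the native 233-sensel layout with the kernel renormalized over
in-mask neighbours; (iv) heel strikes detected independently on force-plate
vertical GRF and insole total pressure — coarse rising crossings of 30 % of
the robust peak, debounced at 0.4 s, then refined to the rising crossing of
3 % of the per-stride peak floored at a 4σ noise estimate of the unloaded
phase; (v) the insole clock recovered stride-by-stride by matching
sub-sample mid-rise (50 % of local peak) crossing times between the two
signals — steep-slope features that are insensitive to noise and sampling
quantization — with outlier rejection (±30 ms about the median) and a
9-stride running mean; the IMU clock correction uses the recorded offset,
standing in for the motion-capture synchronization step of a lab pipeline;
(vi) linear interpolation of insole and IMU channels onto the 100 Hz
force-plate grid, with the force targets averaged within each 10 ms bin and
converted to %BW (anterior positive); (vii) subtraction of the per-sensel
mean over the first stride's swing phase in each bout; (viii) area-overlap
(box) interpolation of each embedded 31 × 11 frame to 28 × 28 — exact
integration of the piecewise-constant input over each output cell, which
preserves constants and the grid mean to machine precision and is verified
against a brute-force overlap oracle.

Stance masking and stride labels come from the force-plate events
(intervals [heel-strike, toe-off), 0-based frames). Min-max normalization
constants are computed from training frames only, per group: the whole
pressure map, the CoP pair, and one block per IMU sensor-and-signal type
(e.g. one 3-axis acceleration block shares constants). Degenerate constant
groups get span 1 (mapping to 0) with a warning; values outside the
training range are not clipped. Estimator samples pair the current frame's
28 × 28 map with a 5-frame sequence of the 21 IMU + 2 CoP channels
restricted to the same stance segment, left-padded at stance starts by
repeating the first stance frame; targets stay in raw %BW.

## 4. Estimators (`models`, `_nn`)

Three input configurations share one merge-head design (ReLU after every
layer except the final linear unit):

* insole branch — LeNet-style CNN on the 28 × 28 map: conv 5×5 (6 ch) →
  avg-pool 2×2 → conv 3×3 (16 ch) → avg-pool 2×2 → dense 84;
* time-series branch — 3 stacked bidirectional LSTM layers, 128 hidden
  units per direction, over 5-timestep sequences, then dense 256 → 256 →
  84. The sequence feature is each direction's final state (forward at the
  last timestep, backward at the first) — the standard completion that lets
  both directions consume the whole window;
* head — concatenated branch outputs (168 in fusion mode; 84 single-mode)
  → dense 168 (fusion) / 84 (single) → dense 10 → linear 1. The final
  linear unit is the minimal completion from a 10-unit layer to a signed
  scalar %BW estimate, with no ReLU so braking (negative) values are
  representable.

CoP routing: the fusion LSTM consumes IMU + CoP per timestep; the
insole-only LSTM consumes CoP alone; IMU-only uses no CoP. Each leg's model
uses ipsilateral sensors only. Weight init is fan-in uniform
(U(±1/√fan-in)) from a fixed seed; two builds from the same spec and seed
are identical.

The layers, Adam (with L2 weight decay folded into the gradient, matching
the common framework convention), and MSE loss are implemented in numpy
(float32) with hand-derived reverse-mode gradients, verified in the test
suite against central finite differences in float64. The first layer of
each branch skips its input gradient. Everything is single-threaded and
deterministic given the seed and batch order.

## 5. Training and splits (`training`)

* **By-bout split:** the two bouts whose centre speeds are nearest the CWS
  become validation (nearer; ties go to the earlier bout) and test; the
  rest train. Requires ≥ 3 bouts.
* **Ratio splits:** per bout, the first (forward) or last (reverse) f·N
  frames train, f ∈ {0.15, 0.30, 0.45, 0.60}; the adjacent 0.10·N validate;
  the remainder tests. Splits always partition the frames exactly.
* **Optimization:** Adam, lr 5e-4, weight decay 1e-5, MSE on stance frames.
  Individual models: 500 epochs, best-validation weight selection.
  Pre-training: all healthy legs' training frames pooled, 1000 epochs,
  last-epoch weights. Fine-tuning: initialize from pre-trained weights,
  500 epochs, best-validation, using all or the chronologically last half
  of each bout's train+val frames (the test set unchanged). Normalization
  is always refit on the active training frames. Batch size defaults to
  256 (the source protocol does not state one).

**Desk-scale presets.** The defaults above are full-study settings; for
single-CPU runs the package documents a reduced preset
(`TrainConfig.reduced()`: 20 epochs, every 6th training frame, every 8th
validation frame, batch 128) used by the acceptance script, and the test
suite uses a slightly smaller variant (11 epochs, every 8th frame). These
sizes were chosen so a full five-seed, two-leg experiment fits in tens of
minutes on one CPU; validation-loss curves plateau within the preset's
epoch budget on the default synthetic sessions.

## 6. Evaluation (`metrics`)

Time-series RMSE/NRMSE/R² are computed over stance frames only, in %BW;
NRMSE is RMSE scaled to the range of the test-set stance data. Point
metrics are computed per stride from the 100 Hz stance trace: peak = max
(ties to the earliest frame), timing = argmax as % of stance duration,
impulse = trapezoid of the zero-clamped trace (the O(Δt²) boundary error of
clamping versus root-finding is far below reporting precision at 100 Hz).
Strides with fewer than 5 stance frames are skipped. Symmetry uses
per-session mean impulses of the two legs. Model comparisons use two-sided
paired t-tests over per-dataset stance RMSEs (≥ 3 pairs; identical inputs
raise a degenerate-case error rather than returning p-values).

## 7. What passing tests do and do not show

The generator reproduces the *structure* of the measurement problem —
multi-rate streams, clock offsets, sensor offsets and noise, speed-varying
stride mechanics, bilateral asymmetry, and partially complementary
modalities — but not the physiology of real hemiparetic gait: no double
support/loading asymmetries beyond the propulsion deficit, no compensatory
kinematics, no drift or placement error in the IMUs, no insole creep or
hysteresis, and latent factors that are per-stride i.i.d. rather than
autocorrelated. Passing the desk-scale acceptance thresholds therefore
shows the pipeline is implemented correctly and that fusion recovers the
constructed complementary information; it does not certify equivalent
accuracy on human data.

## 8. Numerical choices and degenerate inputs

Intervals are half-open [start, end); frames and indices 0-based. Heel
strikes use a 3 % stance threshold with 0.4 s debounce (the source protocol
names no value). Linear interpolation everywhere. Filtering raises on
signals shorter than the filtfilt padding; event detection returns empty
arrays (with a warning) on zero signals; zeroing raises when no foot-off
window exists and accepts all-zero streams; min-max spans of zero map to 0;
the paired t-test refuses < 3 pairs. The perturbation hook clamps
propulsion at zero. Checkpoints guard against spec mismatch by hash.

## 9. Limitations

Single-CPU numpy training is orders of magnitude slower than a GPU
framework, so full 500/1000-epoch runs are long; the presets are the
intended desk-scale operating point. The simulator's stride phase is shared
between modalities through the force-plate-derived events, so it cannot
probe event-detection failure modes harsher than its noise model. MDC
constants are population constants taken from the literature, not derived
here.
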