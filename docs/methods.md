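# Methods

`enosekit` implements a complete continuous malodor-quantification pipeline
for electronic-nose (e-nose) sensor arrays: a mechanistic simulator of the
array, signal preprocessing, time/frequency feature extraction, ensemble
channel selection, a family of encoder-decoder CNN/LSTM concentration
models with DCT channel attention and an external drift-compensation
branch, and an RMSE/R²/CORR evaluation harness. This note documents the
models, the defaults, and the choices made where the design was open.

## The sensing problem

Eight regulated malodor gases (hydrogen sulfide, methyl sulfide, dimethyl
disulfide, methyl mercaptan, carbon disulfide, styrene at 0–14 ppm; ammonia
and trimethylamine at 0–20 ppm) are sampled by a 23-channel array: nine
electrochemical (EC) cells, five metal-oxide (MOS) resistive sensors, six
photoionization detectors (PID), one NDIR channel, and two reference
channels (pressure; temperature/humidity). The task is the regression
y = f(X): given a fixed-length window of the multichannel 1 Hz response
(AD counts), output the current 8-gas concentration vector in ppm.

Two sampling protocols are modelled. *Intermittent* detection alternates
clean air and a 3-minute gas exposure, recorded as 600 points per cycle
(300 s pre-clean / 180 s gas / 120 s post-clean — clean stretches outside
the recorded window are simulated but not recorded, since a 5–10 min clean
cannot fit a 600 s cycle). *Non-intermittent* (continuous) detection starts
with a 20-minute clean stretch and then applies random concentration steps
with random hold times (default uniform 60–300 s) and occasional
ventilation steps, without purging.

## Sensor simulator

Each channel has a static steady-state response

    R_ss(t) = baseline + Σ_j g_j · c_j(t)^{p_j}
              + k_T (T − 25 °C) + k_RH (RH − 57 %) + k_P (P − 101.3 kPa)

with per-gas gains g_j (AD counts/ppm at reference conditions) and
power-law exponents p_j (1.0 for EC/PID/NDIR, 0.6 for MOS — MOS sensors are
canonically sublinear). The default gain matrix gives every EC cell its
nominal target as the largest gain, the MOS channels broad sublinear
sensitivity (with TGS2602/TGS2603 elevated for the amines), and the PIDs
strong organic response but near-blindness to H₂S/NH₃. The two reference
channels have zero gas sensitivity.

Dynamics are asymmetric first-order relaxation: the internal state relaxes
toward R_ss with time constant τ_resp when rising and τ_rec (slower) when
recovering. The state is advanced with the exact one-step exponential
update of the first-order ODE at the 1 s sampling interval
(α = 1 − e^{−1/τ}), toward the previous instant's target so that a step at
t₀ first moves the response at t₀+1; at t₀+τ the response has covered
1 − e⁻¹ of the step for every τ. Short-term drift, when enabled, adds

* a per-channel random-walk baseline (default step σ 0.2–0.8 AD), and
* a carry-over term: when a gas segment ends, a fraction (0.10–0.30 by
  principle) of the channel's excess over its gas-free level is injected
  into a hysteresis state that decays with a 600 s constant. Because the
  relaxation state is also never reset, identical pulses separated by a
  short clean gap produce unequal absolute response levels — the classic
  short-term-drift signature of real arrays.

Gaussian measurement noise (2–3 AD) is added and the result is quantized
to nonnegative integer AD counts. Chamber temperature (15–36 °C), humidity
(30–84 %) and pressure are slow bounded sinusoid-plus-walk series; gas
channels couple linearly to them, which is both a nuisance (drift source)
and the information the compensation branch can exploit through the
reference channels.

What the simulator does *not* model: adsorption chemistry, month-scale
aging, flow/pressure transients of the gas distributor, cross-channel
interference beyond the additive gas/environment terms. Passing tests
therefore demonstrate that the pipeline recovers concentrations under
first-order response dynamics with realistic noise, environmental coupling
and short-term drift — not performance on any physical array.

## Preprocessing

Order is fixed: lag shift → scalar random-walk Kalman filter →
Savitzky-Golay smoother, per channel; reference channels are smoothed but
not lag-shifted.

* **Lag.** The response lags the true concentration by roughly one
  response constant. The lag is a hyperparameter estimated by
  cross-correlating the true input with the response
  (`estimate_lag`); the experiment pipeline uses 25 s (≈ the EC τ_resp)
  for the default array. Without it, windows ending shortly after a
  concentration step carry labels the sensors have not yet expressed,
  which caps attainable accuracy well below what the data support.
* **Kalman.** Defaults q = 10, r = 4 AD²: r matches the default noise
  variance and q gives a steady-state gain ≈ 0.77, light enough to track
  the step transients (hundreds of AD counts) while still averaging noise.
  Heavier smoothing (small q/r) lags the transitions so badly that it
  *increases* the error against the noise-free signal.
* **Savitzky-Golay.** Window 11, order 3, polynomial edge handling —
  exact for locally cubic signals, which the exponential transients are to
  good approximation.
* **Scaling.** Min-max normalization per channel, fitted on the training
  split only; out-of-range test values are not clipped. The same
  normalization is applied to the training targets during optimization
  (predictions are mapped back to ppm): unit-scale outputs condition the
  optimizer and roughly halve the error reached in a fixed epoch budget.
* **Windows.** Sliding windows (600 points intermittent, 180 s continuous
  at full scale) labelled with the truth at the window's *last* step — the
  online-detector convention; mean-over-window labelling is available.

## Features and channel selection

Nine features per gas channel: response integral (Σx·Δt), differential
(max first difference; the standard e-nose kinetic slope feature — a
net-change alternative is selectable), average differential (mean |Δ|),
maximum, minimum, mean; and from the demeaned, Hann-windowed one-sided
spectrum: barycenter frequency (power-weighted), average frequency
(amplitude-weighted, kept distinct from the barycenter on purpose) and
peak-power frequency. 21 gas channels × 9 = 189 columns.

Four rankers score all columns against the eight targets: |Pearson r|,
binned mutual information (equal-width bins, √(n/5) per axis; standing in
for MIC), multi-output random-forest impurity importance, and linear
SVM-RFE (10 % eliminated per iteration, per-target rankings averaged; an
RBF SVM has no feature weights so it is used only as a baseline regressor,
never for RFE). Filter methods aggregate over targets by the max (a
feature useful for *any* gas is kept). Ties receive average ranks, so
every rank vector has mean (m+1)/2. The ensemble rank is the per-feature
mean over the four methods; a sensor's rank is the mean of its nine
feature ranks; the best k gas channels (default k = 16, giving an
18-channel input with the two reference channels always appended) feed the
models. Ties are broken by channel id for determinism.

## Models

All networks map a (batch, L, C) window to 8 concentrations and are built
on the package's own numpy reverse-mode autodiff engine (`enosekit.nn`):
float64 throughout, explicit seeding, bit-identical retraining on a single
thread. Training minimizes MSE with Adam (default lr 1e-3, batch 32).

* **CNN block**: three same-padded 1-D convolutions (widths 32/64/64,
  kernel 3) with ReLU, layer normalization after the third.
* **Encoder**: the CNN block in parallel with a two-layer bidirectional
  LSTM; outputs concatenated along the feature axis and linearly projected.
* **DCT attention**: per feature channel, the summed magnitudes of the
  first dct_k (16) orthonormal DCT-II coefficients along time form a
  descriptor; a squeeze-excite bottleneck (reduction 4) and a sigmoid
  produce per-channel gates in (0,1) that rescale the encoding. At zero
  bottleneck weights the gates are exactly ½.
* **Decoder**: two unidirectional LSTM layers; the last hidden state goes
  through fully connected layers to 8 outputs (one-shot, not
  autoregressive).
* **Compensation branch**: the input window (gas + reference channels) is
  decomposed into trend (centered moving average, width 25, edge
  replication — exact additive reconstruction) and seasonal residual; the
  trend passes through a pointwise MLP and the seasonal part through one
  post-norm transformer encoder layer; the two streams are concatenated,
  gated by DCT attention, flattened and mapped to an 8-vector that is
  *added* to the decoder output. The branch's output layer is
  zero-initialized, so the full model starts exactly at its
  no-compensation ablation. Zeroing the branch weights makes
  IED-CNN-LSTM exactly reproduce ED-CNN-DCT-LSTM, and parameter counts
  strictly increase along ED → ED-DCT → IED.

Compensated models train in **two stages**: the main encoder-decoder first
(the zero-initialized branch contributes nothing), then the branch alone —
main weights frozen — on the full-model loss, for half as many epochs by
default. The external correction therefore fits the *residual error* of
the trained main model instead of co-adapting with it; jointly trained,
the branch's flattened head tends to memorize small training sets and adds
variance without reducing test error. Decoupled (AdamW-style) weight decay
is available and, in the scaled drift experiment, shared by every model so
comparisons stay fair.

Simple baselines (CNN, LSTM, BiLSTM, CNN-LSTM, CNN-BiLSTM) reuse the same
blocks and hidden sizes so comparisons vary architecture only. Classical
feature-based baselines keep their tuned hyperparameters: KNN (k = 4,
distance weights), RBF SVM (C = 50, standardized inputs), random forest
(700 trees, depth 9, seed 42), XGBoost (850 learners, lr 0.025, depth 4,
λ = 0.026), MLP (300/150, lr 4e-4, 100 iterations, standardized inputs).

## Scaled study sizes

The reference experiments are deliberate scale reductions chosen from
runtime measurements of the engine, fixed before any accuracy was looked
at:

| experiment | conditions | window/stride | model | epochs |
|---|---|---|---|---|
| drift-free recovery | 60 | 120 s / 30 s | ED-CNN-LSTM, hidden 32 | 30 |
| drift ablation (3 seeds) | 40 | 90 s / 30 s | ED / ED-DCT / IED, hidden 32 | 10 + 5 comp (lr 2e-3, wd 1e-3) |
| filter pairing | 20 seeds × 2 cycles | — | — | — |
| selection recovery | 20 seeds, 150 samples, 6 sensors | — | — | — |

On these sizes the drift-free model reaches held-out pooled R² ≈ 0.9, and
the drift ablation reproduces the qualitative ordering
IED ≤ ED-DCT ≤ ED in median test RMSE. Numbers at full scale on a real
array are not implied; absolute metric levels depend on the simulator's
noise and drift settings.

## Numerical details and limitations

* Windows too short for a filter, even decomposition kernels, non-odd SG
  windows, empty channel subsets, constant series in lag estimation, and
  ragged rank matrices all raise explicit errors; constant feature columns
  rank worst rather than propagating NaN; constant scaler columns map to 0
  with a warning.
* The DCT is orthonormal (Parseval holds to 1e-12); the decomposition
  reconstructs exactly by construction.
* Determinism: every stochastic stage takes an explicit seed; the CLI
  derives per-stage seeds from one global seed by fixed offsets.
* The engine is tape-based python/numpy: correct (finite-difference
  checked) but slow; sequence lengths beyond a few hundred steps or hidden
  sizes beyond ~128 are impractical to train with it.
* Random 80/20 splitting of overlapping sliding windows lets near-duplicate
  windows straddle the split, as in the original protocol; a chronological
  split is provided for leakage-sensitive analyses.
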