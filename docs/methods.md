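# Methods

`bedpress` reconstructs a continuous arterial blood-pressure (BP) waveform
from the four load cells under the legs of a bed — a ballistocardiographic
(BCG) measurement — and derives systolic/diastolic pressure (SBP/DBP) and
method-agreement statistics from it. This note documents the model, the
synthetic cohort it is exercised on, and the numerical and design choices
a maintainer would want spelled out.

## The regression model

BP reconstruction is cast as sliding-window regression: the sample BP(t)
at the 100 Hz working rate is predicted from the strictly causal window of
the four band-passed load-cell signals at indices [t−N, t−1], with N = 50
(500 ms). Successive 1-sample shifts cover every index from N to L−1, so
the entire waveform except the initial N samples is reconstructed.

The regressor is a stack of three 30-unit LSTM layers — the first two
returning full sequences, the third its last hidden state — followed by a
single linear dense unit. With 4 input features per time step this network
has exactly 18,871 trainable parameters (per LSTM layer 4·(u·(f+u)+u);
4,200 + 7,320 + 7,320 + 31). The parameter count is used as an
architecture identity in the tests: no other assignment of feature
dimension, depth, or head width reproduces it.

Training minimizes mean squared error with Adam (lr 10⁻³, β₁ 0.9,
β₂ 0.999) on minibatches of 256 from Glorot-normal initial weights, and
per-epoch validation MSE decides the checkpoint: the weights returned are
those of the epoch with the lowest validation error (earliest on ties),
not the final epoch. The default protocol runs 300 epochs; the scaled-down
study in the test suite runs 30 (see below).

### Engine

No deep-learning framework is a dependency: the LSTM stack, its
backpropagation-through-time gradients, Glorot-normal initialization and
Adam are implemented in NumPy (`bedpress.nn`). Correctness rests on a
central-finite-difference gradient check in double precision (worst
relative error ~10⁻⁵ at step 10⁻⁵) and on the closed-form parameter-count
identity. Two implementation choices matter for behaviour:

- The forget-gate bias starts at 1 (standard stabilization); other
  biases start at zero. Input kernels use Glorot-normal draws; recurrent
  kernels use per-gate orthogonal matrices — the recurrent default of the
  mainstream LSTM implementations, which trains noticeably better here
  than Glorot recurrent draws.
- Computation is float32, feature-major ((T, features, batch)) so the
  per-step gate blocks are contiguous; sigmoid is evaluated as
  (1 + tanh(z/2))/2 to reuse the SIMD tanh. Bit-exact reproducibility
  across platforms is not promised — only statistical reproducibility of
  seeded runs.

### Target scaling

Targets are min-max normalized to [0, 1] with statistics of the *training*
participants only; the identical affine map is applied to validation and
test targets (values outside the training range map outside [0, 1], no
clipping), and every mmHg metric is computed after the exact inverse
transform. Training on normalized targets keeps the loss scale independent
of the cohort's pressure range; reports carry both normalized and mmHg
waveform errors because the two scales differ by roughly the squared
training range (~10³–10⁴) and are otherwise easy to confuse. Load-cell
inputs are fed in raw filtered units by default; a config switch
(`ModelConfig.normalize_inputs`) enables per-recording z-scoring for data
with large inter-device gain variation.

## Signal conditioning

Load-cell channels are band-passed 0.05–35 Hz with a 4th-order Butterworth
filter applied forward–backward (zero phase, so extrema timing is
preserved); the effective magnitude response is the squared Butterworth
response. Padding for the forward–backward pass is sized to the low-cut
settling time (fs/low_cut samples) because the 0.05 Hz edge otherwise
rings visibly into the output. The BP channel is decimated but not
band-passed — its DC level *is* the measurement. Decimation from 1000 to
100 Hz low-passes at 40 Hz (8th-order Butterworth, zero phase) and keeps
every 10th sample; at 100 Hz input it is the identity.

## SBP/DBP extraction

Local maxima are proposed where the first difference crosses zero going
negative (d[i−1] > 0 and d[i] ≤ 0, so plateaus resolve to their first
sample), minima at positive-going crossings. Proposals survive only inside
the physiological amplitude gates — systolic 100–150 mmHg, diastolic
60–100 mmHg — and after a refractory rule: same-kind events must be at
least 50 samples (500 ms) apart, i.e. no faster than 120 bpm. The rule
does not say which of two close events to keep, so the implementation is
greedy by amplitude: the more extreme event (higher maximum / lower
minimum) wins, ties to the earlier index. Consecutive non-overlapping
5-second windows average the event amplitudes of each kind; a window with
no events of a kind carries an absent value, never zero. The final partial
window is included — with ~480 s recordings the effect is negligible
either way. The per-recording SBP/DBP is the unweighted mean of the
present window values.

Reference SBP/DBP are computed by running this same detector on the
reference BP waveform: there is no separate gold-standard algorithm, so
estimated-vs-reference differences isolate reconstruction error.

## Agreement analysis

Waveform fidelity: MSE, MAE, and R² = 1 − SSres/SStot (SStot about the
reference mean) against the reference truncated by its first N samples.
Bland–Altman agreement uses d = estimated − reference, bias = mean(d), and
95% limits of agreement bias ± 1.96·SD(d) with the sample (n−1) SD, at two
levels: pooled 5-s windows across all test recordings (pairs are
index-aligned on the shared timeline and used only when both methods have
a value in that window) and one pair per recording. Recording-level limits
are expected to be tighter than window-level ones whenever window errors
are imperfectly correlated — averaging within a recording cancels part of
the noise.

## The synthetic cohort

Real paired bed-sensor/finger-cuff recordings cannot ship with the
package, so a simulator generates cohorts with the statistical structure
the method assumes:

- **BP waveform** — beats at inter-beat intervals 60/(HR + jitter), each a
  raised-cosine upstroke (0.15 s) from the diastolic to the systolic level
  followed by an exponential relaxation (τ = 0.25 s) renormalized to land
  exactly on the diastolic level at the next onset; plus ±2 mmHg
  respiratory modulation and a ~1 mmHg slow drift.
- **Load cells** — an impulse train at the beat onsets (impulses split
  fractionally across neighbouring samples, so sub-sample timing
  survives) convolved with one compact cardiac complex (σ = 0.05 s,
  ~0.3 s support) that superposes three co-located shapes: a biphasic
  derivative-of-Gaussian mimicking the I–J–K complex, with amplitude
  affine in the pulse pressure (0.2 + 0.02·PP, so PP = 40 mmHg → ~1
  signal unit); a Gaussian wave proportional to the diastolic level
  (0.5·DBP/160); and a fixed-amplitude (0.3) Ricker wave as a gain
  reference. The channel gain scales the whole complex, so amplitude
  *ratios* between the shapes are gain-invariant: both pulse pressure and
  the absolute level remain decodable from shape alone, while a single
  event per beat keeps beat phase unambiguous even for a linear decoder.
  Respiration (amplitude 0.1), white Gaussian noise and slow sinusoidal
  drift are added per channel.
- **Population defaults** — SBP ~ U(108, 142) mmHg, DBP ~ U(68, 92) mmHg
  (inside the detector's gates by construction), HR ~ N(65, 8) bpm
  truncated above 40, respiratory rate ~ U(12, 18) /min, channel gains
  ~ U(0.8, 1.2), beat-to-beat HR jitter SD 2 bpm, noise SD 0.1 signal
  units (≈10% of a nominal pulse), drift amplitude 0.2 units.

Per-participant seeds derive from `np.random.SeedSequence(master_seed)`
spawn keys, so cohorts are pure functions of (config, master seed) and
stable across platforms.

What the simulator does *not* model: body movement and bed-exit
artifacts, arrhythmias, circadian BP variation, and any physical model of
force transduction through a bed frame. Passing tests therefore
demonstrate that the pipeline implements the method correctly and that
the network can learn a BCG-to-pressure mapping of realistic temporal
structure — not that it reaches any particular accuracy on real bed
sensors.

## Scaled-down study in the test suite

The end-to-end check trains on a seeded cohort of 12 participants
(8 train / 2 validation / 2 test — the 60/15/25% split of the full
protocol applied to 12), 120 s per recording at 100 Hz, default moderate
noise, 30 epochs. Problem sizes were chosen so the full suite remains
practical on a single CPU while leaving the mapping genuinely nontrivial
(~95,600 training windows). Asserted on this run: held-out reconstruction
R² ≥ 0.5, recording-level |bias| ≤ 5 mmHg for SBP and DBP, recording-level
LoA width ≤ window-level LoA width, checkpoint dominance over the final
epoch, and train-R² ≥ test-R² for the seeded run.

Two caveats about this scale. First, absolute-level transfer is the
binding difficulty: decoding a participant's pressure *level* (rather
than the waveform's shape) from the gain-invariant amplitude ratios
requires a computation nothing in the MSE objective forces the network
to discover, and with eight training participants, partially memorizing
their levels is the easier optimum — an instance of the general
difficulty of generalizing such models across individuals. Residual
level error appears as regression toward the training mean and shows up
directly in the recording-level bias when the held-out participants sit
at the edge of the cohort distribution. Second, with only two test
recordings the recording-level limits of agreement rest on the sample SD
of two differences (√2 × half their spread); the expected narrowing
relative to pooled windows holds only when the between-participant bias
spread is below the within-recording window noise, so that comparison is
statistically fragile at this size.

## Degenerate inputs and edge policies

- Recordings shorter than N+1 samples, constant reference waveforms (R²
  undefined), constant training targets (scaler undefined), single-pair
  agreement inputs (SD undefined) and empty window sets all raise
  explicit `ValueError`s rather than returning silent zeros.
- Non-finite training loss aborts with a diagnostic rather than
  continuing.
- Windows never span recording boundaries; datasets from multiple
  recordings are concatenated after windowing.
- Recordings in which the detector finds no events are listed in the
  evaluation report, not silently dropped.

## Known limitations

- The NumPy engine is CPU-only and unoptimized beyond cache-friendly
  layout; the full 300-epoch protocol on a 38-participant cohort is an
  overnight job on one core.
- The simulator's cardiac complex is a convenience template, not a fitted
  physiological shape; its shape-ratio pressure code is an explicit
  artifact convention standing in for whatever morphology real BCG
  signals carry about absolute pressure.
- No motion-artifact rejection: the pipeline assumes a still subject.
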