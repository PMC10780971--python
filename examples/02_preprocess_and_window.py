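"""Condition a 1000 Hz recording and build the sliding-window dataset.

Load cells are band-passed 0.05-35 Hz (zero-phase Butterworth) and all
five channels decimated to the 100 Hz working rate; the regression dataset
pairs each strictly causal 50-sample (500 ms) 4-channel window with the
concurrent BP sample.
"""

import bedpress as bp

params = bp.ParticipantParams(participant_id="demo", seed=3)
raw = bp.simulate_participant(params, duration=30.0, fs=1000.0)
print(f"raw:          {raw.n_samples} samples at {raw.fs:.0f} Hz")

rec = bp.preprocess_recording(raw, bp.FilterSpec(low_cut=0.05, high_cut=35.0))
print(f"preprocessed: {rec.n_samples} samples at {rec.fs:.0f} Hz")
print(f"BP extrema preserved: max {raw.bp.max():.2f} -> {rec.bp.max():.2f}, "
      f"min {raw.bp.min():.2f} -> {rec.bp.min():.2f} mmHg")

ds = bp.build_windows(rec, N=50)
print(f"windows:      {len(ds)} pairs "
      f"(= {rec.n_samples} - 50; the first 50 samples have no window)")
print(f"input shape:  {ds.inputs.shape}  targets: {ds.targets.shape}")

# Each of the L-50 rows is a 50-step x 4-channel matrix; successive rows
# are 1-sample shifts, so predicting every row reconstructs the whole BP
# waveform at 100 Hz except the initial half second.
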