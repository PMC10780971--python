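"""Signal conditioning: band-pass filtering and decimation to 100 Hz.

Load-cell channels are band-passed between 0.05 and 35 Hz (zero-phase
Butterworth) and all channels are subsampled from the acquisition rate to
the 100 Hz working rate. The reference BP channel is decimated but not
band-passed, since the pressure baseline (its DC level) is the quantity of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import Recording

__all__ = ["FilterSpec", "bandpass", "decimate_to_100hz",
           "preprocess_recording", "TARGET_FS"]

TARGET_FS = 100.0
#: anti-alias low-pass applied before 1000->100 Hz downsampling
_ANTIALIAS_ORDER = 8
_ANTIALIAS_CUTOFF_HZ = 40.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: Butterworth, zero-phase (forward-backward)."""

    low_cut: float = 0.05   # Hz
    high_cut: float = 35.0  # Hz
    order: int = 4
    design: str = "butterworth"

    def validate(self, fs: float) -> None:
        if self.design != "butterworth":
            raise ValueError(f"unsupported filter design: {self.design}")
        if not (0 < self.low_cut < self.high_cut < fs / 2):
            raise ValueError(
                f"need 0 < low_cut < high_cut < fs/2; got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}")


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None
             ) -> np.ndarray:
    """Zero-phase band-pass filter; same length as the input.

    Applied forward-backward (sosfiltfilt) so extrema timing is not
    shifted; the effective magnitude response is the squared Butterworth
    response.
    """
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise ValueError("signal too short for stable filtering")
    sos = signal.butter(spec.order, [spec.low_cut, spec.high_cut],
                        btype="bandpass", fs=fs, output="sos")
    # pad on the scale of the low-cut settling time, not the default few
    # samples; otherwise the ~1/low_cut transient leaks into the output
    padlen = int(min(x.shape[-1] - 1, fs / spec.low_cut))
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def decimate_to_100hz(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Subsample a signal to 100 Hz.

    At 100 Hz input this is the identity; at 1000 Hz the signal is
    low-passed (8th-order Butterworth at 40 Hz, zero-phase) and every 10th
    sample kept. Output length is floor(L / 10).
    """
    x = np.asarray(x, dtype=float)
    if fs_in == 100:
        return x.copy()
    if fs_in != 1000:
        raise ValueError(f"unsupported input rate: {fs_in}")
    sos = signal.butter(_ANTIALIAS_ORDER, _ANTIALIAS_CUTOFF_HZ,
                        btype="lowpass", fs=fs_in, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    L = y.shape[-1] - (y.shape[-1] % 10)
    return y[..., :L][..., ::10]


def preprocess_recording(rec: Recording, spec: FilterSpec | None = None
                         ) -> Recording:
    """Band-pass the four load-cell channels, then decimate all five to 100 Hz."""
    spec = spec or FilterSpec()
    lcs = bandpass(rec.load_cells, rec.fs, spec)
    lcs = decimate_to_100hz(lcs, rec.fs)
    bp = decimate_to_100hz(rec.bp, rec.fs)
    return Recording(participant_id=rec.participant_id, fs=TARGET_FS,
                     load_cells=lcs, bp=bp)
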