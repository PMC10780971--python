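"""Systolic/diastolic estimation from a BP waveform.

Local maxima are proposed at negative-going zero-crossings of the first
difference of the waveform, local minima at positive-going crossings.
Proposals survive only if their amplitude falls inside the physiological
gate for their kind (systolic 100-150 mmHg, diastolic 60-100 mmHg) and if
they are separated from adjacent same-kind events by at least 50 samples
(500 ms at 100 Hz, i.e. faster than any plausible resting heart rate).
Surviving events are aggregated into consecutive five-second windows and a
per-recording mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BPEvent", "WindowEstimate", "RecordingEstimate",
           "detect_events", "window_estimates", "recording_estimate",
           "SYSTOLIC_GATE", "DIASTOLIC_GATE", "REFRACTORY_SAMPLES"]

SYSTOLIC_GATE = (100.0, 150.0)   # mmHg
DIASTOLIC_GATE = (60.0, 100.0)   # mmHg
REFRACTORY_SAMPLES = 50          # minimum same-kind separation
WINDOW_S = 5.0


@dataclass(frozen=True)
class BPEvent:
    sample_index: int
    time: float          # seconds
    amplitude: float     # mmHg
    kind: str            # "systolic" | "diastolic"


@dataclass(frozen=True)
class WindowEstimate:
    window_start: float          # seconds
    sbp: float | None            # mean systolic amplitude, or None
    dbp: float | None
    n_sys_events: int
    n_dia_events: int


@dataclass(frozen=True)
class RecordingEstimate:
    sbp_mean: float
    dbp_mean: float
    n_windows_sbp: int
    n_windows_dbp: int


def _propose_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-crossing extrema proposals (indices of maxima, minima).

    With d[i] = x[i+1] - x[i]: a maximum at i when d[i-1] > 0 and
    d[i] <= 0; a minimum at i when d[i-1] < 0 and d[i] >= 0. Plateaus
    resolve to their first sample.
    """
    d = np.diff(x)
    i = np.arange(1, len(d))
    maxima = i[(d[:-1] > 0) & (d[1:] <= 0)]
    minima = i[(d[:-1] < 0) & (d[1:] >= 0)]
    return maxima, minima


def _apply_refractory(indices: np.ndarray, amplitudes: np.ndarray,
                      keep_largest: bool, min_sep: int) -> np.ndarray:
    """Greedy amplitude-priority thinning to >= min_sep sample separation.

    Candidates are visited from most to least extreme (ties -> earlier
    index); a candidate is kept if no already-kept event lies closer than
    min_sep samples. Returns kept indices in ascending order.
    """
    if len(indices) == 0 or min_sep <= 0:
        return indices
    key = -amplitudes if keep_largest else amplitudes
    order = np.lexsort((indices, key))
    kept: list[int] = []
    for j in order:
        idx = indices[j]
        if all(abs(idx - k) >= min_sep for k in kept):
            kept.append(idx)
    return np.array(sorted(kept), dtype=indices.dtype)


def detect_events(waveform: np.ndarray, fs: float = 100.0,
                  sys_gate: tuple[float, float] = SYSTOLIC_GATE,
                  dia_gate: tuple[float, float] = DIASTOLIC_GATE,
                  refractory: int = REFRACTORY_SAMPLES) -> list[BPEvent]:
    """Detect gated systolic peaks and diastolic troughs.

    Pass ``refractory=0`` to obtain the raw gated proposals without the
    minimum-separation rule (useful for cross-checking the detector).
    """
    x = np.asarray(waveform, dtype=float)
    if len(x) < 3:
        raise ValueError("waveform too short for extrema detection")
    maxima, minima = _propose_extrema(x)

    maxima = maxima[(x[maxima] >= sys_gate[0]) & (x[maxima] <= sys_gate[1])]
    minima = minima[(x[minima] >= dia_gate[0]) & (x[minima] <= dia_gate[1])]

    maxima = _apply_refractory(maxima, x[maxima], keep_largest=True,
                               min_sep=refractory)
    minima = _apply_refractory(minima, x[minima], keep_largest=False,
                               min_sep=refractory)

    events = [BPEvent(int(i), i / fs, float(x[i]), "systolic")
              for i in maxima]
    events += [BPEvent(int(i), i / fs, float(x[i]), "diastolic")
               for i in minima]
    events.sort(key=lambda e: e.sample_index)
    return events


def window_estimates(events: list[BPEvent], waveform_duration: float,
                     window: float = WINDOW_S) -> list[WindowEstimate]:
    """Aggregate events into consecutive non-overlapping windows.

    Windows are half-open [start, start + window); the final partial
    window is included. A window's SBP (DBP) is the mean amplitude of its
    systolic (diastolic) events; windows without events of a kind carry
    None, never zero.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = max(1, math.ceil(waveform_duration / window))
    out = []
    for w in range(n_windows):
        start = w * window
        in_w = [e for e in events if start <= e.time < start + window]
        sys_amp = [e.amplitude for e in in_w if e.kind == "systolic"]
        dia_amp = [e.amplitude for e in in_w if e.kind == "diastolic"]
        out.append(WindowEstimate(
            window_start=start,
            sbp=float(np.mean(sys_amp)) if sys_amp else None,
            dbp=float(np.mean(dia_amp)) if dia_amp else None,
            n_sys_events=len(sys_amp), n_dia_events=len(dia_amp)))
    return out


def recording_estimate(wins: list[WindowEstimate]) -> RecordingEstimate:
    """Unweighted mean of the present window values, per kind."""
    sbp_vals = [w.sbp for w in wins if w.sbp is not None]
    dbp_vals = [w.dbp for w in wins if w.dbp is not None]
    if not sbp_vals or not dbp_vals:
        raise ValueError(
            f"no usable windows (sbp: {len(sbp_vals)}, dbp: {len(dbp_vals)})")
    return RecordingEstimate(
        sbp_mean=float(np.mean(sbp_vals)), dbp_mean=float(np.mean(dbp_vals)),
        n_windows_sbp=len(sbp_vals), n_windows_dbp=len(dbp_vals))
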