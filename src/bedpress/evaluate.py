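"""Waveform reconstruction metrics and Bland–Altman agreement analysis.

Waveform fidelity is summarized by MSE, MAE and the coefficient of
determination R² against the reference BP waveform (reference truncated to
drop the initial N samples that cannot be reconstructed). Agreement of the
extracted SBP/DBP estimates with the reference values uses Bland–Altman
bias and 95% limits of agreement, bias ± 1.96 × SD of the paired
differences (sample SD, n−1 denominator), at two levels: pooled
five-second windows across all recordings, and one value per recording.
Reference SBP/DBP come from the same detection/aggregation code path run
on the reference waveform — there is no separate gold-standard algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .extract import (detect_events, recording_estimate, window_estimates)
from .model import ReconstructedWaveform, reconstruct
from .synthetic import Recording

__all__ = ["WaveformMetrics", "AgreementResult", "waveform_metrics",
           "bland_altman", "loa_width", "evaluate_cohort",
           "bland_altman_plot"]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class WaveformMetrics:
    mse: float
    mae: float
    r2: float
    scale: str = "mmHg"   # or "normalized"


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    n: int
    level: str = ""    # "window" | "recording"
    kind: str = ""     # "sbp" | "dbp"


def waveform_metrics(reference: np.ndarray, reconstructed: np.ndarray,
                     scale: str = "mmHg") -> WaveformMetrics:
    """MSE, MAE and R² of a reconstruction against its reference."""
    reference = np.asarray(reference, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if reference.shape != reconstructed.shape:
        raise ValueError(
            f"length mismatch: {reference.shape} vs {reconstructed.shape}")
    if reference.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(reference) == 0:
        raise ValueError("constant reference: R^2 undefined")
    return WaveformMetrics(
        mse=float(mean_squared_error(reference, reconstructed)),
        mae=float(mean_absolute_error(reference, reconstructed)),
        r2=float(r2_score(reference, reconstructed)),
        scale=scale)


def bland_altman(estimated: np.ndarray, reference: np.ndarray,
                 level: str = "", kind: str = "") -> AgreementResult:
    """Bias and 95% limits of agreement for paired measurements.

    d = estimated − reference; bias = mean(d); LoA = bias ± 1.96 × SD(d)
    with the sample (n−1) standard deviation.
    """
    estimated = np.asarray(estimated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimated.shape != reference.shape:
        raise ValueError("estimated/reference must be paired (equal length)")
    n = estimated.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = estimated - reference
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(bias=bias,
                           loa_lower=bias - LOA_MULTIPLIER * sd,
                           loa_upper=bias + LOA_MULTIPLIER * sd,
                           sd_diff=sd, n=n, level=level, kind=kind)


def loa_width(res: AgreementResult) -> float:
    """Width of the limits-of-agreement interval, mmHg."""
    return res.loa_upper - res.loa_lower


def _paired_window_values(est_wins, ref_wins, attr: str
                          ) -> tuple[list[float], list[float]]:
    """Index-aligned window pairs where both values are present."""
    est_v, ref_v = [], []
    for ew, rw in zip(est_wins, ref_wins):
        e = getattr(ew, attr)
        r = getattr(rw, attr)
        if e is not None and r is not None:
            est_v.append(e)
            ref_v.append(r)
    return est_v, ref_v


def evaluate_cohort(model, scaler, recordings: list[Recording],
                    N: int = 50, window_s: float = 5.0,
                    reconstructions: list[ReconstructedWaveform] | None = None
                    ) -> dict:
    """Full test-set evaluation: reconstruct → detect → aggregate → agree.

    Returns a JSON-serializable report with per-recording waveform metrics
    (mmHg scale), pooled window-level and recording-level Bland–Altman
    results for SBP and DBP, and a list of recordings in which no events
    were detected (reported, never silently dropped).

    ``reconstructions`` may be supplied to reuse precomputed waveforms
    (e.g. the reference itself, for identity checks).
    """
    per_recording = []
    win_est = {"sbp": [], "dbp": []}
    win_ref = {"sbp": [], "dbp": []}
    rec_est = {"sbp": [], "dbp": []}
    rec_ref = {"sbp": [], "dbp": []}
    empty = []

    for i, rec in enumerate(recordings):
        if reconstructions is not None:
            recon = reconstructions[i]
        else:
            recon = reconstruct(model, scaler, rec, N=N)
        ref = rec.bp[recon.start_index:]
        m = waveform_metrics(ref, recon.values)
        per_recording.append({"participant_id": rec.participant_id,
                              **asdict(m)})

        duration = len(ref) / rec.fs
        est_events = detect_events(recon.values, fs=rec.fs)
        ref_events = detect_events(ref, fs=rec.fs)
        est_wins = window_estimates(est_events, duration, window=window_s)
        ref_wins = window_estimates(ref_events, duration, window=window_s)

        for kind, attr in (("sbp", "sbp"), ("dbp", "dbp")):
            ev, rv = _paired_window_values(est_wins, ref_wins, attr)
            win_est[kind].extend(ev)
            win_ref[kind].extend(rv)

        try:
            e_rec = recording_estimate(est_wins)
            r_rec = recording_estimate(ref_wins)
        except ValueError:
            empty.append(rec.participant_id)
            continue
        rec_est["sbp"].append(e_rec.sbp_mean)
        rec_ref["sbp"].append(r_rec.sbp_mean)
        rec_est["dbp"].append(e_rec.dbp_mean)
        rec_ref["dbp"].append(r_rec.dbp_mean)

    agreement = {}
    for level, est_d, ref_d in (("window", win_est, win_ref),
                                ("recording", rec_est, rec_ref)):
        for kind in ("sbp", "dbp"):
            key = f"{level}_{kind}"
            if len(est_d[kind]) >= 2:
                res = bland_altman(np.array(est_d[kind]),
                                   np.array(ref_d[kind]),
                                   level=level, kind=kind)
                agreement[key] = {**asdict(res), "loa_width": loa_width(res)}
            else:
                agreement[key] = None

    return {
        "per_recording_waveform_metrics": per_recording,
        "agreement": agreement,
        "recordings_without_events": empty,
        "n_recordings": len(recordings),
    }


def bland_altman_plot(estimated, reference, ax=None, title: str = ""):
    """Standard Bland–Altman scatter with bias and LoA lines."""
    import matplotlib.pyplot as plt

    estimated = np.asarray(estimated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    res = bland_altman(estimated, reference)
    if ax is None:
        _, ax = plt.subplots()
    mean = (estimated + reference) / 2
    ax.scatter(mean, estimated - reference, s=12, alpha=0.6)
    ax.axhline(res.bias, color="b", ls="--", label=f"bias {res.bias:.2f}")
    ax.axhline(res.loa_upper, color="r", ls="--",
               label=f"LoA [{res.loa_lower:.2f}, {res.loa_upper:.2f}]")
    ax.axhline(res.loa_lower, color="r", ls="--")
    ax.set_xlabel("mean of methods (mmHg)")
    ax.set_ylabel("difference (mmHg)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
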