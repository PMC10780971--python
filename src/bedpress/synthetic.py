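"""Synthetic paired load-cell / blood-pressure recordings.

Generates participant-level recordings with the statistical structure the
reconstruction method assumes: a beat-by-beat arterial pressure waveform
(systolic peak, diastolic trough, respiratory modulation, slow drift) and
four ballistocardiogram-like force channels in which each heartbeat appears
as a biphasic mechanical pulse whose amplitude encodes the beat's pulse
pressure. The simulator is an artifact convention for testing the pipeline
end to end; it makes no claim about the physical transduction of cardiac
forces through a bed frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParticipantParams",
    "Recording",
    "CohortConfig",
    "simulate_participant",
    "simulate_cohort",
]

#: duration of the raised-cosine systolic upstroke, seconds
UPSTROKE_S = 0.15
#: time constant of the diastolic relaxation, seconds
DECAY_TAU_S = 0.25
#: width parameter (sigma) of the derivative-of-Gaussian BCG kernel, seconds
BCG_SIGMA_S = 0.05
#: half-support of the BCG kernel, seconds (total support ~0.3 s)
BCG_HALF_SUPPORT_S = 0.15
#: affine map from pulse pressure (mmHg) to BCG pulse peak amplitude
BCG_AMP_OFFSET = 0.2
BCG_AMP_SLOPE = 0.02  # per mmHg of pulse pressure; PP=40 -> peak ~1.0
#: the full cardiac impulse response superposes the compact ejection
#: complex with two damped sinusoids of distinct frequencies that carry
#: oscillatory energy across most of the beat (as the I-J-K-L-M waves and
#: ringing of a real BCG do). Their amplitude ratios encode the pressures
#: independently of the unknown channel gain: one oscillation is
#: proportional to the diastolic level, the other has fixed amplitude and
#: serves as the gain reference.
LEVEL_OSC_FREQ_HZ = 3.0
REF_OSC_FREQ_HZ = 4.5
OSC_DECAY_TAU_S = 0.25
OSC_SUPPORT_S = 0.9
LEVEL_WAVE_SCALE = 0.5 / 160.0  # oscillation amplitude = scale * dbp_level
REF_WAVE_AMPLITUDE = 0.3        # fixed reference-oscillation amplitude
#: amplitude of the respiratory component added to each load-cell channel
LC_RESP_AMPLITUDE = 0.1


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters for one participant.

    Blood-pressure levels default inside (100, 150) / (60, 100) mmHg so that
    every generated systolic peak and diastolic trough passes the amplitude
    gates used by the extrema detector downstream.
    """

    participant_id: str
    sbp_level: float = 120.0          # mmHg, systolic plateau
    dbp_level: float = 80.0           # mmHg, diastolic baseline
    heart_rate: float = 60.0          # beats/min
    hr_jitter_sd: float = 2.0         # beats/min, beat-to-beat variability
    resp_rate: float = 15.0           # breaths/min
    channel_gains: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 0.1             # per-channel white noise, signal units
    drift_amplitude: float = 0.2      # load-cell baseline drift, signal units
    resp_bp_mmhg: float = 2.0         # respiratory BP modulation amplitude
    bp_drift_mmhg: float = 1.0        # slow BP drift amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sbp_level > self.dbp_level:
            raise ValueError("sbp_level must exceed dbp_level")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if self.resp_rate <= 0:
            raise ValueError("resp_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.channel_gains) != 4:
            raise ValueError("channel_gains must have exactly 4 entries")


@dataclass
class Recording:
    """Synchronized 4-channel load-cell + reference BP waveform.

    ``load_cells`` has shape (4, L); ``bp`` has shape (L,), in mmHg.
    All five channels share one length and one sampling rate.
    """

    participant_id: str
    fs: float
    load_cells: np.ndarray
    bp: np.ndarray

    def __post_init__(self) -> None:
        self.load_cells = np.asarray(self.load_cells, dtype=float)
        self.bp = np.asarray(self.bp, dtype=float)
        if self.load_cells.ndim != 2 or self.load_cells.shape[0] != 4:
            raise ValueError("load_cells must have shape (4, L)")
        if self.bp.shape != (self.load_cells.shape[1],):
            raise ValueError("bp length must match load-cell channel length")

    @property
    def n_samples(self) -> int:
        return self.bp.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs


def _beat_onsets(params: ParticipantParams, duration: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Beat onset times covering [0, duration), first beat at t=0.

    Inter-beat intervals are 60/hr_k with hr_k = heart_rate + Gaussian
    jitter (truncated above 30 bpm to keep intervals bounded).
    """
    onsets = [0.0]
    while onsets[-1] < duration:
        hr = params.heart_rate + rng.normal(0.0, params.hr_jitter_sd)
        hr = max(hr, 30.0)
        onsets.append(onsets[-1] + 60.0 / hr)
    return np.asarray(onsets)


def _bp_waveform(t: np.ndarray, onsets: np.ndarray,
                 params: ParticipantParams) -> np.ndarray:
    """Piecewise beat template evaluated at sample times ``t``.

    Each beat rises from the diastolic level to the systolic level with a
    raised-cosine upstroke over UPSTROKE_S, then relaxes exponentially; the
    decay is renormalized so the waveform returns exactly to the diastolic
    level at the next beat onset (continuous waveform, trough = dbp_level).
    """
    pp = params.sbp_level - params.dbp_level
    # beat index of each sample: last onset <= t
    k = np.searchsorted(onsets, t, side="right") - 1
    k = np.clip(k, 0, len(onsets) - 2)
    s = t - onsets[k]                       # time since beat onset
    ibi = onsets[k + 1] - onsets[k]
    x = np.empty_like(t)
    up = s < UPSTROKE_S
    x[up] = 0.5 * (1.0 - np.cos(np.pi * s[up] / UPSTROKE_S))
    sd = s[~up] - UPSTROKE_S                # time into the decay segment
    span = np.maximum(ibi[~up] - UPSTROKE_S, 1e-6)
    # decay renormalized to land exactly at 0 at the next onset
    e_end = np.exp(-span / DECAY_TAU_S)
    x[~up] = (np.exp(-sd / DECAY_TAU_S) - e_end) / (1.0 - e_end)
    return params.dbp_level + pp * x


def _kernel_grid(fs: float) -> np.ndarray:
    """Common kernel time base, seconds relative to the beat onset."""
    return np.arange(-BCG_HALF_SUPPORT_S, OSC_SUPPORT_S + 0.5 / fs, 1.0 / fs)


def _bcg_kernel(fs: float) -> np.ndarray:
    """Biphasic derivative-of-Gaussian ejection complex, peak 1 near the
    onset (~0.3 s support on the shared grid)."""
    tk = _kernel_grid(fs)
    k = -tk / BCG_SIGMA_S**2 * np.exp(-(tk**2) / (2 * BCG_SIGMA_S**2))
    return k / np.max(np.abs(k))


def _damped_osc_kernel(fs: float, freq_hz: float, phase: float = 0.0
                       ) -> np.ndarray:
    """Causal damped sinusoid spanning most of the beat, peak ~1."""
    tk = _kernel_grid(fs)
    k = np.where(tk >= 0,
                 np.sin(2 * np.pi * freq_hz * tk + phase)
                 * np.exp(-np.maximum(tk, 0.0) / OSC_DECAY_TAU_S),
                 0.0)
    return k / np.max(np.abs(k))


def _fractional_impulses(times: np.ndarray, amplitude: float, L: int,
                         fs: float) -> np.ndarray:
    """Impulse train with sub-sample placement.

    Each impulse is split linearly across the two neighbouring samples, so
    convolution with a smooth kernel approximates the continuously shifted
    pulse to first order — the timing information survives sampling while
    the signal stays a linear combination of grid-shifted kernels.
    """
    out = np.zeros(L)
    pos = times * fs
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    ok = (i0 >= 0) & (i0 < L - 1)
    np.add.at(out, i0[ok], amplitude * (1.0 - frac[ok]))
    np.add.at(out, i0[ok] + 1, amplitude * frac[ok])
    return out


def _cardiac_force(t: np.ndarray, onsets: np.ndarray,
                   params: ParticipantParams, fs: float) -> np.ndarray:
    """Gain-1 cardiac component of a load-cell channel.

    Each beat contributes one impulse response: the superposition of a
    biphasic derivative-of-Gaussian ejection complex whose amplitude is
    affine in the beat's pulse pressure, a damped 3 Hz oscillation
    proportional to the diastolic level, and a fixed-amplitude damped
    4.5 Hz oscillation serving as a gain reference. The oscillations
    carry energy across most of the beat, so every 0.5-s window sees
    cardiac signal; all components share one onset (beat phase stays
    unambiguous) and their amplitude ratios are invariant to the unknown
    per-channel gain, keeping both pressures decodable from shape alone.
    """
    L = len(t)
    pp = params.sbp_level - params.dbp_level
    impulses = _fractional_impulses(onsets, 1.0, L, fs)
    amp_pp = BCG_AMP_OFFSET + BCG_AMP_SLOPE * pp
    amp_lvl = LEVEL_WAVE_SCALE * params.dbp_level
    kernel = (amp_pp * _bcg_kernel(fs)
              + amp_lvl * _damped_osc_kernel(fs, LEVEL_OSC_FREQ_HZ)
              + REF_WAVE_AMPLITUDE * _damped_osc_kernel(fs, REF_OSC_FREQ_HZ))
    # causal alignment: the kernel grid starts BCG_HALF_SUPPORT_S before
    # the onset, so shift the full convolution accordingly
    offset = int(round(BCG_HALF_SUPPORT_S * fs))
    full = np.convolve(impulses, kernel, mode="full")
    return full[offset:offset + L]


def simulate_participant(params: ParticipantParams, duration: float = 480.0,
                         fs: float = 100.0) -> Recording:
    """Simulate one synchronized load-cell + BP recording.

    Parameters
    ----------
    params
        Generative parameters; all randomness derives from ``params.seed``,
        so identical inputs yield bit-identical recordings.
    duration
        Recording length in seconds (must be positive).
    fs
        Sampling rate; 100 Hz (native working rate) or 1000 Hz (to exercise
        the decimation path).

    Returns
    -------
    Recording
        ``L = round(duration * fs)`` samples per channel.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs not in (100, 1000, 100.0, 1000.0):
        raise ValueError("fs must be 100 or 1000 Hz")

    rng = np.random.default_rng(params.seed)
    L = int(round(duration * fs))
    t = np.arange(L) / fs

    onsets = _beat_onsets(params, duration + 1.0, rng)
    bp = _bp_waveform(t, onsets, params)

    f_resp = params.resp_rate / 60.0
    resp_phase = rng.uniform(0, 2 * np.pi)
    bp += params.resp_bp_mmhg * np.sin(2 * np.pi * f_resp * t + resp_phase)
    drift_freq = rng.uniform(0.01, 0.03)    # Hz, slow baseline wander
    drift_phase = rng.uniform(0, 2 * np.pi)
    bp += params.bp_drift_mmhg * np.sin(2 * np.pi * drift_freq * t + drift_phase)

    # --- load cells: per-beat BCG complex + level-encoding wave ---
    bcg = _cardiac_force(t, onsets, params, fs)

    load_cells = np.empty((4, L))
    for j in range(4):
        ch_phase = rng.uniform(0, 2 * np.pi)
        ch = params.channel_gains[j] * bcg
        ch = ch + LC_RESP_AMPLITUDE * np.sin(2 * np.pi * f_resp * t + ch_phase)
        if params.drift_amplitude > 0:
            dphase = rng.uniform(0, 2 * np.pi)
            ch = ch + params.drift_amplitude * np.sin(
                2 * np.pi * drift_freq * t + dphase)
        if params.noise_sd > 0:
            ch = ch + rng.normal(0.0, params.noise_sd, size=L)
        load_cells[j] = ch

    return Recording(participant_id=params.participant_id, fs=float(fs),
                     load_cells=load_cells, bp=bp)


@dataclass(frozen=True)
class CohortConfig:
    """Population-level sampling distributions for a simulated cohort.

    Defaults: SBP ~ U(108, 142) mmHg, DBP ~ U(68, 92) mmHg, heart rate
    ~ N(65, 8) bpm truncated above 40, respiratory rate ~ U(12, 18)
    breaths/min, per-channel gains ~ U(0.8, 1.2).
    """

    sbp_range: tuple[float, float] = (108.0, 142.0)
    dbp_range: tuple[float, float] = (68.0, 92.0)
    hr_mean: float = 65.0
    hr_sd: float = 8.0
    hr_min: float = 40.0
    resp_range: tuple[float, float] = (12.0, 18.0)
    gain_range: tuple[float, float] = (0.8, 1.2)
    hr_jitter_sd: float = 2.0
    noise_sd: float = 0.1
    drift_amplitude: float = 0.2
    resp_bp_mmhg: float = 2.0
    bp_drift_mmhg: float = 1.0


def draw_participant_params(config: CohortConfig, participant_id: str,
                            param_rng: np.random.Generator,
                            seed: int) -> ParticipantParams:
    """Draw one participant's parameters from the cohort distributions."""
    hr = param_rng.normal(config.hr_mean, config.hr_sd)
    while hr <= config.hr_min:
        hr = param_rng.normal(config.hr_mean, config.hr_sd)
    return ParticipantParams(
        participant_id=participant_id,
        sbp_level=param_rng.uniform(*config.sbp_range),
        dbp_level=param_rng.uniform(*config.dbp_range),
        heart_rate=hr,
        hr_jitter_sd=config.hr_jitter_sd,
        resp_rate=param_rng.uniform(*config.resp_range),
        channel_gains=tuple(param_rng.uniform(*config.gain_range, size=4)),
        noise_sd=config.noise_sd,
        drift_amplitude=config.drift_amplitude,
        resp_bp_mmhg=config.resp_bp_mmhg,
        bp_drift_mmhg=config.bp_drift_mmhg,
        seed=seed,
    )


def cohort_params(n_participants: int, config: CohortConfig | None = None,
                  master_seed: int = 0) -> list[ParticipantParams]:
    """Deterministically derive the parameter list for a cohort.

    Per-participant seeds come from ``np.random.SeedSequence(master_seed)``
    spawn keys, which are stable across platforms and NumPy versions.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    config = config or CohortConfig()
    base = np.random.SeedSequence(master_seed)
    param_rng = np.random.default_rng(base.spawn(1)[0])
    out = []
    for i in range(n_participants):
        child = np.random.SeedSequence(master_seed, spawn_key=(1, i))
        seed = int(child.generate_state(1)[0])
        out.append(draw_participant_params(
            config, f"P{i + 1:02d}", param_rng, seed))
    return out


def simulate_cohort(n_participants: int, config: CohortConfig | None = None,
                    master_seed: int = 0, duration: float = 480.0,
                    fs: float = 100.0) -> list[Recording]:
    """Simulate a cohort of paired recordings.

    A pure function of (config, master_seed, duration, fs): calling twice
    with the same arguments yields bit-identical cohorts.
    """
    params = cohort_params(n_participants, config, master_seed)
    return [simulate_participant(p, duration=duration, fs=fs) for p in params]


def params_to_dict(p: ParticipantParams) -> dict:
    d = dataclasses.asdict(p)
    d["channel_gains"] = list(d["channel_gains"])
    return d
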