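"""Shared fixtures.

The expensive end-to-end training run (12-participant cohort, 8/2/2
participant split, 120 s recordings, 30 epochs) is session-scoped so the
acceptance-style tests and the statistical property tests share one seeded
execution.
"""

from __future__ import annotations

import dataclasses

import pytest

import bedpress as bp
from bedpress.config import ExperimentConfig, SimulatorConfig
from bedpress.pipeline import run_experiment


@pytest.fixture(scope="session")
def noiseless_params() -> bp.ParticipantParams:
    """Degenerate generator settings: no noise, jitter, drift or respiration."""
    return bp.ParticipantParams(
        participant_id="clean", sbp_level=125.0, dbp_level=78.0,
        heart_rate=60.0, hr_jitter_sd=0.0, noise_sd=0.0,
        drift_amplitude=0.0, resp_bp_mmhg=0.0, bp_drift_mmhg=0.0, seed=3)


@pytest.fixture(scope="session")
def small_recording() -> bp.Recording:
    params = bp.ParticipantParams(participant_id="P01", seed=42)
    return bp.simulate_participant(params, duration=30.0, fs=100.0)


@pytest.fixture(scope="session")
def e2e_study() -> dict:
    """One seeded end-to-end experiment at the scaled-down study size.

    Synthetic cohort of 12 participants (8 train / 2 validation / 2 test),
    120 s each at 100 Hz with the default moderate-noise generator, 30
    training epochs at batch 256.
    """
    cfg = dataclasses.replace(
        ExperimentConfig(),
        simulator=SimulatorConfig(n_participants=12, duration=120.0,
                                  fs=100.0, master_seed=7),
        split_fractions=(8 / 12, 2 / 12, 2 / 12), split_seed=7,
        train=bp.TrainConfig(epochs=30, batch_size=256, seed=0))
    report = run_experiment(cfg)
    report["_config"] = cfg
    return report
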