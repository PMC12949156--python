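"""Shared fixtures: small synthetic trial sets and reduced cohort configs."""

from __future__ import annotations

import numpy as np
import pytest

from synaptometry.cohort import CohortConfig
from synaptometry.efr import EFRTrialSet


def make_trialset(
    harmonic_amps=(1.0,),
    fm_hz: float = 100.0,
    sample_rate_hz: float = 4096.0,
    duration_s: float = 0.5,
    noise_sd: float = 0.0,
    artifact_amp: float = 0.0,
    carrier_hz: float = 1200.0,
    n_per_polarity: int = 8,
    seed: int = 0,
    phases=None,
) -> EFRTrialSet:
    """Small analytic trial set: harmonics of fm plus optional white noise
    and a polarity-inverting carrier-frequency artifact."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    response = np.zeros(n)
    for i, a in enumerate(harmonic_amps):
        ph = 0.0 if phases is None else phases[i]
        response += a * np.sin(2 * np.pi * (i + 1) * fm_hz * t + ph)
    artifact = artifact_amp * np.sin(2 * np.pi * carrier_hz * t)
    n_trials = 2 * n_per_polarity
    polarity = np.where(np.arange(n_trials) % 2 == 0, 1, -1)
    trials = (
        response[None, :]
        + rng.normal(0.0, noise_sd, size=(n_trials, n)) * (noise_sd > 0)
        + polarity[:, None] * artifact[None, :]
    )
    return EFRTrialSet(
        trials=trials,
        sample_rate_hz=sample_rate_hz,
        polarity=polarity,
        fm_hz=fm_hz,
        carrier_hz=carrier_hz,
    )


@pytest.fixture
def small_cohort_config():
    """Reduced-size cohort for fast structural tests (defaults otherwise)."""
    return CohortConfig(
        seed=42,
        group_sizes={"young": 6, "acute_noise": 5, "aged": 5, "aged_noise": 5},
    )


@pytest.fixture
def default_cohort_config():
    return CohortConfig(seed=7)
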