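"""Envelope-following-response (EFR) magnitude estimation.

The estimator is a balanced bootstrap over trials: each draw samples, with
replacement, an equal number of trials from each stimulus polarity, averages
the sampled waveforms, and takes the single-sided DFT amplitude spectrum of
the average. Harmonic amplitudes ``f_0..f_4`` are read off the bins at the
modulation frequency and its first four multiples; the noise floor ``n_i``
around each harmonic is the mean amplitude in the 4th-7th DFT bins on either
side (eight bins total). The estimate of record for each quantity is the mean
over bootstrap draws.

Five magnitude metrics are derived from the bootstrap distribution:

====================  =====================================================
``f0``                ``20*log10(f_0)``                  (dB re 1 uV)
``f0_4``              ``20*log10(sum_i f_i)``            (dB re 1 uV)
``f0_snr``            ``20*log10(f_0 / n_0)``            (dB)
``f0_4_snr``          ``20*log10(sum_i f_i / n_i)``      (dB)
``f0_4_power``        ``10*log10(sum_i f_i**2)``         (dB re 1 uV^2)
``plv``               phase-locking value, in [0, 1]
====================  =====================================================

Amplitudes are single-sided spectral amplitudes in uV; the dB reference is
1 uV. The SNR metrics are reference-free. The PLV is the bootstrap mean of
the per-draw magnitude of the mean unit phasor of the sampled trials' f_0
phases.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EFRTrialSet",
    "BootstrapSpectrum",
    "EFRMethod",
    "EFRMeasures",
    "amplitude_spectrum",
    "bootstrap_spectrum",
    "estimate_noise_floor",
    "compute_efr_measure",
    "compute_plv",
    "save_trialset",
    "load_trialset",
]

#: noise-floor bins on either side of the harmonic: the 4th through 7th.
NOISE_BIN_OFFSETS = np.array([-7, -6, -5, -4, 4, 5, 6, 7])

#: number of harmonics analysed (f_0 .. f_4).
N_HARMONICS = 5


class EFRMethod(str, enum.Enum):
    F0 = "f0"
    F0_4 = "f0_4"
    F0_SNR = "f0_snr"
    F0_4_SNR = "f0_4_snr"
    PLV = "plv"
    F0_4_POWER = "f0_4_power"


@dataclass
class EFRTrialSet:
    """Trial-level evoked responses to a single amplitude-modulated stimulus.

    ``trials`` is an (n_trials, n_samples) matrix in uV; ``polarity`` holds
    the per-trial stimulus polarity label (+1 or -1), with equal counts per
    polarity. The epoch length must place the modulation frequency exactly on
    a DFT bin (``fm_hz * n_samples / sample_rate_hz`` integer).
    """

    trials: np.ndarray
    sample_rate_hz: float
    polarity: np.ndarray
    fm_hz: float
    carrier_hz: float
    ear_id: str = ""
    stimulus: str = ""

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials)
        self.polarity = np.asarray(self.polarity)
        if self.trials.ndim != 2:
            raise ValueError("trials must be a 2-D (n_trials, n_samples) matrix")
        if len(self.polarity) != self.trials.shape[0]:
            raise ValueError("one polarity label per trial required")
        n_pos = int(np.sum(self.polarity > 0))
        n_neg = int(np.sum(self.polarity < 0))
        if n_pos != n_neg:
            raise ValueError(
                f"unequal trial counts per polarity ({n_pos} positive, {n_neg} inverted)"
            )
        cycles = self.fm_hz * self.trials.shape[1] / self.sample_rate_hz
        if abs(cycles - round(cycles)) > 1e-6:
            raise ValueError(
                f"modulation frequency {self.fm_hz} Hz does not fall on a DFT bin "
                f"of the {self.trials.shape[1]}-sample epoch"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def bin_hz(self) -> float:
        return self.sample_rate_hz / self.trials.shape[1]


@dataclass
class BootstrapSpectrum:
    """Bootstrap distribution of harmonic and noise-floor amplitudes.

    ``mags`` and ``noise`` are (n_draws, 5) arrays of amplitudes (uV) at
    f_0..f_4 and their surrounding noise floors; ``phase_f0`` is the per-draw
    DFT phase at f_0 (radians). ``draw_counts`` logs, for reproducibility, how
    many times each trial entered each draw.
    """

    n_draws: int
    mags: np.ndarray
    noise: np.ndarray
    phase_f0: np.ndarray
    bin_hz: float
    harmonic_hz: np.ndarray
    draw_counts: np.ndarray | None = None
    #: per-draw phase-locking value across the draw's sampled trials
    plv_draws: np.ndarray | None = None
    ear_id: str = ""
    stimulus: str = ""

    def mean_mags(self) -> np.ndarray:
        """Across-draw mean harmonic amplitudes (the estimates of record)."""
        return self.mags.mean(axis=0)

    def mean_noise(self) -> np.ndarray:
        return self.noise.mean(axis=0)


@dataclass
class EFRMeasures:
    """A single scalar EFR magnitude metric."""

    method: EFRMethod
    value: float
    ear_id: str = ""
    stimulus: str = ""


def amplitude_spectrum(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Single-sided DFT amplitude spectrum.

    Returns amplitudes such that a sinusoid ``A*sin(2*pi*f*t)`` with ``f`` on
    a bin yields amplitude ``A`` at that bin. No window is applied
    (rectangular), so on-bin components are exact.
    """
    x = np.asarray(x)
    n = x.shape[axis]
    spec = np.abs(np.fft.rfft(x, axis=axis)) * (2.0 / n)
    # DC (and Nyquist, if present) are not doubled
    sl = [slice(None)] * spec.ndim
    sl[axis] = 0
    spec[tuple(sl)] /= 2.0
    if n % 2 == 0:
        sl[axis] = -1
        spec[tuple(sl)] /= 2.0
    return spec


def estimate_noise_floor(spectrum: np.ndarray, harmonic_bin: int) -> float:
    """Noise floor around a harmonic: mean of the 4th-7th bins on each side.

    ``spectrum`` is a full single-sided amplitude spectrum; exactly eight bins
    ({-7..-4, +4..+7} relative to ``harmonic_bin``) contribute.
    """
    spectrum = np.asarray(spectrum)
    if harmonic_bin < 7 or harmonic_bin > len(spectrum) - 8:
        raise ValueError(
            f"harmonic bin {harmonic_bin} closer than 7 bins to the spectrum edge"
        )
    return float(np.mean(spectrum[harmonic_bin + NOISE_BIN_OFFSETS]))


def _harmonic_bins(t: EFRTrialSet) -> np.ndarray:
    bins = np.array(
        [round((i + 1) * t.fm_hz / t.bin_hz) for i in range(N_HARMONICS)], dtype=int
    )
    n_bins = t.trials.shape[1] // 2 + 1
    if bins[-1] > n_bins - 8:
        raise ValueError(
            f"highest harmonic ({(N_HARMONICS) * t.fm_hz} Hz) too close to Nyquist "
            f"for noise-floor estimation"
        )
    return bins


def bootstrap_spectrum(
    t: EFRTrialSet,
    n_draws: int = 100,
    draw_size: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> BootstrapSpectrum:
    """Balanced bootstrap of the EFR magnitude spectrum.

    Each of ``n_draws`` draws samples ``draw_size/2`` trials with replacement
    from each polarity (default ``draw_size`` = the number of trials, i.e.
    128 draws of 64 + 64 for the standard acquisition), averages the sampled
    waveforms, and computes the amplitude spectrum of the average. Polarity
    balance cancels components that invert with stimulus polarity (stimulus
    artifact, cochlear microphonic).
    """
    if draw_size is None:
        draw_size = t.n_trials
    if draw_size % 2 != 0:
        raise ValueError("draw_size must be even (balanced across polarities)")
    rng = np.random.default_rng(rng)
    half = draw_size // 2

    pos = np.flatnonzero(t.polarity > 0)
    neg = np.flatnonzero(t.polarity < 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("trials required in both polarities")

    # multiplicity of each trial in each draw; multinomial sampling is
    # equivalent to `half` independent draws with replacement
    counts = np.zeros((n_draws, t.n_trials))
    counts[:, pos] = rng.multinomial(half, np.full(len(pos), 1.0 / len(pos)), size=n_draws)
    counts[:, neg] = rng.multinomial(half, np.full(len(neg), 1.0 / len(neg)), size=n_draws)

    trials = t.trials if t.trials.dtype == np.float64 else t.trials.astype(np.float32)
    draw_means = (counts.astype(trials.dtype) @ trials) / draw_size

    n = draw_means.shape[1]
    coeffs = np.fft.rfft(draw_means, axis=1)
    spectra = np.abs(coeffs) * (2.0 / n)
    spectra[:, 0] /= 2.0
    if n % 2 == 0:
        spectra[:, -1] /= 2.0

    bins = _harmonic_bins(t)
    mags = spectra[:, bins]
    noise = np.stack(
        [spectra[:, b + NOISE_BIN_OFFSETS].mean(axis=1) for b in bins], axis=1
    )
    phase_f0 = np.angle(coeffs[:, bins[0]])

    # per-trial f0 phasors (single DFT bin) -> per-draw PLV over the trials
    # the draw sampled, weighted by multiplicity
    k = bins[0]
    basis = np.exp(-2j * np.pi * k * np.arange(n) / n)
    trial_phasors = (t.trials.astype(np.float64) @ basis)
    unit = trial_phasors / np.maximum(np.abs(trial_phasors), 1e-300)
    plv_draws = np.abs(counts @ unit) / draw_size

    return BootstrapSpectrum(
        n_draws=n_draws,
        mags=np.asarray(mags, dtype=np.float64),
        noise=np.asarray(noise, dtype=np.float64),
        phase_f0=np.asarray(phase_f0, dtype=np.float64),
        bin_hz=t.bin_hz,
        harmonic_hz=(np.arange(N_HARMONICS) + 1) * t.fm_hz,
        draw_counts=counts.astype(np.int32),
        plv_draws=plv_draws,
        ear_id=t.ear_id,
        stimulus=t.stimulus,
    )


def compute_plv(b: BootstrapSpectrum) -> EFRMeasures:
    """Phase-locking value at f_0, in [0, 1].

    The estimate of record is the bootstrap mean of the per-draw PLV, where
    each draw's PLV is the magnitude of the mean unit phasor of its sampled
    trials' f_0 phases (multiplicity-weighted). Identical trials give 1;
    phase-incoherent noise gives ~1/sqrt(n_trials). For a spectrum built
    without per-trial phases, the across-draw phasor of the draw-average
    phase is used instead.
    """
    if b.plv_draws is not None:
        plv = float(np.mean(b.plv_draws))
    else:
        plv = float(np.abs(np.mean(np.exp(1j * b.phase_f0))))
    return EFRMeasures(EFRMethod.PLV, plv, b.ear_id, b.stimulus)


def measures_from_amplitudes(
    f: np.ndarray, n: np.ndarray | None, method: EFRMethod
) -> float:
    """Evaluate a magnitude metric on harmonic amplitudes ``f`` (uV) and
    noise floors ``n`` (uV). Exposed separately so the same formulas apply to
    bootstrap means and to closed-form expected spectra."""
    f = np.asarray(f, dtype=float)
    if method is EFRMethod.F0:
        return float(20.0 * np.log10(f[0]))
    if method is EFRMethod.F0_4:
        return float(20.0 * np.log10(np.sum(f)))
    if method is EFRMethod.F0_4_POWER:
        return float(10.0 * np.log10(np.sum(f**2)))
    if method in (EFRMethod.F0_SNR, EFRMethod.F0_4_SNR):
        if n is None:
            raise ValueError("noise floors required for SNR metrics")
        n = np.asarray(n, dtype=float)
        if np.any(n == 0.0):
            raise ValueError(
                "zero noise floor: SNR metrics are undefined for noiseless input"
            )
        if method is EFRMethod.F0_SNR:
            return float(20.0 * np.log10(f[0] / n[0]))
        return float(20.0 * np.log10(np.sum(f / n)))
    raise ValueError(f"unsupported method {method}")


def compute_efr_measure(b: BootstrapSpectrum, method: EFRMethod | str) -> EFRMeasures:
    """Evaluate one magnitude metric on the across-draw mean amplitudes."""
    method = EFRMethod(method)
    if method is EFRMethod.PLV:
        return compute_plv(b)
    value = measures_from_amplitudes(b.mean_mags(), b.mean_noise(), method)
    return EFRMeasures(method, value, b.ear_id, b.stimulus)


def save_trialset(t: EFRTrialSet, path) -> None:
    """Write a trial set as a one-line JSON header followed by a float32
    row-major trial matrix."""
    header = {
        "n_trials": int(t.n_trials),
        "n_samples": int(t.trials.shape[1]),
        "sample_rate_hz": t.sample_rate_hz,
        "fm_hz": t.fm_hz,
        "carrier_hz": t.carrier_hz,
        "ear_id": t.ear_id,
        "stimulus": t.stimulus,
        "polarity": [int(p) for p in t.polarity],
        "dtype": "float32",
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        fh.write(np.ascontiguousarray(t.trials, dtype=np.float32).tobytes())


def load_trialset(path) -> EFRTrialSet:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        data = np.frombuffer(fh.read(), dtype=np.float32)
    trials = data.reshape(header["n_trials"], header["n_samples"])
    return EFRTrialSet(
        trials=trials,
        sample_rate_hz=header["sample_rate_hz"],
        polarity=np.array(header["polarity"]),
        fm_hz=header["fm_hz"],
        carrier_hz=header["carrier_hz"],
        ear_id=header.get("ear_id", ""),
        stimulus=header.get("stimulus", ""),
    )
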