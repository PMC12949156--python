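"""ABR wave-1 metrics: amplitudes, growth slopes, and thresholds.

Wave 1 of the auditory brainstem response is the earliest component,
generated by the auditory nerve. From a level series (10-80 dB SPL in 5 dB
steps) this module extracts the wave-1 amplitude at fixed levels (60/70/80 dB
SPL), the growth slope over the two highest levels (``slope_2``: 75 and 80),
the four highest (``slope_4``: 65-80), or all collected levels
(``slope_all``), and a simple threshold.

Amplitude convention: peak-to-following-trough (configurable to
baseline-to-peak). The threshold criterion — lowest level whose amplitude
exceeds ``k`` times the noise scale with all higher levels also exceeding it
— is a deliberately simple, documented procedure, not a re-implementation of
published peak-picking/threshold software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ABRGrowth",
    "ABRSummary",
    "Wave1Pick",
    "bandpass_abr",
    "pick_wave1",
    "wave1_slope",
    "estimate_abr_threshold",
    "abr_summary",
]

SLOPE_LEVELS = {"TOP2": (75.0, 80.0), "TOP4": (65.0, 70.0, 75.0, 80.0)}


@dataclass
class ABRGrowth:
    """Wave-1 amplitude as a function of stimulus level for one ear x frequency."""

    ear_id: str
    frequency_hz: float
    levels: np.ndarray
    wave1_uv: np.ndarray
    threshold_db: float | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.wave1_uv = np.asarray(self.wave1_uv, dtype=float)
        if len(self.levels) != len(self.wave1_uv):
            raise ValueError("levels and amplitudes must align")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if not np.all(np.isfinite(self.wave1_uv)):
            raise ValueError("amplitudes must be finite")

    def amplitude_at(self, level: float) -> float:
        idx = np.flatnonzero(np.isclose(self.levels, level))
        if len(idx) == 0:
            raise ValueError(f"level {level} dB SPL not measured")
        return float(self.wave1_uv[idx[0]])


@dataclass
class ABRSummary:
    ear_id: str
    frequency_hz: float
    amp80: float
    amp70: float
    amp60: float
    slope2: float
    slope4: float
    slope_all: float
    threshold_db: float | None


@dataclass
class Wave1Pick:
    latency_s: float
    amplitude_uv: float
    flagged: bool = False


def bandpass_abr(
    waveform: np.ndarray,
    sample_rate_hz: float,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 300-3000 Hz) of an averaged
    ABR trace."""
    if sample_rate_hz <= 2.0 * high_hz:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low for a {high_hz} Hz band edge"
        )
    sos = signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float))


def pick_wave1(
    trace: np.ndarray,
    sample_rate_hz: float,
    window_s: tuple[float, float] = (0.001, 0.003),
    noise_uv: float = 0.0,
    convention: str = "peak_to_trough",
) -> Wave1Pick:
    """Locate wave 1 in a filtered trace and measure its amplitude.

    The first prominent positive peak inside ``window_s`` is taken as wave 1;
    amplitude is the peak minus the following trough (or the peak value
    itself with ``convention="baseline_to_peak"``). If no peak rises above
    the noise criterion the pick is flagged and the trace maximum within the
    window is reported as a noise-level amplitude.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(window_s[0] * sample_rate_hz))
    i1 = int(round(window_s[1] * sample_rate_hz))
    if i0 < 0 or i1 > len(trace) or i1 <= i0:
        raise ValueError("window outside trace")
    seg = trace[i0:i1]
    peaks, props = signal.find_peaks(seg, prominence=max(noise_uv, 1e-12))
    if len(peaks) == 0:
        j = int(np.argmax(seg))
        return Wave1Pick((i0 + j) / sample_rate_hz, float(max(seg[j], 0.0)), True)
    p = peaks[0]
    latency = (i0 + p) / sample_rate_hz
    if convention == "baseline_to_peak":
        return Wave1Pick(latency, float(seg[p]))
    # following trough: minimum between this peak and the next peak (or the
    # end of a trailing window of the same width as the search window)
    tail_end = peaks[1] if len(peaks) > 1 else min(len(trace) - i0, 2 * (i1 - i0))
    after = seg[p:tail_end] if tail_end > p + 1 else trace[i0 + p : i1]
    trough = float(np.min(after)) if len(after) else float(seg[p])
    return Wave1Pick(latency, float(seg[p] - trough))


def wave1_slope(g: ABRGrowth, which: str = "ALL") -> float:
    """OLS slope (uV/dB) of wave-1 amplitude against level.

    ``which`` selects the levels: ``"TOP2"`` (75, 80 dB SPL), ``"TOP4"``
    (65-80 dB SPL), or ``"ALL"`` (every collected level).
    """
    which = which.upper()
    if which == "ALL":
        levels, amps = g.levels, g.wave1_uv
    elif which in SLOPE_LEVELS:
        wanted = SLOPE_LEVELS[which]
        mask = np.isin(g.levels, wanted)
        if mask.sum() != len(wanted):
            raise ValueError(f"levels {wanted} required for {which} slope")
        levels, amps = g.levels[mask], g.wave1_uv[mask]
    else:
        raise ValueError(f"unknown slope selector {which!r}")
    if len(levels) < 2:
        raise ValueError("at least two levels required for a slope")
    return float(np.polyfit(levels, amps, 1)[0])


def estimate_abr_threshold(
    g: ABRGrowth, noise_uv: float, k: float = 3.0
) -> float | None:
    """Lowest level whose amplitude exceeds ``k * noise_uv`` with every higher
    level also exceeding it; ``None`` if no level qualifies ("not reached")."""
    if len(g.levels) < 3:
        raise ValueError("at least three levels required")
    above = g.wave1_uv > k * noise_uv
    # suffix of levels that are all above criterion
    for i in range(len(above)):
        if above[i:].all():
            return float(g.levels[i])
    return None


def abr_summary(g: ABRGrowth, noise_uv: float = 0.05) -> ABRSummary:
    """Extract the amplitude, slope, and threshold summaries used as model
    predictors."""
    return ABRSummary(
        ear_id=g.ear_id,
        frequency_hz=g.frequency_hz,
        amp80=g.amplitude_at(80.0),
        amp70=g.amplitude_at(70.0),
        amp60=g.amplitude_at(60.0),
        slope2=wave1_slope(g, "TOP2"),
        slope4=wave1_slope(g, "TOP4"),
        slope_all=wave1_slope(g, "ALL"),
        threshold_db=estimate_abr_threshold(g, noise_uv),
    )
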