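"""Synthesis of the acoustic stimuli used in evoked-potential assays.

Three stimulus families are supported:

* **SAM** — sinusoidally amplitude-modulated carrier tones,
  envelope ``(1 + depth * sin(2*pi*fm*t))``.
* **RAM** — rectangularly amplitude-modulated carrier tones: within each
  modulation period the envelope is "on" for ``duty_cycle`` of the period and
  zero otherwise, with raised-cosine (Tukey-style) tapers at each on/off edge.
* **Tone pips** — short gated tones with cosine-squared rise/fall ramps,
  presented in interleaved frequency x level trains.

All levels are overall RMS levels in dB SPL re 20 uPa.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "StimulusKind",
    "StimulusSpec",
    "Waveform",
    "InterleavedSchedule",
    "synthesize",
    "synthesize_sam",
    "synthesize_ram",
    "synthesize_tone_pip",
    "scale_to_spl",
    "build_interleaved_train",
    "P_REF_PA",
]

#: SPL reference pressure, 20 uPa RMS.
P_REF_PA = 20e-6


class StimulusKind(str, enum.Enum):
    SAM = "SAM"
    RAM = "RAM"
    TONE_PIP = "TONE_PIP"


class ConfigurationError(ValueError):
    """Raised when a stimulus specification violates its invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of a SAM/RAM/tone-pip stimulus.

    Parameters
    ----------
    kind
        Stimulus family.
    carrier_hz
        Carrier frequency in Hz; must be below Nyquist.
    fm_hz
        Modulation frequency in Hz (0 for tone pips). For SAM/RAM,
        ``fm_hz * duration_s`` must be a positive integer so the modulation
        frequency falls exactly on a DFT bin of the analysis epoch.
    depth
        Modulation depth fraction in [0, 1].
    duty_cycle
        RAM only: fraction of each modulation period at full envelope.
    edge_fraction
        RAM only: taper span at each on/off edge, as a fraction of the full
        modulation period.
    rise_fall_ms
        Tone pip only: cosine-squared ramp duration.
    duration_s
        Total stimulus duration in seconds.
    level_db_spl
        Overall RMS level, dB SPL re 20 uPa.
    sample_rate_hz
        Synthesis rate (default 100 kHz, comfortably above 2x a 32 kHz
        carrier).
    """

    kind: StimulusKind
    carrier_hz: float
    fm_hz: float = 0.0
    depth: float = 1.0
    duty_cycle: float = 0.25
    edge_fraction: float = 0.025
    rise_fall_ms: float = 0.5
    duration_s: float = 0.5
    level_db_spl: float = 70.0
    sample_rate_hz: float = 100_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ConfigurationError(f"depth must be in [0, 1], got {self.depth}")
        if self.kind is StimulusKind.RAM and not 0.0 < self.duty_cycle <= 1.0:
            raise ConfigurationError(
                f"duty_cycle must be in (0, 1], got {self.duty_cycle}"
            )
        if not 0.0 <= self.edge_fraction < 0.5:
            raise ConfigurationError(
                f"edge_fraction must be in [0, 0.5), got {self.edge_fraction}"
            )
        if self.carrier_hz >= self.sample_rate_hz / 2:
            raise ConfigurationError(
                f"carrier {self.carrier_hz} Hz at or above Nyquist "
                f"({self.sample_rate_hz / 2} Hz)"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.kind in (StimulusKind.SAM, StimulusKind.RAM):
            cycles = self.fm_hz * self.duration_s
            if cycles <= 0 or abs(cycles - round(cycles)) > 1e-9:
                raise ConfigurationError(
                    f"fm_hz * duration_s must be a positive integer "
                    f"(got {cycles}); the modulation frequency would not land "
                    f"on a DFT bin"
                )

    def to_json(self) -> str:
        d = asdict(self)
        d["kind"] = self.kind.value
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        d = json.loads(s)
        d["kind"] = StimulusKind(d["kind"])
        return cls(**d)


@dataclass
class Waveform:
    """A sampled pressure waveform (Pa) with its generating spec."""

    samples: np.ndarray
    sample_rate_hz: float
    spec: StimulusSpec | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def spl(self) -> float:
        """Overall level in dB SPL re 20 uPa RMS."""
        return 20.0 * np.log10(self.rms() / P_REF_PA)

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times(), "pressure_pa": self.samples}).to_csv(
            path, index=False
        )


def _time_axis(spec: StimulusSpec) -> np.ndarray:
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    return np.arange(n) / spec.sample_rate_hz


def scale_to_spl(w: Waveform, level_db_spl: float) -> Waveform:
    """Rescale a waveform so its overall RMS equals ``level_db_spl``.

    Target RMS pressure is ``20 uPa * 10**(level/20)``.
    """
    rms = w.rms()
    if rms == 0.0:
        raise ValueError("cannot scale an all-zero waveform to a target SPL")
    target = P_REF_PA * 10.0 ** (level_db_spl / 20.0)
    return Waveform(w.samples * (target / rms), w.sample_rate_hz, w.spec)


def sam_envelope(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    return 1.0 + spec.depth * np.sin(2.0 * np.pi * spec.fm_hz * t)


def ram_envelope(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    """Rectangular envelope with raised-cosine edge tapers.

    Within each modulation period of length ``T = 1/fm`` the envelope is at
    full scale for ``duty_cycle * T`` and zero otherwise; each on/off edge is
    smoothed by a raised-cosine taper spanning ``edge_fraction * T``. The
    taper span is defined relative to the full modulation period and lies
    inside the on-portion, so the above-half-maximum time is
    ``(duty_cycle - edge_fraction) * T``.
    """
    duty, edge = spec.duty_cycle, spec.edge_fraction
    if duty < 2.0 * edge:
        raise ConfigurationError(
            f"on-portion (duty_cycle={duty}) shorter than two taper spans "
            f"(2 * edge_fraction = {2 * edge}); no flat top remains"
        )
    phase = np.mod(t * spec.fm_hz, 1.0)  # position within the cycle, [0, 1)
    env = np.zeros_like(phase)
    if edge > 0:
        # rising edge centred on phase 0 .. edge; flat top; falling edge
        rise = (phase < edge)
        env[rise] = 0.5 * (1.0 - np.cos(np.pi * phase[rise] / edge))
        flat = (phase >= edge) & (phase <= duty - edge)
        env[flat] = 1.0
        fall = (phase > duty - edge) & (phase < duty)
        env[fall] = 0.5 * (1.0 - np.cos(np.pi * (duty - phase[fall]) / edge))
    else:
        env[phase < duty] = 1.0
    # modulation depth < 1 lifts the floor
    return (1.0 - spec.depth) + spec.depth * env


def synthesize_sam(spec: StimulusSpec) -> Waveform:
    """Sinusoidally amplitude-modulated carrier, scaled to ``level_db_spl``."""
    if spec.kind is not StimulusKind.SAM:
        raise ConfigurationError(f"expected kind SAM, got {spec.kind}")
    t = _time_axis(spec)
    x = sam_envelope(spec, t) * np.sin(2.0 * np.pi * spec.carrier_hz * t)
    return scale_to_spl(Waveform(x, spec.sample_rate_hz, spec), spec.level_db_spl)


def synthesize_ram(spec: StimulusSpec) -> Waveform:
    """Rectangularly amplitude-modulated carrier, scaled to ``level_db_spl``."""
    if spec.kind is not StimulusKind.RAM:
        raise ConfigurationError(f"expected kind RAM, got {spec.kind}")
    t = _time_axis(spec)
    x = ram_envelope(spec, t) * np.sin(2.0 * np.pi * spec.carrier_hz * t)
    return scale_to_spl(Waveform(x, spec.sample_rate_hz, spec), spec.level_db_spl)


def tone_pip_envelope(spec: StimulusSpec, t: np.ndarray) -> np.ndarray:
    rise = spec.rise_fall_ms / 1000.0
    dur = spec.duration_s
    if dur < 2.0 * rise:
        raise ConfigurationError(
            f"duration {dur * 1e3:g} ms shorter than rise + fall "
            f"({2 * rise * 1e3:g} ms)"
        )
    env = np.ones_like(t)
    if rise > 0:
        on = t < rise
        env[on] = np.sin(0.5 * np.pi * t[on] / rise) ** 2
        off = t > dur - rise
        env[off] = np.sin(0.5 * np.pi * (dur - t[off]) / rise) ** 2
    return env


def synthesize_tone_pip(spec: StimulusSpec) -> Waveform:
    """Gated tone pip: cos^2 onset/offset ramps with a steady-state plateau."""
    if spec.kind is not StimulusKind.TONE_PIP:
        raise ConfigurationError(f"expected kind TONE_PIP, got {spec.kind}")
    t = _time_axis(spec)
    x = tone_pip_envelope(spec, t) * np.sin(2.0 * np.pi * spec.carrier_hz * t)
    return scale_to_spl(Waveform(x, spec.sample_rate_hz, spec), spec.level_db_spl)


_SYNTH = {
    StimulusKind.SAM: synthesize_sam,
    StimulusKind.RAM: synthesize_ram,
    StimulusKind.TONE_PIP: synthesize_tone_pip,
}


def synthesize(spec: StimulusSpec) -> Waveform:
    """Dispatch to the synthesizer for ``spec.kind``."""
    return _SYNTH[spec.kind](spec)


@dataclass
class InterleavedSchedule:
    """Presentation schedule for an interleaved frequency x level train.

    One train cycle presents every (frequency, level) pair once, with
    frequencies rotating fastest so consecutive stimuli differ in frequency;
    interleaving spaces repeats of any one frequency far apart, limiting
    auditory-nerve adaptation. The effective rate seen by a single frequency
    is ``overall_rate_hz / n_frequencies``.
    """

    entries: list = field(default_factory=list)  # (freq_hz, level_db, onset_s)
    overall_rate_hz: float = 81.0
    per_frequency_rate_hz: float = 0.0


def build_interleaved_train(
    frequencies, levels, overall_rate_hz: float = 81.0
) -> InterleavedSchedule:
    """Build one train cycle of an interleaved frequency x level schedule.

    Frequencies are presented in ascending order within each level step and
    levels ascend across steps (a "ramp"); the exact ordering does not affect
    downstream metrics, only the schedule contract that consecutive entries
    differ in frequency.
    """
    frequencies = sorted(frequencies)
    levels = sorted(levels)
    if not frequencies or not levels:
        raise ValueError("need at least one frequency and one level")
    entries = []
    i = 0
    for level in levels:
        for freq in frequencies:
            entries.append((float(freq), float(level), i / overall_rate_hz))
            i += 1
    return InterleavedSchedule(
        entries=entries,
        overall_rate_hz=overall_rate_hz,
        per_frequency_rate_hz=overall_rate_hz / len(frequencies),
    )


def efr_presentation_rate(
    duration_s: float = 0.5, isi_low_s: float = 0.100, isi_high_s: float = 0.120
) -> float:
    """Average presentation rate for jittered stimuli.

    A ``duration_s`` stimulus followed by an inter-stimulus interval drawn
    uniformly from [isi_low, isi_high] repeats on average every
    ``duration + (isi_low + isi_high)/2`` seconds.
    """
    return 1.0 / (duration_s + 0.5 * (isi_low_s + isi_high_s))
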