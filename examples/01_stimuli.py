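"""Synthesize SAM/RAM/tone-pip stimuli and inspect levels and schedules.

Builds the two envelope-following-response stimuli (sinusoidally and
rectangularly amplitude-modulated 16 kHz tones at 110 Hz), scales both to the
same overall level, and prints their RMS levels and peak pressures; then
builds the interleaved tone-pip train and prints its effective per-frequency
rate.
"""

import numpy as np

from synaptometry.stimuli import (
    StimulusKind,
    StimulusSpec,
    build_interleaved_train,
    efr_presentation_rate,
    ram_envelope,
    synthesize,
)

sam = StimulusSpec(StimulusKind.SAM, carrier_hz=16000.0, fm_hz=110.0,
                   level_db_spl=70.0)
ram = StimulusSpec(StimulusKind.RAM, carrier_hz=16000.0, fm_hz=110.0,
                   duty_cycle=0.25, edge_fraction=0.025, level_db_spl=70.0)

w_sam, w_ram = synthesize(sam), synthesize(ram)
print(f"SAM: {w_sam.spl():.2f} dB SPL, peak {w_sam.samples.max()*1e3:.1f} mPa")
print(f"RAM: {w_ram.spl():.2f} dB SPL, peak {w_ram.samples.max()*1e3:.1f} mPa")
# Both carry the same overall energy (70 dB SPL); the RAM envelope is "on"
# for only a quarter of each modulation cycle, so its peak pressure is higher.

t = np.arange(int(0.5 * ram.sample_rate_hz)) / ram.sample_rate_hz
frac_on = np.mean(ram_envelope(ram, t) > 0.5)
print(f"RAM envelope above half-maximum: {frac_on:.3f} of the time "
      f"(duty cycle 0.25, tapered edges)")

freqs = [5600 * 2 ** (i / 2) for i in range(7)]  # 5.6-45.2 kHz, half octaves
levels = list(range(10, 85, 5))                  # 10-80 dB SPL, 5 dB steps
sched = build_interleaved_train(freqs, levels, overall_rate_hz=81.0)
print(f"\nInterleaved ABR train: {len(sched.entries)} tone pips per cycle, "
      f"{sched.overall_rate_hz:g}/s overall -> "
      f"{sched.per_frequency_rate_hz:.1f}/s per frequency")
# Interleaving frequencies keeps repeats of any one cochlear place ~7x
# slower than the overall rate, limiting auditory-nerve adaptation.

print(f"EFR presentation rate (500 ms stimulus, 100-120 ms jitter): "
      f"{efr_presentation_rate():.2f}/s")
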