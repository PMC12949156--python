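"""DPOAE input-output summaries used as OHC-function covariates.

Distortion-product otoacoustic emissions (2*f1 - f2) index outer-hair-cell
function. From an input-output function (emission level vs. primary level L2,
10-80 dB SPL in 5 dB steps, L1 = L2 + 10, f2/f1 = 1.2) three covariates are
extracted: the threshold (L2 at which the emission crosses 0 dB SPL), and the
emission levels at L2 = 40 and 55 dB SPL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DPOAEIO", "DPOAESummary", "dpoae_threshold", "dpoae_level_at", "dpoae_summary"]


@dataclass
class DPOAEIO:
    """DPOAE input-output function for one ear x f2."""

    ear_id: str
    f2_hz: float
    l2_levels: np.ndarray
    dp_level_db_spl: np.ndarray
    #: provenance of the primary-level rule and ratio
    l1_rule: str = "L2+10"
    f2_f1_ratio: float = 1.2

    def __post_init__(self) -> None:
        self.l2_levels = np.asarray(self.l2_levels, dtype=float)
        self.dp_level_db_spl = np.asarray(self.dp_level_db_spl, dtype=float)
        if len(self.l2_levels) != len(self.dp_level_db_spl):
            raise ValueError("l2_levels and dp_level_db_spl must align")
        if np.any(np.diff(self.l2_levels) <= 0):
            raise ValueError("l2_levels must be strictly increasing")


@dataclass
class DPOAESummary:
    ear_id: str
    f2_hz: float
    threshold_db: float | None
    level_at_40: float | None
    level_at_55: float | None


def dpoae_threshold(io: DPOAEIO, method: str = "interp") -> float | None:
    """L2 at which the DPOAE level first crosses 0 dB SPL from below.

    With ``method="interp"`` (default) the crossing is linearly interpolated
    in dB-dB coordinates; ``method="step"`` reports the lowest measured L2
    with a non-negative emission. Returns ``None`` ("not reached") if the
    emission never reaches 0 dB SPL; if the emission is already non-negative
    at the lowest measured L2, that L2 is returned.
    """
    if len(io.l2_levels) < 2:
        raise ValueError("at least two points required")
    dp = io.dp_level_db_spl
    l2 = io.l2_levels
    nonneg = np.flatnonzero(dp >= 0.0)
    if len(nonneg) == 0:
        return None
    if method == "step":
        return float(l2[nonneg[0]])
    i = nonneg[0]
    if i == 0:
        return float(l2[0])
    # lowest upward crossing: interpolate between the bracketing levels
    frac = (0.0 - dp[i - 1]) / (dp[i] - dp[i - 1])
    return float(l2[i - 1] + frac * (l2[i] - l2[i - 1]))


def dpoae_level_at(io: DPOAEIO, l2: float) -> float:
    """The recorded emission level (dB SPL) at a measured L2."""
    idx = np.flatnonzero(np.isclose(io.l2_levels, l2))
    if len(idx) == 0:
        raise ValueError(f"L2 = {l2} dB SPL was not measured")
    return float(io.dp_level_db_spl[idx[0]])


def dpoae_summary(io: DPOAEIO) -> DPOAESummary:
    def _maybe(l2):
        try:
            return dpoae_level_at(io, l2)
        except ValueError:
            return None

    return DPOAESummary(
        ear_id=io.ear_id,
        f2_hz=io.f2_hz,
        threshold_db=dpoae_threshold(io),
        level_at_40=_maybe(40.0),
        level_at_55=_maybe(55.0),
    )
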