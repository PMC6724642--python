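"""Compound-stimulus saliency: saturation and AND-gated cutoff of channel sums.

When tone and flash are presented together, each stimulus degrades the
other's effective salience. Two non-linearities implement this, applied to
each channel's Go/No-Go weighted sum before it reaches the final integrator:

1. *Saturation* — the sum operator's activation becomes piecewise linear:
   the raw sum is scaled by the channel's saturation constant and clipped to
   +/- that constant. This removes the overshoot a purely linear combination
   of the two trained channels would produce.

2. *Cutoff switch* — an AND gate per channel: when the *other* channel's sum
   is still present (|sum| above a small threshold epsilon) AND the channel's
   own No-Go unit has fallen below its cutoff threshold, the channel's
   transmission to the final integrator is switched off entirely, leaving the
   integrator to discharge.

Both effects exist only on compound trials; single-stimulus trials use plain
linear sum operators.

Cutoff thresholds are published at four-decimal precision, so threshold
comparisons carry a small absolute tolerance (default 1e-4): the No-Go
activation trips a cutoff when it is below the threshold to within that
rounding scale. With the reference parameter set this places the tone cutoff
at absolute step 27 and the flash cutoff at step 54.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "SaliencyParams",
    "CompoundDrive",
    "saturating_sum",
    "cutoff_gate",
    "compound_drive",
    "first_crossing_step",
]

#: Absolute tolerance for comparisons against the 4-decimal published cutoffs.
CUTOFF_TOL = 1e-4


@dataclass(frozen=True)
class SaliencyParams:
    """Constants of the compound-stimulus saliency operator.

    Parameters
    ----------
    t_sat
        Tone (auditory) sum-operator saturation level and slope.
    f_sat
        Flash (visual) sum-operator saturation level and slope.
    cutoff_a
        Auditory cutoff: tone transmission stops once the tone No-Go unit
        falls below this (negative) threshold while flash is present.
    cutoff_v
        Visual cutoff: likewise for the flash No-Go unit.
    epsilon
        Presence threshold — the other channel's sum counts as "present"
        when its magnitude exceeds epsilon.
    latch
        If True a tripped cutoff stays tripped. With the reference weights
        the No-Go units are monotone after crossing, so latched and
        unlatched runs coincide; the flag exists to make that checkable.
    cutoff_tol
        Absolute tolerance on the cutoff comparison (see module docstring).
    """

    t_sat: float = 1.6
    f_sat: float = 0.85
    cutoff_a: float = -0.8632
    cutoff_v: float = -0.2
    epsilon: float = 0.01
    latch: bool = False
    cutoff_tol: float = CUTOFF_TOL

    def __post_init__(self) -> None:
        if not (self.t_sat > 0 and self.f_sat > 0):
            raise ValueError("saturation levels must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (self.cutoff_a < 0 and self.cutoff_v < 0):
            raise ValueError("cutoff thresholds must be negative")


class CompoundDrive(NamedTuple):
    """Per-step output of the saliency pipeline for one time step."""

    t_sum: float
    f_sum: float
    tone_cut: int
    flash_cut: int


def saturating_sum(raw_sum: float, sat: float) -> float:
    """Piecewise-linear sum-operator activation: slope ``sat``, clipped to ±``sat``.

    ``min(sat*x, sat)`` for non-negative ``x``, ``max(sat*x, -sat)`` otherwise.
    Odd, monotone non-decreasing, bounded by ``sat`` in magnitude.
    """
    if sat <= 0:
        raise ValueError("saturation level must be positive")
    if raw_sum >= 0:
        return min(sat * raw_sum, sat)
    return max(sat * raw_sum, -sat)


def cutoff_gate(
    other_sum: float,
    own_nogo: float,
    cutoff: float,
    epsilon: float,
    cutoff_tol: float = CUTOFF_TOL,
) -> int:
    """AND-gated cutoff switch: 1 (transmission blocked) iff the other
    channel's sum is present (|other_sum| > epsilon) AND the channel's own
    No-Go activation is below ``cutoff`` (within ``cutoff_tol``)."""
    return int(abs(other_sum) > epsilon and own_nogo < cutoff + cutoff_tol)


def compound_drive(
    t_raw: float,
    f_raw: float,
    t_nogo: float,
    f_nogo: float,
    params: SaliencyParams,
    tone_was_cut: bool = False,
    flash_was_cut: bool = False,
) -> CompoundDrive:
    """Apply the full saliency pipeline for one compound-trial time step.

    Both raw sums are first saturated; each channel's cutoff gate then sees
    the *other* channel's post-saturation (pre-cutoff) sum, so a channel can
    keep gating its partner even after being cut off itself. Returns the
    gated (t_sum, f_sum) pair that drives the final integrator, plus the two
    gate states.
    """
    t_sat = saturating_sum(t_raw, params.t_sat)
    f_sat = saturating_sum(f_raw, params.f_sat)
    tone_cut = cutoff_gate(
        f_sat, t_nogo, params.cutoff_a, params.epsilon, params.cutoff_tol
    )
    flash_cut = cutoff_gate(
        t_sat, f_nogo, params.cutoff_v, params.epsilon, params.cutoff_tol
    )
    if params.latch:
        tone_cut = int(tone_cut or tone_was_cut)
        flash_cut = int(flash_cut or flash_was_cut)
    return CompoundDrive(
        t_sum=0.0 if tone_cut else t_sat,
        f_sum=0.0 if flash_cut else f_sat,
        tone_cut=tone_cut,
        flash_cut=flash_cut,
    )


def first_crossing_step(
    nogo_series: np.ndarray, cutoff: float, cutoff_tol: float = CUTOFF_TOL
) -> int | None:
    """First 1-based absolute step at which a No-Go trajectory falls below
    ``cutoff`` (within ``cutoff_tol``), or None if it never does."""
    below = np.asarray(nogo_series, dtype=float) < cutoff + cutoff_tol
    if not below.any():
        return None
    return int(np.argmax(below)) + 1
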