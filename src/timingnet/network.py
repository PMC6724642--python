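"""The full two-stimulus timing network.

Each stimulus (tone, flash) drives its own pair of opponent squashing
integrator units — a fast-saturating "Go" unit and a slowly declining
"No-Go" unit. A sum operator combines each pair into a timed pulse, the two
pulses add, and a fixed-weight linear integrator (input weight 0.1, recurrent
weight 0.9) turns the summed pulse into the model's response curve, which is
compared against normalized lever-press rate.

Update order within one step: Go/No-Go next-states are computed from the
current states, the sums from the NEW Go/No-Go values, and the final
integrator from the NEW sums. With 1-based absolute steps and stimulus onset
at step 21, this convention reproduces the published cutoff-crossing steps
(27 for tone, 54 for flash).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from .core import IntegratorParams, run_unit
from .saliency import SaliencyParams, compound_drive

__all__ = [
    "NetworkWeights",
    "StimulusProtocol",
    "Trajectory",
    "simulate_channel",
    "linear_sum",
    "final_integrator_step",
    "simulate_network",
    "tone_protocol",
    "flash_protocol",
    "compound_protocol",
]

Channel = Literal["tone", "flash"]

#: Names of the weights trained during each fitting stage. The final
#: integrator (w13, w14) is never trainable.
TONE_WEIGHTS = ("w1", "w2", "w3", "w4", "w5", "w6")
FLASH_WEIGHTS = ("w7", "w8", "w9", "w10", "w11", "w12")
FIXED_WEIGHTS = ("w13", "w14")


@dataclass(frozen=True)
class NetworkWeights:
    """The fourteen connection weights of the timing network.

    w1/w2: tone Go/No-Go input weights; w3/w4: tone Go/No-Go recurrent
    weights; w5/w6: tone Go/No-Go sum weights; w7-w12: the flash channel
    analogues; w13/w14: final-integrator input and recurrent weights (fixed,
    not trainable — their values set the output stage's long time constant).
    """

    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 0.0
    w5: float = 0.0
    w6: float = 0.0
    w7: float = 0.0
    w8: float = 0.0
    w9: float = 0.0
    w10: float = 0.0
    w11: float = 0.0
    w12: float = 0.0
    w13: float = 0.1
    w14: float = 0.9

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"weight {f.name} must be finite, got {v!r}")

    names = tuple(f"w{i}" for i in range(1, 15))

    def to_dict(self) -> dict[str, float]:
        """Weights as an ordered {"W1": value, ...} mapping."""
        return {n.upper(): getattr(self, n) for n in self.names}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "NetworkWeights":
        """Build from a mapping with case-insensitive keys W1..W14."""
        unknown = [k for k in d if k.lower() not in cls.names]
        if unknown:
            raise ValueError(f"unknown weight keys: {sorted(unknown)}")
        return cls(**{k.lower(): float(v) for k, v in d.items()})

    def asarray(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([getattr(self, n) for n in names], dtype=float)

    def updated(self, names: tuple[str, ...], values: np.ndarray) -> "NetworkWeights":
        return replace(self, **{n: float(v) for n, v in zip(names, values)})

    def channel_params(self, channel: Channel) -> tuple[IntegratorParams, IntegratorParams]:
        """(Go, No-Go) integrator parameters for one channel."""
        if channel == "tone":
            go = IntegratorParams(self.w3, self.w1, "squashing")
            nogo = IntegratorParams(self.w4, self.w2, "squashing")
        elif channel == "flash":
            go = IntegratorParams(self.w9, self.w7, "squashing")
            nogo = IntegratorParams(self.w10, self.w8, "squashing")
        else:
            raise ValueError(f"channel must be 'tone' or 'flash', got {channel!r}")
        return go, nogo


@dataclass(frozen=True)
class StimulusProtocol:
    """A peak-procedure trial protocol: ``n_pre`` silent steps followed by
    ``n_stim`` steps of constant stimulation on the flagged channels."""

    n_pre: int = 20
    n_stim: int = 80
    tone_on: bool = False
    flash_on: bool = False
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pre < 0 or self.n_stim < 1:
            raise ValueError("need n_pre >= 0 and n_stim >= 1")

    @property
    def n_steps(self) -> int:
        return self.n_pre + self.n_stim

    @property
    def onset_step(self) -> int:
        """1-based absolute step of stimulus onset."""
        return self.n_pre + 1

    def input_series(self, channel: Channel) -> np.ndarray:
        """The channel's input over the protocol: 0 pre-stimulus, then
        ``amplitude`` if the channel's flag is on (0 throughout otherwise)."""
        on = self.tone_on if channel == "tone" else self.flash_on
        u = np.zeros(self.n_steps)
        if on:
            u[self.n_pre:] = self.amplitude
        return u

    @property
    def is_compound(self) -> bool:
        return self.tone_on and self.flash_on


def tone_protocol(**kw) -> StimulusProtocol:
    return StimulusProtocol(tone_on=True, flash_on=False, **kw)


def flash_protocol(**kw) -> StimulusProtocol:
    return StimulusProtocol(tone_on=False, flash_on=True, **kw)


def compound_protocol(**kw) -> StimulusProtocol:
    return StimulusProtocol(tone_on=True, flash_on=True, **kw)


@dataclass
class Trajectory:
    """Per-step record of every unit over one simulated trial.

    ``step`` is the 1-based absolute step; ``t_sum``/``f_sum`` are the sums
    as delivered to the final integrator (post-saliency on compound trials);
    ``x_out`` is the final integrator's state, the model's response.
    """

    step: np.ndarray
    t_go: np.ndarray
    t_nogo: np.ndarray
    f_go: np.ndarray
    f_nogo: np.ndarray
    t_sum: np.ndarray
    f_sum: np.ndarray
    x_out: np.ndarray
    tone_cut: np.ndarray = field(default=None)  # type: ignore[assignment]
    flash_cut: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.step)
        if self.tone_cut is None:
            self.tone_cut = np.zeros(n, dtype=int)
        if self.flash_cut is None:
            self.flash_cut = np.zeros(n, dtype=int)
        for name in ("t_go", "t_nogo", "f_go", "f_nogo", "t_sum", "f_sum",
                     "x_out", "tone_cut", "flash_cut"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length mismatch")

    columns = ("step", "t_go", "t_nogo", "f_go", "f_nogo",
               "t_sum", "f_sum", "x_out", "tone_cut", "flash_cut")

    def __len__(self) -> int:
        return len(self.step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in self.columns})

    @property
    def peak_step(self) -> int:
        """1-based absolute step at which x_out is maximal."""
        return int(np.argmax(self.x_out)) + 1

    @property
    def x_out_normalized(self) -> np.ndarray:
        """x_out divided by its maximum, for comparison with normalized
        behavioral curves. Requires a positive maximum."""
        m = float(np.max(self.x_out))
        if m <= 0:
            raise ValueError("cannot normalize: x_out has no positive maximum")
        return self.x_out / m


def simulate_channel(
    protocol: StimulusProtocol, channel: Channel, weights: NetworkWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one channel's Go and No-Go squashing units from zero initial
    state; returns the two state trajectories."""
    go_p, nogo_p = weights.channel_params(channel)
    u = protocol.input_series(channel)
    return run_unit(u, go_p), run_unit(u, nogo_p)


def linear_sum(go_value, nogo_value, w_go: float, w_nogo: float):
    """Linear sum-operator activation: ``w_go*go + w_nogo*nogo``.

    Accepts scalars or arrays.
    """
    return w_go * np.asarray(go_value) + w_nogo * np.asarray(nogo_value)


def final_integrator_step(state: float, drive: float, weights: NetworkWeights) -> float:
    """One linear step of the final integrator: ``w14*x + w13*drive``."""
    return weights.w14 * state + weights.w13 * drive


def simulate_network(
    protocol: StimulusProtocol,
    weights: NetworkWeights,
    saliency: SaliencyParams | None = None,
) -> Trajectory:
    """Run the full network over a protocol.

    Single-stimulus trials use linear sum operators; compound trials with
    ``saliency`` supplied pass both sums through the saturation/cutoff
    pipeline before they drive the final integrator. Supplying saliency with
    a single-stimulus protocol raises a warning and ignores it.
    """
    if saliency is not None and not protocol.is_compound:
        warnings.warn(
            "saliency applies only to compound (tone+flash) protocols; ignored",
            UserWarning,
            stacklevel=2,
        )
        saliency = None

    t_go, t_nogo = simulate_channel(protocol, "tone", weights)
    f_go, f_nogo = simulate_channel(protocol, "flash", weights)
    t_raw = linear_sum(t_go, t_nogo, weights.w5, weights.w6)
    f_raw = linear_sum(f_go, f_nogo, weights.w11, weights.w12)

    n = protocol.n_steps
    t_sum = np.array(t_raw)
    f_sum = np.array(f_raw)
    tone_cut = np.zeros(n, dtype=int)
    flash_cut = np.zeros(n, dtype=int)

    if saliency is not None:
        was_t = was_f = False
        for i in range(n):
            d = compound_drive(
                t_raw[i], f_raw[i], t_nogo[i], f_nogo[i], saliency,
                tone_was_cut=was_t, flash_was_cut=was_f,
            )
            t_sum[i], f_sum[i] = d.t_sum, d.f_sum
            tone_cut[i], flash_cut[i] = d.tone_cut, d.flash_cut
            was_t, was_f = bool(d.tone_cut), bool(d.flash_cut)

    x = 0.0
    x_out = np.empty(n)
    for i in range(n):
        x = final_integrator_step(x, t_sum[i] + f_sum[i], weights)
        x_out[i] = x

    return Trajectory(
        step=np.arange(1, n + 1),
        t_go=t_go, t_nogo=t_nogo, f_go=f_go, f_nogo=f_nogo,
        t_sum=t_sum, f_sum=f_sum, x_out=x_out,
        tone_cut=tone_cut, flash_cut=flash_cut,
    )
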