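"""Single recurrent integrator unit — the dynamical primitive of the timing network.

A unit holds one scalar state ``x`` that is updated once per 1-s time step from
its own delayed output (through a recurrent feedback weight) and an external
input (through a feed-forward weight)::

    linear:     x(n+1) = w1 * x(n) + w0 * u(n)
    squashing:  x(n+1) = tanh(w1 * x(n) + w0 * u(n))

In the control-systems literature this is a (leaky) integrator: the feedback
weight ``w1`` sets the unit's time constant — the closer ``w1`` is to 1, the
longer the rise time to steady state — and with the convention ``w0 = 1 - w1``
the linear unit's step response rises to exactly the input amplitude.

Time is discrete, 1 step = 1 s, and absolute step indexing is 1-based: in the
standard peak-procedure protocol steps 1-20 are pre-stimulus and steps 21-100
are stimulus-on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "Activation",
    "IntegratorParams",
    "step_unit",
    "run_unit",
    "linear_closed_form",
    "accumulator_closed_form",
]

Activation = Literal["linear", "squashing"]

_ACTIVATIONS = ("linear", "squashing")


@dataclass(frozen=True)
class IntegratorParams:
    """Parameters of one recurrent integrator unit.

    Parameters
    ----------
    w_feedback
        Recurrent (delayed self-connection) weight; sets the time constant.
    w_input
        Feed-forward weight from the input unit; sets the step-response gain.
    activation
        ``"linear"`` (identity) or ``"squashing"`` (tanh).
    """

    w_feedback: float
    w_input: float
    activation: Activation = "linear"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.w_feedback) and math.isfinite(self.w_input)):
            raise ValueError("integrator weights must be finite")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {_ACTIVATIONS}, got {self.activation!r}"
            )


def step_unit(state: float, input_value: float, params: IntegratorParams) -> float:
    """Advance the unit one time step.

    Returns ``w1*x + w0*u`` for a linear unit, ``tanh(w1*x + w0*u)`` for a
    squashing unit.
    """
    if not (math.isfinite(state) and math.isfinite(input_value)):
        raise ValueError("state and input must be finite")
    pre = params.w_feedback * state + params.w_input * input_value
    if params.activation == "squashing":
        return math.tanh(pre)
    return pre


def run_unit(
    input_series: np.ndarray,
    params: IntegratorParams,
    initial_state: float = 0.0,
) -> np.ndarray:
    """Iterate the unit over an input series; returns the state trajectory.

    ``output[i]`` is the state at (1-based) step ``i+1``, i.e. after consuming
    ``input_series[i]``. The initial state (default 0, the pre-stimulus resting
    assumption) is not included in the output.
    """
    u = np.asarray(input_series, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("input series must be a non-empty 1-D sequence")
    if not math.isfinite(initial_state):
        raise ValueError("initial state must be finite")
    out = np.empty_like(u)
    x = float(initial_state)
    for i, ui in enumerate(u):
        x = step_unit(x, float(ui), params)
        out[i] = x
    return out


def linear_closed_form(
    n: int, params: IntegratorParams, step_amplitude: float = 1.0
) -> float:
    """Closed-form step response of the *linear* unit at step ``n``.

    For a step of amplitude ``U`` applied from step 1 and ``w1 != 1``::

        x(n) = w0 * U * (1 - w1**n) / (1 - w1)

    With ``w0 = 1 - w1`` the asymptote (``n -> inf``, ``|w1| < 1``) equals
    ``U``. The pure-accumulator case ``w1 == 1`` is not covered here — use
    :func:`accumulator_closed_form`.
    """
    if params.activation != "linear":
        raise ValueError("closed form applies to the linear activation only")
    if params.w_feedback == 1.0:
        raise ValueError(
            "w_feedback = 1 is a pure accumulator; use accumulator_closed_form"
        )
    if n < 0:
        raise ValueError("step index must be non-negative")
    w1, w0 = params.w_feedback, params.w_input
    return w0 * step_amplitude * (1.0 - w1**n) / (1.0 - w1)


def accumulator_closed_form(
    n: int, params: IntegratorParams, step_amplitude: float = 1.0
) -> float:
    """Step response at step ``n`` of the non-leaky accumulator (``w1 == 1``):
    ``x(n) = n * w0 * U``."""
    if n < 0:
        raise ValueError("step index must be non-negative")
    return n * params.w_input * step_amplitude
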