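"""Fitting the timing network to behavioral curves.

The network is trained in stages against a 100-bin normalized lever-press
curve by minimizing the mean squared error between the final integrator's
output and the target, over all bins (pre-stimulus included):

* tone stage — tone-channel weights (w1-w6) are trained with the flash input
  held at zero and the flash and final-integrator weights frozen;
* flash stage — flash-channel weights (w7-w12) are trained with the tone
  input at zero, the tone weights frozen at their fitted values, and the
  final integrator still frozen (w13 = 0.1, w14 = 0.9 throughout).

Gradients come from backpropagation through time (BPTT): the recurrent
computation is unrolled into one layer per time step and differentiated in
reverse. The optimizer is damped least squares (Levenberg-Marquardt), whose
Jacobian of per-step residuals is assembled from exact per-time-step
sensitivities of the unrolled network (a finite-difference fallback exists
behind a config flag). Saliency is excluded from training: its gates are
discontinuous, so gradients are defined only for the smooth single-stimulus
system — the saliency constants are instead tuned by exhaustive grid search
against a compound-trial target (:func:`tune_saliency`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.signal import lfilter

from .network import (
    FLASH_WEIGHTS,
    TONE_WEIGHTS,
    NetworkWeights,
    StimulusProtocol,
    flash_protocol,
    simulate_network,
    tone_protocol,
)
from .saliency import SaliencyParams

__all__ = [
    "FitConfig",
    "FitResult",
    "PeakTimingModel",
    "PeakTimingResults",
    "loss",
    "bptt_gradient",
    "residual_jacobian",
    "fit_stage",
    "tune_saliency",
    "TuneSaliencyResult",
]

Stage = Literal["tone", "flash"]

_STAGE_TRAINABLE = {"tone": TONE_WEIGHTS, "flash": FLASH_WEIGHTS}

# (input-weight, recurrent-weight, sum-weight) names per (channel, unit).
_UNIT_WEIGHTS = {
    ("tone", "go"): ("w1", "w3", "w5"),
    ("tone", "nogo"): ("w2", "w4", "w6"),
    ("flash", "go"): ("w7", "w9", "w11"),
    ("flash", "nogo"): ("w8", "w10", "w12"),
}


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of one Levenberg-Marquardt fitting stage.

    ``damping_init`` is the initial LM damping; it divides by 10 on an
    accepted step and multiplies by 10 on a rejected one. Convergence is
    declared when the relative loss reduction of an accepted step falls
    below ``tolerance`` or the gradient's max component falls below
    ``gradient_tol``. ``seed`` controls the random initialization of the
    stage's trainable weights: input weights uniform in [-init_scale,
    init_scale], recurrent weights uniform in [0.5, 1.5] (the fitted
    solutions have recurrent weights >= 1, and tanh saturation kills
    gradients far from that regime); the two sum weights are then solved by
    exact linear least squares — the network output is linear in them given
    the unit trajectories, so this places every start in a sensible basin.
    Set ``init_from_start`` to optimize from the supplied starting weights
    instead. ``finite_diff`` swaps the analytic BPTT Jacobian for a central
    finite-difference one.
    """

    stage: Stage = "tone"
    max_iterations: int = 3000
    damping_init: float = 1e-3
    tolerance: float = 1e-12
    seed: int = 0
    init_scale: float = 0.5
    init_from_start: bool = False
    finite_diff: bool = False
    max_damping: float = 1e12
    gradient_tol: float = 1e-14

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.damping_init <= 0 or self.tolerance <= 0:
            raise ValueError("damping_init and tolerance must be positive")
        if self.stage not in _STAGE_TRAINABLE:
            raise ValueError(f"stage must be 'tone' or 'flash', got {self.stage!r}")


@dataclass
class FitResult:
    """Outcome of one fitting stage."""

    weights: NetworkWeights
    loss_trace: np.ndarray
    converged: bool
    n_iterations: int
    stage: Stage = "tone"

    @property
    def mse(self) -> float:
        return float(self.loss_trace[-1])


def _check_target(protocol: StimulusProtocol, target: np.ndarray) -> np.ndarray:
    y = np.asarray(target, dtype=float)
    if y.ndim != 1 or len(y) != protocol.n_steps:
        raise ValueError(
            f"target length {y.shape} does not match protocol length "
            f"{protocol.n_steps}"
        )
    return y


def loss(
    weights: NetworkWeights,
    protocol: StimulusProtocol,
    target: np.ndarray,
    saliency: SaliencyParams | None = None,
) -> float:
    """Mean squared error between the network output and a target curve,
    over every step of the protocol (pre-stimulus bins included)."""
    y = _check_target(protocol, target)
    x = simulate_network(protocol, weights, saliency).x_out
    return float(np.mean((x - y) ** 2))


def _forward(weights: NetworkWeights, protocol: StimulusProtocol) -> dict:
    """Forward pass retaining every intermediate series (for BPTT)."""
    traj = simulate_network(protocol, weights, saliency=None)
    return {
        "u_tone": protocol.input_series("tone"),
        "u_flash": protocol.input_series("flash"),
        ("tone", "go"): traj.t_go,
        ("tone", "nogo"): traj.t_nogo,
        ("flash", "go"): traj.f_go,
        ("flash", "nogo"): traj.f_nogo,
        "drive": traj.t_sum + traj.f_sum,
        "x": traj.x_out,
    }


def _normalize_mask(trainable: Sequence[str] | Mapping[str, bool] | None) -> set[str]:
    if trainable is None:
        return set(NetworkWeights.names)
    if isinstance(trainable, Mapping):
        return {k for k, v in trainable.items() if v}
    return set(trainable)


def bptt_gradient(
    weights: NetworkWeights,
    protocol: StimulusProtocol,
    target: np.ndarray,
    trainable: Sequence[str] | Mapping[str, bool] | None = None,
    saliency: SaliencyParams | None = None,
) -> dict[str, float]:
    """Exact gradient of :func:`loss` w.r.t. each weight, by reverse
    accumulation through the unrolled 100-step computation.

    ``trainable`` masks the result: weights not listed get gradient 0.
    Saliency must be disabled (its switches are non-differentiable).
    """
    if saliency is not None:
        raise NotImplementedError(
            "BPTT gradients are undefined with saliency enabled; "
            "tune saliency constants by grid search instead"
        )
    y = _check_target(protocol, target)
    fw = _forward(weights, protocol)
    x, d = fw["x"], fw["drive"]
    n = len(x)
    mask = _normalize_mask(trainable)

    # adjoint of x: lam_x[i] = dL/dx[i]
    lam_x = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc = (2.0 / n) * (x[i] - y[i]) + weights.w14 * acc
        lam_x[i] = acc
        acc = lam_x[i]  # carried into step i-1 through the recurrent path

    mu = weights.w13 * lam_x  # dL/d drive[i]
    x_prev = np.concatenate([[0.0], x[:-1]])
    grads = {name: 0.0 for name in NetworkWeights.names}
    grads["w13"] = float(np.dot(lam_x, d))
    grads["w14"] = float(np.dot(lam_x, x_prev))

    for (channel, unit), (wi_name, wr_name, ws_name) in _UNIT_WEIGHTS.items():
        g = fw[(channel, unit)]
        u = fw[f"u_{channel}"]
        ws = getattr(weights, ws_name)
        wr = getattr(weights, wr_name)
        g_prev = np.concatenate([[0.0], g[:-1]])
        # adjoint of the unit's pre-activation
        lam_a = np.empty(n)
        carry = 0.0
        for i in range(n - 1, -1, -1):
            dg = ws * mu[i] + wr * carry
            lam_a[i] = dg * (1.0 - g[i] ** 2)
            carry = lam_a[i]
        grads[ws_name] = float(np.dot(mu, g))
        grads[wr_name] = float(np.dot(lam_a, g_prev))
        grads[wi_name] = float(np.dot(lam_a, u))

    return {k: (v if k in mask else 0.0) for k, v in grads.items()}


def residual_jacobian(
    weights: NetworkWeights,
    protocol: StimulusProtocol,
    trainable: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian of the per-step residuals w.r.t. the trainable weights.

    Returns ``(x, J)`` where ``x`` is the network output and ``J[i, k]`` is
    the exact sensitivity ``dx[i]/dw_k`` from forward accumulation through
    the unrolled network (the residual is ``x - target``, so J is also the
    residual Jacobian).
    """
    fw = _forward(weights, protocol)
    x = fw["x"]
    n = len(x)
    # per-unit state sensitivities to (input weight, recurrent weight)
    dsum: dict[str, np.ndarray] = {}  # name -> d drive / d w, per step
    for (channel, unit), (wi_name, wr_name, ws_name) in _UNIT_WEIGHTS.items():
        g = fw[(channel, unit)]
        u = fw[f"u_{channel}"]
        wr = getattr(weights, wr_name)
        ws = getattr(weights, ws_name)
        sg_wi = np.empty(n)
        sg_wr = np.empty(n)
        prev_g = prev_wi = prev_wr = 0.0
        for i in range(n):
            sech2 = 1.0 - g[i] ** 2
            sg_wi[i] = sech2 * (u[i] + wr * prev_wi)
            sg_wr[i] = sech2 * (prev_g + wr * prev_wr)
            prev_g, prev_wi, prev_wr = g[i], sg_wi[i], sg_wr[i]
        dsum[wi_name] = ws * sg_wi
        dsum[wr_name] = ws * sg_wr
        dsum[ws_name] = g

    cols = []
    b, a = [weights.w13], [1.0, -weights.w14]
    x_prev = np.concatenate([[0.0], x[:-1]])
    for name in trainable:
        if name in dsum:
            cols.append(lfilter(b, a, dsum[name]))
        elif name == "w13":
            cols.append(lfilter([1.0], a, fw["drive"]))
        elif name == "w14":
            cols.append(lfilter([1.0], a, x_prev))
        else:
            raise ValueError(f"unknown weight name {name!r}")
    return x, np.column_stack(cols)


def _fd_jacobian(
    weights: NetworkWeights,
    protocol: StimulusProtocol,
    trainable: Sequence[str],
    h: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Central finite-difference residual Jacobian (fallback path)."""
    x0 = simulate_network(protocol, weights).x_out
    cols = []
    for name in trainable:
        v = getattr(weights, name)
        step = h * max(1.0, abs(v))
        xp = simulate_network(protocol, replace(weights, **{name: v + step})).x_out
        xm = simulate_network(protocol, replace(weights, **{name: v - step})).x_out
        cols.append((xp - xm) / (2 * step))
    return x0, np.column_stack(cols)


def _default_protocol(stage: Stage) -> StimulusProtocol:
    return tone_protocol() if stage == "tone" else flash_protocol()


def _init_stage_weights(
    start: NetworkWeights,
    stage: Stage,
    config: FitConfig,
    protocol: StimulusProtocol,
    target: np.ndarray,
) -> NetworkWeights:
    """Random unit weights plus linear-least-squares sum weights.

    The final integrator is linear, so for fixed Go/No-Go trajectories the
    output is linear in the stage's two sum weights; solving them exactly at
    initialization avoids the worst tanh-saturation plateaus.
    """
    if config.init_from_start:
        return start
    rng = np.random.default_rng(config.seed)
    init = {}
    sum_names = []
    for (channel, unit), (wi, wr, ws) in _UNIT_WEIGHTS.items():
        if wi in _STAGE_TRAINABLE[stage]:
            init[wi] = rng.uniform(-config.init_scale, config.init_scale)
            init[wr] = rng.uniform(0.5, 1.5)
            init[ws] = 0.0
            sum_names.append(ws)
    w = replace(start, **init)
    # output of everything except the stage's sum weights
    x_base = simulate_network(protocol, w).x_out
    fw = _forward(w, protocol)
    b, a = [w.w13], [1.0, -w.w14]
    channel = "tone" if stage == "tone" else "flash"
    cols = [
        lfilter(b, a, fw[(channel, "go")]),
        lfilter(b, a, fw[(channel, "nogo")]),
    ]
    coef, *_ = np.linalg.lstsq(np.column_stack(cols), target - x_base, rcond=None)
    return w.updated(tuple(sum_names), coef)


def fit_stage(
    target: np.ndarray,
    stage: Stage,
    start: NetworkWeights | None = None,
    config: FitConfig | None = None,
    protocol: StimulusProtocol | None = None,
) -> FitResult:
    """Fit one stage's trainable weights to a target curve by damped least
    squares; everything outside the stage (including w13/w14) stays frozen
    bit-identically."""
    config = config or FitConfig(stage=stage)
    if config.stage != stage:
        config = replace(config, stage=stage)
    protocol = protocol or _default_protocol(stage)
    y = _check_target(protocol, target)
    start = start if start is not None else NetworkWeights()
    trainable = _STAGE_TRAINABLE[stage]
    w = _init_stage_weights(start, stage, config, protocol, y)

    jac = _fd_jacobian if config.finite_diff else residual_jacobian
    n = protocol.n_steps
    lam = config.damping_init
    x, J = jac(w, protocol, trainable)
    r = x - y
    current = float(r @ r) / n
    trace = [current]
    converged = False
    n_iter = 0

    for n_iter in range(1, config.max_iterations + 1):
        grad = J.T @ r
        if np.max(np.abs(grad)) < config.gradient_tol:
            converged = True
            break
        accepted = False
        while lam <= config.max_damping:
            JtJ = J.T @ J
            damped = JtJ + lam * np.diag(np.maximum(np.diag(JtJ), 1e-12))
            try:
                delta = np.linalg.solve(damped, -grad)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            w_try = w.updated(trainable, w.asarray(trainable) + delta)
            x_try = simulate_network(protocol, w_try).x_out
            new = float((x_try - y) @ (x_try - y)) / n
            if np.isfinite(new) and new < current:
                w = w_try
                reduction = (current - new) / max(current, 1e-300)
                current = new
                trace.append(current)
                lam = max(lam / 10, 1e-15)
                accepted = True
                break
            lam *= 10
        if not accepted:
            break  # no acceptable step at any damping: stalled
        if reduction < config.tolerance:
            converged = True
            break
        x, J = jac(w, protocol, trainable)
        r = x - y

    # bit-identical freezing: restore every non-trainable weight from `start`
    frozen = {n_: getattr(start, n_) for n_ in NetworkWeights.names
              if n_ not in trainable}
    w = replace(w, **frozen)
    return FitResult(
        weights=w,
        loss_trace=np.asarray(trace),
        converged=converged,
        n_iterations=n_iter,
        stage=stage,
    )


class TuneSaliencyResult(NamedTuple):
    params: SaliencyParams
    mse: float
    n_evaluated: int


def tune_saliency(
    weights: NetworkWeights,
    compound_target: np.ndarray,
    grid: Mapping[str, Sequence[float]],
    protocol: StimulusProtocol | None = None,
    base: SaliencyParams | None = None,
) -> TuneSaliencyResult:
    """Exhaustive grid search over saliency constants against a compound
    target; the single-stimulus weights are already fitted and stay frozen.

    ``grid`` maps SaliencyParams field names to candidate value lists; absent
    fields keep their ``base`` (default) values. Ties break in first-in-grid
    order (strict improvement required to replace the incumbent).
    """
    from .network import compound_protocol

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("saliency grid must have at least one candidate per field")
    bad = set(grid) - {"t_sat", "f_sat", "cutoff_a", "cutoff_v", "epsilon"}
    if bad:
        raise ValueError(f"unknown saliency grid field(s): {sorted(bad)}")
    protocol = protocol or compound_protocol()
    y = _check_target(protocol, compound_target)
    base = base or SaliencyParams()

    names = list(grid)
    best: tuple[float, SaliencyParams] | None = None
    count = 0
    for combo in itertools.product(*(grid[n] for n in names)):
        params = replace(base, **dict(zip(names, combo)))
        mse = loss(weights, protocol, y, saliency=params)
        count += 1
        if best is None or mse < best[0]:
            best = (mse, params)
    assert best is not None
    return TuneSaliencyResult(params=best[1], mse=best[0], n_evaluated=count)


class PeakTimingModel:
    """Timing-network model bound to one behavioral target curve.

    Parameters
    ----------
    target
        100-bin normalized response curve (20 pre-stimulus + 80 stimulus
        bins by default) the network output should reproduce.
    stage
        Which channel is being trained: ``"tone"`` or ``"flash"``. The
        protocol presents only that stimulus.
    start_weights
        Weights for the frozen part of the network (and, with
        ``init_from_start``, the starting point of the trainable part).
        For the flash stage pass the tone-stage result here.
    protocol
        Override the default 20+80 single-stimulus protocol.

    ``fit`` runs staged Levenberg-Marquardt/BPTT and returns a
    :class:`PeakTimingResults`.
    """

    def __init__(
        self,
        target: np.ndarray,
        stage: Stage = "tone",
        start_weights: NetworkWeights | None = None,
        protocol: StimulusProtocol | None = None,
    ) -> None:
        self.stage: Stage = stage
        self.protocol = protocol or _default_protocol(stage)
        self.target = _check_target(self.protocol, target)
        self.start_weights = start_weights

    @classmethod
    def from_curve(cls, curve, stage: Stage = "tone", **kw) -> "PeakTimingModel":
        """Build from a :class:`~timingnet.behavior.BehavioralCurve`."""
        return cls(np.asarray(curve.rate, dtype=float), stage=stage, **kw)

    def loss(self, weights: NetworkWeights) -> float:
        return loss(weights, self.protocol, self.target)

    def gradient(self, weights: NetworkWeights) -> dict[str, float]:
        return bptt_gradient(
            weights, self.protocol, self.target,
            trainable=_STAGE_TRAINABLE[self.stage],
        )

    def fit(self, config: FitConfig | None = None, **overrides) -> "PeakTimingResults":
        config = config or FitConfig(stage=self.stage)
        if overrides:
            config = replace(config, **overrides)
        res = fit_stage(
            self.target, self.stage, start=self.start_weights,
            config=config, protocol=self.protocol,
        )
        return PeakTimingResults(self, res)

    def fit_multistart(
        self, seeds: Sequence[int], config: FitConfig | None = None
    ) -> "PeakTimingResults":
        """Fit once per seed and keep the lowest-MSE result."""
        best = None
        for seed in seeds:
            cfg = replace(config or FitConfig(stage=self.stage), seed=seed)
            r = self.fit(cfg)
            if best is None or r.mse < best.mse:
                best = r
        assert best is not None
        return best


class PeakTimingResults:
    """Results of fitting a :class:`PeakTimingModel`.

    Carries the fitted weights, the accepted-step loss trace, and the usual
    result conveniences (fitted values, residuals, ``summary()``).
    """

    def __init__(self, model: PeakTimingModel, result: FitResult) -> None:
        self.model = model
        self.weights = result.weights
        self.loss_trace = result.loss_trace
        self.converged = result.converged
        self.n_iterations = result.n_iterations
        self.stage = result.stage

    @property
    def mse(self) -> float:
        return float(self.loss_trace[-1])

    @property
    def fittedvalues(self) -> np.ndarray:
        return simulate_network(self.model.protocol, self.weights).x_out

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.target

    def predict(
        self,
        protocol: StimulusProtocol | None = None,
        saliency: SaliencyParams | None = None,
    ) -> np.ndarray:
        """Simulate the fitted network under any protocol."""
        return simulate_network(
            protocol or self.model.protocol, self.weights, saliency
        ).x_out

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        trainable = set(_STAGE_TRAINABLE[self.stage])
        rows = [
            [name.upper(), f"{getattr(self.weights, name):.6g}",
             "yes" if name in trainable else "no"]
            for name in NetworkWeights.names
        ]
        head = SimpleTable(
            [
                ["stage", self.stage],
                ["n steps", str(self.model.protocol.n_steps)],
                ["MSE", f"{self.mse:.3e}"],
                ["iterations", str(self.n_iterations)],
                ["converged", str(self.converged)],
            ],
            title="Peak timing network fit",
        )
        body = SimpleTable(rows, headers=["weight", "value", "trained"])
        return f"{head.as_text()}\n{body.as_text()}"

    def plot(self, ax=None):
        """Target vs fitted output over absolute time steps."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        steps = np.arange(1, self.model.protocol.n_steps + 1)
        ax.plot(steps, self.model.target, label="target", color="k", lw=1)
        ax.plot(steps, self.fittedvalues, label="model", color="C3")
        ax.axvline(self.model.protocol.onset_step, ls=":", color="gray")
        ax.set_xlabel("time step (s)")
        ax.set_ylabel("normalized response")
        ax.legend()
        return ax
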