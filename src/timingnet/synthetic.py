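"""Synthetic peak-procedure behavioral data.

Generates rat-like lever-press curves and cohorts with controlled peak time,
width, asymmetry, baseline and noise, so the analysis and fitting pipeline
can be exercised end to end without the original animal data. A single curve
is a deterministic 100-bin rate function: a flat pre-stimulus baseline
followed by an asymmetric double-sigmoid bump whose argmax and half-max span
are calibrated to the requested peak time and width-50, optionally with a
late sub-baseline undershoot (tone-trained rats suppress responding below
baseline late in the stimulus). Trial-to-trial noise is per-bin Poisson on
press counts; between-rat variation perturbs each rat's peak time and width
with clipped normal draws.

Default cohort parameters mirror the published 15-rat dataset: tone trials
peaking near 4.7 s (width 9.1 s), flash near 26.1 s (width 40.6 s), compound
near 16.2 s (width 35.9 s), with the per-rat spreads seen in that table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .behavior import BehavioralCurve, double_sigmoid

__all__ = [
    "CurveSpec",
    "CohortSpec",
    "make_curve",
    "sample_trials",
    "make_cohort",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class CurveSpec:
    """Shape parameters of one idealized behavioral curve.

    ``asymmetry`` is the rise/fall slope ratio (>1 = steeper rise than
    fall, as in tone-trained responding); ``undershoot`` is the depth
    (presses/s) of the late below-baseline dip, 0 for none. Rates are in
    presses/s, times in s.
    """

    peak_time: float
    width50: float
    asymmetry: float = 1.0
    baseline: float = 0.0
    amplitude: float = 1.0
    undershoot: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.peak_time < 80:
            raise ValueError("peak_time must lie in (0, 80) s")
        if self.width50 <= 0:
            raise ValueError("width50 must be positive")
        if not self.amplitude > self.baseline >= 0:
            raise ValueError("need amplitude > baseline >= 0")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")
        if self.undershoot < 0:
            raise ValueError("undershoot must be non-negative")


def _measure_bump(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Argmax and half-max span of a unimodal bump on a dense grid."""
    i = int(np.argmax(f))
    half = f[i] / 2.0
    above = f >= half
    idx = np.nonzero(above)[0]
    return float(t[i]), float(t[idx[-1]] - t[idx[0]])


def _calibrated_bump(spec: CurveSpec, t: np.ndarray) -> np.ndarray:
    """Unit-peak double-sigmoid bump placed so the *full* curve
    (baseline + scaled bump) has its argmax at spec.peak_time and its
    half-of-peak span equal to spec.width50 — the same observables the
    downstream peak analysis measures. Found by fixed-point calibration of
    the sigmoid's center and plateau width on a dense grid.

    The requested half-max span is only realizable if the left half-crossing
    lands after stimulus onset (rise half-width < peak time); when the
    requested (peak_time, width50, asymmetry) combination violates that, the
    rise is steepened just enough — early-peaked wide curves rise sharply,
    as peak-procedure data do."""
    # rise half-width ~ width50/(1+asymmetry); keep it below peak_time
    a_min = spec.width50 / max(spec.peak_time - 0.5, 0.3) - 1.0
    asym = max(spec.asymmetry, 1.3 * a_min)
    s_fall = max(spec.width50 / 6.0, 0.05)
    s_rise = s_fall / asym
    grid = np.arange(0.0, float(t[-1]) + 1.0, 0.01)
    c, w = spec.peak_time, spec.width50
    for _ in range(100):
        bump = double_sigmoid(grid, 1.0, c, w, s_rise, s_fall)
        bump = bump / max(float(np.max(bump)), 1e-12)
        full = spec.baseline + (spec.amplitude - spec.baseline) * bump
        pt, w50 = _measure_bump(grid, full)
        dc, dw = spec.peak_time - pt, spec.width50 - w50
        c += dc
        w = max(w + dw, 0.01)
        if abs(dc) < 5e-3 and abs(dw) < 5e-3:
            break
    return double_sigmoid(t, 1.0, c, w, s_rise, s_fall)


def make_curve(spec: CurveSpec, n_pre: int = 20, n_stim: int = 80) -> BehavioralCurve:
    """Deterministic 100-bin curve realizing a :class:`CurveSpec`.

    Bins 1..n_pre sit at the baseline; the stimulus window carries the
    calibrated bump scaled to peak at ``amplitude`` (the binned maximum is
    exactly ``amplitude``), minus the optional late undershoot. Rates are
    clipped at zero (press rates cannot be negative).
    """
    tau = np.arange(n_stim) + 0.5  # stimulus-relative bin centers
    bump = _calibrated_bump(spec, tau)
    bump = bump / float(np.max(bump))
    rate_stim = spec.baseline + (spec.amplitude - spec.baseline) * bump
    if spec.undershoot > 0:
        from scipy.special import expit

        dip_center = spec.peak_time + spec.width50
        dip_scale = max(spec.width50 / 6.0, 0.5)
        rate_stim = rate_stim - spec.undershoot * expit(
            (tau - dip_center) / dip_scale
        ) * bump_complement(bump)
    rate = np.concatenate([np.full(n_pre, spec.baseline), rate_stim])
    return BehavioralCurve(rate=np.clip(rate, 0.0, None), n_pre=n_pre)


def bump_complement(bump: np.ndarray) -> np.ndarray:
    """1 where the bump has died off; keeps the undershoot away from the peak."""
    return 1.0 - bump


def sample_trials(
    curve: BehavioralCurve, n_trials: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-trial binned press counts: ``n_trials x n_bins`` Poisson draws
    with mean ``rate * bin_width``. Same seed, same counts."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.clip(curve.rate, 0.0, None) * curve.bin_width
    return rng.poisson(lam, size=(n_trials, curve.n_bins))


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of simulated rats, one averaged curve per rat and trial type.

    ``curve_specs`` gives the cohort-mean curve per trial type;
    ``peak_time_sd``/``width50_sd`` the between-rat SDs of those two
    parameters (normal perturbations, clipped to valid ranges). Each rat
    contributes ``n_trials_per_rat`` Poisson-noisy trials per type, which
    are averaged and normalized exactly as the empirical pipeline does.
    """

    curve_specs: Mapping[str, CurveSpec]
    n_rats: int = 15
    peak_time_sd: Mapping[str, float] = field(default_factory=dict)
    width50_sd: Mapping[str, float] = field(default_factory=dict)
    n_trials_per_rat: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rats < 1:
            raise ValueError("n_rats must be >= 1")
        if any(v < 0 for v in self.peak_time_sd.values()):
            raise ValueError("peak_time SDs must be >= 0")
        if any(v < 0 for v in self.width50_sd.values()):
            raise ValueError("width50 SDs must be >= 0")


def default_cohort_spec(
    n_rats: int = 15, n_trials_per_rat: int = 64, seed: int = 0
) -> CohortSpec:
    """Cohort emulating the published 15-rat tone/flash/compound dataset:
    means and between-rat spreads set to that table's values, peak rates to
    the reported per-trial-type maxima, and a low pre-stimulus baseline."""
    return CohortSpec(
        curve_specs={
            "tone": CurveSpec(peak_time=4.7, width50=9.1, asymmetry=2.0,
                              baseline=0.15, amplitude=1.10, undershoot=0.10),
            "flash": CurveSpec(peak_time=26.1, width50=40.6, asymmetry=1.5,
                               baseline=0.15, amplitude=1.28),
            "compound": CurveSpec(peak_time=16.2, width50=35.9, asymmetry=1.5,
                                  baseline=0.15, amplitude=1.23),
        },
        n_rats=n_rats,
        peak_time_sd={"tone": 0.70, "flash": 2.69, "compound": 2.47},
        width50_sd={"tone": 2.33, "flash": 5.56, "compound": 4.36},
        n_trials_per_rat=n_trials_per_rat,
        seed=seed,
    )


def make_cohort(
    spec: CohortSpec, noise: bool = True, normalize: bool = True
) -> tuple[dict[tuple[int, str], BehavioralCurve], "np.ndarray"]:
    """Generate per-rat, per-trial-type averaged curves.

    Draws each rat's peak time and width around the cohort means, samples
    ``n_trials_per_rat`` Poisson trials (skipped when ``noise=False``),
    averages them into a rate curve and normalizes it to its maximum.
    Returns ``(curves, truth)`` where ``curves`` maps ``(rat_id,
    trial_type)`` to the analysis-ready curve and ``truth`` is a record
    array of the per-rat generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    curves: dict[tuple[int, str], BehavioralCurve] = {}
    truth = []
    for rat in range(1, spec.n_rats + 1):
        for trial_type, base in spec.curve_specs.items():
            pt_sd = spec.peak_time_sd.get(trial_type, 0.0)
            w_sd = spec.width50_sd.get(trial_type, 0.0)
            pt = float(np.clip(base.peak_time + rng.normal() * pt_sd, 1.0, 70.0))
            w = float(np.clip(base.width50 + rng.normal() * w_sd, 2.0, 75.0))
            rat_spec = replace(base, peak_time=pt, width50=w)
            curve = make_curve(rat_spec)
            if noise:
                counts = sample_trials(curve, spec.n_trials_per_rat, rng)
                mean_rate = counts.mean(axis=0) / curve.bin_width
                curve = BehavioralCurve(rate=mean_rate, n_pre=curve.n_pre)
            if normalize and curve.rate.max() > 0:
                from .behavior import normalize_curve

                curve = normalize_curve(curve)
            curves[(rat, trial_type)] = curve
            truth.append((rat, trial_type, pt, w))
    truth_arr = np.array(
        truth, dtype=[("rat_id", int), ("trial_type", "U16"),
                      ("peak_time", float), ("width50", float)],
    )
    return curves, truth_arr
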