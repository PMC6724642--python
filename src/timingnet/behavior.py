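"""Peak-procedure behavioral analysis.

Pipeline for empirical (or synthetic) lever-press curves: normalize each
100-bin curve to its maximum, fit a dual asymmetric sigmoid over the 80
stimulus bins, and read peak time (PT) and width at 50% of peak (W-50) off
the fitted function on a dense grid. Per-rat statistics aggregate into a
cohort table; trial-type differences are tested with a one-way
repeated-measures ANOVA (subjects as the blocking factor) and
Bonferroni-corrected paired t-tests.

The peak function is the product of a rising and a falling logistic with
independent slopes, plus a baseline offset::

    f(t) = y0 + A * s((t - c + w/2)/s1) * [1 - s((t - c - w/2)/s2)]

where ``s`` is the standard logistic. With s1 = s2 the bump is symmetric
about ``c``; unequal slopes give the asymmetric rise/fall seen in peak
data. PT is the argmax of ``f`` on a 0.01-s grid; W-50 is the span between
the two crossings of half the peak value (the right edge clamps at the end
of the stimulus window if the function never falls that far).

Scalar timing (Weber's law) would make the coefficient of variation
CV = W-50 / PT constant across trained intervals; computing per-trial-type
CVs is how that property is checked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "BehavioralCurve",
    "PeakStats",
    "double_sigmoid",
    "normalize_curve",
    "PeakFunctionModel",
    "PeakFunctionResults",
    "fit_peak_function",
    "peak_stats",
    "build_cohort_table",
    "cohort_summary",
    "AnovaResult",
    "rm_anova",
    "posthoc_pairwise",
    "PosthocResult",
]

TRIAL_TYPES = ("tone", "flash", "compound")

#: Grid resolution (s) on which PT and W-50 are measured.
GRID_STEP = 0.01


@dataclass
class BehavioralCurve:
    """One trial-averaged lever-press curve in 1-s bins.

    ``rate[i]`` is the press rate in (1-based) bin ``i+1``; the first
    ``n_pre`` bins precede stimulus onset. ``normalized`` marks rates
    expressed as a proportion of the curve's maximum.
    """

    rate: np.ndarray
    bin_width: float = 1.0
    n_pre: int = 20
    normalized: bool = False

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.ndim != 1 or self.rate.size <= self.n_pre:
            raise ValueError("curve must be 1-D and longer than its pre-stimulus span")
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("curve contains non-finite rates")

    @property
    def n_bins(self) -> int:
        return len(self.rate)

    @property
    def n_stim(self) -> int:
        return self.n_bins - self.n_pre

    def stimulus_times(self) -> np.ndarray:
        """Bin-center times (s) relative to stimulus onset, stimulus bins only."""
        return (np.arange(self.n_pre, self.n_bins) - self.n_pre + 0.5) * self.bin_width

    def stimulus_rates(self) -> np.ndarray:
        return self.rate[self.n_pre:]


def normalize_curve(curve: BehavioralCurve) -> BehavioralCurve:
    """Express the curve as a proportion of its maximal rate (max becomes 1)."""
    m = float(np.max(curve.rate))
    if m <= 0:
        raise ValueError("cannot normalize an all-zero (or negative) curve")
    return replace(curve, rate=curve.rate / m, normalized=True)


@dataclass(frozen=True)
class PeakStats:
    """Peak time, width at half peak, and their two ratios for one curve."""

    peak_time: float
    width50: float

    def __post_init__(self) -> None:
        if self.peak_time <= 0 or self.width50 <= 0:
            raise ValueError("peak_time and width50 must be positive")

    @property
    def ratio(self) -> float:
        """PT / W-50."""
        return self.peak_time / self.width50

    @property
    def cv(self) -> float:
        """Coefficient of variation, W-50 / PT (the scalar-timing index)."""
        return self.width50 / self.peak_time


def double_sigmoid(t, amplitude, center, width, s_rise, s_fall, baseline=0.0):
    """Dual asymmetric sigmoid: rising logistic times falling logistic.

    ``center`` and ``width`` place the two half-activation points at
    ``center -/+ width/2``; ``s_rise``/``s_fall`` are the two logistic
    scales (smaller = steeper). ``amplitude`` scales the bump, ``baseline``
    offsets it.
    """
    t = np.asarray(t, dtype=float)
    rise = expit((t - center + width / 2.0) / s_rise)
    fall = 1.0 - expit((t - center - width / 2.0) / s_fall)
    return baseline + amplitude * rise * fall


_PARAM_NAMES = ("amplitude", "center", "width", "s_rise", "s_fall", "baseline")


class PeakFunctionModel:
    """Dual-asymmetric-sigmoid model of one behavioral curve.

    Fit over the stimulus bins only, by non-linear least squares. A fit with
    R-squared below ``r2_threshold`` (default 0.5 — e.g. a flat or multi-modal
    curve with no clear peak) is flagged invalid and excluded from cohort
    statistics downstream.
    """

    def __init__(self, curve: BehavioralCurve, r2_threshold: float = 0.5) -> None:
        self.curve = curve
        self.r2_threshold = r2_threshold
        self.t = curve.stimulus_times()
        self.y = curve.stimulus_rates()

    def _initial_guesses(self) -> tuple[list[np.ndarray], tuple]:
        """Several starting points (noise makes the least-squares surface
        multimodal for broad, plateau-like curves) plus shared bounds."""
        t, y = self.t, self.y
        k = min(5, len(y))
        ys = np.convolve(y, np.ones(k) / k, mode="same")  # smoothed, for guesses
        ymax, ymin = float(np.max(ys)), float(np.min(ys))
        amp = max(ymax - ymin, 1e-6)
        c_mode = float(t[np.argmax(ys)])
        weights = np.clip(ys - ymin, 0.0, None)
        c_mass = float(np.sum(t * weights) / max(np.sum(weights), 1e-12))
        above = t[ys > ymin + amp / 2.0]
        w_est = float(above[-1] - above[0]) if len(above) > 1 else max(t[-1] / 10, 1.0)
        w_est = max(w_est, 0.5)
        t_span = float(t[-1] - t[0])
        lower = [1e-8, t[0] - t_span, 0.0, 1e-3, 1e-3, 0.0]
        upper = [10 * max(amp, 1.0), t[-1] + t_span, 4 * t_span, t_span, t_span,
                 max(float(np.max(y)), 1e-6)]
        guesses = []
        for c0 in dict.fromkeys((c_mode, c_mass)):
            for w0 in (0.6 * w_est, w_est, 1.5 * w_est):
                p0 = np.array([amp, c0, w0, w0 / 6.0, w0 / 6.0, max(ymin, 0.0)])
                guesses.append(np.clip(p0, lower, upper))
        return guesses, (lower, upper)

    def fit(self) -> "PeakFunctionResults":
        guesses, bounds = self._initial_guesses()
        best_popt = None
        best_sse = np.inf
        for p0 in guesses:
            try:
                popt, _ = optimize.curve_fit(
                    double_sigmoid, self.t, self.y, p0=p0, bounds=bounds,
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((self.y - double_sigmoid(self.t, *popt)) ** 2))
            if sse < best_sse:
                best_sse, best_popt = sse, popt
        if best_popt is None:
            return PeakFunctionResults(
                self, params=dict(zip(_PARAM_NAMES, guesses[0])),
                r_squared=-np.inf, valid=False,
            )
        ss_tot = float(np.sum((self.y - np.mean(self.y)) ** 2))
        r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else -np.inf
        params = dict(zip(_PARAM_NAMES, (float(v) for v in best_popt)))
        valid = bool(np.isfinite(r2) and r2 >= self.r2_threshold)
        res = PeakFunctionResults(self, params=params, r_squared=r2, valid=valid)
        # a peak pinned to the window edge is not a clear peak function
        if valid:
            pt = res._argmax()
            if not (0.0 < pt < self.t[-1]):
                res.valid = False
        return res


@dataclass
class PeakFunctionResults:
    """Fitted peak function plus validity flag and derived statistics."""

    model: PeakFunctionModel
    params: dict[str, float]
    r_squared: float
    valid: bool
    grid_step: float = GRID_STEP

    def __call__(self, t) -> np.ndarray:
        return double_sigmoid(t, **self.params)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense evaluation grid over the stimulus window (0 .. n_stim s)."""
        t_end = self.model.curve.n_stim * self.model.curve.bin_width
        t = np.arange(0.0, t_end + self.grid_step / 2, self.grid_step)
        return t, self(t)

    def _argmax(self) -> float:
        t, f = self.grid()
        return float(t[np.argmax(f)])

    def peak_stats(self) -> PeakStats:
        """PT and W-50 measured on the dense grid (see :func:`peak_stats`)."""
        if not self.valid:
            raise ValueError("peak statistics are undefined for an invalid fit")
        t, f = self.grid()
        i_peak = int(np.argmax(f))
        peak = float(f[i_peak])
        half = peak / 2.0
        # left crossing: last point below half before the peak
        left_below = np.nonzero(f[: i_peak + 1] < half)[0]
        if len(left_below):
            i = left_below[-1]
            t_left = _interp_crossing(t[i], t[i + 1], f[i], f[i + 1], half)
        else:
            t_left = float(t[0])
        right_below = np.nonzero(f[i_peak:] < half)[0]
        if len(right_below):
            j = i_peak + right_below[0]
            t_right = _interp_crossing(t[j - 1], t[j], f[j - 1], f[j], half)
        else:
            t_right = float(t[-1])  # clamp at end of stimulus window
        return PeakStats(peak_time=float(t[i_peak]), width50=t_right - t_left)

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        rows = [[k, f"{v:.4f}"] for k, v in self.params.items()]
        rows.append(["R^2", f"{self.r_squared:.4f}"])
        rows.append(["valid", str(self.valid)])
        if self.valid:
            ps = self.peak_stats()
            rows += [["peak time", f"{ps.peak_time:.2f}"],
                     ["width-50", f"{ps.width50:.2f}"],
                     ["CV", f"{ps.cv:.3f}"]]
        return SimpleTable(rows, title="Dual asymmetric sigmoid fit").as_text()


def _interp_crossing(t0, t1, f0, f1, level) -> float:
    if f1 == f0:
        return float(t1)
    return float(t0 + (level - f0) * (t1 - t0) / (f1 - f0))


def fit_peak_function(curve: BehavioralCurve, r2_threshold: float = 0.5) -> PeakFunctionResults:
    """Fit the dual asymmetric sigmoid to a curve's stimulus window."""
    return PeakFunctionModel(curve, r2_threshold=r2_threshold).fit()


def peak_stats(fit: PeakFunctionResults) -> PeakStats:
    """Peak time and width-50 of a fitted peak function.

    PT is the argmax of the fitted function on a 0.01-s grid; W-50 spans the
    first half-peak crossing left of PT to the first right of it (clamped at
    the end of the stimulus window when the function never falls below half).
    """
    return fit.peak_stats()


def build_cohort_table(
    curves: Mapping[tuple, BehavioralCurve],
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Fit every (rat, trial_type) curve and tabulate per-rat peak stats.

    ``curves`` maps ``(rat_id, trial_type)`` to a curve. Invalid fits yield
    NA rows (the rat is then dropped listwise by downstream statistics).
    """
    rows = []
    for (rat, trial_type), curve in curves.items():
        fit = fit_peak_function(curve, r2_threshold=r2_threshold)
        if fit.valid:
            ps = fit.peak_stats()
            rows.append((rat, trial_type, ps.peak_time, ps.width50))
        else:
            rows.append((rat, trial_type, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["rat_id", "trial_type", "peak_time", "width50"])


def _complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Listwise exclusion: keep rats with valid stats on every trial type."""
    df = table.copy()
    bad = df.loc[df[["peak_time", "width50"]].isna().any(axis=1), "rat_id"].unique()
    return df[~df["rat_id"].isin(bad)]


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trial-type mean and SEM of PT, W-50, PT/W-50 and CV over included
    rats (rats with any missing entry are excluded listwise)."""
    df = _complete_cases(table)
    if df["rat_id"].nunique() < 2:
        raise ValueError("cohort summary needs at least 2 complete rats")
    df = df.assign(
        ratio=df["peak_time"] / df["width50"],
        cv=df["width50"] / df["peak_time"],
    )
    g = df.groupby("trial_type")[["peak_time", "width50", "ratio", "cv"]]
    out = pd.concat({"mean": g.mean(), "sem": g.sem()}, axis=1)
    order = [t for t in TRIAL_TYPES if t in out.index]
    return out.loc[order]


def pivot_measure(table: pd.DataFrame, measure: str = "peak_time") -> pd.DataFrame:
    """Rats x trial-types matrix of one measure, complete cases only."""
    df = _complete_cases(table)
    if measure == "cv":
        df = df.assign(cv=df["width50"] / df["peak_time"])
    elif measure == "ratio":
        df = df.assign(ratio=df["peak_time"] / df["width50"])
    wide = df.pivot(index="rat_id", columns="trial_type", values=measure)
    order = [t for t in TRIAL_TYPES if t in wide.columns]
    return wide[order]


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def rm_anova(values: np.ndarray | pd.DataFrame) -> AnovaResult:
    """One-way repeated-measures ANOVA (subjects as the blocking factor).

    ``values`` is an n_subjects x k_conditions matrix with no missing cells.
    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1)).
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n>=2 subjects by k>=2 conditions matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has missing cells; exclude incomplete subjects first")
    n, k = m.shape
    grand = m.mean()
    ss_cond = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    return AnovaResult(F=float(f), df1=df1, df2=df2, p=float(stats.f.sf(f, df1, df2)))


@dataclass
class PosthocResult:
    """Pairwise within-subject comparisons and the induced mean ordering."""

    table: pd.DataFrame
    ordering: list[str]
    all_significant: bool
    anova: AnovaResult = field(default=None)  # type: ignore[assignment]


def posthoc_pairwise(
    values: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Bonferroni-corrected paired t-tests over all condition pairs.

    Returns the pairwise table, the ordering of condition means (descending),
    and whether every pair is significant at ``alpha`` after correction.
    The omnibus RM-ANOVA is computed alongside; pairwise decisions are only
    meaningful when it is significant.
    """
    if isinstance(values, pd.DataFrame):
        labels = list(values.columns)
        m = values.to_numpy(dtype=float)
    else:
        m = np.asarray(values, dtype=float)
        labels = list(labels) if labels is not None else [
            f"cond{j}" for j in range(m.shape[1])
        ]
    anova = rm_anova(m)
    k = m.shape[1]
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = m[:, i] - m[:, j]
        if np.allclose(diff, diff[0]):
            tstat, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
        else:
            tstat, p = stats.ttest_rel(m[:, i], m[:, j])
        p_adj = min(float(p) * n_pairs, 1.0)
        rows.append((labels[i], labels[j], float(np.mean(diff)), float(tstat),
                     float(p), p_adj, p_adj < alpha))
    table = pd.DataFrame(
        rows, columns=["a", "b", "mean_diff", "t", "p", "p_bonferroni", "significant"]
    )
    ordering = [labels[j] for j in np.argsort(-m.mean(axis=0))]
    return PosthocResult(
        table=table,
        ordering=ordering,
        all_significant=bool(table["significant"].all()),
        anova=anova,
    )
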