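"""File formats: weight files, step series, trajectories, cohort tables.

Weight files are flat ``key: value`` text (one entry per line, ``#``
comments), holding the fourteen network weights W1..W14 and, optionally, the
saliency constants (t_sat, f_sat, cutoff_a, cutoff_v, epsilon). Values
round-trip as decimal strings. Step series and trajectories are TSV with a
header row.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkWeights, Trajectory
from .saliency import SaliencyParams

__all__ = [
    "read_weights",
    "write_weights",
    "reference_weights",
    "reference_peak_table",
    "read_step_series",
    "write_step_series",
    "read_trajectory",
    "write_trajectory",
    "read_cohort_table",
    "write_cohort_table",
]

_WEIGHT_KEYS = tuple(f"W{i}" for i in range(1, 15))
_SALIENCY_KEYS = ("t_sat", "f_sat", "cutoff_a", "cutoff_v", "epsilon")
_REQUIRED_SALIENCY = ("t_sat", "f_sat", "cutoff_a", "cutoff_v")


class WeightsFormatError(ValueError):
    """Malformed weights file (missing/duplicate key, non-numeric value)."""


def _parse_kv_lines(text: str, source: str) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if ":" not in stripped:
            raise WeightsFormatError(
                f"{source}:{lineno}: expected 'key: value', got {stripped!r}"
            )
        key, _, value = stripped.partition(":")
        key = key.strip()
        if key in entries:
            raise WeightsFormatError(f"{source}: duplicate key {key!r}")
        entries[key] = value.strip()
    return entries


def _parse_float(entries: dict[str, str], key: str, source: str) -> float:
    try:
        return float(entries[key])
    except ValueError:
        raise WeightsFormatError(
            f"{source}: non-numeric value for key {key!r}: {entries[key]!r}"
        ) from None


def parse_weights_text(
    text: str, source: str = "<string>"
) -> tuple[NetworkWeights, SaliencyParams | None]:
    entries = _parse_kv_lines(text, source)
    missing = [k for k in _WEIGHT_KEYS if k not in entries]
    if missing:
        raise WeightsFormatError(f"{source}: missing weight key(s) {missing}")
    unknown = set(entries) - set(_WEIGHT_KEYS) - set(_SALIENCY_KEYS)
    if unknown:
        raise WeightsFormatError(f"{source}: unknown key(s) {sorted(unknown)}")
    weights = NetworkWeights.from_dict(
        {k: _parse_float(entries, k, source) for k in _WEIGHT_KEYS}
    )
    present = [k for k in _SALIENCY_KEYS if k in entries]
    if not present:
        return weights, None
    missing_sal = [k for k in _REQUIRED_SALIENCY if k not in entries]
    if missing_sal:
        raise WeightsFormatError(
            f"{source}: saliency keys present but missing {missing_sal}"
        )
    kw = {k: _parse_float(entries, k, source) for k in present}
    return weights, SaliencyParams(**kw)


def read_weights(path) -> tuple[NetworkWeights, SaliencyParams | None]:
    """Read a weights file; returns (weights, saliency-or-None)."""
    path = Path(path)
    return parse_weights_text(path.read_text(), source=str(path))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_weights(
    weights: NetworkWeights,
    path,
    saliency: SaliencyParams | None = None,
) -> None:
    """Write a weights file (optionally with saliency constants)."""
    lines = [f"{k}: {_fmt(v)}" for k, v in weights.to_dict().items()]
    if saliency is not None:
        for k in _SALIENCY_KEYS:
            lines.append(f"{k}: {_fmt(getattr(saliency, k))}")
    Path(path).write_text("\n".join(lines) + "\n")


def reference_weights() -> tuple[NetworkWeights, SaliencyParams]:
    """The packaged reference parameter set (published fitted weights and
    saliency constants for the 5-s tone / 30-s flash dataset)."""
    text = resources.files("timingnet.data").joinpath(
        "reference_weights.txt"
    ).read_text()
    weights, sal = parse_weights_text(text, source="reference_weights.txt")
    assert sal is not None
    return weights, sal


def reference_peak_table() -> pd.DataFrame:
    """The packaged per-rat peak-time / width-50 table (published values;
    one rat has no valid flash/compound fit and is marked NA)."""
    with resources.files("timingnet.data").joinpath(
        "reference_peak_stats.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def write_step_series(values: np.ndarray, path) -> None:
    """Write a step series as two-column TSV (step, value)."""
    df = pd.DataFrame(
        {"step": np.arange(1, len(values) + 1), "value": np.asarray(values, float)}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_step_series(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column")
    return df["value"].to_numpy(dtype=float)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV, one row per step."""
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in Trajectory.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory column(s) {missing}")
    kw = {c: df[c].to_numpy() for c in Trajectory.columns}
    kw["step"] = kw["step"].astype(int)
    kw["tone_cut"] = kw["tone_cut"].astype(int)
    kw["flash_cut"] = kw["flash_cut"].astype(int)
    return Trajectory(**kw)


def write_cohort_table(table: pd.DataFrame, path) -> None:
    """Write a per-rat cohort table (rat_id, trial_type, peak_time, width50)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"rat_id", "trial_type", "peak_time", "width50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df
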