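"""Reduce raw per-well measurements to energy-production summaries.

The OmniLog incubator-reader records per-well optical density every 15 min
over a 24 h incubation; NADH production reduces a redox dye, so OD is a
proxy for cellular energy production.  Two per-well summaries are
supported:

* ``auc`` — trapezoidal area under the kinetic OD curve, in OD*min;
* ``endpoint`` — relative absorbance A590-750 (the reading at the dye's
  590 nm absorbance peak minus a 750 nm background reading).

Either summary is carried downstream on a log10 scale, with non-positive
raw values floored at a small epsilon before the log.  The group
statistics are rank-based and therefore invariant to the log, but the
single-case box-whisker limits operate on the logged values directly
(matching the quantity plotted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .plates import WellAddress

__all__ = [
    "KineticsError",
    "KineticCurve",
    "EndpointRead",
    "WellSummary",
    "relative_absorbance",
    "auc_trapezoid",
    "log_transform",
    "summarize_well",
    "read_kinetics",
    "read_endpoints",
    "summarize_dataset",
    "DEFAULT_FLOOR_EPS",
]

#: floor applied to raw summaries before log10 (OD*min); keeps logs of
#: background-subtracted endpoint reads near zero well defined.
DEFAULT_FLOOR_EPS = 1e-3

Source = Literal["auc", "endpoint"]


class KineticsError(ValueError):
    """Raised for invalid curves, reads, or configuration."""


@dataclass(frozen=True)
class KineticCurve:
    """Per-well OD time series; times in minutes since dye addition."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size or t.size == 0:
            raise KineticsError("times and od must be 1-D arrays of equal, nonzero length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise KineticsError("times and od must be finite")
        if t[0] < 0:
            raise KineticsError("times must start at >= 0 minutes")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise KineticsError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)


@dataclass(frozen=True)
class EndpointRead:
    """Paired endpoint absorbances: 590 nm (dye peak) and 750 nm (background)."""

    a590: float
    a750: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a590) and math.isfinite(self.a750)):
            raise KineticsError("endpoint absorbances must be finite")


@dataclass(frozen=True)
class WellSummary:
    """Reduced per-well energy-production value on raw and log10 scales."""

    log_value: float
    source: Source
    auc: float | None = None
    rel_abs: float | None = None

    def __post_init__(self) -> None:
        if self.auc is None and self.rel_abs is None:
            raise KineticsError("WellSummary needs at least one of auc / rel_abs")


def relative_absorbance(read: EndpointRead) -> float:
    """A590-750; may be negative (handled by the floor at the log step)."""
    return read.a590 - read.a750


def auc_trapezoid(curve: KineticCurve) -> float:
    """Trapezoidal integral of OD over time, in OD*min."""
    if curve.times.size < 2:
        raise KineticsError("AUC needs at least 2 time points")
    return float(np.trapezoid(curve.od, curve.times))


def log_transform(value: float, floor_eps: float = DEFAULT_FLOOR_EPS) -> float:
    """log10 of ``value`` floored at ``floor_eps`` (> 0)."""
    if not floor_eps > 0:
        raise KineticsError(f"floor_eps must be > 0, got {floor_eps}")
    return math.log10(max(value, floor_eps))


def summarize_well(
    curve: KineticCurve | None = None,
    endpoint: EndpointRead | None = None,
    source: Source = "auc",
    floor_eps: float = DEFAULT_FLOOR_EPS,
) -> WellSummary:
    """Compute the per-well summary selected by ``source``.

    Both measurement kinds are summarised when both are supplied, but
    ``log_value`` always comes from the selected source.
    """
    if source not in ("auc", "endpoint"):
        raise KineticsError(f"source must be 'auc' or 'endpoint', got {source!r}")
    auc = auc_trapezoid(curve) if curve is not None else None
    rel = relative_absorbance(endpoint) if endpoint is not None else None
    raw = auc if source == "auc" else rel
    if raw is None:
        raise KineticsError(f"source={source!r} but the matching measurement is missing")
    return WellSummary(log_value=log_transform(raw, floor_eps), source=source, auc=auc, rel_abs=rel)


_KINETIC_COLS = ["sample_id", "plate", "well", "time_min", "od"]
_ENDPOINT_COLS = ["sample_id", "plate", "well", "a590", "a750"]


def _canonicalize(df: pd.DataFrame, path: object) -> pd.DataFrame:
    canon = {}
    for plate, well in df[["plate", "well"]].drop_duplicates().itertuples(index=False):
        canon[(plate, well)] = WellAddress.parse(plate, well).well
    df = df.copy()
    df["well"] = [canon[(p, w)] for p, w in zip(df["plate"], df["well"])]
    return df


def read_kinetics(path: str | Path) -> pd.DataFrame:
    """Long-format kinetic reads: sample_id,plate,well,time_min,od."""
    df = pd.read_csv(path)
    missing = [c for c in _KINETIC_COLS if c not in df.columns]
    if missing:
        raise KineticsError(f"{path}: missing kinetic columns {missing}")
    df = df[_KINETIC_COLS].astype({"time_min": float, "od": float})
    if not np.all(np.isfinite(df["time_min"])) or not np.all(np.isfinite(df["od"])):
        raise KineticsError(f"{path}: non-finite time or OD values")
    return _canonicalize(df, path)


def read_endpoints(path: str | Path) -> pd.DataFrame:
    """Endpoint reads: sample_id,plate,well,a590,a750."""
    df = pd.read_csv(path)
    missing = [c for c in _ENDPOINT_COLS if c not in df.columns]
    if missing:
        raise KineticsError(f"{path}: missing endpoint columns {missing}")
    df = df[_ENDPOINT_COLS].astype({"a590": float, "a750": float})
    if not np.all(np.isfinite(df[["a590", "a750"]].to_numpy())):
        raise KineticsError(f"{path}: non-finite absorbances")
    return _canonicalize(df, path)


def _auc_by_well(kinetics: pd.DataFrame) -> pd.DataFrame:
    keys = ["sample_id", "plate", "well"]
    df = kinetics.sort_values(keys + ["time_min"], kind="mergesort").reset_index(drop=True)
    grp = df.groupby(keys, sort=False)
    dt = df["time_min"].diff()
    mean_od = 0.5 * (df["od"] + df["od"].shift())
    first = grp.cumcount() == 0
    sizes = grp["od"].transform("size")
    if (sizes < 2).any():
        bad = df.loc[sizes < 2, keys].drop_duplicates().iloc[0].tolist()
        raise KineticsError(f"well {bad} has fewer than 2 time points")
    if ((dt <= 0) & ~first).any():
        bad = df.loc[(dt <= 0) & ~first, keys].iloc[0].tolist()
        raise KineticsError(f"well {bad} has non-increasing or duplicate times")
    contrib = (mean_od * dt).where(~first, 0.0)
    out = contrib.groupby([df[k] for k in keys], sort=False).sum().rename("value")
    return out.reset_index()


def summarize_dataset(
    kinetics: pd.DataFrame | None = None,
    endpoints: pd.DataFrame | None = None,
    source: Source = "auc",
    floor_eps: float = DEFAULT_FLOOR_EPS,
) -> pd.DataFrame:
    """Per-(sample, plate, well) summary table feeding the statistics.

    Returns columns ``sample_id, plate, well, value, log_value`` where
    ``value`` is the raw summary selected by ``source`` (AUC in OD*min,
    or relative absorbance) and ``log_value`` its floored log10.
    """
    if not floor_eps > 0:
        raise KineticsError(f"floor_eps must be > 0, got {floor_eps}")
    if source == "auc":
        if kinetics is None:
            raise KineticsError("source='auc' requires kinetic reads")
        out = _auc_by_well(kinetics)
    elif source == "endpoint":
        if endpoints is None:
            raise KineticsError("source='endpoint' requires endpoint reads")
        out = endpoints.copy()
        out["value"] = out["a590"] - out["a750"]
        out = out[["sample_id", "plate", "well", "value"]]
    else:
        raise KineticsError(f"source must be 'auc' or 'endpoint', got {source!r}")
    out = out.copy()
    out["log_value"] = np.log10(np.maximum(out["value"], floor_eps))
    return out.sort_values(["sample_id", "plate", "well"], kind="mergesort").reset_index(drop=True)
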