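"""Single-case classification against a normative control cohort.

With one or two patient cell lines, ordinary group tests are badly
underpowered, so each patient's per-well log summary is compared against
the control cohort's box-and-whisker limits (informally, the
"inter-ocular trauma test"): a well is of interest when the patient's
value falls strictly above the upper outer limit or strictly below the
lower one.  Two readings of "outer limits" are supported:

* ``whisker`` (default) — the most extreme control values that still lie
  inside the Tukey fences; this is what a box plot actually draws.
* ``fence`` — the Tukey fences themselves, Q1 - 1.5*IQR and
  Q3 + 1.5*IQR.

Quartiles are computed by linear interpolation between order statistics
(position (n-1)*p), so limits are reproducible bit-for-bit.  Values equal
to a limit classify as "within" (conservative for calling abnormality).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .plates import PlateLayout, WellAddress

__all__ = [
    "SingleCaseError",
    "ControlLimits",
    "SingleCaseCall",
    "CallSet",
    "control_limits",
    "classify_value",
    "call_wells",
    "calls_to_frame",
    "write_calls_tsv",
    "read_calls_tsv",
]

Method = Literal["whisker", "fence"]
Call = Literal["below", "within", "above"]

MIN_CONTROLS = 4


class SingleCaseError(ValueError):
    """Raised for invalid control sets or configuration."""


@dataclass(frozen=True)
class ControlLimits:
    """Control-cohort quartiles and the outer limits derived from them."""

    q1: float
    q3: float
    lower: float
    upper: float
    method: Method

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def control_limits(control_values: Sequence[float], method: Method = "whisker") -> ControlLimits:
    """Outer limits of the control distribution for one well.

    Fences are Q1 - 1.5*IQR and Q3 + 1.5*IQR; whisker limits are the most
    extreme control values lying within those fences.
    """
    if method not in ("whisker", "fence"):
        raise SingleCaseError(f"method must be 'whisker' or 'fence', got {method!r}")
    v = np.asarray(control_values, dtype=float)
    if v.size < MIN_CONTROLS:
        raise SingleCaseError(f"need >= {MIN_CONTROLS} control values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise SingleCaseError("control values must be finite")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation, position (n-1)*p
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if method == "fence":
        lower, upper = lo_fence, hi_fence
    else:
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        # quartiles are always inside the fences, so `inside` is non-empty
        lower, upper = float(inside.min()), float(inside.max())
    return ControlLimits(q1=float(q1), q3=float(q3), lower=float(lower), upper=float(upper), method=method)


def classify_value(value: float, limits: ControlLimits) -> Call:
    """"above" iff value > upper, "below" iff value < lower, else "within"."""
    if value > limits.upper:
        return "above"
    if value < limits.lower:
        return "below"
    return "within"


@dataclass(frozen=True)
class SingleCaseCall:
    """Classification of one patient value at one well."""

    address: WellAddress
    patient_id: str
    value: float
    limits: ControlLimits
    call: Call


@dataclass(frozen=True)
class CallSet:
    """All calls for one patient plus wells skipped for missing data."""

    patient_id: str
    calls: tuple[SingleCaseCall, ...]
    skipped: tuple[tuple[WellAddress, str], ...] = ()

    def counts(self) -> dict[str, int]:
        out = {"below": 0, "within": 0, "above": 0}
        for c in self.calls:
            out[c.call] += 1
        return out


def call_wells(
    summaries: pd.DataFrame,
    patient_id: str,
    control_ids: Iterable[str],
    method: Method = "whisker",
    plates: Iterable[str] | None = None,
) -> CallSet:
    """Classify one patient against the controls, well by well.

    ``summaries`` is the per-(sample, plate, well) log-summary table.
    Scope is every well where the controls are complete (optionally
    restricted to ``plates``); wells with a missing patient value or
    fewer than 4 control values are reported as skipped, not an error.
    """
    control_ids = sorted(set(control_ids))
    if patient_id in control_ids:
        raise SingleCaseError(f"patient {patient_id!r} cannot also be a control")
    if plates is not None:
        summaries = summaries[summaries["plate"].isin(set(plates))]
    wide = summaries.pivot_table(index=["plate", "well"], columns="sample_id", values="log_value")
    present_controls = [c for c in control_ids if c in wide.columns]
    if len(present_controls) < MIN_CONTROLS:
        raise SingleCaseError(
            f"need >= {MIN_CONTROLS} controls with data, got {len(present_controls)}"
        )

    calls: list[SingleCaseCall] = []
    skipped: list[tuple[WellAddress, str]] = []
    ctrl = wide[present_controls].to_numpy()
    patient = (
        wide[patient_id].to_numpy()
        if patient_id in wide.columns
        else np.full(len(wide), np.nan)
    )
    for (plate, well), crow, pval in zip(wide.index, ctrl, patient):
        addr = WellAddress(plate, well)
        cvals = crow[np.isfinite(crow)]
        if np.isnan(pval):
            skipped.append((addr, "missing patient value"))
            continue
        if cvals.size < MIN_CONTROLS:
            skipped.append((addr, f"only {cvals.size} control values"))
            continue
        limits = control_limits(cvals, method=method)
        calls.append(
            SingleCaseCall(addr, patient_id, float(pval), limits, classify_value(float(pval), limits))
        )
    calls.sort(key=lambda c: c.address)
    skipped.sort(key=lambda s: s[0])
    return CallSet(patient_id=patient_id, calls=tuple(calls), skipped=tuple(skipped))


def calls_to_frame(callset: CallSet, layout: PlateLayout | None = None) -> pd.DataFrame:
    rows = []
    for c in callset.calls:
        rows.append(
            {
                "patient_id": c.patient_id,
                "plate": c.address.plate,
                "well": c.address.well,
                "compound": layout.compound(c.address) if layout and c.address in layout else "",
                "value": c.value,
                "lower": c.limits.lower,
                "upper": c.limits.upper,
                "method": c.limits.method,
                "call": c.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "plate", "well", "compound", "value", "lower", "upper", "method", "call"],
    )


def write_calls_tsv(
    callsets: Iterable[CallSet], path: str | Path, layout: PlateLayout | None = None
) -> None:
    frames = [calls_to_frame(cs, layout) for cs in callsets]
    df = pd.concat(frames, ignore_index=True) if frames else calls_to_frame(CallSet("", ()))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the calls table written by :func:`write_calls_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "compound": str})
    needed = {"patient_id", "plate", "well", "value", "lower", "upper", "method", "call"}
    missing = needed - set(df.columns)
    if missing:
        raise SingleCaseError(f"{path}: missing calls columns {sorted(missing)}")
    return df
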