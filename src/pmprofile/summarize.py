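"""Aggregate per-well outcomes into compound-level reporting artifacts.

Three report shapes are produced:

* trend tables — per patient group, which compounds produced higher
  ("increased") or lower ("decreased") NADH-proxy signal than controls;
* opposite / shared trend lists — compounds moving in strictly opposite
  directions in two groups, or in the same direction in all groups;
* cluster fractions — within a named set of wells (e.g. all wells
  containing glycine), the fraction carrying a stated direction,
  reported as k/n and a percentage to one decimal (round half up).

A compound occupying several wells (a concentration series) gets a group
direction only when at least one of its wells is called and no well is
called in the opposite direction; conflicting calls are recorded as
"mixed" and excluded from the opposite/shared lists and the counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .plates import PlateLayout, WellAddress
from .single_case import CallSet, SingleCaseCall
from .stats import WellTestResult, round_half_up

__all__ = [
    "SummarizeError",
    "TrendRow",
    "TrendTable",
    "ClusterSummary",
    "direction_table",
    "direction_table_from_frame",
    "opposite_trends",
    "shared_trend",
    "cluster_fraction",
    "trend_table_to_frame",
    "write_trend_tsv",
    "render_trend_table",
]

Direction = Literal["increased", "decreased"]

_CALL_TO_DIRECTION = {"above": "increased", "below": "decreased"}


class SummarizeError(ValueError):
    """Raised for empty clusters or malformed aggregation inputs."""


@dataclass(frozen=True)
class TrendRow:
    group: str
    plate: str
    compound: str
    direction: str  # increased / decreased / mixed
    n_wells_called: int


@dataclass(frozen=True)
class TrendTable:
    """Per-compound directions for one or more groups, with per-plate counts."""

    rows: tuple[TrendRow, ...]

    def group_counts(self, group: str) -> tuple[int, int]:
        """(n increased, n decreased) compounds for a group; mixed excluded."""
        inc = sum(1 for r in self.rows if r.group == group and r.direction == "increased")
        dec = sum(1 for r in self.rows if r.group == group and r.direction == "decreased")
        return inc, dec

    def plate_counts(self) -> dict[tuple[str, str], Counter]:
        out: dict[tuple[str, str], Counter] = {}
        for r in self.rows:
            out.setdefault((r.group, r.plate), Counter())[r.direction] += 1
        return out

    def compounds(self, group: str, direction: str) -> list[str]:
        return sorted(r.compound for r in self.rows if r.group == group and r.direction == direction)

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.rows})


def _compound_rows(
    group: str, records: Iterable[tuple[WellAddress, str, str]]
) -> list[TrendRow]:
    """Aggregate (address, compound, call) records into per-compound rows."""
    per_compound: dict[str, dict] = {}
    for addr, compound, call in records:
        direction = _CALL_TO_DIRECTION.get(call)
        if direction is None:  # "within" calls carry no trend
            continue
        slot = per_compound.setdefault(compound, {"dirs": set(), "plates": set(), "n": 0})
        slot["dirs"].add(direction)
        slot["plates"].add(addr.plate)
        slot["n"] += 1
    rows = []
    for compound in sorted(per_compound):
        slot = per_compound[compound]
        direction = slot["dirs"].pop() if len(slot["dirs"]) == 1 else "mixed"
        plate = "+".join(sorted(slot["plates"]))
        rows.append(TrendRow(group, plate, compound, direction, slot["n"]))
    return rows


def _records_from_calls(
    calls: Iterable[SingleCaseCall], layout: PlateLayout
) -> list[tuple[WellAddress, str, str]]:
    return [
        (c.address, layout.compound(c.address) if c.address in layout else str(c.address), c.call)
        for c in calls
    ]


def direction_table(
    calls_by_group: Mapping[str, Iterable[SingleCaseCall] | CallSet], layout: PlateLayout
) -> TrendTable:
    """Build the trend table from single-case calls grouped by patient group.

    Calls from all patients of a group are pooled before the per-compound
    direction rule is applied, so two patients calling the same compound
    in opposite directions yield "mixed".
    """
    rows: list[TrendRow] = []
    for group in sorted(calls_by_group):
        calls = calls_by_group[group]
        if isinstance(calls, CallSet):
            calls = calls.calls
        rows.extend(_compound_rows(group, _records_from_calls(calls, layout)))
    return TrendTable(tuple(rows))


def direction_table_from_frame(calls: pd.DataFrame, group_of: Mapping[str, str]) -> TrendTable:
    """Trend table from a calls TSV frame; ``group_of`` maps patient_id to group."""
    rows: list[TrendRow] = []
    calls = calls.copy()
    unknown = set(calls["patient_id"]) - set(group_of)
    if unknown:
        raise SummarizeError(f"no group for patients {sorted(unknown)}")
    calls["group"] = calls["patient_id"].map(group_of)
    for group in sorted(calls["group"].unique()):
        sub = calls[calls["group"] == group]
        records = [
            (WellAddress.parse(r.plate, r.well), r.compound, r.call)
            for r in sub.itertuples(index=False)
        ]
        rows.extend(_compound_rows(group, records))
    return TrendTable(tuple(rows))


def opposite_trends(table_a: TrendTable, table_b: TrendTable) -> list[str]:
    """Compounds trending in strictly opposite directions in the two tables.

    Each input table must carry exactly one group; "mixed" compounds never
    qualify.  The result is order-independent (a vs b == b vs a).
    """
    dirs_a = _single_group_directions(table_a)
    dirs_b = _single_group_directions(table_b)
    out = [
        comp
        for comp, d in dirs_a.items()
        if comp in dirs_b
        and {d, dirs_b[comp]} == {"increased", "decreased"}
    ]
    return sorted(out)


def _single_group_directions(table: TrendTable) -> dict[str, str]:
    groups = table.groups()
    if len(groups) > 1:
        raise SummarizeError(f"expected a single-group table, got groups {groups}")
    return {r.compound: r.direction for r in table.rows if r.direction != "mixed"}


def shared_trend(tables_by_group: Mapping[str, TrendTable], direction: Direction) -> list[str]:
    """Compounds carrying ``direction`` in every group (>= 2 groups)."""
    if direction not in ("increased", "decreased"):
        raise SummarizeError(f"direction must be 'increased' or 'decreased', got {direction!r}")
    if len(tables_by_group) < 2:
        raise SummarizeError("shared_trend needs at least 2 groups")
    sets = []
    for table in tables_by_group.values():
        dirs = _single_group_directions(table)
        sets.append({c for c, d in dirs.items() if d == direction})
    shared = set.intersection(*sets)
    return sorted(shared)


@dataclass(frozen=True)
class ClusterSummary:
    """k of n wells in a named cluster carrying one direction."""

    cluster_name: str
    k: int
    n: int
    direction: str

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise SummarizeError(f"cluster {self.cluster_name!r}: k={self.k} outside [0, n={self.n}]")

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.k / self.n)


def cluster_fraction(
    items: Sequence[SingleCaseCall | WellTestResult],
    cluster_wells: Sequence[WellAddress],
    direction: Direction,
    cluster_name: str = "cluster",
    criterion: Literal["raw", "fdr", None] = "fdr",
) -> ClusterSummary:
    """Fraction of a well cluster carrying ``direction``.

    For :class:`WellTestResult` items a well counts when it is significant
    under ``criterion`` with the stated direction; for single-case calls,
    when at least one call at the well maps to the direction and none
    opposes it.  ``n`` is the cluster size.
    """
    if len(cluster_wells) == 0:
        raise SummarizeError("cluster_wells must be non-empty")
    if direction not in ("increased", "decreased"):
        raise SummarizeError(f"direction must be 'increased' or 'decreased', got {direction!r}")
    cluster = set(cluster_wells)
    per_well: dict[WellAddress, set[str]] = {}
    for item in items:
        if item.address not in cluster:
            continue
        if isinstance(item, WellTestResult):
            if criterion == "fdr" and not item.fdr_sig:
                continue
            if criterion == "raw" and not item.raw_sig:
                continue
            d = item.direction
            if d == "none":
                continue
        else:
            d = _CALL_TO_DIRECTION.get(item.call)
            if d is None:
                continue
        per_well.setdefault(item.address, set()).add(d)
    k = sum(1 for dirs in per_well.values() if dirs == {direction})
    return ClusterSummary(cluster_name, k, len(cluster), direction)


def trend_table_to_frame(table: TrendTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "plate": r.plate,
                "compound": r.compound,
                "direction": r.direction,
                "n_wells_called": r.n_wells_called,
            }
            for r in table.rows
        ],
        columns=["group", "plate", "compound", "direction", "n_wells_called"],
    )


def write_trend_tsv(table: TrendTable, path: str | Path) -> None:
    trend_table_to_frame(table).to_csv(path, sep="\t", index=False)


def render_trend_table(table: TrendTable) -> str:
    """Plain-text rendering of the trend table, one block per group."""
    lines = []
    for group in table.groups():
        inc, dec = table.group_counts(group)
        lines.append(f"== {group}: {inc} increased, {dec} decreased ==")
        for r in table.rows:
            if r.group == group:
                lines.append(f"  {r.plate:<14} {r.compound:<32} {r.direction:<9} ({r.n_wells_called} well(s))")
    return "\n".join(lines)
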