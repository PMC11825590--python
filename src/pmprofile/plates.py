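"""PM-M plate geometry and the well-to-compound annotation.

Biolog Phenotype Mammalian MicroArray (PM-M) plates are standard 96-well
plates (rows A-H, columns 1-12), each well pre-loaded with a different
compound: carbon energy sources on PM-M1, amino acids and dipeptides on
PM-M2 to PM-M4, ionic compounds (in concentration series) on PM-M5, and
hormones / metabolic effectors on PM-M6 to PM-M8.  Every downstream stage
(well summaries, group statistics, single-case calls, trend tables) keys
its results by the :class:`WellAddress` defined here and annotates them
through a :class:`PlateLayout`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "PLATE_IDS",
    "ROWS",
    "N_COLUMNS",
    "WELLS_PER_PLATE",
    "CATEGORIES",
    "LayoutError",
    "WellAddress",
    "CompoundAnnotation",
    "PlateLayout",
    "load_layout",
    "write_layout",
    "wells_matching",
    "concentration_series",
]

PLATE_IDS: tuple[str, ...] = tuple(f"PM-M{i}" for i in range(1, 9))
ROWS = "ABCDEFGH"
N_COLUMNS = 12
WELLS_PER_PLATE = 96

#: Fixed annotation vocabulary for what a well contains.
CATEGORIES = frozenset(
    {
        "carbon_source",
        "amino_acid",
        "dipeptide",
        "ion",
        "hormone",
        "metabolic_effector",
        "other",
    }
)

_WELL_RE = re.compile(r"^([A-Ha-h])(0?[1-9]|1[0-2])$")


class LayoutError(ValueError):
    """Raised for malformed well addresses or inconsistent layout tables."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well on one PM-M plate, e.g. ``PM-M8:G10``.

    ``well`` is stored canonically as row letter + zero-padded column
    (``D6`` and ``D06`` parse to the same address), so lexicographic
    ordering of ``(plate, well)`` is the natural plate / row / column
    reading order.
    """

    plate: str
    well: str

    @classmethod
    def parse(cls, plate: str, well: str) -> "WellAddress":
        plate = str(plate).strip()
        if plate not in PLATE_IDS:
            raise LayoutError(f"unknown plate identifier {plate!r} (expected one of {', '.join(PLATE_IDS)})")
        m = _WELL_RE.match(str(well).strip())
        if m is None:
            raise LayoutError(f"malformed well address {well!r} (expected row A-H + column 1-12)")
        row = m.group(1).upper()
        col = int(m.group(2))
        return cls(plate, f"{row}{col:02d}")

    @property
    def row(self) -> str:
        return self.well[0]

    @property
    def column(self) -> int:
        return int(self.well[1:])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.plate}:{self.well}"


@dataclass(frozen=True)
class CompoundAnnotation:
    """What a well contains: compound name, category, and optional
    membership in a concentration series (``series_id`` groups replicate
    wells of one compound, ``conc_rank`` orders them by increasing
    concentration, starting at 1)."""

    compound_name: str
    category: str
    series_id: str | None = None
    conc_rank: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LayoutError(
                f"unknown category {self.category!r} (expected one of {sorted(CATEGORIES)})"
            )
        if (self.series_id is None) != (self.conc_rank is None):
            raise LayoutError(
                f"series_id and conc_rank must be given together ({self.compound_name!r})"
            )
        if self.conc_rank is not None and self.conc_rank < 1:
            raise LayoutError(f"conc_rank must be >= 1, got {self.conc_rank}")


def _all_wells(plate: str) -> Iterator[WellAddress]:
    for row in ROWS:
        for col in range(1, N_COLUMNS + 1):
            yield WellAddress(plate, f"{row}{col:02d}")


@dataclass
class PlateLayout:
    """Validated mapping from :class:`WellAddress` to :class:`CompoundAnnotation`.

    ``plates_present`` is the set of plates that are *fully* annotated
    (all 96 wells); partial plates may still appear in ``entries`` (useful
    for small fixtures) but are not reported as present.
    """

    entries: dict[WellAddress, CompoundAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate_series()

    @property
    def plates_present(self) -> frozenset[str]:
        counts: dict[str, int] = {}
        for addr in self.entries:
            counts[addr.plate] = counts.get(addr.plate, 0) + 1
        return frozenset(p for p, n in counts.items() if n == WELLS_PER_PLATE)

    def _validate_series(self) -> None:
        by_series: dict[str, list[int]] = {}
        for addr, ann in self.entries.items():
            if ann.series_id is not None:
                by_series.setdefault(ann.series_id, []).append(ann.conc_rank)
        for sid, ranks in by_series.items():
            if sorted(ranks) != list(range(1, len(ranks) + 1)):
                raise LayoutError(
                    f"series {sid!r}: conc_rank values {sorted(ranks)} are not distinct "
                    f"and consecutive from 1"
                )

    def __contains__(self, addr: WellAddress) -> bool:
        return addr in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def annotation(self, addr: WellAddress) -> CompoundAnnotation:
        try:
            return self.entries[addr]
        except KeyError:
            raise LookupError(f"well {addr} is not annotated in this layout") from None

    def compound(self, addr: WellAddress) -> str:
        return self.annotation(addr).compound_name

    def wells_for_plate(self, plate: str) -> list[WellAddress]:
        return sorted(a for a in self.entries if a.plate == plate)

    def sorted_addresses(self) -> list[WellAddress]:
        return sorted(self.entries)


_COLUMNS = ["plate", "well", "compound", "category", "series_id", "conc_rank"]


def load_layout(path: str | Path) -> PlateLayout:
    """Read a layout CSV (columns plate,well,compound,category,series_id,conc_rank).

    Empty series columns mean the well is not part of a concentration
    series.  Duplicate ``(plate, well)`` rows, malformed addresses and
    unknown categories are rejected with the offending file row named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing layout columns {missing}")
    entries: dict[WellAddress, CompoundAnnotation] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # header is row 1
        try:
            addr = WellAddress.parse(rec.plate, rec.well)
            sid = rec.series_id.strip() or None
            rank_txt = rec.conc_rank.strip()
            rank = int(rank_txt) if rank_txt else None
            ann = CompoundAnnotation(rec.compound.strip(), rec.category.strip(), sid, rank)
        except (LayoutError, ValueError) as exc:
            raise LayoutError(f"{path}, row {rownum}: {exc}") from None
        if addr in entries:
            raise LayoutError(f"{path}, row {rownum}: duplicate address {addr}")
        entries[addr] = ann
    return PlateLayout(entries)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write the canonical form: sorted addresses, zero-padded wells."""
    rows = []
    for addr in layout.sorted_addresses():
        ann = layout.entries[addr]
        rows.append(
            {
                "plate": addr.plate,
                "well": addr.well,
                "compound": ann.compound_name,
                "category": ann.category,
                "series_id": ann.series_id or "",
                "conc_rank": "" if ann.conc_rank is None else ann.conc_rank,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def wells_matching(layout: PlateLayout, query: str) -> list[WellAddress]:
    """All addresses whose compound name contains ``query`` (case-insensitive)
    or whose category equals ``query``, in plate / row / column order.

    This is how compound clusters are defined, e.g. "all wells containing
    glycine" across the dipeptide plates.
    """
    if query in CATEGORIES:
        hits = [a for a, ann in layout.entries.items() if ann.category == query]
    else:
        needle = query.lower()
        hits = [a for a, ann in layout.entries.items() if needle in ann.compound_name.lower()]
    return sorted(hits)


def concentration_series(layout: PlateLayout, series_id: str) -> list[WellAddress]:
    """Addresses of one concentration series, ordered by increasing rank."""
    members = [
        (ann.conc_rank, addr)
        for addr, ann in layout.entries.items()
        if ann.series_id == series_id
    ]
    if not members:
        raise LookupError(f"unknown series_id {series_id!r}")
    return [addr for _, addr in sorted(members)]
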