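"""Per-well two-group comparison with false-discovery-rate control.

Each comparison contrasts two disjoint sample selections (e.g. the two
Rett-syndrome lines versus 50 controls, or the female patients versus
female controls) well by well with a two-sided Mann-Whitney rank test,
then adjusts the per-well p-values with the Benjamini-Hochberg step-up
procedure across all wells of that comparison.  Thresholds are strict:
raw significance is p < alpha and FDR significance is p_adj < q, both
defaulting to 0.05.

The Mann-Whitney test is exact (full enumeration of group assignments,
tie-aware) whenever the number of splits C(n_a+n_b, n_a) is at most
20,000 — which covers the study's 2-vs-50 designs — and otherwise falls
back to the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .plates import PlateLayout, WellAddress

__all__ = [
    "StatsError",
    "MannWhitneyResult",
    "mann_whitney_two_sided",
    "benjamini_hochberg",
    "SampleSelector",
    "ComparisonSpec",
    "WellTestResult",
    "run_comparison",
    "PercentSignificant",
    "percent_significant",
    "round_half_up",
    "results_to_frame",
    "write_results_tsv",
    "EXACT_ENUMERATION_LIMIT",
]

#: largest number of group-assignment splits enumerated exactly.
EXACT_ENUMERATION_LIMIT = 20_000

Direction = Literal["increased", "decreased", "none"]


class StatsError(ValueError):
    """Raised for invalid statistical inputs or selectors."""


class MannWhitneyResult(NamedTuple):
    u_stat: float
    p: float
    method: str  # "exact" or "asymptotic"


@lru_cache(maxsize=64)
def _splits(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets of size k, as an array of row indices."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def mann_whitney_two_sided(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of ``values_a`` vs ``values_b``.

    U counts pairs where a > b plus half of the tied pairs.  The exact
    branch enumerates every assignment of the pooled (tied) ranks to
    group a and reports the fraction of splits at least as extreme as the
    observed U (distance from the null mean n_a*n_b/2).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    mu = n_a * n_b / 2.0
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        return MannWhitneyResult(u, 1.0, "exact")
    if math.comb(n, n_a) <= exact_limit:
        combs = _splits(n, n_a)
        u_all = ranks[combs].sum(axis=1) - n_a * (n_a + 1) / 2
        p = float(np.mean(np.abs(u_all - mu) >= abs(u - mu) - 1e-12))
        method = "exact"
    else:
        p = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "asymptotic"
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return MannWhitneyResult(u, p, method)


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment and strict flags.

    Returns ``(p_adj, flags)`` where ``p_adj`` are the monotonized
    step-up values (p_(i)*m/i with a cumulative minimum from the largest
    p, capped at 1) and ``flags[i]`` is True iff ``p_adj[i] < q``.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise StatsError(f"q must be in (0, 1), got {q}")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise StatsError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


@dataclass(frozen=True)
class SampleSelector:
    """Selects samples from the sample sheet by group label, explicit ids,
    and/or sex; conditions are combined with AND."""

    groups: frozenset[str] | None = None
    sample_ids: frozenset[str] | None = None
    sex: str | None = None

    @classmethod
    def make(
        cls,
        groups: Iterable[str] | str | None = None,
        sample_ids: Iterable[str] | str | None = None,
        sex: str | None = None,
    ) -> "SampleSelector":
        def _norm(x):
            if x is None:
                return None
            if isinstance(x, str):
                x = [x]
            return frozenset(x)

        return cls(_norm(groups), _norm(sample_ids), sex)

    def select(self, samples: pd.DataFrame) -> list[str]:
        mask = pd.Series(True, index=samples.index)
        if self.groups is not None:
            mask &= samples["group"].isin(self.groups)
        if self.sample_ids is not None:
            mask &= samples["sample_id"].isin(self.sample_ids)
        if self.sex is not None:
            mask &= samples["sex"] == self.sex
        return sorted(samples.loc[mask, "sample_id"])


@dataclass(frozen=True)
class ComparisonSpec:
    """One named comparison family: group_a vs group_b over a set of plates.

    The BH family is every well of every included plate, tested once in
    this comparison.
    """

    name: str
    group_a: SampleSelector
    group_b: SampleSelector
    plates: frozenset[str]

    def __post_init__(self) -> None:
        if not self.plates:
            raise StatsError(f"comparison {self.name!r}: no plates included")


@dataclass(frozen=True)
class WellTestResult:
    """Outcome of one per-well group comparison."""

    address: WellAddress
    n_a: int
    n_b: int
    u_stat: float
    p: float
    p_adj: float
    direction: Direction
    raw_sig: bool
    fdr_sig: bool
    comparison: str = ""


def run_comparison(
    summaries: pd.DataFrame,
    samples: pd.DataFrame,
    spec: ComparisonSpec,
    q: float = 0.05,
    alpha: float = 0.05,
) -> list[WellTestResult]:
    """Run one comparison family: a Mann-Whitney test per well plus BH.

    ``summaries`` is the per-(sample, plate, well) table from
    :func:`pmprofile.kinetics.summarize_dataset`; ``samples`` the sample
    sheet with columns sample_id, group, sex.  Direction is the sign of
    (median_a - median_b) on log values, "none" on an exact tie.
    """
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must be in (0, 1), got {alpha}")
    ids_a = spec.group_a.select(samples)
    ids_b = spec.group_b.select(samples)
    if not ids_a or not ids_b:
        raise StatsError(f"comparison {spec.name!r}: a selector matched no samples")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise StatsError(f"comparison {spec.name!r}: selectors overlap on {sorted(overlap)}")

    sub = summaries[summaries["plate"].isin(spec.plates)]
    wide = sub.pivot_table(index=["plate", "well"], columns="sample_id", values="log_value")
    needed = ids_a + ids_b
    missing_cols = [s for s in needed if s not in wide.columns]
    if missing_cols:
        raise StatsError(
            f"comparison {spec.name!r}: no data for samples {missing_cols}"
        )
    wide = wide[needed]
    if wide.isna().any().any():
        bad = wide[wide.isna().any(axis=1)].index[0]
        raise StatsError(
            f"comparison {spec.name!r}: incomplete data at well {bad[0]}:{bad[1]}"
        )

    addresses: list[WellAddress] = []
    u_stats: list[float] = []
    p_vals: list[float] = []
    directions: list[Direction] = []
    vals = wide.to_numpy()
    n_a, n_b = len(ids_a), len(ids_b)
    for (plate, well), row in zip(wide.index, vals):
        va, vb = row[:n_a], row[n_a:]
        res = mann_whitney_two_sided(va, vb)
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        if med_a > med_b:
            direction: Direction = "increased"
        elif med_a < med_b:
            direction = "decreased"
        else:
            direction = "none"
        addresses.append(WellAddress(plate, well))
        u_stats.append(res.u_stat)
        p_vals.append(res.p)
        directions.append(direction)

    p_adj, flags = benjamini_hochberg(p_vals, q=q)
    results = [
        WellTestResult(
            address=addr,
            n_a=n_a,
            n_b=n_b,
            u_stat=u,
            p=p,
            p_adj=float(pa),
            direction=d,
            raw_sig=p < alpha,
            fdr_sig=bool(f),
            comparison=spec.name,
        )
        for addr, u, p, pa, d, f in zip(addresses, u_stats, p_vals, p_adj, directions, flags)
    ]
    results.sort(key=lambda r: r.address)
    return results


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 14.15 -> 14.2), matching reported percentages."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


class PercentSignificant(NamedTuple):
    count: int
    total: int
    percent: float


def percent_significant(
    results: Sequence[WellTestResult], criterion: Literal["raw", "fdr"] = "fdr"
) -> PercentSignificant:
    """Count and percentage of significant wells (one decimal, round half up)."""
    if not results:
        raise StatsError("percent_significant needs a non-empty result list")
    if criterion == "raw":
        count = sum(r.raw_sig for r in results)
    elif criterion == "fdr":
        count = sum(r.fdr_sig for r in results)
    else:
        raise StatsError(f"criterion must be 'raw' or 'fdr', got {criterion!r}")
    total = len(results)
    return PercentSignificant(count, total, round_half_up(100.0 * count / total))


def results_to_frame(
    results: Sequence[WellTestResult], layout: PlateLayout | None = None
) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "comparison": r.comparison,
                "plate": r.address.plate,
                "well": r.address.well,
                "compound": layout.compound(r.address) if layout and r.address in layout else "",
                "n_a": r.n_a,
                "n_b": r.n_b,
                "u_stat": r.u_stat,
                "p": r.p,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "raw_sig": r.raw_sig,
                "fdr_sig": r.fdr_sig,
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(
    results: Sequence[WellTestResult],
    path: str | Path,
    layout: PlateLayout | None = None,
) -> None:
    """Write the per-well results table (floats at 6 significant digits)."""
    results_to_frame(results, layout).to_csv(path, sep="\t", index=False, float_format="%.6g")
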