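"""End-to-end orchestration: files in, result tables out.

`run_profile` ties the stages together: per-well summaries from the raw
reads, one Mann-Whitney/BH comparison family per configured contrast,
single-case box-whisker calls for every non-control sample, and the
compound-level trend table.  The CLI wraps these functions; they are
equally usable from Python.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .kinetics import DEFAULT_FLOOR_EPS, read_endpoints, read_kinetics, summarize_dataset
from .plates import PlateLayout, load_layout
from .single_case import CallSet, call_wells, write_calls_tsv
from .stats import (
    ComparisonSpec,
    SampleSelector,
    StatsError,
    WellTestResult,
    percent_significant,
    run_comparison,
    write_results_tsv,
)
from .summarize import TrendTable, direction_table, write_trend_tsv

__all__ = ["RunConfig", "ProfileResult", "read_samples", "run_profile", "write_profile_outputs"]

CONTROL_GROUP = "control"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration (YAML-loadable; see ``RunConfig.from_yaml``)."""

    source: str = "auc"  # which summary feeds the statistics: auc | endpoint
    alpha: float = 0.05
    q: float = 0.05
    method: str = "whisker"  # single-case outer-limit rule: whisker | fence
    floor_eps: float = DEFAULT_FLOOR_EPS
    comparisons: tuple[ComparisonSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.q < 1:
            raise StatsError("alpha and q must be in (0, 1)")
        if self.source not in ("auc", "endpoint"):
            raise StatsError(f"source must be 'auc' or 'endpoint', got {self.source!r}")
        if self.method not in ("whisker", "fence"):
            raise StatsError(f"method must be 'whisker' or 'fence', got {self.method!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        comps = []
        for c in data.get("comparisons", []):
            comps.append(
                ComparisonSpec(
                    name=c["name"],
                    group_a=SampleSelector.make(**c.get("group_a", {})),
                    group_b=SampleSelector.make(**c.get("group_b", {})),
                    plates=frozenset(c["plates"]),
                )
            )
        kwargs = {k: data[k] for k in ("source", "alpha", "q", "method", "floor_eps", "seed") if k in data}
        return cls(comparisons=tuple(comps), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "alpha": self.alpha,
            "q": self.q,
            "method": self.method,
            "floor_eps": self.floor_eps,
            "seed": self.seed,
            "comparisons": [
                {
                    "name": c.name,
                    "group_a": _selector_dict(c.group_a),
                    "group_b": _selector_dict(c.group_b),
                    "plates": sorted(c.plates),
                }
                for c in self.comparisons
            ],
        }


def _selector_dict(sel: SampleSelector) -> dict:
    out = {}
    if sel.groups is not None:
        out["groups"] = sorted(sel.groups)
    if sel.sample_ids is not None:
        out["sample_ids"] = sorted(sel.sample_ids)
    if sel.sex is not None:
        out["sex"] = sel.sex
    return out


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "group", "sex"} - set(df.columns)
    if missing:
        raise StatsError(f"{path}: missing sample-sheet columns {sorted(missing)}")
    return df


def default_comparisons(samples: pd.DataFrame, summaries: pd.DataFrame) -> tuple[ComparisonSpec, ...]:
    """One comparison per non-control group against the full control cohort,
    over the plates for which every selected sample has data."""
    specs = []
    for group in sorted(samples["group"].unique()):
        if group == CONTROL_GROUP:
            continue
        ids = set(samples.loc[samples["group"] == group, "sample_id"])
        ids |= set(samples.loc[samples["group"] == CONTROL_GROUP, "sample_id"])
        counts = summaries[summaries["sample_id"].isin(ids)].groupby("plate")["sample_id"].nunique()
        plates = frozenset(counts[counts == len(ids)].index)
        if not plates:
            continue
        specs.append(
            ComparisonSpec(
                name=f"{group}_vs_control",
                group_a=SampleSelector.make(groups=group),
                group_b=SampleSelector.make(groups=CONTROL_GROUP),
                plates=plates,
            )
        )
    return tuple(specs)


@dataclass
class ProfileResult:
    summaries: pd.DataFrame
    comparisons: dict[str, list[WellTestResult]]
    calls: dict[str, CallSet]
    trend: TrendTable
    config: RunConfig


def run_profile(
    layout: PlateLayout,
    samples: pd.DataFrame,
    config: RunConfig,
    kinetics: pd.DataFrame | None = None,
    endpoints: pd.DataFrame | None = None,
) -> ProfileResult:
    """Run summaries -> group comparisons -> single-case calls -> trends."""
    summaries = summarize_dataset(
        kinetics=kinetics, endpoints=endpoints, source=config.source, floor_eps=config.floor_eps
    )
    specs = config.comparisons or default_comparisons(samples, summaries)
    comparisons = {
        spec.name: run_comparison(summaries, samples, spec, q=config.q, alpha=config.alpha)
        for spec in specs
    }
    control_ids = samples.loc[samples["group"] == CONTROL_GROUP, "sample_id"].tolist()
    calls: dict[str, CallSet] = {}
    if len(control_ids) >= 4:
        for sid in samples.loc[samples["group"] != CONTROL_GROUP, "sample_id"]:
            calls[sid] = call_wells(summaries, sid, control_ids, method=config.method)
    group_of = dict(zip(samples["sample_id"], samples["group"]))
    calls_by_group: dict[str, list] = {}
    for sid, cs in calls.items():
        calls_by_group.setdefault(group_of[sid], []).extend(cs.calls)
    trend = direction_table(calls_by_group, layout)
    return ProfileResult(summaries=summaries, comparisons=comparisons, calls=calls, trend=trend, config=config)


def write_profile_outputs(result: ProfileResult, layout: PlateLayout, out_dir: str | Path) -> dict[str, Path]:
    """Write results TSVs, calls TSV, trend TSV, a text summary and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    all_results: list[WellTestResult] = []
    for name, results in result.comparisons.items():
        all_results.extend(results)
    paths["results"] = out / "well_tests.tsv"
    write_results_tsv(all_results, paths["results"], layout)
    paths["calls"] = out / "single_case_calls.tsv"
    write_calls_tsv(result.calls.values(), paths["calls"], layout)
    paths["trend"] = out / "trend_table.tsv"
    write_trend_tsv(result.trend, paths["trend"])

    lines = []
    for name, results in result.comparisons.items():
        raw = percent_significant(results, "raw")
        fdr = percent_significant(results, "fdr")
        lines.append(
            f"{name}: {raw.count}/{raw.total} wells raw-significant ({raw.percent}%), "
            f"{fdr.count}/{fdr.total} FDR-significant ({fdr.percent}%)"
        )
    for sid, cs in result.calls.items():
        c = cs.counts()
        lines.append(
            f"{sid}: {c['above']} above / {c['below']} below / {c['within']} within"
            + (f"; {len(cs.skipped)} wells skipped" if cs.skipped else "")
        )
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")

    cfg = result.config.to_dict()
    log = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "pmprofile_version": __version__,
        "seed": result.config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(json.dumps(log, indent=2) + "\n")
    return paths
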