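"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The study design being emulated: a normative cohort of 50 control
lymphoblastoid lines (26 female, 24 male) plus one to two patient lines
per condition, each assayed on up to eight 96-well PM-M plates with OD
read every 15 min over 24 h.  Per-well kinetics follow a logistic
colour-development curve

    od(t) = b + A / (1 + exp(-(t - m) / s)) + eps(t),   eps ~ N(0, sigma^2)

with the amplitude A drawn log-normally per well per sample; a patient
effect is a shift ``delta`` on log A (``A * exp(delta)``), so ``delta = 0``
means a null well.  Endpoint reads are derived from the curve value at
24 h plus a small simulated 750 nm background.

Randomness: each sample owns an independent RNG stream derived from the
master seed and a CRC-32 hash of the sample id (``SeedSequence([seed,
crc32(sample_id)])``), so adding samples to a config never perturbs the
data of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import DEFAULT_FLOOR_EPS, KineticCurve, KineticsError
from .plates import PLATE_IDS, PlateLayout, WellAddress
from .stats import benjamini_hochberg, mann_whitney_two_sided
from . import layouts

__all__ = [
    "SimulationError",
    "CurveParams",
    "SimulationConfig",
    "PatientSpec",
    "Cohort",
    "simulate_curve",
    "logistic_od",
    "simulate_cohort",
    "write_cohort",
    "study_patients",
    "study_effect_map",
    "study_sex_effects",
    "recovery_experiment",
    "fdr_experiment",
    "simulate_log_values",
]


class SimulationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class CurveParams:
    """Logistic curve parameters (time unit: minutes; OD units elsewhere).

    Defaults describe a well that develops colour around mid-incubation:
    baseline 0.05 OD, median amplitude 0.5 OD with 0.2 log-normal spread,
    midpoint 720 min, steepness 120 min, and 0.01 OD read noise.
    """

    baseline: float = 0.05
    amplitude_median: float = 0.5
    amplitude_sdlog: float = 0.2
    midpoint_min: float = 720.0
    steepness_min: float = 120.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SimulationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude_sdlog < 0:
            raise SimulationError(f"amplitude_sdlog must be >= 0, got {self.amplitude_sdlog}")
        if self.amplitude_median <= 0 or self.steepness_min <= 0:
            raise SimulationError("amplitude_median and steepness_min must be > 0")


@dataclass(frozen=True)
class PatientSpec:
    sample_id: str
    group: str
    sex: str  # "F" or "M"
    label: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level design: cohort sizes, plates, time grid, curve model, seed."""

    n_controls: int = 50
    n_female: int = 26
    n_male: int = 24
    plates: tuple[str, ...] = PLATE_IDS
    t_start_min: float = 0.0
    t_end_min: float = 1440.0
    t_step_min: float = 15.0
    curve: CurveParams = field(default_factory=CurveParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female + self.n_male != self.n_controls:
            raise SimulationError(
                f"n_female ({self.n_female}) + n_male ({self.n_male}) must equal "
                f"n_controls ({self.n_controls})"
            )
        if self.t_step_min <= 0 or self.t_end_min <= self.t_start_min:
            raise SimulationError("invalid time grid")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.t_start_min, self.t_end_min + self.t_step_min / 2, self.t_step_min)


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """The documented per-sample stream-splitting rule."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode())]))


def logistic_od(times: np.ndarray, amplitude: float, params: CurveParams) -> np.ndarray:
    """Noise-free logistic curve at the given times."""
    z = (np.asarray(times, float) - params.midpoint_min) / params.steepness_min
    return params.baseline + amplitude / (1.0 + np.exp(-z))


def simulate_curve(
    params: CurveParams,
    rng: np.random.Generator | None,
    times: np.ndarray,
    amplitude: float | None = None,
    log_amp_shift: float = 0.0,
) -> KineticCurve:
    """One per-well kinetic curve.

    The amplitude is drawn log-normally (median ``amplitude_median``,
    spread ``amplitude_sdlog``) times ``exp(log_amp_shift)`` unless given
    explicitly.  ``rng`` may be None only when both the amplitude is
    explicit and ``noise_sd`` is zero.
    """
    if amplitude is None:
        if rng is None:
            raise SimulationError("rng required to draw an amplitude")
        amplitude = float(
            rng.lognormal(mean=np.log(params.amplitude_median), sigma=params.amplitude_sdlog)
        ) * float(np.exp(log_amp_shift))
    od = logistic_od(times, amplitude, params)
    if params.noise_sd > 0:
        if rng is None:
            raise SimulationError("rng required for noisy curves")
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    return KineticCurve(times=np.asarray(times, float), od=od)


@dataclass(frozen=True)
class Cohort:
    """In-memory simulated dataset: long kinetics, endpoint reads, sample sheet."""

    kinetics: pd.DataFrame
    endpoints: pd.DataFrame
    samples: pd.DataFrame


def _control_specs(config: SimulationConfig) -> list[PatientSpec]:
    out = []
    for i in range(config.n_controls):
        sex = "F" if i < config.n_female else "M"
        out.append(PatientSpec(f"CTRL{i + 1:02d}", "control", sex, "control"))
    return out


def simulate_cohort(
    config: SimulationConfig,
    layout: PlateLayout,
    patients: Sequence[PatientSpec] = (),
    effects: Mapping[tuple[str, WellAddress], float] | None = None,
    control_sex_effects: Mapping[WellAddress, float] | None = None,
) -> Cohort:
    """Simulate the full cohort (controls first, then patients).

    ``effects`` maps ``(sample_id, address)`` to a log-amplitude shift;
    controls always have shift zero unless ``control_sex_effects`` gives
    the *male controls* a per-well shift (a device for cohort
    heterogeneity: a well with a sex-dimorphic control response can show
    a patient deficit against the female controls that is masked in the
    pooled cohort).  Every effect key must reference a simulated patient
    and an annotated well on an included plate.
    """
    effects = dict(effects or {})
    control_sex_effects = dict(control_sex_effects or {})
    specs = _control_specs(config) + list(patients)
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate sample ids")
    patient_ids = {s.sample_id for s in patients}
    wells: list[WellAddress] = []
    for plate in config.plates:
        plate_wells = layout.wells_for_plate(plate)
        if not plate_wells:
            raise SimulationError(f"plate {plate} has no annotated wells in the layout")
        wells.extend(plate_wells)
    well_index = {w: i for i, w in enumerate(wells)}
    for (sid, addr), delta in effects.items():
        if sid not in patient_ids:
            raise SimulationError(f"effect references unknown patient {sid!r}")
        if addr not in well_index:
            raise SimulationError(f"effect references well {addr} outside the simulated plates")
    for addr in control_sex_effects:
        if addr not in well_index:
            raise SimulationError(f"sex effect references well {addr} outside the simulated plates")

    times = config.grid
    n_w, n_t = len(wells), times.size
    params = config.curve
    log_a0 = np.log(params.amplitude_median)

    kin_frames, end_frames, sample_rows = [], [], []
    plates_col = np.array([w.plate for w in wells])
    wells_col = np.array([w.well for w in wells])
    for spec in specs:
        rng = sample_rng(config.seed, spec.sample_id)
        shift = np.zeros(n_w)
        if spec.sample_id in patient_ids:
            for (sid, addr), delta in effects.items():
                if sid == spec.sample_id:
                    shift[well_index[addr]] = delta
        elif spec.sex == "M":
            for addr, delta in control_sex_effects.items():
                shift[well_index[addr]] = delta
        amp = rng.lognormal(mean=log_a0, sigma=params.amplitude_sdlog, size=n_w) * np.exp(shift)
        od = params.baseline + amp[:, None] / (
            1.0 + np.exp(-(times[None, :] - params.midpoint_min) / params.steepness_min)
        )
        if params.noise_sd > 0:
            od = od + rng.normal(0.0, params.noise_sd, size=(n_w, n_t))
        bg = 0.04 + rng.normal(0.0, 0.002, size=n_w)
        a750 = bg + rng.normal(0.0, 0.002, size=n_w)
        a590 = od[:, -1] + bg
        kin_frames.append(
            pd.DataFrame(
                {
                    "sample_id": spec.sample_id,
                    "plate": np.repeat(plates_col, n_t),
                    "well": np.repeat(wells_col, n_t),
                    "time_min": np.tile(times, n_w),
                    "od": od.ravel(),
                }
            )
        )
        end_frames.append(
            pd.DataFrame(
                {
                    "sample_id": spec.sample_id,
                    "plate": plates_col,
                    "well": wells_col,
                    "a590": a590,
                    "a750": a750,
                }
            )
        )
        sample_rows.append(
            {"sample_id": spec.sample_id, "group": spec.group, "sex": spec.sex, "label": spec.label}
        )
    return Cohort(
        kinetics=pd.concat(kin_frames, ignore_index=True),
        endpoints=pd.concat(end_frames, ignore_index=True),
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "group", "sex", "label"]),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write kinetics.csv, endpoints.csv and samples.csv with stable formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "kinetics": out / "kinetics.csv",
        "endpoints": out / "endpoints.csv",
        "samples": out / "samples.csv",
    }
    cohort.kinetics.to_csv(paths["kinetics"], index=False, float_format="%.6g")
    cohort.endpoints.to_csv(paths["endpoints"], index=False, float_format="%.6g")
    cohort.samples.to_csv(paths["samples"], index=False)
    return paths


# --------------------------------------------------------------------------
# The emulated study conditions: 2 female loss-of-function (RTT-like) lines,
# 1 male duplication (MRXSL-like) line, and the qualitative effect pattern
# the profiling is expected to surface.

OPPOSITE_COMPOUNDS = ("FGF-1(aFGF)", "IL-1beta", "Glu-Trp", "Gln-Gly", "Trp-Tyr")
SHARED_UP_COMPOUNDS = ("Pectin", "Adenosine", "Pyruvic acid", "Ile-Gln", "Ser-Gln")

#: log-amplitude effect size for clearly shifted wells (~6 control SD on the
#: log scale, so a true deficit is essentially never missed)
STUDY_DELTA = 1.2
#: fractions of the glycine / tyrosine clusters that carry a true deficit
GLYCINE_AFFECTED = 12
TYROSINE_AFFECTED = 11


def study_patients() -> list[PatientSpec]:
    return [
        PatientSpec("RTT01", "RTT", "F", "LOF nonsense"),
        PatientSpec("RTT02", "RTT", "F", "LOF missense"),
        PatientSpec("DUP01", "MRXSL", "M", "duplication"),
    ]


def _affected_amino_wells(layout: PlateLayout) -> list[WellAddress]:
    """The 12 glycine- and 11 tyrosine-containing wells (in plate order)
    carrying a true deficit in the loss-of-function lines.

    Wells belonging to both clusters (e.g. Gly-Tyr) are left unaffected
    and Trp-Tyr — which carries a deficit anyway as an opposite-trend
    compound — is counted inside the tyrosine allocation, so each cluster
    ends up with exactly its stated number of shifted wells.
    """
    from .plates import wells_matching

    def name(a: WellAddress) -> str:
        return layout.compound(a).lower()

    gly = [a for a in wells_matching(layout, "Gly") if "tyr" not in name(a)][:GLYCINE_AFFECTED]
    trp_tyr = [a for a in wells_matching(layout, "Trp-Tyr")]
    tyr = trp_tyr + [
        a for a in wells_matching(layout, "Tyr") if "gly" not in name(a) and a not in set(trp_tyr)
    ][: TYROSINE_AFFECTED - len(trp_tyr)]
    return gly + tyr


def study_effect_map(
    layout: PlateLayout, delta: float = STUDY_DELTA
) -> dict[tuple[str, WellAddress], float]:
    """Effect map emulating the reported qualitative pattern.

    * LOF (RTT-like) lines: amplitude deficit on every PM-M8 well except
      G10 (TNF-alpha); deficit on 12 glycine-containing and 11
      tyrosine-containing wells (see :func:`study_sex_effects`); deficit
      on the five opposite-trend compounds; surplus on the five
      shared-increase compounds.
    * Duplication (MRXSL-like) line: surplus on main energy sources
      (carbon-source and dipeptide blocks) plus the shared/opposite
      compounds; deficit on the most-concentrated replicate of the first
      twelve PM-M5 ion series and on a set of hormone/effector wells.
    """
    from .plates import concentration_series, wells_matching

    eff: dict[tuple[str, WellAddress], float] = {}
    rtt_ids = ["RTT01", "RTT02"]
    dup_id = "DUP01"

    def set_for(ids: Iterable[str], addrs: Iterable[WellAddress], value: float) -> None:
        for sid in ids:
            for addr in addrs:
                eff[(sid, addr)] = value

    m8 = [a for a in layout.wells_for_plate("PM-M8") if a.well != "G10"]
    set_for(rtt_ids, m8, -delta)
    set_for(rtt_ids, _affected_amino_wells(layout), -delta)
    opposite = [a for name in OPPOSITE_COMPOUNDS for a in wells_matching(layout, name)]
    shared = [a for name in SHARED_UP_COMPOUNDS for a in wells_matching(layout, name)]
    set_for(rtt_ids, opposite, -delta)
    set_for(rtt_ids, shared, +delta)

    # duplication line: increased utilisation of main energy sources ...
    dup_up = [
        a for a in layout.wells_for_plate("PM-M1") if a.row in "ABC" and a.well != "A01"
    ]
    dup_up += [a for p in ("PM-M2", "PM-M3") for a in layout.wells_for_plate(p) if a.row == "E"]
    set_for([dup_id], dup_up + shared + opposite, +delta)
    # ... and decreased response to concentrated ions and several hormones/effectors
    dup_down = [concentration_series(layout, f"M5-S{i:02d}")[-1] for i in range(1, 13)]
    dup_down += [WellAddress("PM-M6", w) for w in ("B01", "B02", "B03", "B04", "B05", "B06")]
    dup_down += [WellAddress("PM-M7", "A02")]
    dup_down += [WellAddress("PM-M8", w) for w in ("C08", "D06", "D11", "E06", "E09", "F12")]
    set_for([dup_id], dup_down, -delta)
    return eff


def study_sex_effects(layout: PlateLayout, delta: float = STUDY_DELTA) -> dict[WellAddress, float]:
    """Male-control heterogeneity on the affected amino-acid wells.

    The male half of the control cohort shares the patients' deficit on
    the 12 glycine and 11 tyrosine wells, so the (female) LOF patients
    separate from the controls on those wells only when compared against
    female controls — the pooled comparison sees only the PM-M8 block.
    """
    return {addr: -delta for addr in _affected_amino_wells(layout)}


# --------------------------------------------------------------------------
# Validation harness: operating characteristics of the per-well test.


def simulate_log_values(
    rng: np.random.Generator,
    n_wells: int,
    n_samples: int,
    params: CurveParams,
    floor_eps: float = DEFAULT_FLOOR_EPS,
    shift: np.ndarray | float = 0.0,
    base: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Vectorized log10-AUC well values (wells x samples), single RNG stream.

    Equivalent in distribution to simulating full logistic curves and
    integrating: the trapezoidal AUC of the noise-free curve is computed
    analytically and the read noise enters through its exact trapezoidal
    weights.  ``base`` optionally supplies pre-drawn (log-amplitude,
    noise) matrices so experiments can reuse common random numbers across
    effect sizes.
    """
    grid = SimulationConfig().grid
    dt = float(grid[1] - grid[0])
    z = (grid - params.midpoint_min) / params.steepness_min
    logistic_vals = 1.0 / (1.0 + np.exp(-z))
    weights = np.full(grid.size, dt)
    weights[0] = weights[-1] = dt / 2
    curve_integral = float(weights @ logistic_vals)
    total_time = float(grid[-1] - grid[0])
    noise_scale = params.noise_sd * float(np.sqrt((weights**2).sum()))

    if base is None:
        log_amp = rng.normal(np.log(params.amplitude_median), params.amplitude_sdlog, (n_wells, n_samples))
        noise = rng.normal(0.0, 1.0, (n_wells, n_samples))
    else:
        log_amp, noise = base
    amp = np.exp(log_amp + shift)
    auc = params.baseline * total_time + amp * curve_integral + noise * noise_scale
    return np.log10(np.maximum(auc, floor_eps))


def _per_well_pvalues(values: np.ndarray, n_a: int) -> np.ndarray:
    return np.array(
        [mann_whitney_two_sided(row[:n_a], row[n_a:]).p for row in values]
    )


def recovery_experiment(
    effect_sizes: Sequence[float],
    n_wells: int = 1000,
    n_a: int = 2,
    n_b: int = 50,
    params: CurveParams | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rates of the per-well test across a grid of effect sizes.

    Every simulated well carries the same log-amplitude shift ``delta`` in
    the n_a patient columns (delta = 0 gives the type-I error rate; the BH
    family is the full set of ``n_wells`` wells).  Common random numbers
    are used across the grid, so power comparisons between effect sizes
    are paired.  Returns one row per delta with raw/FDR rejection
    fractions and their binomial standard errors.
    """
    if n_wells < 1:
        raise SimulationError("n_wells must be >= 1")
    params = params or CurveParams()
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    base = (
        rng.normal(np.log(params.amplitude_median), params.amplitude_sdlog, (n_wells, n)),
        rng.normal(0.0, 1.0, (n_wells, n)),
    )
    rows = []
    for delta in effect_sizes:
        shift = np.zeros(n)
        shift[:n_a] = delta
        values = simulate_log_values(rng, n_wells, n, params, shift=shift, base=base)
        p = _per_well_pvalues(values, n_a)
        _, flags = benjamini_hochberg(p, q=q)
        raw = float(np.mean(p < alpha))
        fdr = float(np.mean(flags))
        rows.append(
            {
                "delta": float(delta),
                "n_wells": n_wells,
                "raw_rate": raw,
                "raw_se": float(np.sqrt(raw * (1 - raw) / n_wells)),
                "fdr_rate": fdr,
                "fdr_se": float(np.sqrt(fdr * (1 - fdr) / n_wells)),
            }
        )
    return pd.DataFrame(rows)


def fdr_experiment(
    n_wells: int = 1000,
    frac_nonnull: float = 0.1,
    delta: float = 2.0,
    n_a: int = 2,
    n_b: int = 50,
    params: CurveParams | None = None,
    q: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical FDR of the BH procedure with a known non-null fraction.

    The first ``round(frac_nonnull * n_wells)`` wells carry a true
    log-amplitude shift of ``delta``; the rest are null.  Returns the
    number of flagged wells, how many of them were truly null, and the
    realized false-discovery proportion.
    """
    params = params or CurveParams()
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    n_nonnull = int(round(frac_nonnull * n_wells))
    shift = np.zeros((n_wells, n))
    shift[:n_nonnull, :n_a] = delta
    values = simulate_log_values(rng, n_wells, n, params, shift=shift)
    p = _per_well_pvalues(values, n_a)
    _, flags = benjamini_hochberg(p, q=q)
    flagged = int(flags.sum())
    false = int(flags[n_nonnull:].sum())
    return {
        "n_wells": n_wells,
        "n_nonnull": n_nonnull,
        "n_flagged": flagged,
        "n_false_flagged": false,
        "empirical_fdr": false / flagged if flagged else 0.0,
        "power": float(flags[:n_nonnull].mean()) if n_nonnull else 0.0,
    }
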