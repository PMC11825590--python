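import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from conftest import make_summaries
from pmprofile.plates import WellAddress
from pmprofile.stats import (
    ComparisonSpec,
    SampleSelector,
    StatsError,
    WellTestResult,
    benjamini_hochberg,
    mann_whitney_two_sided,
    percent_significant,
    results_to_frame,
    round_half_up,
    run_comparison,
)


def brute_force_mw_p(a, b):
    """Independent oracle: enumerate every split of the pooled values and
    count pairwise comparisons directly (no ranks)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    mu = n_a * (len(pooled) - n_a) / 2.0
    u_obs = u_of(a, b)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def test_mw_identical_samples_p_one():
    assert mann_whitney_two_sided([1, 2, 3], [1, 2, 3]).p == 1.0
    assert mann_whitney_two_sided([1, 1], [1, 1]).p == 1.0


def test_mw_hand_example():
    res = mann_whitney_two_sided([1, 2], [3, 4, 5])
    assert res.u_stat == 0 and res.p == pytest.approx(0.2) and res.method == "exact"


def test_mw_empty_group_rejected():
    with pytest.raises(StatsError):
        mann_whitney_two_sided([], [1.0])


def test_mw_exact_matches_brute_force_including_ties():
    rng = np.random.default_rng(12345)
    for n_a in range(1, 8):
        for n_b in range(1, 9 - n_a):
            for _ in range(3):
                a = rng.integers(0, 3, size=n_a).astype(float)  # heavy ties
                b = rng.integers(0, 3, size=n_b).astype(float)
                got = mann_whitney_two_sided(a, b)
                u_exp, p_exp = brute_force_mw_p(a, b)
                assert got.u_stat == pytest.approx(u_exp)
                assert got.p == pytest.approx(p_exp)
                a = rng.normal(size=n_a)  # and continuous, tie-free
                b = rng.normal(size=n_b)
                got = mann_whitney_two_sided(a, b)
                u_exp, p_exp = brute_force_mw_p(a, b)
                assert got.p == pytest.approx(p_exp)


def test_mw_exact_agrees_with_scipy_when_tie_free():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.normal(size=rng.integers(2, 6))
        b = rng.normal(size=rng.integers(2, 6))
        ours = mann_whitney_two_sided(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.u_stat == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)


def test_mw_exact_vs_asymptotic_within_005():
    # Exhaustive over tie-free rank configurations.  The 0.05 band holds
    # whenever both groups have >= 2 members and n >= 6; singleton groups
    # can disagree by up to ~0.13 and are excluded by design (documented).
    for n in range(6, 11):
        for n_a in range(2, n - 1):
            for idx in itertools.combinations(range(n), n_a):
                vals = np.arange(n, dtype=float)
                a = vals[list(idx)]
                b = np.delete(vals, list(idx))
                exact = mann_whitney_two_sided(a, b).p
                approx = mann_whitney_two_sided(a, b, exact_limit=0).p
                assert abs(exact - approx) <= 0.05


def test_mw_switches_to_asymptotic_above_limit():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=10), rng.normal(size=10)  # C(20,10) = 184756
    assert mann_whitney_two_sided(a, b).method == "asymptotic"


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 5), st.floats(-10, 10))
def test_mw_rank_invariance_and_symmetry(seed, scale, shift):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=3)
    b = rng.normal(size=4)
    base = mann_whitney_two_sided(a, b)
    # strictly increasing transforms leave the p-value untouched
    for f in (lambda x: scale * x + shift, np.exp, lambda x: x**3):
        assert mann_whitney_two_sided(f(a), f(b)).p == pytest.approx(base.p)
    # swapping the groups mirrors U and preserves p
    sw = mann_whitney_two_sided(b, a)
    assert sw.p == pytest.approx(base.p)
    assert sw.u_stat == pytest.approx(len(a) * len(b) - base.u_stat)


# -- Benjamini-Hochberg


def test_bh_hand_vectors():
    adj, flags = benjamini_hochberg([0.03], q=0.05)
    assert adj.tolist() == pytest.approx([0.03]) and flags.tolist() == [True]
    adj, flags = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert adj.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert flags.tolist() == [True] * 4
    adj, flags = benjamini_hochberg([0.005, 0.5], q=0.05)
    assert adj.tolist() == pytest.approx([0.01, 0.5])
    assert flags.tolist() == [True, False]


def test_bh_validation():
    with pytest.raises(StatsError):
        benjamini_hochberg([0.0, 0.5])
    with pytest.raises(StatsError):
        benjamini_hochberg([1.5])
    with pytest.raises(StatsError):
        benjamini_hochberg([0.5], q=1.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=40))
def test_bh_properties(p_values):
    adj, flags05 = benjamini_hochberg(p_values, q=0.05)
    _, flags01 = benjamini_hochberg(p_values, q=0.01)
    assert np.all(adj >= np.asarray(p_values) - 1e-12)  # adjustment never shrinks p
    assert np.all(adj <= 1.0)
    assert set(np.where(flags01)[0]) <= set(np.where(flags05)[0])  # FDR monotone in q


# -- comparison runner


def _dataset(layout, groups, seed=0, plates=None, shift_wells=(), shift=0.0):
    """groups: mapping sample_id -> group; same log-normal null everywhere
    except `shift_wells` for non-control samples."""
    rng = np.random.default_rng(seed)
    plates = plates or [p for p in layout.plates_present]
    wells = [a for p in sorted(plates) for a in layout.wells_for_plate(p)]
    shift_set = set(shift_wells)
    values = {}
    for sid, grp in groups.items():
        v = rng.normal(2.5, 0.1, size=len(wells))
        if grp != "control" and shift_set:
            v += np.array([shift if a in shift_set else 0.0 for a in wells])
        values[sid] = v
    samples = pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values()), "sex": "F"}
    )
    return make_summaries(values, wells), samples, wells


def test_run_comparison_well_count_672(layout):
    groups = {"P1": "RTT", "P2": "RTT", "C1": "control", "C2": "control", "C3": "control"}
    plates = [p for p in layout.plates_present if p != "PM-M5"]
    summaries, samples, _ = _dataset(layout, groups, plates=plates)
    spec = ComparisonSpec(
        "rtt_vs_control",
        SampleSelector.make(groups="RTT"),
        SampleSelector.make(groups="control"),
        frozenset(plates),
    )
    results = run_comparison(summaries, samples, spec)
    assert len(results) == 672  # 7 plates x 96 wells
    for r in results:
        assert r.p_adj >= r.p - 1e-12
        assert not (r.fdr_sig and not r.raw_sig)  # fdr set nested in raw set
    frame = results_to_frame(results, layout)
    assert frame.loc[(frame.plate == "PM-M8") & (frame.well == "G10"), "compound"].item() == "TNF-alpha"


def test_run_comparison_identical_groups_all_p_one(layout):
    wells = layout.wells_for_plate("PM-M8")
    vals = np.linspace(2, 3, len(wells))
    summaries = make_summaries({"A1": vals, "A2": vals, "B1": vals, "B2": vals}, wells)
    samples = pd.DataFrame(
        {"sample_id": ["A1", "A2", "B1", "B2"], "group": ["ga", "ga", "gb", "gb"], "sex": "F"}
    )
    spec = ComparisonSpec(
        "null", SampleSelector.make(groups="ga"), SampleSelector.make(groups="gb"), frozenset({"PM-M8"})
    )
    results = run_comparison(summaries, samples, spec)
    assert all(r.p == 1.0 and not r.fdr_sig and r.direction == "none" for r in results)


def test_run_comparison_extreme_well_attains_min_exact_p(layout):
    groups = {f"C{i:02d}": "control" for i in range(50)}
    groups.update({"P1": "case", "P2": "case"})
    target = WellAddress("PM-M8", "D06")
    summaries, samples, _ = _dataset(
        layout, groups, plates=["PM-M8"], shift_wells=[target], shift=-5.0
    )
    spec = ComparisonSpec(
        "case", SampleSelector.make(groups="case"), SampleSelector.make(groups="control"), frozenset({"PM-M8"})
    )
    results = {r.address: r for r in run_comparison(summaries, samples, spec)}
    # minimum achievable two-sided exact p for 2 vs 50 is 2 / C(52, 2)
    assert results[target].p == pytest.approx(2 / math.comb(52, 2))
    assert results[target].direction == "decreased"


def test_run_comparison_selector_errors(layout):
    groups = {"P1": "case", "C1": "control"}
    summaries, samples, _ = _dataset(layout, groups, plates=["PM-M8"])
    bad = ComparisonSpec(
        "none", SampleSelector.make(groups="missing"), SampleSelector.make(groups="control"),
        frozenset({"PM-M8"}),
    )
    with pytest.raises(StatsError, match="no samples"):
        run_comparison(summaries, samples, bad)
    overlapping = ComparisonSpec(
        "overlap", SampleSelector.make(), SampleSelector.make(groups="control"), frozenset({"PM-M8"})
    )
    with pytest.raises(StatsError, match="overlap"):
        run_comparison(summaries, samples, overlapping)


def test_run_comparison_incomplete_data_rejected(layout):
    groups = {"P1": "case", "C1": "control", "C2": "control"}
    summaries, samples, wells = _dataset(layout, groups, plates=["PM-M8"])
    holed = summaries[~((summaries.sample_id == "P1") & (summaries.well == "B03"))]
    spec = ComparisonSpec(
        "case", SampleSelector.make(groups="case"), SampleSelector.make(groups="control"),
        frozenset({"PM-M8"}),
    )
    with pytest.raises(StatsError, match="incomplete"):
        run_comparison(holed, samples, spec)


# -- reporting helpers


def _dummy_results(n_total, n_raw, n_fdr):
    out = []
    for i in range(n_total):
        out.append(
            WellTestResult(
                address=WellAddress("PM-M1", f"A{i % 12 + 1:02d}"),
                n_a=2, n_b=50, u_stat=0.0,
                p=0.01 if i < n_raw else 0.5,
                p_adj=0.01 if i < n_fdr else 0.5,
                direction="decreased",
                raw_sig=i < n_raw,
                fdr_sig=i < n_fdr,
            )
        )
    return out


def test_percent_significant_matches_reported_arithmetic():
    res = _dummy_results(672, 264, 95)
    assert percent_significant(res, "raw") == (264, 672, 39.3)
    assert percent_significant(res, "fdr") == (95, 672, 14.1)
    assert percent_significant(_dummy_results(672, 0, 0), "fdr").percent == 0.0
    with pytest.raises(StatsError):
        percent_significant([])


def test_round_half_up_is_decimal_not_bankers():
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(0.35, 1) == 0.4
    assert round_half_up(39.2857, 1) == 39.3
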