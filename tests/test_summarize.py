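import numpy as np
import pytest

from pmprofile.plates import CompoundAnnotation, PlateLayout, WellAddress
from pmprofile.single_case import ControlLimits, SingleCaseCall
from pmprofile.stats import WellTestResult
from pmprofile.summarize import (
    ClusterSummary,
    SummarizeError,
    TrendTable,
    cluster_fraction,
    direction_table,
    opposite_trends,
    shared_trend,
    trend_table_to_frame,
)

LIMITS = ControlLimits(q1=1.0, q3=2.0, lower=0.0, upper=3.0, method="whisker")
VALUE_FOR = {"above": 4.0, "below": -1.0, "within": 1.5}


def call(addr, kind, patient="P"):
    return SingleCaseCall(addr, patient, VALUE_FOR[kind], LIMITS, kind)


def grid_layout(n, plate="PM-M1", prefix="cmp"):
    """n wells, each with a distinct compound name."""
    wells = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)][:n]
    entries = {
        WellAddress(plate, w): CompoundAnnotation(f"{prefix}-{i:03d}", "other")
        for i, w in enumerate(wells)
    }
    return PlateLayout(entries), sorted(entries)


def test_direction_table_counts_66_25():
    layout, wells = grid_layout(96)
    calls = [call(a, "above") for a in wells[:66]] + [call(a, "below") for a in wells[66:91]]
    table = direction_table({"dup": calls}, layout)
    assert table.group_counts("dup") == (66, 25)


def test_direction_table_counts_5_64():
    layout, wells = grid_layout(69)
    calls = [call(a, "above") for a in wells[:5]] + [call(a, "below") for a in wells[5:69]]
    table = direction_table({"lof": calls}, layout)
    assert table.group_counts("lof") == (5, 64)


def test_direction_table_all_within_is_empty():
    layout, wells = grid_layout(10)
    table = direction_table({"g": [call(a, "within") for a in wells]}, layout)
    assert table.rows == ()


def test_multi_well_compound_conflict_is_mixed():
    layout, wells = grid_layout(4)
    # two wells share one compound: agreement keeps the direction, conflict -> mixed
    shared = PlateLayout(
        {
            wells[0]: CompoundAnnotation("pectin", "other"),
            wells[1]: CompoundAnnotation("pectin", "other"),
            wells[2]: CompoundAnnotation("inosine", "other"),
            wells[3]: CompoundAnnotation("inosine", "other"),
        }
    )
    calls = [call(wells[0], "above"), call(wells[1], "below"),
             call(wells[2], "above"), call(wells[3], "above")]
    table = direction_table({"g": calls}, shared)
    by = {r.compound: r for r in table.rows}
    assert by["pectin"].direction == "mixed" and by["pectin"].n_wells_called == 2
    assert by["inosine"].direction == "increased"
    assert table.group_counts("g") == (1, 0)  # mixed excluded from counts


OPPOSITE = ["FGF-1(aFGF)", "IL-1beta", "Glu-Trp", "Gln-Gly", "Trp-Tyr"]


def _named_tables():
    layout, wells = grid_layout(12)
    names = OPPOSITE + ["Pectin", "Adenosine", "Pyruvic acid", "Ile-Gln", "Ser-Gln", "x1", "x2"]
    named = PlateLayout(
        {w: CompoundAnnotation(n, "other") for w, n in zip(wells, names)}
    )
    dup_calls = [call(w, "above", "DUP") for w in wells[:10]]  # opposite 5 + shared 5 up
    lof_calls = [call(w, "below", "L1") for w in wells[:5]] + [
        call(w, "above", "L1") for w in wells[5:10]
    ]
    table = direction_table({"dup": dup_calls, "lof": lof_calls}, named)
    dup = TrendTable(tuple(r for r in table.rows if r.group == "dup"))
    lof = TrendTable(tuple(r for r in table.rows if r.group == "lof"))
    return dup, lof


def test_opposite_trends_finds_exactly_the_five():
    dup, lof = _named_tables()
    assert opposite_trends(dup, lof) == sorted(OPPOSITE)
    assert opposite_trends(dup, lof) == opposite_trends(lof, dup)  # symmetric


def test_opposite_trends_identical_or_empty_tables():
    dup, _ = _named_tables()
    assert opposite_trends(dup, dup) == []
    assert opposite_trends(dup, TrendTable(())) == []


def test_shared_trend_intersection():
    dup, lof = _named_tables()
    shared = shared_trend({"dup": dup, "lof": lof}, "increased")
    assert shared == sorted(["Pectin", "Adenosine", "Pyruvic acid", "Ile-Gln", "Ser-Gln"])
    assert shared_trend({"dup": dup, "lof": lof}, "decreased") == []
    with pytest.raises(SummarizeError):
        shared_trend({"dup": dup}, "increased")


def test_shared_trend_singleton():
    layout, wells = grid_layout(1)
    a = direction_table({"a": [call(wells[0], "above")]}, layout)
    b = direction_table({"b": [call(wells[0], "above")]}, layout)
    a = TrendTable(tuple(r for r in a.rows))
    b = TrendTable(tuple(r for r in b.rows))
    assert shared_trend({"a": a, "b": b}, "increased") == ["cmp-000"]


def test_conservation_of_calls():
    layout, wells = grid_layout(30)
    rng = np.random.default_rng(0)
    kinds = rng.choice(["above", "below", "within"], size=30)
    calls = [call(w, k) for w, k in zip(wells, kinds)]
    table = direction_table({"g": calls}, layout)
    inc, dec = table.group_counts("g")
    within = sum(k == "within" for k in kinds)
    assert inc + dec + within == 30  # distinct compounds: no mixed rows possible


def test_cluster_fraction_from_calls():
    layout, wells = grid_layout(30)
    calls = [call(w, "below") for w in wells[:12]] + [call(w, "within") for w in wells[12:]]
    cs = cluster_fraction(calls, wells, "decreased", "glycine")
    assert (cs.k, cs.n, cs.percent) == (12, 30, 40.0)


def test_cluster_fraction_from_test_results():
    layout, wells = grid_layout(27)
    results = [
        WellTestResult(
            address=w, n_a=2, n_b=26, u_stat=0.0, p=0.005, p_adj=0.01 if i < 11 else 0.5,
            direction="decreased", raw_sig=True, fdr_sig=i < 11,
        )
        for i, w in enumerate(wells)
    ]
    cs = cluster_fraction(results, wells, "decreased", "tyrosine", criterion="fdr")
    assert (cs.k, cs.n, cs.percent) == (11, 27, 40.7)
    # raw criterion counts all of them
    assert cluster_fraction(results, wells, "decreased", criterion="raw").k == 27


def test_cluster_fraction_zero_and_validation():
    layout, wells = grid_layout(5)
    cs = cluster_fraction([call(w, "within") for w in wells], wells, "increased")
    assert (cs.k, cs.percent) == (0, 0.0)
    with pytest.raises(SummarizeError):
        cluster_fraction([], [], "increased")
    with pytest.raises(SummarizeError):
        ClusterSummary("bad", 6, 5, "increased")


def test_trend_frame_round_trip_columns():
    dup, _ = _named_tables()
    df = trend_table_to_frame(dup)
    assert list(df.columns) == ["group", "plate", "compound", "direction", "n_wells_called"]
    assert len(df) == len(dup.rows)
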