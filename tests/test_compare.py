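"""Directional overlap classification against brute force and hand values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypro.compare import (
    RegulationSet,
    export_summaries,
    intersect_and_classify,
    pairwise_overlap_grid,
    regression_of_shared,
    round_half_up,
)


def make_pair(n_shared, n_co, n_a, n_b, mag=2.0):
    """Sets with exactly n_shared common genes, n_co sign-concordant."""
    a, b = {}, {}
    for i in range(n_shared):
        s = 1.0 if i % 2 else -1.0
        a[f"s{i}"] = s * mag
        b[f"s{i}"] = s * mag if i < n_co else -s * mag
    for i in range(n_a - n_shared):
        a[f"a{i}"] = mag
    for i in range(n_b - n_shared):
        b[f"b{i}"] = -mag
    return RegulationSet("A", a), RegulationSet("B", b)


@pytest.mark.parametrize(
    "n_shared,n_co,attr,expected",
    [
        (264, 236, "co_pct", 89),  # 236/264 co-regulated
        (216, 59, "anti_pct", 73),  # 157/216 anti-regulated
    ],
)
def test_reported_percentages_on_worked_counts(n_shared, n_co, attr, expected):
    a, b = make_pair(n_shared, n_co, 909, 1945)
    summary, _ = intersect_and_classify(a, b)
    assert summary.shared == n_shared
    assert getattr(summary, attr) == expected


def test_shared_fraction_of_set_a():
    a, b = make_pair(649, 400, 1090, 3811)
    summary, _ = intersect_and_classify(a, b)
    assert summary.shared_pct_of_a == 60  # 649 of 1090


def test_half_up_rounding():
    assert round_half_up(89.5) == 90
    assert round_half_up(89.49) == 89
    assert round_half_up(0.5) == 1  # not banker's rounding


def test_identity_overlap_is_all_co():
    a, _ = make_pair(10, 5, 20, 20)
    summary, _ = intersect_and_classify(a, a)
    assert summary.shared == len(a)
    assert summary.co == summary.shared
    assert summary.co_pct == 100


def test_disjoint_sets_have_undefined_percentage():
    a = RegulationSet("A", {"x": 1.0})
    b = RegulationSet("B", {"y": -1.0})
    summary, table = intersect_and_classify(a, b)
    assert summary.shared == 0
    assert summary.co_pct is None
    assert table.empty


def test_empty_set_allowed():
    a = RegulationSet("A", {})
    summary, _ = intersect_and_classify(a, a)
    assert summary.shared == 0


def test_zero_direction_rejected():
    with pytest.raises(ValueError, match="direction"):
        RegulationSet("A", {"g": 0.0})


@settings(max_examples=40, deadline=None)
@given(
    st.dictionaries(
        st.integers(0, 300),
        st.sampled_from([-2.0, -1.5, 1.5, 2.0]),
        max_size=80,
    ),
    st.dictionaries(
        st.integers(0, 300),
        st.sampled_from([-2.0, -1.5, 1.5, 2.0]),
        max_size=80,
    ),
)
def test_conservation_symmetry_and_brute_force(da, db):
    a = RegulationSet("A", {f"g{k}": v for k, v in da.items()})
    b = RegulationSet("B", {f"g{k}": v for k, v in db.items()})
    s_ab, _ = intersect_and_classify(a, b)
    s_ba, _ = intersect_and_classify(b, a)
    # conservation: the four direction cells partition the overlap
    assert sum(s_ab.breakdown.values()) == s_ab.shared
    assert s_ab.co + s_ab.anti == s_ab.shared
    # symmetry: shared/co/anti invariant, breakdown transposes
    assert (s_ab.shared, s_ab.co, s_ab.anti) == (s_ba.shared, s_ba.co, s_ba.anti)
    assert s_ab.breakdown["up-down"] == s_ba.breakdown["down-up"]
    # naive per-gene loop oracle
    shared = set(a.log2fc) & set(b.log2fc)
    co = sum(
        1 for g in shared if np.sign(a.log2fc[g]) == np.sign(b.log2fc[g])
    )
    assert s_ab.co == co and s_ab.shared == len(shared)


def test_pairwise_grid_diagonal_and_symmetry():
    c, _ = make_pair(5, 3, 10, 10)
    c.label = "C"
    a, b = make_pair(8, 2, 15, 12)
    grid = pairwise_overlap_grid([c, a, b])
    for label in grid.index:
        assert grid.loc[label, label].co_pct == 100
    assert grid.loc["A", "B"].shared == grid.loc["B", "A"].shared


def test_planted_co_fraction_round_trips_through_classification(small_dataset):
    _, truth = small_dataset
    stage, trans = "primary", "primary_to_immortalized"
    a = RegulationSet(stage, truth.hdeg_sets[stage])
    b = RegulationSet(trans, truth.deg_sets[trans])
    summary, _ = intersect_and_classify(a, b)
    assert summary.co_fraction == pytest.approx(truth.co_fraction[(stage, trans)])


def test_regression_slopes_on_mirrored_and_hand_pairs():
    genes = {f"g{i}": v for i, v in enumerate([1.0, 2.0, -1.5, 3.0, -2.0])}
    a = RegulationSet("A", genes)
    b_same = RegulationSet("B", dict(genes))
    _, table = intersect_and_classify(a, b_same)
    reg = regression_of_shared(table)
    assert reg["slope"] == pytest.approx(1.0) and reg["intercept"] == pytest.approx(0.0)
    b_mirror = RegulationSet("B", {g: -v for g, v in genes.items()})
    _, table = intersect_and_classify(a, b_mirror)
    assert regression_of_shared(table)["slope"] == pytest.approx(-1.0)
    # hand-made 5 pairs vs closed-form least squares
    x = np.array([1.0, 2.0, -1.5, 3.0, -2.0])
    y = np.array([1.2, 1.8, -2.0, 2.5, -1.0])
    b_hand = RegulationSet("B", dict(zip(genes, y)))
    _, table = intersect_and_classify(a, b_hand)
    reg = regression_of_shared(table)
    # table is sorted by gene name; align accordingly
    order = np.argsort(list(genes))
    xs, ys = x[order], y[order]
    slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
    assert reg["slope"] == pytest.approx(slope)
    assert reg["intercept"] == pytest.approx(ys.mean() - slope * xs.mean())


def test_regression_omitted_below_two_shared():
    table = pd.DataFrame({"gene": ["g"], "l2fc_a": [1.0], "l2fc_b": [2.0], "class": ["co"]})
    assert regression_of_shared(table) is None


def test_export_summaries_table_layout(tmp_path):
    a, b = make_pair(6, 4, 12, 9)
    out = export_summaries([a, b], outdir=tmp_path)
    arc = {row["set"]: row for row in out["arc"]}
    assert arc["A"]["up"] + arc["A"]["down"] == 12
    assert out["venn"][0]["a_only"] == 12 - 6
    assert (tmp_path / "arc_counts.tsv").exists()
    assert (tmp_path / "venn_counts.tsv").exists()
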