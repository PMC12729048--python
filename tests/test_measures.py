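"""The 12 appointment-system measures, window averaging and scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gpclusters.annotate import annotate_counts
from gpclusters.measures import (
    MEASURE_COLUMNS,
    average_window,
    compute_measures_table,
    compute_monthly_measures,
    scale_matrix,
)
from tests.conftest import make_rows


def annotated(rows, dictionary):
    return annotate_counts(make_rows(rows), dictionary)


TOY_ROWS = [
    ("P1", "2023-08", "gp", "face_to_face", "d8_14", "Routine appointment", 60),
    ("P1", "2023-08", "other", "telephone", "same_day", "Same day appointment", 40),
]

TOY_EXPECTED = {
    "p_gp": 0.6,
    "p_booked_gt1wk": 0.6,
    "p_tel": 0.4,
    "p_tel_gp": 0.0,
    "p_sameday_gp": 0.0,
    "p_annot_sameday": 0.4,
    "p_tel_annot_sameday": 0.4,
    "p_gp_annot_sameday": 0.0,
    "p_annot_routine": 0.6,
    "p_routine_within1": 0.0,
    "triage_use": 0.0,
    "appt_rate": 10.0,
}


def test_toy_practice_all_twelve_measures(dictionary):
    """Hand-computed 100-appointment practice reproduces every measure."""
    vec = compute_monthly_measures(annotated(TOY_ROWS, dictionary), list_size=10_000)
    for measure, expected in TOY_EXPECTED.items():
        assert getattr(vec, measure) == pytest.approx(expected), measure
    assert vec.denominator_flags == set()


def test_single_cell_practice(dictionary):
    rows = [("P1", "2023-08", "gp", "telephone", "same_day", "Same day appointment", 100)]
    vec = compute_monthly_measures(annotated(rows, dictionary), list_size=1000)
    assert vec.p_gp == vec.p_tel == vec.p_tel_gp == vec.p_sameday_gp == 1.0
    assert vec.p_annot_sameday == vec.p_tel_annot_sameday == 1.0
    assert vec.p_gp_annot_sameday == 1.0
    assert vec.p_annot_routine == 0.0
    assert vec.p_routine_within1 == 0.0 and "p_routine_within1" in vec.denominator_flags
    assert vec.triage_use == 0.0
    assert vec.appt_rate == pytest.approx(100.0)


def test_vectorised_table_matches_per_month_reference(annotated_small, registry_small):
    """The grouped implementation agrees with the single-practice path."""
    months = ["2023-08", "2023-09"]
    table = compute_measures_table(annotated_small, registry_small, months)
    sample = table.sample(n=10, random_state=0)
    for _, row in sample.iterrows():
        sub = annotated_small[
            (annotated_small["practice_id"] == row["practice_id"])
            & (annotated_small["month"] == row["month"])
        ]
        ref = compute_monthly_measures(
            sub, int(registry_small.loc[row["practice_id"], "list_size"])
        )
        for m in MEASURE_COLUMNS:
            assert row[m] == pytest.approx(getattr(ref, m)), (m, row["practice_id"])


def test_row_order_invariance(dictionary):
    base = annotated(TOY_ROWS, dictionary)
    flipped = base.iloc[::-1].reset_index(drop=True)
    a = compute_monthly_measures(base, 10_000)
    b = compute_monthly_measures(flipped, 10_000)
    assert a.as_dict() == b.as_dict()


def test_list_size_must_be_positive(dictionary):
    with pytest.raises(ValueError):
        compute_monthly_measures(annotated(TOY_ROWS, dictionary), list_size=0)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.data())
def test_subset_invariants_hold_for_arbitrary_tables(data):
    """p_tel_gp <= min(p_tel, p_gp) and friends, over random count tables."""
    from gpclusters.synthdata import ANNOTATION_ENTRIES
    from gpclusters.annotate import AnnotationDictionary

    d = AnnotationDictionary(dict(ANNOTATION_ENTRIES))
    hcps = ["gp", "other"]
    modes = ["face_to_face", "telephone", "video"]
    bands = ["same_day", "d1", "d2_7", "d8_14", "gt28"]
    cats = list(ANNOTATION_ENTRIES) + ["Off list"]
    n = data.draw(st.integers(min_value=1, max_value=12))
    rows, seen = [], set()
    for _ in range(n):
        key = (
            data.draw(st.sampled_from(hcps)),
            data.draw(st.sampled_from(modes)),
            data.draw(st.sampled_from(bands)),
            data.draw(st.sampled_from(cats)),
        )
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            ("P1", "2023-08", *key, data.draw(st.integers(min_value=0, max_value=99)))
        )
    vec = compute_monthly_measures(annotate_counts(make_rows(rows), d), 5000)
    for m in MEASURE_COLUMNS[:-1]:
        assert 0.0 <= getattr(vec, m) <= 1.0, m
    assert vec.p_tel_gp <= min(vec.p_tel, vec.p_gp) + 1e-12
    assert vec.p_sameday_gp <= vec.p_gp + 1e-12
    assert vec.p_tel_annot_sameday <= vec.p_annot_sameday + 1e-12
    assert vec.p_gp_annot_sameday <= vec.p_annot_sameday + 1e-12
    assert vec.p_annot_sameday + vec.p_annot_routine <= 1.0 + 1e-12
    assert vec.appt_rate >= 0.0


def _monthly_frame(values_by_month):
    rows = []
    for month, values in values_by_month.items():
        row = {"practice_id": "P1", "month": month, "denominator_flags": ""}
        row.update({m: 0.0 for m in MEASURE_COLUMNS})
        row.update(values)
        rows.append(row)
    return pd.DataFrame(rows)


def test_average_window_single_month_identity():
    monthly = _monthly_frame({"2023-08": {"p_tel": 0.25, "triage_use": 1.0}})
    out = average_window(monthly)
    assert out.loc["P1", "p_tel"] == 0.25
    assert out.loc["P1", "n_months"] == 1


def test_average_window_means():
    monthly = _monthly_frame(
        {
            "2023-08": {"p_tel": 0.2, "triage_use": 1.0},
            "2023-09": {"p_tel": 0.4, "triage_use": 0.0},
            "2023-10": {"p_tel": 0.3, "triage_use": 1.0},
        }
    )
    out = average_window(monthly)
    assert out.loc["P1", "p_tel"] == pytest.approx(0.3)
    assert out.loc["P1", "triage_use"] == pytest.approx(2 / 3)


def test_average_window_commutes_with_scaling():
    monthly = _monthly_frame(
        {"2023-08": {"p_tel": 0.2}, "2023-09": {"p_tel": 0.6}}
    )
    a = average_window(monthly)["p_tel"] * 3.0 + 1.0
    scaled = monthly.copy()
    scaled["p_tel"] = scaled["p_tel"] * 3.0 + 1.0
    b = average_window(scaled)["p_tel"]
    assert a.equals(b)


def _vector_frame(columns):
    df = pd.DataFrame(0.0, index=["A", "B", "C"], columns=MEASURE_COLUMNS)
    for col, vals in columns.items():
        df[col] = vals
    return df


def test_scale_matrix_linear_map():
    scaled = scale_matrix(_vector_frame({"appt_rate": [0.0, 5.0, 10.0]}))
    assert list(scaled.values["appt_rate"]) == [0.0, 0.5, 1.0]
    assert scaled.column_ranges["appt_rate"] == (0.0, 10.0)


def test_scale_matrix_constant_column_maps_to_zero():
    scaled = scale_matrix(_vector_frame({"p_gp": [0.4, 0.4, 0.4]}))
    assert (scaled.values["p_gp"] == 0.0).all()


def test_scale_matrix_idempotent_on_nonconstant_columns():
    once = scale_matrix(_vector_frame({"p_tel": [0.1, 0.3, 0.9]}))
    twice = scale_matrix(once.values)
    pd.testing.assert_series_equal(once.values["p_tel"], twice.values["p_tel"])


def test_scale_matrix_needs_two_practices():
    with pytest.raises(ValueError):
        scale_matrix(_vector_frame({}).iloc[:1])


def test_scale_matrix_reuse_ranges_clips():
    train = scale_matrix(_vector_frame({"p_tel": [0.2, 0.4, 0.6]}))
    new = _vector_frame({"p_tel": [0.0, 0.4, 0.9]})
    out = scale_matrix(new, column_ranges=train.column_ranges)
    assert list(out.values["p_tel"]) == pytest.approx([0.0, 0.5, 1.0])
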