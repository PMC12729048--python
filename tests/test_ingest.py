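"""Appointment/registry reading, validation and the staged quality filter."""

import pandas as pd
import pytest

from gpclusters.annotate import annotate_counts
from gpclusters.ingest import (
    APPOINTMENT_COLUMNS,
    CleaningConfig,
    ValidationError,
    filter_practices,
    read_appointments,
    read_registry,
)
from tests.conftest import make_rows


def write_appts(tmp_path, df, name="appts.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


def test_read_empty_file(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text(",".join(APPOINTMENT_COLUMNS) + "\n")
    assert len(read_appointments(p)) == 0


def test_read_single_row(tmp_path):
    p = tmp_path / "one.csv"
    p.write_text(
        ",".join(APPOINTMENT_COLUMNS)
        + "\nP1,2023-08,gp,telephone,same_day,Same day appointment,40\n"
    )
    df = read_appointments(p)
    assert len(df) == 1
    assert df.loc[0, "count"] == 40


@pytest.mark.parametrize(
    "row,message",
    [
        (("P1", "2023-08", "nurse", "telephone", "same_day", "X", "1"), "hcp_type"),
        (("P1", "2023-08", "gp", "fax", "same_day", "X", "1"), "mode"),
        (("P1", "2023-08", "gp", "telephone", "someday", "X", "1"), "wait_band"),
        (("P1", "2023-13", "gp", "telephone", "same_day", "X", "1"), "month"),
        (("P1", "2023-08", "gp", "telephone", "same_day", "X", "-2"), "negative"),
    ],
)
def test_read_rejects_bad_rows(tmp_path, row, message):
    p = write_appts(tmp_path, make_rows([row]))
    with pytest.raises(ValidationError, match=message):
        read_appointments(p)


def test_read_rejects_duplicate_key(tmp_path):
    row = ("P1", "2023-08", "gp", "telephone", "same_day", "X", 1)
    p = write_appts(tmp_path, make_rows([row, row]))
    with pytest.raises(ValidationError, match="duplicate"):
        read_appointments(p)


def test_bundle_round_trip(tmp_path, small_bundle):
    """Generated appointment files re-read row-identically."""
    paths = small_bundle.write(tmp_path)
    for month in small_bundle.config.months:
        on_disk = read_appointments(paths[f"appointments_{month}"])
        original = small_bundle.appointments[
            small_bundle.appointments["month"] == month
        ].reset_index(drop=True)
        pd.testing.assert_frame_equal(on_disk, original)
    registry = read_registry(paths["registry"])
    assert len(registry) == small_bundle.config.n_practices


def _simple_registry(entries):
    rows = []
    for pid, list_size in entries:
        row = {
            "practice_id": pid, "list_size": list_size, "region": "London",
            "rural_urban": "urban", "imd_quintile": 3, "mean_age": 40.0,
            "age_under20": 0.2, "age_20_49": 0.4, "age_50_64": 0.2,
            "age_65_79": 0.15, "age_80_plus": 0.05, "white_share": 0.8,
        }
        for role in ("gp", "all_nurses", "practice_nurses", "anp",
                     "extended_roles", "pharmacists", "paramedics",
                     "physician_associates", "non_patient_facing"):
            row[f"fte_{role}"] = 1.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("practice_id", drop=False)


def test_small_list_excluded_at_stage_one(dictionary):
    rows = annotate_counts(
        make_rows(
            [("P1", "2023-08", "gp", "face_to_face", "d2_7", "Routine appointment", 500)]
        ),
        dictionary,
    )
    registry = _simple_registry([("P1", 900)])
    included, report = filter_practices(rows, registry, ["2023-08"])
    assert included == set()
    assert report.reasons == {"P1": "small_list"}
    assert report.n_excluded_size_rate == 1


def test_zero_appointments_included(dictionary):
    """No appointments: rate 0, unmapped and coverage rules vacuous."""
    rows = annotate_counts(
        make_rows(
            [("P2", "2023-08", "gp", "face_to_face", "d2_7", "Routine appointment", 5)]
        ),
        dictionary,
    )
    rows = pd.concat(
        [rows, rows.assign(practice_id="P1", count=0)], ignore_index=True
    )
    registry = _simple_registry([("P1", 5000), ("P2", 5000)])
    included, report = filter_practices(
        rows, registry, ["2023-08"], standard_categories={"Routine appointment"}
    )
    assert "P1" in included


def test_zero_list_size_never_crashes(dictionary):
    rows = annotate_counts(
        make_rows(
            [("P1", "2023-08", "gp", "face_to_face", "d2_7", "Routine appointment", 10)]
        ),
        dictionary,
    )
    registry = _simple_registry([("P1", 0)])
    included, report = filter_practices(rows, registry, ["2023-08"])
    assert report.reasons == {"P1": "zero_list_size"}


def test_missing_registry_excludes(dictionary):
    rows = annotate_counts(
        make_rows(
            [("P9", "2023-08", "gp", "face_to_face", "d2_7", "Routine appointment", 10)]
        ),
        dictionary,
    )
    registry = _simple_registry([("P1", 5000)])
    _, report = filter_practices(rows, registry, ["2023-08"])
    assert report.reasons == {"P9": "no_registry"}


def test_defect_bundle_filtering(defect_bundle, dictionary):
    """One practice per defect type is excluded at the right stage."""
    ann = annotate_counts(defect_bundle.appointments, dictionary)
    registry = defect_bundle.registry.set_index("practice_id", drop=False)
    included, report = filter_practices(
        ann,
        registry,
        list(defect_bundle.config.months),
        standard_categories=defect_bundle.standard_categories,
    )
    assert len(included) == 8
    for reason in ("small_list", "high_rate", "unmapped", "low_annotation"):
        assert report.count(reason) == 1, reason
    # first-failing-stage attribution matches the injected defect ledger
    expected = dict(
        zip(defect_bundle.defects["practice_id"], defect_bundle.defects["defect"])
    )
    remap = {"rate_outlier": "high_rate"}
    got = {p: remap.get(r, r) for p, r in report.reasons.items()}
    assert {p: remap.get(d, d) for p, d in expected.items()} == got
    # partition invariant
    assert report.n_input == report.n_included + len(report.reasons)
    assert set(expected) & included == set()


def test_filter_idempotent(defect_bundle, dictionary):
    ann = annotate_counts(defect_bundle.appointments, dictionary)
    registry = defect_bundle.registry.set_index("practice_id", drop=False)
    months = list(defect_bundle.config.months)
    cats = defect_bundle.standard_categories
    included, _ = filter_practices(ann, registry, months, standard_categories=cats)
    again, report2 = filter_practices(
        ann[ann["practice_id"].isin(included)],
        registry,
        months,
        standard_categories=cats,
    )
    assert again == included
    assert report2.reasons == {}


@pytest.mark.parametrize(
    "tighter",
    [
        CleaningConfig(min_list_size=5000),
        CleaningConfig(rate_threshold=400.0),
        CleaningConfig(max_unmapped_share=0.0),
        CleaningConfig(min_annotation_coverage=0.99),
    ],
)
def test_tightening_thresholds_monotone(defect_bundle, dictionary, tighter):
    ann = annotate_counts(defect_bundle.appointments, dictionary)
    registry = defect_bundle.registry.set_index("practice_id", drop=False)
    months = list(defect_bundle.config.months)
    cats = defect_bundle.standard_categories
    base, _ = filter_practices(ann, registry, months, standard_categories=cats)
    tight, _ = filter_practices(
        ann, registry, months, config=tighter, standard_categories=cats
    )
    assert tight <= base


def test_yearly_rate_reading_excludes_typical_practices(small_bundle, dictionary):
    """The literal yearly reading of the rate rule is exposed in config and
    excludes essentially every realistic practice."""
    ann = annotate_counts(small_bundle.appointments, dictionary)
    registry = small_bundle.registry.set_index("practice_id", drop=False)
    months = list(small_bundle.config.months)
    literal = CleaningConfig(rate_threshold=1500.0, rate_period="year")
    included, _ = filter_practices(
        ann, registry, months, config=literal,
        standard_categories=small_bundle.standard_categories,
    )
    assert included == set()
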