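"""The 12 appointment-system measures, window averaging and scaling.

Per practice-month the measures are:

==================== ==========================================================
p_gp                 appointments with a GP / total appointments
p_booked_gt1wk       booked >1 week ahead (wait band 8+ days) / total
p_tel                telephone appointments / total
p_tel_gp             telephone appointments with a GP / total
p_sameday_gp         same-day (wait band) appointments with a GP / total
p_annot_sameday      appointments annotated 'same day' / annotated appointments
p_tel_annot_sameday  telephone 'same day'-annotated / annotated
p_gp_annot_sameday   GP 'same day'-annotated / annotated
p_annot_routine      appointments annotated 'routine' / annotated
p_routine_within1    'routine'-annotated fulfilled within one day of booking
                     (same day or next day) / 'routine'-annotated
triage_use           any clinical-triage recording in the month (0/1)
appt_rate            total appointments per 1000 registered patients
==================== ==========================================================

"Annotated" means the care-model label is not ``unknown``. The first five
measures are taken over all appointments; a measure whose denominator is
zero is set to 0 and flagged, keeping vectors complete for clustering.
Monthly vectors are averaged unweighted over the analysis window (the 0/1
triage flag averages to a usage proportion) and then min-max scaled per
column to [0, 1] across practices before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import LABEL_COLUMN

MEASURE_COLUMNS = [
    "p_gp",
    "p_booked_gt1wk",
    "p_tel",
    "p_tel_gp",
    "p_sameday_gp",
    "p_annot_sameday",
    "p_tel_annot_sameday",
    "p_gp_annot_sameday",
    "p_annot_routine",
    "p_routine_within1",
    "triage_use",
    "appt_rate",
]

GT1WK_BANDS = frozenset({"d8_14", "d15_21", "d22_28", "gt28"})
WITHIN1_BANDS = frozenset({"same_day", "d1"})


@dataclass
class MeasureVector:
    """The 12 measures for one practice (one month or a window average)."""

    practice_id: str
    p_gp: float
    p_booked_gt1wk: float
    p_tel: float
    p_tel_gp: float
    p_sameday_gp: float
    p_annot_sameday: float
    p_tel_annot_sameday: float
    p_gp_annot_sameday: float
    p_annot_routine: float
    p_routine_within1: float
    triage_use: float
    appt_rate: float
    denominator_flags: set[str] = field(default_factory=set)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MEASURE_COLUMNS], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURE_COLUMNS}


def _ratio(num: float, den: float, flag: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(flag)
        return 0.0
    return num / den


def compute_monthly_measures(
    annotated_rows: pd.DataFrame,
    list_size: int,
    include_home_visits: bool = True,
) -> MeasureVector:
    """Compute the 12 measures for a single practice-month.

    ``annotated_rows`` must cover exactly one practice and one month and
    carry ``annotation_label``. ``include_home_visits=False`` drops
    home-visit rows from every numerator and denominator.
    """
    if list_size <= 0:
        raise ValueError(f"list_size must be positive, got {list_size}")
    df = annotated_rows
    if df["practice_id"].nunique() > 1 or df["month"].nunique() > 1:
        raise ValueError("expected rows for a single practice-month")
    if not include_home_visits:
        df = df[df["mode"] != "home_visit"]
    pid = str(df["practice_id"].iloc[0]) if len(df) else "<empty>"

    count = df["count"].to_numpy(dtype=float)
    gp = (df["hcp_type"] == "gp").to_numpy()
    tel = (df["mode"] == "telephone").to_numpy()
    gt1wk = df["wait_band"].isin(GT1WK_BANDS).to_numpy()
    sameday_band = (df["wait_band"] == "same_day").to_numpy()
    within1 = df["wait_band"].isin(WITHIN1_BANDS).to_numpy()
    label = df[LABEL_COLUMN].to_numpy()
    annotated = label != "unknown"
    lab_sd = label == "same_day"
    lab_rt = label == "routine"
    lab_tr = label == "triage"

    total = count.sum()
    n_annot = count[annotated].sum()
    n_routine = count[lab_rt].sum()
    flags: set[str] = set()

    vec = MeasureVector(
        practice_id=pid,
        p_gp=_ratio(count[gp].sum(), total, "p_gp", flags),
        p_booked_gt1wk=_ratio(count[gt1wk].sum(), total, "p_booked_gt1wk", flags),
        p_tel=_ratio(count[tel].sum(), total, "p_tel", flags),
        p_tel_gp=_ratio(count[tel & gp].sum(), total, "p_tel_gp", flags),
        p_sameday_gp=_ratio(count[sameday_band & gp].sum(), total, "p_sameday_gp", flags),
        p_annot_sameday=_ratio(count[lab_sd].sum(), n_annot, "p_annot_sameday", flags),
        p_tel_annot_sameday=_ratio(
            count[lab_sd & tel].sum(), n_annot, "p_tel_annot_sameday", flags
        ),
        p_gp_annot_sameday=_ratio(
            count[lab_sd & gp].sum(), n_annot, "p_gp_annot_sameday", flags
        ),
        p_annot_routine=_ratio(count[lab_rt].sum(), n_annot, "p_annot_routine", flags),
        p_routine_within1=_ratio(
            count[lab_rt & within1].sum(), n_routine, "p_routine_within1", flags
        ),
        triage_use=float(count[lab_tr].sum() > 0),
        appt_rate=total / list_size * 1000.0,
        denominator_flags=flags,
    )
    return vec


def compute_measures_table(
    annotated_rows: pd.DataFrame,
    registry: pd.DataFrame,
    window_months: list[str],
    include_home_visits: bool = True,
) -> pd.DataFrame:
    """Vectorised per-practice-month measure table over a window.

    Returns one row per (practice_id, month) with the 12 measure columns
    plus ``denominator_flags`` (semicolon-joined). Equivalent to calling
    :func:`compute_monthly_measures` per practice-month, but grouped.
    """
    df = annotated_rows[annotated_rows["month"].isin(window_months)].copy()
    if not include_home_visits:
        df = df[df["mode"] != "home_visit"]
    if df.empty:
        raise ValueError("no rows in the requested window")
    c = df["count"].astype(float)
    gp = df["hcp_type"] == "gp"
    tel = df["mode"] == "telephone"
    annotated = df[LABEL_COLUMN] != "unknown"
    lab_sd = df[LABEL_COLUMN] == "same_day"
    lab_rt = df[LABEL_COLUMN] == "routine"
    lab_tr = df[LABEL_COLUMN] == "triage"
    parts = {
        "total": c,
        "n_gp": c * gp,
        "n_gt1wk": c * df["wait_band"].isin(GT1WK_BANDS),
        "n_tel": c * tel,
        "n_tel_gp": c * (tel & gp),
        "n_sameday_gp": c * ((df["wait_band"] == "same_day") & gp),
        "n_annot": c * annotated,
        "n_lab_sd": c * lab_sd,
        "n_lab_sd_tel": c * (lab_sd & tel),
        "n_lab_sd_gp": c * (lab_sd & gp),
        "n_lab_rt": c * lab_rt,
        "n_lab_rt_w1": c * (lab_rt & df["wait_band"].isin(WITHIN1_BANDS)),
        "n_lab_tr": c * lab_tr,
    }
    agg = (
        pd.DataFrame(parts)
        .assign(practice_id=df["practice_id"].values, month=df["month"].values)
        .groupby(["practice_id", "month"], sort=True)
        .sum()
    )
    list_size = registry["list_size"].reindex(
        agg.index.get_level_values("practice_id")
    )
    if list_size.isna().any() or (list_size <= 0).any():
        bad = agg.index.get_level_values("practice_id")[
            list_size.isna().to_numpy() | (list_size <= 0).to_numpy()
        ]
        raise ValueError(f"missing or non-positive list_size for {sorted(set(bad))}")
    ls = list_size.to_numpy(dtype=float)

    def ratio(num: pd.Series, den: pd.Series) -> np.ndarray:
        d = den.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num.to_numpy(dtype=float) / d
        return np.where(d == 0, 0.0, r)

    out = pd.DataFrame(index=agg.index)
    out["p_gp"] = ratio(agg["n_gp"], agg["total"])
    out["p_booked_gt1wk"] = ratio(agg["n_gt1wk"], agg["total"])
    out["p_tel"] = ratio(agg["n_tel"], agg["total"])
    out["p_tel_gp"] = ratio(agg["n_tel_gp"], agg["total"])
    out["p_sameday_gp"] = ratio(agg["n_sameday_gp"], agg["total"])
    out["p_annot_sameday"] = ratio(agg["n_lab_sd"], agg["n_annot"])
    out["p_tel_annot_sameday"] = ratio(agg["n_lab_sd_tel"], agg["n_annot"])
    out["p_gp_annot_sameday"] = ratio(agg["n_lab_sd_gp"], agg["n_annot"])
    out["p_annot_routine"] = ratio(agg["n_lab_rt"], agg["n_annot"])
    out["p_routine_within1"] = ratio(agg["n_lab_rt_w1"], agg["n_lab_rt"])
    out["triage_use"] = (agg["n_lab_tr"] > 0).astype(float)
    out["appt_rate"] = agg["total"].to_numpy(dtype=float) / ls * 1000.0

    flags = []
    for total, n_annot, n_rt in zip(agg["total"], agg["n_annot"], agg["n_lab_rt"]):
        f = []
        if total == 0:
            f += ["p_gp", "p_booked_gt1wk", "p_tel", "p_tel_gp", "p_sameday_gp"]
        if n_annot == 0:
            f += [
                "p_annot_sameday",
                "p_tel_annot_sameday",
                "p_gp_annot_sameday",
                "p_annot_routine",
            ]
        if n_rt == 0:
            f.append("p_routine_within1")
        flags.append(";".join(f))
    out["denominator_flags"] = flags
    return out.reset_index()


def average_window(monthly: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of each measure over the months present per practice.

    ``monthly`` is the output of :func:`compute_measures_table`. The 0/1
    triage flag averages to a usage proportion; denominator flags are the
    union over months. Indexed by practice_id.
    """
    if monthly.empty:
        raise ValueError("no monthly measures to average")
    grouped = monthly.groupby("practice_id")
    out = grouped[MEASURE_COLUMNS].mean()
    out["denominator_flags"] = grouped["denominator_flags"].agg(
        lambda s: ";".join(sorted(set(f for x in s for f in x.split(";") if f)))
    )
    out["n_months"] = grouped.size()
    return out


@dataclass
class ScaledMatrix:
    """Min-max scaled measure matrix with the per-column ranges used.

    Non-constant columns span exactly [0, 1]; constant columns map to 0.
    ``column_ranges`` records the (min, max) applied, for audit and for
    scaling held-out data with the training ranges.
    """

    values: pd.DataFrame  # practices x 12, scaled
    column_ranges: dict[str, tuple[float, float]]

    @property
    def practice_ids(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def scale_matrix(
    vectors: pd.DataFrame,
    column_ranges: dict[str, tuple[float, float]] | None = None,
) -> ScaledMatrix:
    """Min-max scale each measure column to [0, 1] across practices.

    With ``column_ranges`` given (e.g. from the training window), those
    ranges are applied instead of the data's own, and results are clipped
    to [0, 1].
    """
    df = vectors[MEASURE_COLUMNS].astype(float)
    if len(df) < 2 and column_ranges is None:
        raise ValueError("need at least 2 practices to scale")
    reuse = column_ranges is not None
    ranges: dict[str, tuple[float, float]] = {}
    scaled = {}
    for col in MEASURE_COLUMNS:
        x = df[col].to_numpy()
        lo, hi = column_ranges[col] if reuse else (float(x.min()), float(x.max()))
        ranges[col] = (lo, hi)
        if hi == lo:
            scaled[col] = np.zeros(len(x))
        else:
            scaled[col] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return ScaledMatrix(
        values=pd.DataFrame(scaled, index=df.index), column_ranges=ranges
    )
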