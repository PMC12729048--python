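"""Reading, validation and quality filtering of appointment count tables.

The input mirrors the practice-level monthly extract of the NHS
"Appointments in General Practice" publication: one row per
(practice, month, healthcare-professional type, consultation mode,
wait-time band, national appointment category) cell, with a count.
A companion registry carries per-practice list size, sociodemographics and
workforce full-time equivalents.

Quality filtering follows a staged flow: (1) practices that are too small
or have outlying appointment rates (likely opening/closing practices or
specialist populations), (2) practices with >10% of appointments not mapped
to a standard national category, (3) practices with <50% of appointments
carrying a care-model annotation (likely inaccurate coding). A practice is
attributed to the first stage it fails, so the stage counts partition the
input — the shape of a flow diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import LABEL_COLUMN, annotation_coverage

HCP_TYPES = frozenset({"gp", "other"})
MODES = frozenset({"face_to_face", "telephone", "video", "home_visit", "unknown"})
WAIT_BANDS = ("same_day", "d1", "d2_7", "d8_14", "d15_21", "d22_28", "gt28", "unknown")

APPOINTMENT_COLUMNS = [
    "practice_id",
    "month",
    "hcp_type",
    "mode",
    "wait_band",
    "national_category",
    "count",
]

KEY_COLUMNS = APPOINTMENT_COLUMNS[:-1]


class ValidationError(ValueError):
    """Raised when an input table violates the schema."""


def _check_enum(df: pd.DataFrame, column: str, allowed, path) -> None:
    bad = df[~df[column].isin(allowed)]
    if len(bad):
        i = int(bad.index[0])
        raise ValidationError(
            f"{path}: row {i + 1}, column {column!r}: "
            f"unknown value {bad[column].iloc[0]!r}"
        )


def read_appointments(path: str | Path) -> pd.DataFrame:
    """Read and validate an appointments CSV.

    Columns must be exactly ``practice_id,month,hcp_type,mode,wait_band,
    national_category,count``. Enums are closed, counts are non-negative
    integers, months are ISO ``YYYY-MM``, and the six-column key is unique.
    Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != APPOINTMENT_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {APPOINTMENT_COLUMNS}, found {list(df.columns)}"
        )
    return validate_appointments(df, source=str(path))


def validate_appointments(df: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    df = df.copy()
    _check_enum(df, "hcp_type", HCP_TYPES, source)
    _check_enum(df, "mode", MODES, source)
    _check_enum(df, "wait_band", set(WAIT_BANDS), source)
    months = pd.to_datetime(df["month"], format="%Y-%m", errors="coerce")
    if months.isna().any():
        i = int(months.index[months.isna()][0])
        raise ValidationError(
            f"{source}: row {i + 1}: month {df['month'].iloc[i]!r} "
            "does not parse as YYYY-MM"
        )
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        i = int(counts.index[counts.isna()][0])
        raise ValidationError(f"{source}: row {i + 1}: count is not a number")
    if (counts < 0).any():
        i = int(counts.index[counts < 0][0])
        raise ValidationError(f"{source}: row {i + 1}: negative count")
    if (counts % 1 != 0).any():
        i = int(counts.index[counts % 1 != 0][0])
        raise ValidationError(f"{source}: row {i + 1}: non-integer count")
    df["count"] = counts.astype(int)
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        i = int(df.index[dup][0])
        raise ValidationError(
            f"{source}: row {i + 1}: duplicate key "
            f"{tuple(df.loc[df.index[dup][0], KEY_COLUMNS])}"
        )
    return df


REGISTRY_FTE_ROLES = [
    "gp",
    "all_nurses",
    "practice_nurses",
    "anp",
    "extended_roles",
    "pharmacists",
    "paramedics",
    "physician_associates",
    "non_patient_facing",
]

AGE_BAND_COLUMNS = [
    "age_under20",
    "age_20_49",
    "age_50_64",
    "age_65_79",
    "age_80_plus",
]

REGISTRY_COLUMNS = (
    ["practice_id", "list_size", "region", "rural_urban", "imd_quintile", "mean_age"]
    + AGE_BAND_COLUMNS
    + ["white_share"]
    + [f"fte_{r}" for r in REGISTRY_FTE_ROLES]
)


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read and validate the practice registry CSV.

    One row per practice. ``imd_quintile`` and the workforce FTE columns may
    be missing (blank); shares must lie in [0, 1], age-band shares must sum
    to 1 within 1e-6, and FTEs must be non-negative. Indexed by practice_id.
    """
    df = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: registry missing columns {missing}")
    if df["practice_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate practice_id in registry")
    if (df["list_size"] < 0).any():
        raise ValidationError(f"{path}: negative list_size")
    shares = df[AGE_BAND_COLUMNS + ["white_share"]]
    if ((shares < -1e-9) | (shares > 1 + 1e-9)).any().any():
        raise ValidationError(f"{path}: share outside [0, 1]")
    age_sum = df[AGE_BAND_COLUMNS].sum(axis=1)
    if ((age_sum - 1.0).abs() > 1e-6).any():
        raise ValidationError(f"{path}: age-band shares do not sum to 1")
    fte = df[[f"fte_{r}" for r in REGISTRY_FTE_ROLES]]
    if (fte < 0).any().any():
        raise ValidationError(f"{path}: negative FTE")
    df["list_size"] = df["list_size"].astype(int)
    return df.set_index("practice_id", drop=False)


@dataclass
class CleaningConfig:
    """Thresholds for the staged quality filter.

    ``rate_threshold`` is appointments per 1000 registered patients; with
    ``rate_period="month"`` (the default) it screens the mean monthly rate
    for outliers, with ``"year"`` the annualised rate is compared instead —
    the literal reading of the published rule.
    """

    min_list_size: int = 1000
    rate_threshold: float = 1500.0
    rate_period: str = "month"  # "month" | "year"
    max_unmapped_share: float = 0.10
    min_annotation_coverage: float = 0.50

    def __post_init__(self) -> None:
        if self.rate_period not in ("month", "year"):
            raise ValueError(f"rate_period must be month|year, got {self.rate_period}")


EXCLUSION_REASONS = (
    "no_registry",
    "zero_list_size",
    "small_list",
    "high_rate",
    "unmapped",
    "low_annotation",
)

_STAGE_OF_REASON = {
    "no_registry": "size_rate",
    "zero_list_size": "size_rate",
    "small_list": "size_rate",
    "high_rate": "size_rate",
    "unmapped": "unmapped",
    "low_annotation": "annotation",
}


@dataclass
class CleaningReport:
    """Accounting of the staged exclusion flow.

    The stage counts partition the input: every practice is either included
    or attributed to exactly one exclusion reason, at the first stage it
    failed.
    """

    n_input: int
    reasons: dict[str, str] = field(default_factory=dict)  # practice_id -> reason

    @property
    def n_included(self) -> int:
        return self.n_input - len(self.reasons)

    def count(self, reason: str) -> int:
        return sum(1 for r in self.reasons.values() if r == reason)

    @property
    def n_excluded_size_rate(self) -> int:
        return sum(
            1 for r in self.reasons.values() if _STAGE_OF_REASON[r] == "size_rate"
        )

    @property
    def n_excluded_unmapped(self) -> int:
        return self.count("unmapped")

    @property
    def n_excluded_annotation(self) -> int:
        return self.count("low_annotation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.reasons.items()), columns=["practice_id", "reason"]
        )

    def to_log(self) -> str:
        lines = [
            f"practices in input: {self.n_input}",
            f"excluded at size/rate stage: {self.n_excluded_size_rate}",
        ]
        for reason in ("no_registry", "zero_list_size", "small_list", "high_rate"):
            n = self.count(reason)
            if n:
                lines.append(f"  - {reason}: {n}")
        lines += [
            f"excluded, >{100 * 0.10:.0f}% unmapped categories: "
            f"{self.n_excluded_unmapped}",
            f"excluded, <50% annotated: {self.n_excluded_annotation}",
            f"practices included: {self.n_included}",
        ]
        return "\n".join(lines)


def load_standard_categories(path: str | Path) -> set[str]:
    """Read the standard national category list (one category per line)."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def filter_practices(
    annotated_rows: pd.DataFrame,
    registry: pd.DataFrame,
    window_months: list[str],
    config: CleaningConfig | None = None,
    standard_categories: set[str] | None = None,
) -> tuple[set[str], CleaningReport]:
    """Apply the staged quality filter over a window of months.

    Stage 1 screens list size and appointment rate (mean monthly total over
    the window divided by list size, per 1000 patients); stage 2 the share
    of counts whose category is off the standard list; stage 3 annotation
    coverage. Rows must already carry ``annotation_label``. Practices absent
    from the registry are excluded with reason ``no_registry``; a zero list
    size (rate undefined) excludes with ``zero_list_size``. Practices with
    zero appointments in the window pass stages 2–3 vacuously.
    """
    if config is None:
        config = CleaningConfig()
    if not window_months:
        raise ValueError("window_months must be non-empty")
    if LABEL_COLUMN not in annotated_rows.columns:
        raise ValueError("rows must be annotated before filtering")
    df = annotated_rows[annotated_rows["month"].isin(window_months)]
    practices = sorted(annotated_rows["practice_id"].unique())
    report = CleaningReport(n_input=len(practices))
    included: set[str] = set()
    totals = df.groupby("practice_id")["count"].sum()
    if standard_categories is not None:
        off_list = ~df["national_category"].isin(standard_categories)
        unmapped_totals = (
            df.loc[off_list].groupby("practice_id")["count"].sum()
            if off_list.any()
            else pd.Series(dtype=int)
        )
    else:
        unmapped_totals = pd.Series(dtype=int)
    annotated_totals = (
        df.loc[df[LABEL_COLUMN] != "unknown"].groupby("practice_id")["count"].sum()
    )
    for pid in practices:
        if pid not in registry.index:
            report.reasons[pid] = "no_registry"
            continue
        list_size = int(registry.loc[pid, "list_size"])
        if list_size == 0:
            report.reasons[pid] = "zero_list_size"
            continue
        if list_size < config.min_list_size:
            report.reasons[pid] = "small_list"
            continue
        total = int(totals.get(pid, 0))
        monthly_rate = total / len(window_months) / list_size * 1000.0
        rate = monthly_rate * 12 if config.rate_period == "year" else monthly_rate
        if rate > config.rate_threshold:
            report.reasons[pid] = "high_rate"
            continue
        if total == 0:
            included.add(pid)  # stages 2-3 vacuous with no appointments
            continue
        unmapped_share = int(unmapped_totals.get(pid, 0)) / total
        if unmapped_share > config.max_unmapped_share:
            report.reasons[pid] = "unmapped"
            continue
        coverage = int(annotated_totals.get(pid, 0)) / total
        if coverage < config.min_annotation_coverage:
            report.reasons[pid] = "low_annotation"
            continue
        included.add(pid)
    assert report.n_input == len(included) + len(report.reasons)
    return included, report
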