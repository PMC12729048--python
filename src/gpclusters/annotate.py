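"""Annotation of national appointment categories with care-model labels.

NHS practices map their local appointment-slot types onto a national list of
standardised categories. Those categories are in turn annotated — by manual
clinical review, supplied here as a dictionary file — with one of four
care-model labels: ``same_day``, ``routine``, ``triage`` or ``unknown``.
The share of a practice's appointments that carries a non-``unknown`` label
("annotation coverage") is one of the data-quality screens applied upstream
of clustering: practices with coverage below 50% are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ANNOTATION_LABELS = frozenset({"same_day", "routine", "triage", "unknown"})

LABEL_COLUMN = "annotation_label"


class AnnotationError(ValueError):
    """Raised when an annotation dictionary file is malformed."""


@dataclass(frozen=True)
class AnnotationDictionary:
    """Mapping from national appointment category to care-model label.

    Keys are matched case-sensitively and exactly. Categories absent from
    the dictionary are treated as ``unknown`` at application time; that is
    not an error, it is the normal state of unreviewed categories.
    """

    entries: dict[str, str]
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values()} - ANNOTATION_LABELS
        if bad:
            raise AnnotationError(f"labels outside the closed set: {sorted(bad)}")

    def label_for(self, category: str) -> str:
        return self.entries.get(category, "unknown")

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries.items()), columns=["national_category", "label"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_annotation_dictionary(path: str | Path) -> AnnotationDictionary:
    """Read an annotation dictionary CSV (columns ``national_category,label``).

    Duplicate keys with identical labels are deduplicated with a warning;
    duplicates with conflicting labels are an error, as are labels outside
    the closed set.
    """
    df = pd.read_csv(path, dtype=str)
    expected = ["national_category", "label"]
    if list(df.columns) != expected:
        raise AnnotationError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    entries: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        cat, label = row.national_category, row.label
        if label not in ANNOTATION_LABELS:
            raise AnnotationError(
                f"{path}: row {i + 1}: unknown label {label!r} for category {cat!r}"
            )
        if cat in entries:
            if entries[cat] != label:
                raise AnnotationError(
                    f"{path}: row {i + 1}: category {cat!r} mapped to both "
                    f"{entries[cat]!r} and {label!r}"
                )
            warnings.warn(
                f"{path}: duplicate entry for category {cat!r} (same label); "
                "deduplicated",
                stacklevel=2,
            )
            continue
        entries[cat] = label
    return AnnotationDictionary(entries=entries, source=str(path))


def annotate_counts(
    rows: pd.DataFrame, dictionary: AnnotationDictionary
) -> pd.DataFrame:
    """Attach an ``annotation_label`` column to appointment count rows.

    Categories not present in the dictionary label as ``unknown``. Counts
    are never altered.
    """
    out = rows.copy()
    labels = out["national_category"].map(dictionary.entries)
    out[LABEL_COLUMN] = labels.fillna("unknown")
    return out


def annotation_coverage(
    annotated_rows: pd.DataFrame, window_months: list[str] | None = None
) -> float:
    """Count-weighted share of appointments with a non-``unknown`` label.

    With zero appointments in the window the coverage is defined as 0.0;
    the quality filter treats that case as vacuous rather than excluding.
    """
    df = annotated_rows
    if window_months is not None:
        df = df[df["month"].isin(window_months)]
    total = int(df["count"].sum())
    if total == 0:
        return 0.0
    annotated = int(df.loc[df[LABEL_COLUMN] != "unknown", "count"].sum())
    return annotated / total
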