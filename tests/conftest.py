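"""Shared fixtures: synthetic bundles at various scales.

Everything is generated programmatically; session scope keeps the heavier
bundles to one generation each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gpclusters.annotate import AnnotationDictionary, annotate_counts
from gpclusters.ingest import APPOINTMENT_COLUMNS
from gpclusters.synthdata import (
    ANNOTATION_ENTRIES,
    SyntheticConfig,
    generate_dataset,
)


def make_rows(rows: list[tuple]) -> pd.DataFrame:
    """Build an appointments frame from (pid, month, hcp, mode, band,
    category, count) tuples."""
    return pd.DataFrame(rows, columns=APPOINTMENT_COLUMNS)


@pytest.fixture(scope="session")
def dictionary() -> AnnotationDictionary:
    return AnnotationDictionary(dict(ANNOTATION_ENTRIES), source="fixture")


@pytest.fixture(scope="session")
def small_bundle():
    """40 practices, two training months plus a holdout month, no defects."""
    config = SyntheticConfig(
        n_practices=40,
        months=("2023-08", "2023-09"),
        holdout_month="2023-12",
        master_seed=42,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def defect_bundle():
    """12 practices with exactly one practice per quality-defect type."""
    config = SyntheticConfig(
        n_practices=12,
        months=("2023-08", "2023-09", "2023-10"),
        holdout_month=None,
        defect_rate_small_list=1 / 12,
        defect_rate_rate_outlier=1 / 12,
        defect_rate_unmapped=1 / 12,
        defect_rate_low_annotation=1 / 12,
        master_seed=0,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def annotated_small(small_bundle, dictionary):
    return annotate_counts(small_bundle.appointments, dictionary)


@pytest.fixture(scope="session")
def registry_small(small_bundle):
    return small_bundle.registry.set_index("practice_id", drop=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
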