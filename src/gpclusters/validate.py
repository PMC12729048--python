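"""Cluster stability on a held-out month.

The clustering is re-run from scratch on a later month prepared
identically to the training window; cluster labels from the two runs are
arbitrary, so they are matched by the permutation maximising total
agreement on the practices present in both, and the agreement — the
proportion of common practices that stay in the same (matched) cluster —
is reported together with the cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class StabilityReport:
    """Hold-out agreement between two clusterings of overlapping practices."""

    n_common: int
    permutation: np.ndarray  # applied to the new labels
    agreement: float
    crosstab: pd.DataFrame  # original x matched-new counts

    def to_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "permutation": [int(p) for p in self.permutation],
            "agreement": self.agreement,
            "crosstab": self.crosstab.to_dict(),
        }


def match_clusters(labels_orig: pd.Series, labels_new: pd.Series) -> np.ndarray:
    """Permutation of the new labels maximising agreement on common items.

    Both inputs are label Series indexed by practice_id. Returns ``perm``
    such that ``perm[labels_new]`` is on the original labelling's scale.
    When the identity permutation ties the optimum, identity is preferred.
    """
    common = labels_orig.index.intersection(labels_new.index)
    if len(common) == 0:
        raise ValueError("no common practices between the two labelings")
    a = labels_orig.loc[common].to_numpy(dtype=int)
    b = labels_new.loc[common].to_numpy(dtype=int)
    k = int(max(a.max(), b.max())) + 1
    table = np.zeros((k, k), dtype=np.int64)
    np.add.at(table, (b, a), 1)
    rows, cols = linear_sum_assignment(-table)
    perm = np.arange(k)
    perm[rows] = cols
    if np.trace(table) == table[rows, cols].sum():
        return np.arange(k)  # identity achieves the optimum
    return perm


def stability_report(labels_orig: pd.Series, labels_new: pd.Series) -> StabilityReport:
    """Match clusters and report hold-out agreement on common practices."""
    perm = match_clusters(labels_orig, labels_new)
    common = labels_orig.index.intersection(labels_new.index)
    a = labels_orig.loc[common].to_numpy(dtype=int)
    b = perm[labels_new.loc[common].to_numpy(dtype=int)]
    k = int(max(a.max(), b.max())) + 1
    table = np.zeros((k, k), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    crosstab = pd.DataFrame(
        table,
        index=[f"orig_{i}" for i in range(k)],
        columns=[f"new_{j}" for j in range(k)],
    )
    agreement = float(np.trace(table)) / len(common)
    return StabilityReport(
        n_common=len(common), permutation=perm, agreement=agreement, crosstab=crosstab
    )


def stability_agreement(
    labels_orig: pd.Series,
    labels_new: pd.Series,
) -> float:
    """Proportion of common practices keeping their (matched) cluster."""
    return stability_report(labels_orig, labels_new).agreement
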