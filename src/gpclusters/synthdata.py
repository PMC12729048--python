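"""Synthetic appointment datasets with a two-cluster practice population.

The generator emulates the structure the clustering analysis assumes: a
mixture of two latent practice types — 'routine care' practices (face-to-
face, longer waits, more non-GP staff) and 'same-day care' practices
(telephone, GP-delivered, same-day fulfilment) — with per-type means and
SDs of the 12 appointment-system measures, log-normal list sizes,
month-to-month noise, per-type sociodemographic and workforce covariates,
and optional injected data-quality defects matching the exclusion rules of
the cleaning stage.

Generation is in two steps. ``sample_practice_profile`` draws a latent
cluster and a target measure vector from truncated normals, with the
subset constraints between measures (e.g. GP telephone share cannot exceed
either the GP or the telephone share) enforced by truncating each draw to
its feasible interval given the draws before it. ``realize_counts`` then
deterministically inverts the measure definitions: it allocates a
practice-month's appointment total across (professional x mode x
care-model label x wait band) cells so that recomputing the measures from
the emitted rows reproduces the profile's targets, up to integer rounding
(largest-remainder). That round trip is the generator's fidelity contract:
within 0.02 absolute of every target at 2000+ appointments.

Proportions are modelled as truncated normals because the study conditions
are stated as mean/SD summaries; no within-cluster covariance is imposed
beyond the subset constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .annotate import AnnotationDictionary
from .ingest import APPOINTMENT_COLUMNS, REGISTRY_COLUMNS

ROUTINE, SAMEDAY = "routine", "same_day"

# category strings: the first three are annotated, the fourth is on the
# standard list but unreviewed, the fifth is used for unmapped defects
CATEGORY_OF_LABEL = {
    "same_day": "Same day appointment",
    "routine": "Routine appointment",
    "triage": "Triage appointment",
    "unknown": "General consultation",
}
OFF_LIST_CATEGORY = "Local slot type 1"

STANDARD_CATEGORIES = sorted(CATEGORY_OF_LABEL.values())

ANNOTATION_ENTRIES = {
    "Same day appointment": "same_day",
    "Routine appointment": "routine",
    "Triage appointment": "triage",
    "General consultation": "unknown",
}

# split of the >1-week wait mass across its bands
GT1WK_SPLIT = {"d8_14": 0.50, "d15_21": 0.25, "d22_28": 0.15, "gt28": 0.10}

AGE_MIDPOINTS = np.array([10.0, 35.0, 57.0, 72.0, 85.0])

REGIONS = [
    "East of England",
    "London",
    "Midlands",
    "North East and Yorkshire",
    "North West",
    "South East",
    "South West",
]


@dataclass
class ClusterParams:
    """Per-cluster generative parameters: measure means/SDs plus
    covariate distributions."""

    measure_means: dict[str, float]
    measure_sds: dict[str, float]
    triage_prob: float
    list_size_mean: float
    list_size_sd: float
    region_probs: dict[str, float]
    rural_prob: float
    imd_probs: tuple[float, ...]  # quintiles 1..5
    white_mean: float
    white_sd: float
    age_band_means: tuple[float, ...]  # <20, 20-49, 50-64, 65-79, >=80
    fte_means: dict[str, float]
    fte_sds: dict[str, float]


_FTE_ROUTINE = {
    "gp": 4.4, "all_nurses": 2.7, "practice_nurses": 1.8, "anp": 0.6,
    "extended_roles": 2.5, "pharmacists": 0.2, "paramedics": 0.1,
    "physician_associates": 0.1, "non_patient_facing": 11.6,
}
_FTE_ROUTINE_SD = {
    "gp": 1.9, "all_nurses": 1.7, "practice_nurses": 1.1, "anp": 0.9,
    "extended_roles": 2.5, "pharmacists": 0.5, "paramedics": 0.4,
    "physician_associates": 0.3, "non_patient_facing": 4.1,
}
_FTE_SAMEDAY = {
    "gp": 4.5, "all_nurses": 2.2, "practice_nurses": 1.6, "anp": 0.4,
    "extended_roles": 2.0, "pharmacists": 0.2, "paramedics": 0.1,
    "physician_associates": 0.1, "non_patient_facing": 11.1,
}
_FTE_SAMEDAY_SD = {
    "gp": 1.8, "all_nurses": 1.4, "practice_nurses": 0.9, "anp": 0.7,
    "extended_roles": 2.3, "pharmacists": 0.5, "paramedics": 0.2,
    "physician_associates": 0.4, "non_patient_facing": 4.1,
}

ROUTINE_PARAMS = ClusterParams(
    measure_means={
        "p_gp": 0.48, "p_booked_gt1wk": 0.35, "p_tel": 0.18, "p_tel_gp": 0.11,
        "p_sameday_gp": 0.27, "p_annot_sameday": 0.16, "p_tel_annot_sameday": 0.03,
        "p_gp_annot_sameday": 0.10, "p_annot_routine": 0.70,
        "p_routine_within1": 0.35, "appt_rate": 488.49,
    },
    measure_sds={
        "p_gp": 0.15, "p_booked_gt1wk": 0.13, "p_tel": 0.14, "p_tel_gp": 0.10,
        "p_sameday_gp": 0.12, "p_annot_sameday": 0.13, "p_tel_annot_sameday": 0.05,
        "p_gp_annot_sameday": 0.09, "p_annot_routine": 0.19,
        "p_routine_within1": 0.17, "appt_rate": 128.61,
    },
    triage_prob=0.807,
    list_size_mean=9784.0,
    list_size_sd=6335.0,
    region_probs={
        "East of England": 0.123, "London": 0.157, "Midlands": 0.182,
        "North East and Yorkshire": 0.169, "North West": 0.167,
        "South East": 0.112, "South West": 0.091,
    },
    rural_prob=0.171,
    imd_probs=(0.187, 0.195, 0.193, 0.207, 0.217),
    white_mean=0.81,
    white_sd=0.21,
    age_band_means=(0.22, 0.40, 0.20, 0.13, 0.05),
    fte_means=_FTE_ROUTINE,
    fte_sds=_FTE_ROUTINE_SD,
)

SAMEDAY_PARAMS = ClusterParams(
    measure_means={
        "p_gp": 0.62, "p_booked_gt1wk": 0.26, "p_tel": 0.33, "p_tel_gp": 0.24,
        "p_sameday_gp": 0.41, "p_annot_sameday": 0.43, "p_tel_annot_sameday": 0.16,
        "p_gp_annot_sameday": 0.32, "p_annot_routine": 0.48,
        "p_routine_within1": 0.35, "appt_rate": 462.71,
    },
    measure_sds={
        "p_gp": 0.13, "p_booked_gt1wk": 0.11, "p_tel": 0.17, "p_tel_gp": 0.14,
        "p_sameday_gp": 0.12, "p_annot_sameday": 0.19, "p_tel_annot_sameday": 0.14,
        "p_gp_annot_sameday": 0.14, "p_annot_routine": 0.19,
        "p_routine_within1": 0.17, "appt_rate": 110.36,
    },
    triage_prob=0.754,
    list_size_mean=10377.0,
    list_size_sd=7355.0,
    region_probs={
        "East of England": 0.066, "London": 0.229, "Midlands": 0.231,
        "North East and Yorkshire": 0.080, "North West": 0.182,
        "South East": 0.152, "South West": 0.060,
    },
    rural_prob=0.117,
    imd_probs=(0.216, 0.192, 0.183, 0.204, 0.205),
    white_mean=0.75,
    white_sd=0.22,
    age_band_means=(0.23, 0.42, 0.19, 0.12, 0.04),
    fte_means=_FTE_SAMEDAY,
    fte_sds=_FTE_SAMEDAY_SD,
)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults follow the published two-cluster parameterisation: mixture
    weight 1194/3480 for same-day practices, per-cluster measure means/SDs
    and covariates, a three-month training window plus a December holdout.
    ``month_noise_sd`` / ``holdout_noise_sd`` are additive truncated-normal
    perturbations of the proportion targets per emitted month; the holdout
    default (0.05) is a tuning default for the stability analogue, not an
    observed quantity. Defect rates inject one quality violation per
    designated practice.
    """

    n_practices: int = 600
    mixture_weight_sameday: float = 1194 / 3480
    clusters: dict[str, ClusterParams] = field(
        default_factory=lambda: {ROUTINE: ROUTINE_PARAMS, SAMEDAY: SAMEDAY_PARAMS}
    )
    months: tuple[str, ...] = ("2023-08", "2023-09", "2023-10")
    holdout_month: str | None = "2023-12"
    coverage_mean: float = 0.92
    coverage_sd: float = 0.04
    month_noise_sd: float = 0.02
    rate_noise_rel: float = 0.03
    holdout_noise_sd: float = 0.05
    defect_rate_small_list: float = 0.0
    defect_rate_rate_outlier: float = 0.0
    defect_rate_unmapped: float = 0.0
    defect_rate_low_annotation: float = 0.0
    imd_missing_rate: float = 0.05
    workforce_missing_rate: float = 0.047
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mixture_weight_sameday <= 1:
            raise ValueError("mixture weight must be in [0, 1]")
        if len(self.months) < 1:
            raise ValueError("need at least 1 month")
        rates = [
            self.defect_rate_small_list,
            self.defect_rate_rate_outlier,
            self.defect_rate_unmapped,
            self.defect_rate_low_annotation,
        ]
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("defect rates must be in [0, 1]")
        if sum(rates) > 1:
            raise ValueError("defect rates sum to more than 1")


@dataclass
class PracticeProfile:
    """Latent cluster, target measure vector and covariates for one practice.

    ``triage_prob`` is the practice's per-month probability of recording
    clinical triage; a month-level view (:func:`monthly_profile`) draws the
    month's 0/1 triage state into ``triage_user`` and, for triage-free
    months, renormalises the annotated label shares (the triage-labelled
    mass is redistributed).
    """

    practice_id: str
    cluster: str
    targets: dict[str, float]  # 10 proportions + appt_rate + coverage
    triage_prob: float
    list_size: int
    covariates: dict
    triage_user: bool | None = None  # set on month-level views

    def target_measures(self) -> dict[str, float]:
        """The 12 measures this profile aims for.

        On a month-level view triage is the month's 0/1 state; on the
        practice-level profile it is the expected monthly probability.
        """
        out = {k: v for k, v in self.targets.items() if k != "coverage"}
        out["triage_use"] = (
            float(self.triage_user) if self.triage_user is not None
            else self.triage_prob
        )
        return out


class InfeasibleProfile(RuntimeError):
    pass


def _tn(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """One truncated-normal draw on [lo, hi]."""
    if hi < lo:
        raise InfeasibleProfile(f"empty truncation interval [{lo}, {hi}]")
    if sd <= 0 or hi == lo:
        return float(min(max(mean, lo), hi))
    # inverse-CDF sampling of the normal truncated to [lo, hi]
    pa, pb = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    if pb - pa < 1e-12:
        return float(min(max(mean, lo), hi))
    u = rng.uniform(pa, pb)
    return float(min(max(mean + sd * ndtri(u), lo), hi))


# ---------------------------------------------------------------------------
# Deterministic allocation of a practice-month across count cells
# ---------------------------------------------------------------------------

def _repair_targets(t: dict[str, float]) -> dict[str, float]:
    """Project an independently drawn target vector onto the subset
    constraints with minimal, deterministic adjustments.

    Each conditional constraint clips only the dependent coordinate, so
    measures stay independent within cluster except where a constraint
    binds — the closest realisable analogue of the marginal summaries the
    generator is parameterised by.
    """
    t = dict(t)
    c = t["coverage"]
    g = t["p_gp"] = min(max(t["p_gp"], 0.0), 1.0)
    T = t["p_tel"] = min(max(t["p_tel"], 0.0), 1.0)
    t["p_tel_gp"] = min(max(t["p_tel_gp"], g + T - 1.0, 0.0), g, T)
    tot = t["p_annot_sameday"] + t["p_annot_routine"]
    if tot > 1.0:
        t["p_annot_sameday"] /= tot
        t["p_annot_routine"] /= tot
    s = t["p_annot_sameday"]
    t["p_gp_annot_sameday"] = min(
        max(t["p_gp_annot_sameday"], (g - 1.0 + s * c) / c, 0.0), s, g / c
    )
    t["p_tel_annot_sameday"] = min(
        max(t["p_tel_annot_sameday"], (T - 1.0 + s * c) / c, 0.0), s, T / c
    )
    t["p_sameday_gp"] = min(max(t["p_sameday_gp"], 0.0), g)
    t["p_booked_gt1wk"] = min(max(t["p_booked_gt1wk"], 0.0), 1.0)
    t["p_routine_within1"] = min(max(t["p_routine_within1"], 0.0), 1.0)
    t["appt_rate"] = max(t["appt_rate"], 50.0)
    return t


def _allocate(
    t: dict[str, float], triage_user: bool, repair: bool = False
) -> tuple[dict[tuple, float], dict[str, float]] | None:
    """Distribute unit mass across (hcp, mode, label, wait_band) cells so
    the measure definitions recover the targets ``t`` exactly.

    Returns ``(cells, effective_targets)``. In strict mode mutually
    unsatisfiable targets give None; with ``repair=True`` the few targets
    that interact through the wait-band budget (telephone&GP, GP same-day
    wait, booked >1 week) are nudged to the nearest satisfiable value and
    reported back in ``effective_targets``.
    """
    t = dict(t)
    eps = 1e-9
    if triage_user and repair:
        # a triage-recording month needs some triage-labelled share
        tr_min = 0.02
        tot = t["p_annot_sameday"] + t["p_annot_routine"]
        if 1.0 - tot < tr_min:
            shrink = (1.0 - tr_min) / tot
            t["p_annot_sameday"] *= shrink
            t["p_annot_routine"] *= shrink
            t["p_gp_annot_sameday"] = min(
                t["p_gp_annot_sameday"], t["p_annot_sameday"]
            )
            t["p_tel_annot_sameday"] = min(
                t["p_tel_annot_sameday"], t["p_annot_sameday"]
            )
    g, T, TG = t["p_gp"], t["p_tel"], t["p_tel_gp"]
    SG, B, w1 = t["p_sameday_gp"], t["p_booked_gt1wk"], t["p_routine_within1"]
    s, r = t["p_annot_sameday"], t["p_annot_routine"]
    ts, gs = t["p_tel_annot_sameday"], t["p_gp_annot_sameday"]
    c = t["coverage"]

    A = c
    SD, RT = s * A, r * A
    TR = max((1.0 - s - r), 0.0) * A if triage_user else 0.0
    UNK = 1.0 - SD - RT - TR
    if UNK < -eps:
        return None
    UNK = max(UNK, 0.0)

    # professional split: GP mass inside the same-day label is pinned by
    # the gs target; the rest of the GP mass spreads uniformly over the
    # other labels
    gp_sd = gs * A
    if gp_sd > min(SD, g) + eps:
        return None
    pool_rest = 1.0 - SD
    g_rest = g - gp_sd
    if g_rest < -eps or (pool_rest > eps and g_rest > pool_rest + eps):
        return None
    g_rest = max(g_rest, 0.0)
    frac_gp_rest = g_rest / pool_rest if pool_rest > eps else 0.0
    gp_of = {"routine": frac_gp_rest * RT, "triage": frac_gp_rest * TR,
             "unknown": frac_gp_rest * UNK}

    # telephone split: pinned inside the same-day label by ts, balanced
    # elsewhere so the overall tel and tel&GP targets hold
    tel_sd = ts * A
    if tel_sd > min(SD, T) + eps:
        return None
    tel_rest = T - tel_sd
    if tel_rest < -eps or (pool_rest > eps and tel_rest > pool_rest + eps):
        return None
    tel_rest = max(tel_rest, 0.0)
    # tel & gp inside the same-day label: prefer independence, constrained
    # so that both the sd-label 2x2 and the rest 2x2 stay non-negative
    lo_sd = max(0.0, gp_sd + tel_sd - SD)
    hi_sd = min(gp_sd, tel_sd)
    lo_rest = max(0.0, g_rest + tel_rest - pool_rest)
    hi_rest = min(g_rest, tel_rest)
    if repair:
        TG = t["p_tel_gp"] = min(max(TG, lo_sd + lo_rest), hi_sd + hi_rest)
    lo = max(lo_sd, TG - hi_rest)
    hi = min(hi_sd, TG - lo_rest)
    if lo > hi + eps:
        return None
    pref = gp_sd * tel_sd / SD if SD > eps else 0.0
    tg_sd = min(max(pref, lo), hi)
    tg_rest = TG - tg_sd
    frac_tel_rest = tel_rest / pool_rest if pool_rest > eps else 0.0
    frac_tg_rest = tg_rest / pool_rest if pool_rest > eps else 0.0

    # wait bands. Same-day-labelled GP mass is fulfilled same day up to the
    # SG target; any excess is fulfilled next day (slot category and wait
    # band are recorded independently). If SG exceeds the same-day-labelled
    # GP mass, the extra E comes first from the triage/unknown labels and
    # then from the routine label's within-one-day quota.
    sd_gp_sameday = min(SG, gp_sd)
    sd_gp_d1 = gp_sd - sd_gp_sameday
    E = max(SG - gp_sd, 0.0)
    gp_tr_unk = gp_of["triage"] + gp_of["unknown"]
    e1 = min(E, gp_tr_unk)
    W1 = w1 * RT
    e2 = E - e1
    if e2 > min(gp_of["routine"], W1) + eps:
        if not repair:
            return None
        e2 = min(e2, gp_of["routine"], W1)
        SG = t["p_sameday_gp"] = gp_sd + e1 + e2
    e2 = min(e2, gp_of["routine"], W1)
    sameday_extra = {
        "triage": e1 * (gp_of["triage"] / gp_tr_unk) if gp_tr_unk > eps else 0.0,
        "unknown": e1 * (gp_of["unknown"] / gp_tr_unk) if gp_tr_unk > eps else 0.0,
        "routine": e2,
    }
    # routine label mass still owed a within-one-day wait, placed at d1
    W1_rem = W1 - e2
    rt_gp_left = gp_of["routine"] - e2
    rt_other = RT - gp_of["routine"]
    rt_pool = rt_gp_left + rt_other
    if W1_rem > rt_pool + eps:
        return None
    d1 = {
        ("routine", "gp"): W1_rem * (rt_gp_left / rt_pool) if rt_pool > eps else 0.0,
        ("routine", "other"): W1_rem * (rt_other / rt_pool) if rt_pool > eps else 0.0,
    }

    # eligible mass for >1-week waits: anything not same-day-labelled, not
    # already owed a within-one-day or same-day wait
    elig = {
        ("routine", "gp"): rt_gp_left - d1[("routine", "gp")],
        ("routine", "other"): rt_other - d1[("routine", "other")],
        ("triage", "gp"): gp_of["triage"] - sameday_extra["triage"],
        ("triage", "other"): TR - gp_of["triage"],
        ("unknown", "gp"): gp_of["unknown"] - sameday_extra["unknown"],
        ("unknown", "other"): UNK - gp_of["unknown"],
    }
    if any(v < -eps for v in elig.values()):
        return None
    elig = {k: max(v, 0.0) for k, v in elig.items()}
    P = sum(elig.values())
    if B > P + eps:
        if not repair:
            return None
        B = t["p_booked_gt1wk"] = P
    gt = {k: B * v / P if P > eps else 0.0 for k, v in elig.items()}

    # wait distribution per (label, hcp) group
    def wait_dist(label: str, hcp: str, mass: float) -> dict[str, float]:
        if mass <= eps:
            return {}
        if label == "same_day":
            if hcp == "gp" and sd_gp_d1 > eps:
                return {"same_day": mass - sd_gp_d1 * mass / gp_sd,
                        "d1": sd_gp_d1 * mass / gp_sd}
            return {"same_day": mass}
        key = (label, hcp)
        sd_extra = sameday_extra[label] if hcp == "gp" else 0.0
        d1_mass = d1.get(key, 0.0)
        gt_mass = gt.get(key, 0.0)
        rest = mass - sd_extra - d1_mass - gt_mass
        dist = {"same_day": sd_extra, "d1": d1_mass, "d2_7": max(rest, 0.0)}
        for band, w in GT1WK_SPLIT.items():
            dist[band] = gt_mass * w
        return {b: m for b, m in dist.items() if m > eps}

    label_mass = {"same_day": SD, "routine": RT, "triage": TR, "unknown": UNK}
    cells: dict[tuple, float] = {}
    for label, mass in label_mass.items():
        if mass <= eps:
            continue
        if label == "same_day":
            gp_m, tel_m, tg_m = gp_sd, tel_sd, tg_sd
        else:
            gp_m = gp_of[label]
            tel_m = frac_tel_rest * mass
            tg_m = frac_tg_rest * mass
        hcp_mode = {
            ("gp", "telephone"): tg_m,
            ("gp", "face_to_face"): gp_m - tg_m,
            ("other", "telephone"): tel_m - tg_m,
            ("other", "face_to_face"): mass - gp_m - tel_m + tg_m,
        }
        if any(v < -1e-7 for v in hcp_mode.values()):
            return None
        for (hcp, mode), hm_mass in hcp_mode.items():
            if hm_mass <= eps:
                continue
            hcp_total = gp_m if hcp == "gp" else mass - gp_m
            wdist = wait_dist(label, hcp, hcp_total)
            for band, wm in wdist.items():
                frac = wm / hcp_total if hcp_total > eps else 0.0
                cells[(hcp, mode, label, band)] = (
                    cells.get((hcp, mode, label, band), 0.0) + hm_mass * frac
                )
    total = sum(cells.values())
    if abs(total - 1.0) > 1e-6:
        return None
    return cells, t


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    """Integer allocation of ``total`` across ``weights``, preserving the sum."""
    scaled = np.array(weights, dtype=float)
    scaled = scaled / scaled.sum() * total
    floors = np.floor(scaled).astype(int)
    short = total - int(floors.sum())
    order = np.argsort(-(scaled - floors), kind="stable")
    floors[order[:short]] += 1
    return floors.tolist()


def realize_counts(
    profile: PracticeProfile,
    month: str,
    rng: np.random.Generator | None = None,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Emit appointment count rows for one practice-month.

    Deterministic given the profile: the monthly total is
    ``round(appt_rate * list_size / 1000)`` and the cell allocation inverts
    the measure definitions with largest-remainder rounding. Month-to-month
    noise and the month's triage state are applied beforehand via
    :func:`monthly_profile`.
    """
    if profile.triage_user is None:
        raise ValueError(
            "realize_counts needs a month-level profile; use monthly_profile()"
        )
    result = _allocate(profile.targets, profile.triage_user)
    if result is None:
        raise InfeasibleProfile(
            f"targets for {profile.practice_id} are mutually unsatisfiable"
        )
    cells, _ = result
    total = int(round(profile.targets["appt_rate"] * profile.list_size / 1000.0))
    keys = sorted(cells)
    counts = _largest_remainder([cells[k] for k in keys], total)
    if profile.triage_user:
        # the monthly 0/1 triage measure needs at least one triage row
        tr_idx = [i for i, k in enumerate(keys) if k[2] == "triage"]
        if tr_idx and not any(counts[i] for i in tr_idx):
            donor = int(np.argmax(counts))
            if counts[donor] > 1:
                counts[donor] -= 1
                counts[tr_idx[0]] += 1
    rows = [
        {
            "practice_id": profile.practice_id,
            "month": month,
            "hcp_type": hcp,
            "mode": mode,
            "wait_band": band,
            "national_category": CATEGORY_OF_LABEL[label],
            "count": n,
        }
        for (hcp, mode, label, band), n in zip(keys, counts)
        if n > 0
    ]
    return pd.DataFrame(rows, columns=APPOINTMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Profile sampling
# ---------------------------------------------------------------------------

PROPORTION_ORDER = [
    "p_gp", "p_tel", "p_tel_gp", "p_annot_sameday", "p_annot_routine",
    "p_gp_annot_sameday", "p_tel_annot_sameday", "p_sameday_gp",
    "p_booked_gt1wk", "p_routine_within1",
]


def _renormalise_no_triage(t: dict[str, float]) -> dict[str, float]:
    """Month targets with the triage-labelled mass folded into the
    same-day/routine shares (a triage-free month)."""
    out = dict(t)
    s, r = t["p_annot_sameday"], t["p_annot_routine"]
    tot = s + r
    if tot <= 0:
        out["p_annot_sameday"], out["p_annot_routine"] = 0.0, 1.0
    else:
        out["p_annot_sameday"], out["p_annot_routine"] = s / tot, r / tot
    # keep the pinned same-day sub-shares inside the rescaled share
    out["p_gp_annot_sameday"] = min(t["p_gp_annot_sameday"], out["p_annot_sameday"])
    out["p_tel_annot_sameday"] = min(t["p_tel_annot_sameday"], out["p_annot_sameday"])
    return out


def _draw_targets(
    params: ClusterParams,
    coverage: float,
    rng: np.random.Generator,
    raw_means: dict[str, float] | None = None,
) -> dict[str, float]:
    """Independent truncated-normal draws of every measure from its
    cluster's marginal; constraint repair happens afterwards.

    ``raw_means`` are the (possibly calibration-adjusted) means the raw
    draws use; the published cluster means are what the repaired draws
    should average to.
    """
    m = raw_means if raw_means is not None else params.measure_means
    sd = params.measure_sds
    t: dict[str, float] = {"coverage": coverage}
    for key in PROPORTION_ORDER:
        t[key] = _tn(rng, m[key], sd[key], 0.0, 1.0)
    t["appt_rate"] = _tn(rng, m["appt_rate"], sd["appt_rate"], 50.0, 5000.0)
    return _repair_targets(t)


_CALIBRATION_CACHE: dict[tuple, dict[str, float]] = {}


def _calibrated_raw_means(
    params: ClusterParams, config: "SyntheticConfig"
) -> dict[str, float]:
    """Raw draw means adjusted so that post-repair cluster means match the
    configured (published) values.

    Constraint repair clips draws against each other, which would otherwise
    pull realised cluster means a few hundredths away from the stated
    conditions. A short seeded fixed-point iteration (simulate draws,
    measure the shift, compensate) removes the bias; the result is cached
    per parameter set.
    """
    key = (
        tuple(sorted(params.measure_means.items())),
        tuple(sorted(params.measure_sds.items())),
        round(config.coverage_mean, 6),
        round(config.coverage_sd, 6),
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(987654321)
    raw = dict(params.measure_means)
    n_sim = 1500
    for _ in range(3):
        sums = {k: 0.0 for k in PROPORTION_ORDER}
        count = 0
        for _ in range(n_sim):
            cov = _tn(rng, config.coverage_mean, config.coverage_sd, 0.6, 0.999)
            t = _draw_targets(params, cov, rng, raw_means=raw)
            resolved = _allocate(t, True, repair=True)
            if resolved is None:
                continue
            count += 1
            for k in PROPORTION_ORDER:
                sums[k] += resolved[1][k]
        for k in PROPORTION_ORDER:
            realised = sums[k] / max(count, 1)
            raw[k] = float(
                np.clip(raw[k] + (params.measure_means[k] - realised), 0.0, 1.0)
            )
    _CALIBRATION_CACHE[key] = raw
    return raw


def sample_practice_profile(
    config: SyntheticConfig,
    rng: np.random.Generator,
    practice_id: str = "P0001",
    max_attempts: int = 1000,
) -> PracticeProfile:
    """Draw one practice: latent cluster, feasible targets, covariates.

    Target vectors whose joint allocation is unsatisfiable are redrawn
    (the truncation intervals make that rare); more than ``max_attempts``
    rejections is an error naming the practice.
    """
    cluster = SAMEDAY if rng.random() < config.mixture_weight_sameday else ROUTINE
    params = config.clusters[cluster]
    raw_means = _calibrated_raw_means(params, config)
    targets = None
    for _ in range(max_attempts):
        coverage = _tn(rng, config.coverage_mean, config.coverage_sd, 0.6, 0.999)
        cand = _draw_targets(params, coverage, rng, raw_means=raw_means)
        # every month must be realisable, with or without triage recording;
        # repair nudges the wait-band-coupled targets onto the feasible set
        resolved = _allocate(cand, True, repair=True)
        if resolved is None:
            continue
        cand = resolved[1]
        if _allocate(_renormalise_no_triage(cand), False, repair=True) is not None:
            targets = cand
            break
    if targets is None:
        raise InfeasibleProfile(
            f"{practice_id}: no feasible target vector in {max_attempts} draws "
            "(joint wait-band/label constraints)"
        )
    sigma2 = math.log(1.0 + (params.list_size_sd / params.list_size_mean) ** 2)
    mu = math.log(params.list_size_mean) - sigma2 / 2.0
    list_size = max(int(round(rng.lognormal(mu, math.sqrt(sigma2)))), 1200)

    regions = list(params.region_probs)
    region = regions[rng.choice(len(regions), p=np.array(list(params.region_probs.values())) / sum(params.region_probs.values()))]
    imd_p = np.array(params.imd_probs) / sum(params.imd_probs)
    imd = float(rng.choice(np.arange(1, 6), p=imd_p))
    if rng.random() < config.imd_missing_rate:
        imd = float("nan")
    age = rng.dirichlet(np.array(params.age_band_means) * 60.0)
    covariates = {
        "region": region,
        "rural_urban": "rural" if rng.random() < params.rural_prob else "urban",
        "imd_quintile": imd,
        "white_share": _tn(rng, params.white_mean, params.white_sd, 0.0, 1.0),
        "age_bands": age,
        "mean_age": float(age @ AGE_MIDPOINTS),
    }
    if rng.random() < config.workforce_missing_rate:
        covariates["fte"] = {k: float("nan") for k in params.fte_means}
    else:
        covariates["fte"] = {
            k: _tn(rng, params.fte_means[k], params.fte_sds[k], 0.0, 60.0)
            for k in params.fte_means
        }
    return PracticeProfile(
        practice_id=practice_id,
        cluster=cluster,
        targets=targets,
        triage_prob=params.triage_prob,
        list_size=list_size,
        covariates=covariates,
    )


def monthly_profile(
    profile: PracticeProfile,
    rng: np.random.Generator,
    noise_sd: float,
    rate_noise_rel: float = 0.0,
    max_attempts: int = 50,
) -> PracticeProfile:
    """Month-level view of a practice: the month's 0/1 triage state plus
    noised, still-feasible targets.

    Triage recording is an independent Bernoulli draw per month with the
    practice's probability; in a triage-free month the annotated label
    shares are renormalised (no triage-labelled appointments exist). If no
    feasible noised vector is found the unperturbed targets are kept.
    """
    triage_on = bool(rng.random() < profile.triage_prob)
    base = profile.targets if triage_on else _renormalise_no_triage(profile.targets)
    for _ in range(max_attempts):
        t = dict(base)
        for key in PROPORTION_ORDER:
            if noise_sd > 0:
                t[key] = _tn(rng, t[key], noise_sd, 0.0, 1.0)
        if rate_noise_rel > 0:
            t["appt_rate"] = float(t["appt_rate"] * rng.normal(1.0, rate_noise_rel))
        resolved = _allocate(_repair_targets(t), triage_on, repair=True)
        if resolved is not None:
            return dc_replace(profile, targets=resolved[1], triage_user=triage_on)
    return dc_replace(profile, targets=dict(base), triage_user=triage_on)


def monthly_target(profile: PracticeProfile) -> dict[str, float]:
    """The 12-measure target vector a realized month should reproduce."""
    return profile.target_measures()


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """In-memory synthetic dataset: appointments (per month), registry,
    annotation dictionary, standard categories, ground truth and defects."""

    config: SyntheticConfig
    profiles: list[PracticeProfile]
    appointments: pd.DataFrame  # training window months
    holdout_appointments: pd.DataFrame | None
    registry: pd.DataFrame
    annotation_dictionary: AnnotationDictionary
    standard_categories: set[str]
    truth: pd.DataFrame  # practice_id, cluster, triage_prob
    defects: pd.DataFrame  # practice_id, defect

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as CSV/text files; byte-stable given the seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        months = list(self.config.months)
        frames = {m: self.appointments[self.appointments["month"] == m] for m in months}
        if self.holdout_appointments is not None:
            frames[self.config.holdout_month] = self.holdout_appointments
        for month, frame in frames.items():
            p = out / f"appointments_{month}.csv"
            frame.to_csv(p, index=False)
            paths[f"appointments_{month}"] = p
        p = out / "registry.csv"
        self.registry.to_csv(p, index=False, float_format="%.10g")
        paths["registry"] = p
        p = out / "annotation_dictionary.csv"
        self.annotation_dictionary.write(p)
        paths["annotation_dictionary"] = p
        p = out / "standard_categories.txt"
        p.write_text("\n".join(sorted(self.standard_categories)) + "\n")
        paths["standard_categories"] = p
        p = out / "truth_labels.csv"
        self.truth.to_csv(p, index=False)
        paths["truth_labels"] = p
        p = out / "defect_ledger.csv"
        self.defects.to_csv(p, index=False)
        paths["defect_ledger"] = p
        return paths


def _registry_frame(profiles: list[PracticeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        cov = p.covariates
        row = {
            "practice_id": p.practice_id,
            "list_size": p.list_size,
            "region": cov["region"],
            "rural_urban": cov["rural_urban"],
            "imd_quintile": cov["imd_quintile"],
            "mean_age": cov["mean_age"],
        }
        for name, share in zip(
            ["age_under20", "age_20_49", "age_50_64", "age_65_79", "age_80_plus"],
            cov["age_bands"],
        ):
            row[name] = share
        row["white_share"] = cov["white_share"]
        for role, fte in cov["fte"].items():
            row[f"fte_{role}"] = fte
        rows.append(row)
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def generate_dataset(
    config: SyntheticConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate a full synthetic bundle, optionally writing it to disk.

    Fully reproducible from ``config.master_seed``: profiles, monthly
    noise, the holdout month and injected defects all flow from one
    generator.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.master_seed)
    width = max(4, len(str(config.n_practices)))
    profiles = [
        sample_practice_profile(config, rng, practice_id=f"P{i + 1:0{width}d}")
        for i in range(config.n_practices)
    ]
    month_frames = []
    for month in config.months:
        for profile in profiles:
            monthly = monthly_profile(
                profile, rng, config.month_noise_sd, config.rate_noise_rel
            )
            month_frames.append(realize_counts(monthly, month))
    appointments = pd.concat(month_frames, ignore_index=True)
    holdout = None
    if config.holdout_month is not None:
        frames = []
        for profile in profiles:
            noised = monthly_profile(
                profile, rng, config.holdout_noise_sd, config.rate_noise_rel
            )
            frames.append(realize_counts(noised, config.holdout_month))
        holdout = pd.concat(frames, ignore_index=True)
    registry = _registry_frame(profiles)
    truth = pd.DataFrame(
        {
            "practice_id": [p.practice_id for p in profiles],
            "cluster": [p.cluster for p in profiles],
            "triage_prob": [p.triage_prob for p in profiles],
        }
    )
    bundle = SyntheticBundle(
        config=config,
        profiles=profiles,
        appointments=appointments,
        holdout_appointments=holdout,
        registry=registry,
        annotation_dictionary=AnnotationDictionary(
            entries=dict(ANNOTATION_ENTRIES), source="synthetic"
        ),
        standard_categories=set(STANDARD_CATEGORIES),
        truth=truth,
        defects=pd.DataFrame(columns=["practice_id", "defect"]),
    )
    bundle = inject_quality_issues(bundle, config, rng)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Quality-defect injection
# ---------------------------------------------------------------------------

def _dilute_categories(
    df: pd.DataFrame, pid: str, replacement: str, target_share: float, eligible
) -> pd.DataFrame:
    """Re-categorise rows of one practice until ``target_share`` of its
    counts carry ``replacement``; returns the modified frame."""
    mask = df["practice_id"] == pid
    sub = df.loc[mask]
    for month in sub["month"].unique():
        msub = sub[sub["month"] == month]
        total = msub["count"].sum()
        need = int(math.ceil(target_share * total))
        have = 0
        for idx in msub.index:
            if have >= need:
                break
            if not eligible(df.loc[idx, "national_category"]):
                continue
            df.loc[idx, "national_category"] = replacement
            have += int(df.loc[idx, "count"])
    return df


def inject_quality_issues(
    bundle: SyntheticBundle, config: SyntheticConfig, rng: np.random.Generator
) -> SyntheticBundle:
    """Alter designated practices to violate exactly one cleaning rule each.

    Defect types: ``small_list`` (list size drawn below 1000, counts scaled
    to keep the rate plausible), ``rate_outlier`` (counts inflated past the
    monthly threshold), ``unmapped`` (categories replaced by an off-list
    string for >10% of counts), ``low_annotation`` (annotated share diluted
    below 50%). The same alterations are applied to the holdout month, and
    a ground-truth defect ledger is attached.
    """
    n = config.n_practices
    counts = {
        "small_list": round(config.defect_rate_small_list * n),
        "rate_outlier": round(config.defect_rate_rate_outlier * n),
        "unmapped": round(config.defect_rate_unmapped * n),
        "low_annotation": round(config.defect_rate_low_annotation * n),
    }
    total_defects = sum(counts.values())
    if total_defects == 0:
        return bundle
    ids = [p.practice_id for p in bundle.profiles]
    chosen = rng.choice(len(ids), size=total_defects, replace=False)
    assignments: list[tuple[str, str]] = []
    it = iter(chosen)
    for defect, k in counts.items():
        for _ in range(k):
            assignments.append((ids[int(next(it))], defect))

    appts = bundle.appointments.copy()
    holdout = (
        bundle.holdout_appointments.copy()
        if bundle.holdout_appointments is not None
        else None
    )
    registry = bundle.registry.copy().set_index("practice_id", drop=False)

    for pid, defect in assignments:
        if defect == "small_list":
            old = int(registry.loc[pid, "list_size"])
            new = int(rng.integers(200, 900))
            registry.loc[pid, "list_size"] = new
            factor = new / old
            for frame in (appts, holdout):
                if frame is None:
                    continue
                m = frame["practice_id"] == pid
                frame.loc[m, "count"] = (
                    (frame.loc[m, "count"] * factor).round().astype(int).clip(lower=0)
                )
        elif defect == "rate_outlier":
            # inflate counts so the monthly rate clearly exceeds the
            # 1500-per-1000 screen regardless of the practice's baseline
            list_size = int(registry.loc[pid, "list_size"])
            m = appts["practice_id"] == pid
            months_present = appts.loc[m, "month"].nunique()
            rate = (
                appts.loc[m, "count"].sum() / months_present / list_size * 1000.0
            )
            factor = max(1950.0 / max(rate, 1e-9), 1.0)
            for frame in (appts, holdout):
                if frame is None:
                    continue
                sel = frame["practice_id"] == pid
                frame.loc[sel, "count"] = (
                    (frame.loc[sel, "count"] * factor).round().astype(int)
                )
        elif defect == "unmapped":
            for frame in (appts, holdout):
                if frame is None:
                    continue
                _dilute_categories(
                    frame, pid, OFF_LIST_CATEGORY, 0.20, lambda cat: True
                )
        elif defect == "low_annotation":
            annotated_cats = {
                c for c, lab in ANNOTATION_ENTRIES.items() if lab != "unknown"
            }
            for frame in (appts, holdout):
                if frame is None:
                    continue
                _dilute_categories(
                    frame,
                    pid,
                    CATEGORY_OF_LABEL["unknown"],
                    0.60,
                    lambda cat: cat in annotated_cats,
                )

    # merge duplicate keys created by re-categorisation
    appts = (
        appts.groupby(APPOINTMENT_COLUMNS[:-1], as_index=False, sort=False)["count"]
        .sum()
    )
    if holdout is not None:
        holdout = (
            holdout.groupby(APPOINTMENT_COLUMNS[:-1], as_index=False, sort=False)[
                "count"
            ].sum()
        )
    defects = pd.DataFrame(sorted(assignments), columns=["practice_id", "defect"])
    return dc_replace(
        bundle,
        appointments=appts,
        holdout_appointments=holdout,
        registry=registry.reset_index(drop=True),
        defects=defects,
    )
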