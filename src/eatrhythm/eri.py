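"""The Eating Regularity Index (ERI).

The ERI quantifies how consistently an infant eats at the same clock times
from day to day.  Each diary day is turned into a binary vector over
15-minute epochs (96 entries per 24-h day) with a 1 wherever a meal
starts.  A simple moving average (SMA) of width ``k`` epochs is applied
twice with circular wrap-around, spreading each meal into a small
triangular bump so that near-miss timings still overlap.  Every pair of
days within a subject x assessment is compared by cosine similarity, and
the ERI is the mean over all pairs: 0 = highly irregular, 1 = highly
regular (identical timing every day).

Days without any recorded meal are dropped before smoothing (cosine
similarity is undefined for a zero vector); subjects with fewer than
``min_days`` retained days are excluded from analysis.  Two meal-pattern
covariates accompany the index: the mean number of meals per retained day
and the fraction of meals starting in the daytime window [07:00, 19:00).

The SMA width is a tuning constant; :func:`select_sma_interval` reproduces
the selection procedure, picking the width that maximises between-subject
ERI variability per age group (majority vote across groups, ties towards
the smaller width).  Width 4 (one hour) is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DiaryDay, MealDiary

__all__ = [
    "ERIResult",
    "SmaSelection",
    "binarize_day",
    "sma",
    "double_sma",
    "cosine_similarity",
    "compute_eri",
    "compute_eri_table",
    "select_sma_interval",
    "DAYTIME_WINDOW",
]

#: half-open daytime window in minutes since midnight: [07:00, 19:00)
DAYTIME_WINDOW = (420, 1140)


@dataclass
class ERIResult:
    """ERI and meal covariates for one subject x assessment."""

    subject_id: str
    age: float
    eri: float  # NaN when excluded
    n_days_used: int
    pairwise_similarities: list[tuple[int, int, float]] = field(default_factory=list)
    mean_meals_per_day: float = float("nan")
    daytime_meal_ratio: float = float("nan")
    excluded: bool = False
    reason: str = ""


@dataclass
class SmaSelection:
    """Between-subject ERI standard deviation per (age group, SMA width)."""

    table: pd.DataFrame  # columns: age, k, sd, n_subjects
    chosen_k: int
    per_age_best: dict[float, int] = field(default_factory=dict)


def binarize_day(day: DiaryDay | np.ndarray, epoch_minutes: int = 15) -> np.ndarray:
    """Binary epoch profile of one day: 1 where at least one meal starts.

    Multiple meals falling in the same epoch still give a 1 (the profile
    is binary, not a count).  An empty day gives the all-zero vector.
    """
    if 1440 % epoch_minutes != 0:
        raise ValueError("epoch_minutes must divide 1440")
    n_epochs = 1440 // epoch_minutes
    meals = day.meals if isinstance(day, DiaryDay) else np.asarray(day, dtype=int)
    profile = np.zeros(n_epochs, dtype=float)
    if meals.size:
        if meals.min() < 0 or meals.max() >= 1440:
            raise ValueError("meal times must lie in [0, 1440)")
        profile[meals // epoch_minutes] = 1.0
    return profile


def sma(profile: np.ndarray, k: int) -> np.ndarray:
    """One circular simple-moving-average pass with a width-``k`` kernel.

    The window covers epochs ``[t - floor((k-1)/2), t + ceil((k-1)/2)]``
    (left-biased centre for even widths), indices modulo the profile
    length, so smoothing wraps across midnight.  Total mass is conserved.
    Works on a single profile or row-wise on a (days x epochs) matrix.
    """
    profile = np.asarray(profile, dtype=float)
    n_epochs = profile.shape[-1]
    if not 1 <= k <= n_epochs:
        raise ValueError(f"SMA width k={k} must be in [1, {n_epochs}]")
    lo = (k - 1) // 2
    acc = np.zeros_like(profile)
    for j in range(-lo, k - lo):
        acc += np.roll(profile, -j, axis=-1)
    return acc / k


def double_sma(profile: np.ndarray, k: int) -> np.ndarray:
    """Two identical SMA passes; neighbours of a meal epoch receive weight
    decaying with distance (a triangular bump for a single meal)."""
    return sma(sma(profile, k), k)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two epoch profiles, in [0, 1] for
    non-negative profiles.  Undefined (raises) for a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(a, b) / (na * nb))


def _day_matrix(diary: MealDiary, epoch_minutes: int) -> tuple[np.ndarray, list[int]]:
    """Stack binary day profiles, returning the matrix of non-empty days
    and the indices of the days that were retained."""
    profiles, kept = [], []
    for i, day in enumerate(diary.days):
        if day.meals.size == 0:
            continue
        profiles.append(binarize_day(day, epoch_minutes))
        kept.append(i)
    if not profiles:
        return np.zeros((0, 1440 // epoch_minutes)), kept
    return np.vstack(profiles), kept


def compute_eri(
    diary: MealDiary,
    k: int = 4,
    epoch_minutes: int = 15,
    min_days: int = 5,
) -> ERIResult:
    """ERI for one subject x assessment.

    Zero-meal days are dropped (with the reason recorded); if fewer than
    ``min_days`` days remain the subject x assessment is excluded and no
    index is produced.  Otherwise the ERI is the mean cosine similarity
    over all C(n, 2) day pairs of double-SMA profiles.
    """
    if min_days < 2:
        raise ValueError("min_days must be >= 2 (no day pairs otherwise)")
    binary, kept = _day_matrix(diary, epoch_minutes)
    n_dropped = diary.n_days - len(kept)
    if len(kept) < min_days:
        reason = f"only {len(kept)} non-empty diary days (need >= {min_days})"
        if n_dropped:
            reason += f"; {n_dropped} zero-meal day(s) dropped"
        return ERIResult(
            diary.subject_id, diary.age_months, float("nan"),
            len(kept), [], float("nan"), float("nan"), True, reason,
        )

    smoothed = double_sma(binary, k)
    norms = np.linalg.norm(smoothed, axis=1)
    unit = smoothed / norms[:, None]
    gram = unit @ unit.T
    iu, ju = np.triu_indices(len(kept), 1)
    sims = np.clip(gram[iu, ju], 0.0, 1.0)
    pairs = [(kept[i], kept[j], float(s)) for i, j, s in zip(iu, ju, sims)]

    n_meals = binary.sum(axis=1)
    all_meals = np.concatenate([diary.days[i].meals for i in kept])
    lo, hi = DAYTIME_WINDOW
    daytime = float(np.mean((all_meals >= lo) & (all_meals < hi)))
    reason = f"{n_dropped} zero-meal day(s) dropped" if n_dropped else ""
    return ERIResult(
        diary.subject_id,
        diary.age_months,
        float(sims.mean()),
        len(kept),
        pairs,
        float(n_meals.mean()),
        daytime,
        False,
        reason,
    )


def compute_eri_table(
    diaries: list[MealDiary],
    k: int = 4,
    epoch_minutes: int = 15,
    min_days: int = 5,
) -> pd.DataFrame:
    """ERI results for a cohort as a tidy table, one row per
    subject x assessment (excluded rows carry NaN and the reason)."""
    rows = []
    for diary in diaries:
        res = compute_eri(diary, k=k, epoch_minutes=epoch_minutes, min_days=min_days)
        rows.append(
            dict(
                subject_id=res.subject_id,
                age=res.age,
                eri=res.eri,
                n_days_used=res.n_days_used,
                mean_meals_per_day=res.mean_meals_per_day,
                daytime_meal_ratio=res.daytime_meal_ratio,
                excluded=res.excluded,
                reason=res.reason,
            )
        )
    return pd.DataFrame(rows)


def select_sma_interval(
    diaries: list[MealDiary],
    candidate_ks: list[int],
    epoch_minutes: int = 15,
    min_days: int = 5,
) -> SmaSelection:
    """Choose the SMA width maximising between-subject ERI variability.

    For every candidate width and age group the ERI of all included
    subjects is computed and the between-subject standard deviation
    recorded.  The chosen width is the one that attains the per-age
    maximum SD in the most age groups; ties resolve to the smallest
    width.
    """
    if not candidate_ks:
        raise ValueError("candidate_ks must be non-empty")
    ages = sorted({d.age_months for d in diaries})
    rows = []
    best_per_age: dict[float, int] = {}
    for age in ages:
        group = [d for d in diaries if d.age_months == age]
        sds = {}
        for k in sorted(candidate_ks):
            eris = [
                r.eri
                for d in group
                if not (r := compute_eri(d, k, epoch_minutes, min_days)).excluded
            ]
            if len(eris) < 2:
                raise ValueError(
                    f"age group {age}: need >= 2 included subjects, got {len(eris)}"
                )
            sd = float(np.std(eris, ddof=1))
            sds[k] = sd
            rows.append(dict(age=age, k=k, sd=sd, n_subjects=len(eris)))
        best_sd = max(sds.values())
        best_per_age[age] = min(k for k, s in sds.items() if s == best_sd)

    votes = pd.Series(list(best_per_age.values())).value_counts()
    top = votes.max()
    chosen = int(min(k for k, v in votes.items() if v == top))
    return SmaSelection(pd.DataFrame(rows), chosen, best_per_age)
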