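"""Unit and property tests for the Eating Regularity Index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eatrhythm.eri import (
    binarize_day,
    compute_eri,
    cosine_similarity,
    double_sma,
    select_sma_interval,
    sma,
)
from eatrhythm.io import DiaryDay

from conftest import make_diary, random_diary

# ---------------------------------------------------------------------------
# independent oracle: naive pure-python recomputation


def naive_eri(diary, k, epoch_minutes=15, min_days=5):
    """Brute-force ERI: explicit loops, no shared code with the package
    beyond arithmetic."""
    E = 1440 // epoch_minutes
    lo = (k - 1) // 2
    profiles = []
    for day in diary.days:
        v = [0.0] * E
        for m in day.meals:
            v[m // epoch_minutes] = 1.0
        if sum(v) == 0:
            continue
        for _ in range(2):
            w = [sum(v[(t + j) % E] for j in range(-lo, k - lo)) / k
                 for t in range(E)]
            v = w
        profiles.append(v)
    if len(profiles) < min_days:
        return None
    sims = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i], profiles[j]
            dot = sum(x * y for x, y in zip(a, b))
            na = math.sqrt(sum(x * x for x in a))
            nb = math.sqrt(sum(x * x for x in b))
            sims.append(dot / (na * nb))
    return sum(sims) / len(sims)


# ---------------------------------------------------------------------------
# binarization


def test_binarize_maps_meals_to_epoch_indices():
    day = DiaryDay("d1", [0, 450])  # 00:00 and 07:30
    v = binarize_day(day, 15)
    assert v.shape == (96,)
    assert v[0] == 1 and v[30] == 1
    assert v.sum() == 2


def test_binarize_is_binary_for_coincident_meals():
    # two meals in the same epoch still produce a 1, not a 2
    day = DiaryDay("d1", [450, 450])
    assert binarize_day(day, 15).max() == 1


def test_binarize_empty_day_is_zero_vector():
    v = binarize_day(DiaryDay("d1", []), 15)
    assert v.shape == (96,) and v.sum() == 0


# ---------------------------------------------------------------------------
# smoothing


def test_sma_width_one_is_identity(rng):
    v = rng.random(96)
    assert np.allclose(double_sma(v, 1), v)


def test_single_pass_spreads_impulse_over_k_epochs():
    v = np.zeros(96)
    v[50] = 1.0
    out = sma(v, 4)
    # window [t-1, t+2]: the impulse contributes to t in [48, 51]
    assert np.allclose(out[48:52], 0.25)
    assert out.sum() == pytest.approx(1.0)
    assert np.count_nonzero(out) == 4


def test_double_pass_gives_triangular_profile():
    v = np.zeros(96)
    v[50] = 1.0
    out = double_sma(v, 4)
    # hand double-convolution: support [m-4, m+2], weights /16
    expected = np.array([1, 2, 3, 4, 3, 2, 1]) / 16.0
    assert np.allclose(out[46:53], expected)
    assert out.sum() == pytest.approx(1.0)
    # closer epochs have higher values on both flanks
    assert out[49] > out[48] > out[47] > out[46]


def test_smoothing_wraps_across_midnight():
    v = np.zeros(96)
    v[0] = 1.0  # meal at 00:00
    out = double_sma(v, 4)
    assert out[95] > 0 and out[92] > 0  # mass before midnight
    assert out.sum() == pytest.approx(1.0)


def test_sma_rejects_kernel_wider_than_day():
    with pytest.raises(ValueError):
        sma(np.zeros(96), 97)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 95), min_size=1, max_size=10, unique=True),
       st.integers(1, 12))
def test_mass_conserved_through_double_smoothing(epochs, k):
    v = np.zeros(96)
    v[epochs] = 1.0
    assert double_sma(v, k).sum() == pytest.approx(v.sum())


# ---------------------------------------------------------------------------
# cosine similarity


def test_cosine_of_identical_profiles_is_one(rng):
    v = rng.random(96) + 0.1
    assert cosine_similarity(v, v) == pytest.approx(1.0)


def test_cosine_of_disjoint_supports_is_zero():
    a = double_sma(binarize_day(DiaryDay("a", [150]), 15), 4)
    b = double_sma(binarize_day(DiaryDay("b", [720]), 15), 4)
    assert cosine_similarity(a, b) == pytest.approx(0.0)


def test_cosine_decreases_with_meal_offset():
    base = double_sma(binarize_day(DiaryDay("a", [10 * 15]), 15), 4)
    near = double_sma(binarize_day(DiaryDay("b", [12 * 15]), 15), 4)
    far = double_sma(binarize_day(DiaryDay("c", [20 * 15]), 15), 4)
    s_near = cosine_similarity(base, near)
    s_far = cosine_similarity(base, far)
    assert 0.0 < s_near < 1.0
    assert s_near > s_far


def test_cosine_rejects_zero_profile():
    with pytest.raises(ValueError):
        cosine_similarity(np.zeros(96), np.ones(96))


# ---------------------------------------------------------------------------
# compute_eri


def test_identical_days_score_one(identical_week_diary):
    res = compute_eri(identical_week_diary, k=4)
    assert not res.excluded
    assert res.eri == pytest.approx(1.0, abs=1e-12)
    assert res.n_days_used == 7
    assert res.mean_meals_per_day == pytest.approx(3.0)
    assert res.daytime_meal_ratio == pytest.approx(1.0)


def test_short_diary_is_excluded():
    diary = make_diary("S2", 6, [[480, 720]] * 4)
    res = compute_eri(diary, min_days=5)
    assert res.excluded
    assert math.isnan(res.eri)
    assert "4" in res.reason


def test_zero_meal_days_are_dropped_and_logged():
    diary = make_diary("S3", 6, [[480]] * 5 + [[]])
    res = compute_eri(diary, min_days=5)
    assert not res.excluded
    assert res.n_days_used == 5
    assert "zero-meal" in res.reason


def test_three_day_mixed_similarity_against_pair_enumeration():
    # days 1-2 identical, day 3 far away: ERI = (1 + s + s) / 3
    diary = make_diary("S4", 6, [[480], [480], [1200]])
    res = compute_eri(diary, k=4, min_days=3)
    s = cosine_similarity(
        double_sma(binarize_day(DiaryDay("x", [480]), 15), 4),
        double_sma(binarize_day(DiaryDay("y", [1200]), 15), 4),
    )
    assert res.eri == pytest.approx((1.0 + 2 * s) / 3.0, abs=1e-12)


def test_min_days_below_two_rejected(identical_week_diary):
    with pytest.raises(ValueError):
        compute_eri(identical_week_diary, min_days=1)


def test_eri_matches_naive_oracle_on_random_diaries(rng):
    for i in range(25):
        diary = random_diary(rng, f"R{i}", n_days=int(rng.integers(5, 10)))
        for k in (1, 3, 4):
            res = compute_eri(diary, k=k)
            expected = naive_eri(diary, k)
            if expected is None:
                assert res.excluded
            else:
                assert res.eri == pytest.approx(expected, abs=1e-10)


def test_eri_invariant_to_day_order_and_rotation(rng):
    diary = random_diary(rng, n_days=7)
    base = compute_eri(diary, k=4).eri

    reordered = make_diary("r", 6, [d.meals.tolist() for d in diary.days[::-1]])
    assert compute_eri(reordered, k=4).eri == pytest.approx(base, abs=1e-12)

    shift = 6 * 60  # rotate every day by 6 hours
    rotated = make_diary(
        "s", 6, [sorted((d.meals + shift) % 1440) for d in diary.days]
    )
    assert compute_eri(rotated, k=4).eri == pytest.approx(base, abs=1e-12)


def test_eri_bounded_zero_one(rng):
    for i in range(10):
        res = compute_eri(random_diary(rng, f"B{i}", n_days=6), k=4)
        if not res.excluded:
            assert 0.0 <= res.eri <= 1.0


# ---------------------------------------------------------------------------
# SMA interval selection


def test_degenerate_cohort_selects_smallest_candidate():
    # every subject perfectly regular: SD = 0 for all k -> tie -> min k
    diaries = [make_diary(f"S{i}", 6, [[480 + 60 * i, 900]] * 6) for i in range(4)]
    sel = select_sma_interval(diaries, [2, 3, 4])
    assert (sel.table["sd"] == 0).all()
    assert sel.chosen_k == 2


def test_majority_rule_across_age_groups(monkeypatch):
    import eatrhythm.eri as eri_mod

    # synthetic SD tables: ages 3 and 6 peak at k=4, age 12 at k=3
    peaks = {3.0: 4, 6.0: 4, 12.0: 3}

    def fake_compute(diary, k, epoch_minutes=15, min_days=5):
        sd_peak = peaks[diary.age_months]
        # spread subjects so SD is maximal at the designated k
        spread = 0.1 if k == sd_peak else 0.01
        idx = int(diary.subject_id[1:])
        return eri_mod.ERIResult(diary.subject_id, diary.age_months,
                                 0.5 + spread * idx, 6)

    monkeypatch.setattr(eri_mod, "compute_eri", fake_compute)
    diaries = [make_diary(f"S{i}", a, [[480]] * 6)
               for a in (3, 6, 12) for i in range(3)]
    sel = eri_mod.select_sma_interval(diaries, [3, 4, 5])
    assert sel.chosen_k == 4
    assert sel.per_age_best == {3.0: 4, 6.0: 4, 12.0: 3}


def test_empty_candidate_list_rejected():
    with pytest.raises(ValueError):
        select_sma_interval([], [])
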