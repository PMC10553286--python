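import numpy as np
import pytest

from eatrhythm.io import DiaryDay, MealDiary


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_diary(subject_id, age, day_meals):
    """Build a MealDiary from a list of per-day meal-minute lists."""
    days = [DiaryDay(date=f"d{i+1:02d}", meals=np.array(m, dtype=int))
            for i, m in enumerate(day_meals)]
    return MealDiary(subject_id, age, days)


@pytest.fixture
def identical_week_diary():
    """Seven days with meals at 08:00, 12:00 and 16:00 every day."""
    return make_diary("S1", 6, [[480, 720, 960]] * 7)


def random_diary(rng, subject_id="R1", age=6, n_days=8, n_meals=5,
                 epoch_minutes=15):
    """A diary with meals at random epochs (possibly sparse days)."""
    day_meals = []
    for _ in range(n_days):
        m = rng.integers(0, 1440 // epoch_minutes, size=rng.integers(1, n_meals + 1))
        day_meals.append(sorted(set(int(e) * epoch_minutes for e in m)))
    return make_diary(subject_id, age, day_meals)
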