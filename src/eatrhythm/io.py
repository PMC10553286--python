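"""Readers and writers for the tabular inputs of the eating-rhythm pipeline.

Five kinds of files move through the pipeline:

* meal diaries  — CSV, one row per reported meal start
                  (``subject_id, age_months, date, meal_start``);
* sleep composites — CSV, one row per subject x assessment with the five
                  composite scores;
* covariates    — CSV with sex, exact age, breastfeeding and the parental
                  Structure score;
* taxa tables   — TSV, taxa x samples integer counts, plus a sample
                  metadata CSV;
* phylogenies   — newick with branch lengths (required for UniFrac).

All readers validate rather than coerce: structural problems (missing
columns, zero-sum samples, missing branch lengths) raise, and malformed
diary rows are collected as :class:`RowError` entries with line numbers so
the caller can report them.  Every accepted file round-trips through the
matching writer byte-identically.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "DiaryDay",
    "MealDiary",
    "RowError",
    "COMPOSITE_COLUMNS",
    "COVARIATE_COLUMNS",
    "read_meal_diary",
    "write_meal_diary",
    "read_composites",
    "write_composites",
    "read_covariates",
    "write_covariates",
    "read_taxa_table",
    "write_taxa_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_tree",
]

#: the five actigraphy-derived sleep composites, in canonical column order
COMPOSITE_COLUMNS = [
    "SleepActivity",
    "SleepDay",
    "SleepNight",
    "SleepTiming",
    "SleepVariability",
]

#: covariates used as control variables in every association model;
#: sex is coded 0 = male / 1 = female, breastfeeding 0 = not or rarely /
#: 1 = occasionally, regularly or daily breastfed
COVARIATE_COLUMNS = [
    "sex",
    "exact_age",
    "breastfeeding",
    "structure_score",
]

DIARY_COLUMNS = ["subject_id", "age_months", "date", "meal_start"]


@dataclass
class DiaryDay:
    """A single assessment day: date label plus meal-start clock times.

    Times are minutes since midnight, already snapped to the epoch grid.
    The date is an opaque label; day ordering follows file order.
    """

    date: str
    meals: np.ndarray

    def __post_init__(self) -> None:
        self.meals = np.asarray(self.meals, dtype=int)
        if self.meals.size and (self.meals.min() < 0 or self.meals.max() >= 1440):
            raise ValueError("meal times must lie in [0, 1440) minutes")


@dataclass
class MealDiary:
    """All recorded days for one subject at one assessment age."""

    subject_id: str
    age_months: float
    days: list[DiaryDay] = field(default_factory=list)

    @property
    def n_days(self) -> int:
        return len(self.days)


@dataclass
class RowError:
    """A rejected input row: 1-based line number and the reason."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _parse_clock(text: str) -> int:
    """Parse ``HH:MM`` into minutes since midnight; raises on anything else."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"unparseable clock time {text!r} (expected HH:MM)")
    hh, mm = int(parts[0]), int(parts[1])
    minute = 60 * hh + mm
    if not (0 <= hh and 0 <= mm < 60 and minute < 1440):
        raise ValueError(f"clock time {text!r} out of range [00:00, 24:00)")
    return minute


def read_meal_diary(
    path: str | Path, epoch_minutes: int = 15
) -> tuple[list[MealDiary], list[RowError]]:
    """Read a meal-diary CSV into per-subject, per-assessment diaries.

    Times are snapped to the start of their epoch (floor), duplicate
    (subject, date, epoch) entries are collapsed, and a row with an empty
    ``meal_start`` registers a recorded day with zero meals.  Malformed
    rows are returned as :class:`RowError` entries rather than raised.
    """
    if 1440 % epoch_minutes != 0:
        raise ValueError("epoch_minutes must divide 1440")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DIARY_COLUMNS, "meal diary")

    errors: list[RowError] = []
    # keyed by (subject, age) then date, preserving first-seen order
    diaries: dict[tuple[str, float], dict[str, list[int]]] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        sid = str(row.subject_id).strip()
        try:
            age = float(row.age_months)
        except ValueError:
            errors.append(RowError(line, f"unparseable age {row.age_months!r}"))
            continue
        date = str(row.date).strip()
        if not sid or not date:
            errors.append(RowError(line, "empty subject_id or date"))
            continue
        key = (sid, age)
        days = diaries.setdefault(key, {})
        meals = days.setdefault(date, [])
        raw = str(row.meal_start).strip()
        if raw == "":
            continue  # zero-meal day marker
        try:
            minute = _parse_clock(raw)
        except ValueError as exc:
            errors.append(RowError(line, str(exc)))
            continue
        epoch_start = minute - minute % epoch_minutes
        if epoch_start not in meals:
            meals.append(epoch_start)

    cohort = [
        MealDiary(sid, age, [DiaryDay(d, sorted(m)) for d, m in days.items()])
        for (sid, age), days in diaries.items()
    ]
    return cohort, errors


def write_meal_diary(diaries: Sequence[MealDiary], path: str | Path) -> None:
    rows = []
    for diary in diaries:
        age = f"{float(diary.age_months):g}"
        for day in diary.days:
            if day.meals.size == 0:
                rows.append((diary.subject_id, age, day.date, ""))
            for minute in day.meals:
                clock = f"{minute // 60:02d}:{minute % 60:02d}"
                rows.append((diary.subject_id, age, day.date, clock))
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def _read_numeric_table(
    path: str | Path, required: Sequence[str], what: str
) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "age", *required], what)
    for col in ("age", *required):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{what}: column {col!r} is not numeric")
        if df[col].isna().any():
            raise ValueError(f"{what}: column {col!r} contains missing values")
    return df


def read_composites(path: str | Path) -> pd.DataFrame:
    """Sleep-composite table: subject_id, age, and the five composites."""
    return _read_numeric_table(path, COMPOSITE_COLUMNS, "composites")


def write_composites(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table; validates the 0/1 coding of sex and breastfeeding."""
    df = _read_numeric_table(path, COVARIATE_COLUMNS, "covariates")
    for col in ("sex", "breastfeeding"):
        bad = ~df[col].isin([0, 1])
        if bad.any():
            raise ValueError(
                f"covariates: column {col!r} must be coded 0/1; "
                f"offending rows {df.index[bad].tolist()[:5]}"
            )
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_taxa_table(path: str | Path) -> pd.DataFrame:
    """Taxa x samples integer count table (TSV, taxa labels in column 1).

    Taxon labels carry rank annotations as ``Phylum|Genus``.  Negative
    counts and zero-sum sample columns are structural errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError("taxa table has no sample columns")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("taxa table contains non-numeric entries")
    if (values < 0).any():
        raise ValueError("taxa table contains negative counts")
    zero = df.columns[values.sum(axis=0) == 0].tolist()
    if zero:
        raise ValueError(f"taxa table: zero-sum sample column(s) {zero}")
    return df.astype(int)


def write_taxa_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "taxon")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "subject_id", "age"], "sample metadata")
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a newick phylogeny; every non-root edge must carry a length."""
    tree = skbio.TreeNode.read(str(path))
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "<internal>"
            raise ValueError(f"tree edge above {name!r} has no branch length")
    return tree


def check_tree_tips(tree: skbio.TreeNode, taxa: Sequence[str]) -> None:
    """Fatal if any taxon with observations is absent from the tree tips."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise ValueError(f"taxa absent from tree tips: {missing}")
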