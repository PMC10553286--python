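"""Synthetic infant cohorts with the statistical structure the analysis assumes.

The generator produces the three kinds of data the pipeline consumes —
meal diaries, sleep composites with covariates, and stool taxa count
tables — from a small set of latent quantities that are stored alongside
the data (:class:`SyntheticTruth`) but never consumed by analysis stages.

The backbone is a per-subject latent regularity trait ``r ~ Beta(5, 2)``
(right-shifted, mimicking a cohort clustered at moderate-to-high
regularity).  Each subject has a template meal schedule per assessment
age; every diary day perturbs the template times with Gaussian jitter
whose SD is given by a regularity-to-jitter map, plus independent
meal add/drop events, then snaps to the 15-minute epoch grid with
24-hour wrap-around.  The default map is *calibrated* so that the
expected ERI of a subject with trait ``r`` is ``r`` itself: the expected
day-pair cosine similarity is estimated by Monte Carlo on a grid of
jitter SDs (using the same day machinery) and inverted.  This makes
``r`` and the measured ERI share a scale, so configured effect sizes of
sleep composites on ``r`` are recoverable by regression on the ERI up to
the attenuation from finite diary length.

Sleep composites are linear in ``r`` with subject random intercepts,
Gaussian noise and small covariate effects; sex is Bernoulli(1/2),
breastfeeding is 1 for every subject at 3 months and declines with age,
and the parental Structure score is correlated with ``r`` at a
configurable strength.

Microbiota counts are Dirichlet-multinomial around two enterotype base
compositions (Bifidobacterium-dominated "A" and Bacteroides-dominated
"B"); with age the concentration parameter rises and the base mixes
towards a more even community, so richness and Shannon diversity
increase and membership shifts from A to B.  ``mediation_mode`` controls
whether a microbiota marker sits on the causal path from regularity to a
sleep composite: ``none`` (marker independent of ``r`` given age),
``full`` (community evenness driven by ``r``, and the designated
composite driven by the realised Shannon diversity rather than ``r``),
or ``partial`` (both paths).

Random-number streams are partitioned per subject (seeded by
``(seed, subject_index, stage)``), so enlarging the cohort never
perturbs existing subjects.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .eri import binarize_day, cosine_similarity, double_sma
from .io import COMPOSITE_COLUMNS, DiaryDay, MealDiary

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "calibrated_jitter_map",
    "simulate_diaries",
    "simulate_sleep_and_covariates",
    "simulate_microbiota",
    "simulate_cohort",
    "random_taxon_tree",
    "TAXA",
]

# ---------------------------------------------------------------------------
# configuration

#: default true slopes of each sleep composite on latent regularity.
#: Variability, Activity and Timing are coupled (more regular eating ->
#: lower scores: less day-to-day variability, less fragmented nights,
#: earlier bedtimes); the two duration composites are not.
DEFAULT_EFFECT_SIZES: Mapping[str, float] = {
    "SleepActivity": -1.7,
    "SleepDay": 0.0,
    "SleepNight": 0.0,
    "SleepTiming": -3.5,
    "SleepVariability": -2.0,
}

#: mean reported meals per day at each assessment age (decreasing with
#: age: frequent scattered feeds at 3 months, ~5 meals by 12 months)
DEFAULT_MEALS_PER_DAY: Mapping[float, float] = {3: 8.0, 6: 6.5, 12: 5.0}

#: probability of staying/having become primarily breastfed, per age
_BREASTFEEDING_P: Mapping[float, float] = {3: 1.0, 6: 0.7, 12: 0.4}

#: probability of the Bacteroides-rich enterotype (B), rising with age
_ENTEROTYPE_B_P: Mapping[float, float] = {3: 0.25, 6: 0.45, 12: 0.70}


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 150
    ages_months: tuple[float, ...] = (3, 6, 12)
    days_per_assessment: int = 11
    epoch_minutes: int = 15
    seed: int = 0
    #: map from latent regularity r in [0,1] to meal-time jitter SD in
    #: minutes; must be non-increasing.  None -> calibrated default.
    regularity_jitter_map: Callable[[float], float] | None = None
    meals_per_day_by_age: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_MEALS_PER_DAY)
    )
    meal_add_prob: float = 0.05
    meal_drop_prob: float = 0.05
    regularity_beta_params: tuple[float, float] = (5.0, 2.0)
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    random_intercept_sd: float = 0.5
    residual_sd: float = 1.0
    #: correlation between the parental Structure score and r
    structure_corr: float = 0.3
    mediation_mode: str = "none"  # none | full | partial
    #: slope of the designated composite on the standardised mediator
    mediation_effect: float = -2.0
    mediation_marker: str = "shannon"
    mediation_composite: str = "SleepVariability"
    sequencing_depth: int = 20000
    #: multiplies the age-specific Dirichlet concentration; large values
    #: pin every sample to its expected composition (useful in checks)
    concentration_scale: float = 1.0
    sma_k: int = 4  # only used to calibrate the default jitter map

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.days_per_assessment < 1:
            raise ValueError("days_per_assessment must be >= 1")
        if 1440 % self.epoch_minutes != 0:
            raise ValueError("epoch_minutes must divide 1440")
        for p in (self.meal_add_prob, self.meal_drop_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("add/drop probabilities must be in [0, 1]")
        if self.mediation_mode not in ("none", "full", "partial"):
            raise ValueError(f"unknown mediation_mode {self.mediation_mode!r}")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.mediation_composite not in COMPOSITE_COLUMNS:
            raise ValueError(f"unknown composite {self.mediation_composite!r}")
        if self.regularity_jitter_map is not None:
            grid = np.linspace(0.0, 1.0, 21)
            sds = np.array([self.regularity_jitter_map(r) for r in grid], float)
            if (sds < 0).any() or (np.diff(sds) > 1e-9).any():
                raise ValueError(
                    "regularity_jitter_map must be non-negative and "
                    "non-increasing in r"
                )

    def jitter_map(self) -> Callable[[float], float]:
        if self.regularity_jitter_map is not None:
            return self.regularity_jitter_map
        mean_meals = float(np.mean(list(self.meals_per_day_by_age.values())))
        return calibrated_jitter_map(
            epoch_minutes=self.epoch_minutes,
            k=self.sma_k,
            mean_meals=round(mean_meals, 1),
            add_prob=self.meal_add_prob,
            drop_prob=self.meal_drop_prob,
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort; sidecar data for validation
    only — analysis stages must never read it."""

    subject_ids: list[str]
    regularity: np.ndarray  # latent r per subject
    jitter_sd: np.ndarray  # minutes, per subject
    random_intercepts: np.ndarray
    effect_sizes: dict[str, float]
    mediation_mode: str
    mediation_effect: float = 0.0
    enterotype_tendency: np.ndarray | None = None  # uniform draw per subject
    realized_mediator: pd.Series | None = None  # per sample, when coupled


# ---------------------------------------------------------------------------
# jitter-map calibration


def _subject_rng(seed: int, index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index, stage)))


def _template_times(
    rng: np.random.Generator, mean_meals: float, around_clock: bool
) -> np.ndarray:
    """A subject's habitual meal schedule for one assessment age.

    Young infants feed around the clock; older ones eat within a waking
    window.  Meals are roughly evenly spaced with individual offsets.
    """
    n_meals = max(1, int(round(rng.normal(mean_meals, 0.8))))
    if around_clock:
        start = rng.uniform(0.0, 1440.0 / n_meals)
        base = start + np.arange(n_meals) * 1440.0 / n_meals
    else:
        day_start = rng.uniform(330.0, 450.0)  # 05:30-07:30
        day_end = rng.uniform(1200.0, 1350.0)  # 20:00-22:30
        base = np.linspace(day_start, day_end, n_meals)
    return np.mod(base + rng.normal(0.0, 20.0, n_meals), 1440.0)


def _jitter_day(
    rng: np.random.Generator,
    template: np.ndarray,
    sd: float,
    add_prob: float,
    drop_prob: float,
    epoch_minutes: int,
) -> np.ndarray:
    """One diary day: jittered template, add/drop events, epoch snapping."""
    times = np.mod(template + rng.normal(0.0, sd, template.size), 1440.0)
    if template.size > 1 and rng.random() < drop_prob:
        times = np.delete(times, rng.integers(times.size))
    if rng.random() < add_prob:
        times = np.append(times, rng.uniform(0.0, 1440.0))
    epochs = np.unique((times // epoch_minutes).astype(int) * epoch_minutes)
    return epochs


@functools.lru_cache(maxsize=16)
def calibrated_jitter_map(
    epoch_minutes: int = 15,
    k: int = 4,
    mean_meals: float = 6.5,
    add_prob: float = 0.05,
    drop_prob: float = 0.05,
    n_replicates: int = 600,
) -> Callable[[float], float]:
    """Build the default regularity-to-jitter map by Monte Carlo inversion.

    For each jitter SD on a grid, the expected day-pair cosine similarity
    of double-SMA profiles is estimated with ``n_replicates`` simulated
    template/day pairs (including add/drop events, i.e. exactly the noise
    the diary generator applies).  The resulting decreasing curve
    E[cos | sd] is inverted so that a subject with latent regularity r
    receives the jitter SD with expected pairwise similarity r.  The map
    is a fixed package constant: its internal Monte Carlo seed does not
    depend on any cohort seed.
    """
    rng = np.random.default_rng(20230915)
    grid = np.array(
        [0, 5, 10, 15, 20, 25, 30, 40, 50, 65, 80, 100, 130, 170, 220, 300], float
    )
    expected = np.empty_like(grid)
    for gi, sd in enumerate(grid):
        sims = []
        while len(sims) < n_replicates:
            template = _template_times(rng, mean_meals, around_clock=bool(rng.integers(2)))
            day_a = _jitter_day(rng, template, sd, add_prob, drop_prob, epoch_minutes)
            day_b = _jitter_day(rng, template, sd, add_prob, drop_prob, epoch_minutes)
            if day_a.size == 0 or day_b.size == 0:
                continue
            pa = double_sma(binarize_day(day_a, epoch_minutes), k)
            pb = double_sma(binarize_day(day_b, epoch_minutes), k)
            sims.append(cosine_similarity(pa, pb))
        expected[gi] = np.mean(sims)
    # enforce strict monotone decrease before inversion
    expected = np.minimum.accumulate(expected)
    expected -= 1e-9 * np.arange(grid.size)

    r_knots = expected[::-1]
    sd_knots = grid[::-1]

    def jitter_map(r: float) -> float:
        return float(np.interp(r, r_knots, sd_knots))

    jitter_map.expected_similarity = dict(zip(grid.tolist(), expected.tolist()))
    return jitter_map


# ---------------------------------------------------------------------------
# diaries


def simulate_diaries(config: CohortConfig) -> tuple[list[MealDiary], SyntheticTruth]:
    """Generate meal diaries for the whole cohort plus the ground truth."""
    config.validate()
    jmap = config.jitter_map()
    a, b = config.regularity_beta_params

    diaries: list[MealDiary] = []
    ids, r_all, sd_all, u_all = [], [], [], []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i, stage=0)
        sid = f"S{i + 1:04d}"
        r = float(rng.beta(a, b))
        sd = float(jmap(r))
        ids.append(sid)
        r_all.append(r)
        sd_all.append(sd)
        u_all.append(float(rng.normal(0.0, config.random_intercept_sd)))
        for age in config.ages_months:
            mean_meals = config.meals_per_day_by_age.get(
                age, float(np.mean(list(config.meals_per_day_by_age.values())))
            )
            template = _template_times(rng, mean_meals, around_clock=age <= 3)
            days = []
            for d in range(config.days_per_assessment):
                epochs = _jitter_day(
                    rng, template, sd,
                    config.meal_add_prob, config.meal_drop_prob,
                    config.epoch_minutes,
                )
                days.append(DiaryDay(date=f"day{d + 1:02d}", meals=epochs))
            diaries.append(MealDiary(sid, float(age), days))

    truth = SyntheticTruth(
        subject_ids=ids,
        regularity=np.array(r_all),
        jitter_sd=np.array(sd_all),
        random_intercepts=np.array(u_all),
        effect_sizes=dict(config.effect_sizes),
        mediation_mode=config.mediation_mode,
        mediation_effect=(
            config.mediation_effect if config.mediation_mode != "none" else 0.0
        ),
    )
    return diaries, truth


# ---------------------------------------------------------------------------
# sleep composites and covariates

#: small fixed covariate effects so the control variables do something:
#: per-month age slope and Structure-score slope per composite
_AGE_EFFECTS = {
    "SleepActivity": -0.06,
    "SleepDay": -0.08,
    "SleepNight": -0.02,
    "SleepTiming": -0.04,
    "SleepVariability": -0.03,
}
_STRUCTURE_EFFECTS = {
    "SleepActivity": 0.0,
    "SleepDay": -0.15,
    "SleepNight": 0.15,
    "SleepTiming": -0.25,
    "SleepVariability": -0.08,
}


def simulate_sleep_and_covariates(
    truth: SyntheticTruth,
    config: CohortConfig,
    mediator_by_sample: pd.Series | None = None,
) -> pd.DataFrame:
    """Sleep composites and covariates, one row per subject x age.

    Each composite is ``b * r + covariate effects + subject intercept +
    noise`` with ``b`` from ``effect_sizes``.  When a mediator series
    (indexed by ``subject_id, age``) is supplied and mediation is
    switched on, the designated composite is instead driven by the
    standardised mediator (fully, or half-and-half for partial
    mediation).
    """
    config.validate()
    if config.mediation_mode != "none" and mediator_by_sample is None:
        raise ValueError(
            "mediation_mode is set but no mediator series supplied; "
            "generate microbiota first (or use simulate_cohort)"
        )
    a, b_ = config.regularity_beta_params
    r_mean = a / (a + b_)
    r_sd = np.sqrt(a * b_ / ((a + b_) ** 2 * (a + b_ + 1)))

    if mediator_by_sample is not None:
        med_std = (mediator_by_sample - mediator_by_sample.mean()) / (
            mediator_by_sample.std() or 1.0
        )

    rows = []
    for i, sid in enumerate(truth.subject_ids):
        rng = _subject_rng(config.seed, i, stage=1)
        r = truth.regularity[i]
        u = truth.random_intercepts[i]
        sex = int(rng.integers(2))
        bf_draw = rng.random()
        z = config.structure_corr * (r - r_mean) / r_sd + np.sqrt(
            max(0.0, 1.0 - config.structure_corr**2)
        ) * rng.normal()
        for age in config.ages_months:
            exact_age = float(age) + float(rng.uniform(-0.25, 0.5))
            bf = int(bf_draw < _BREASTFEEDING_P.get(age, 0.5))
            if age <= 3:
                bf = 1  # essentially universal breastfeeding at 3 months
            row = dict(
                subject_id=sid, age=float(age), exact_age=exact_age,
                sex=sex, breastfeeding=bf, structure_score=float(z),
            )
            for comp in COMPOSITE_COLUMNS:
                slope = truth.effect_sizes.get(comp, 0.0)
                signal = slope * r
                if (
                    config.mediation_mode != "none"
                    and comp == config.mediation_composite
                ):
                    m = float(med_std.loc[(sid, float(age))])
                    if config.mediation_mode == "full":
                        signal = config.mediation_effect * m
                    else:  # partial: half direct, half through the mediator
                        signal = 0.5 * slope * r + 0.5 * config.mediation_effect * m
                row[comp] = (
                    signal
                    + _AGE_EFFECTS[comp] * exact_age
                    + _STRUCTURE_EFFECTS[comp] * z
                    + u
                    + float(rng.normal(0.0, config.residual_sd))
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microbiota

#: (phylum, genus) panel used by the simulator; labels are "Phylum|Genus"
TAXA: list[tuple[str, str]] = [
    ("Actinobacteria", "Bifidobacterium"),
    ("Actinobacteria", "Collinsella"),
    ("Actinobacteria", "Eggerthella"),
    ("Bacteroidetes", "Bacteroides"),
    ("Bacteroidetes", "Prevotella"),
    ("Bacteroidetes", "Parabacteroides"),
    ("Bacteroidetes", "Alistipes"),
    ("Firmicutes", "Faecalibacterium"),
    ("Firmicutes", "Blautia"),
    ("Firmicutes", "Ruminococcus"),
    ("Firmicutes", "Clostridium"),
    ("Firmicutes", "Lactobacillus"),
    ("Firmicutes", "Roseburia"),
    ("Firmicutes", "Streptococcus"),
    ("Firmicutes", "Veillonella"),
    ("Firmicutes", "Dorea"),
    ("Firmicutes", "Coprococcus"),
    ("Proteobacteria", "Escherichia"),
    ("Proteobacteria", "Klebsiella"),
    ("Proteobacteria", "Haemophilus"),
    ("Verrucomicrobia", "Akkermansia"),
]

TAXON_LABELS = [f"{p}|{g}" for p, g in TAXA]


#: genera essentially absent from the milk-fed early-infancy gut; they
#: arrive with the even "mature" component, so richness rises with age
_LATE_COLONIZERS = {
    "Faecalibacterium", "Roseburia", "Alistipes", "Akkermansia",
    "Coprococcus", "Dorea", "Eggerthella",
}


def _base_compositions() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Enterotype base compositions (A: Bifidobacterium-dominated,
    B: Bacteroides-dominated) and the broad even community that both mix
    towards as the gut matures."""
    n = len(TAXA)
    base_a = np.full(n, 0.2 / (n - 2))
    base_b = np.full(n, 0.2 / (n - 2))
    idx = {g: i for i, (_, g) in enumerate(TAXA)}
    for genus in _LATE_COLONIZERS:
        base_a[idx[genus]] = 0.0
        base_b[idx[genus]] = 0.0
    base_a[idx["Bifidobacterium"]] = 0.55
    base_a[idx["Bacteroides"]] = 0.05
    base_b[idx["Bacteroides"]] = 0.45
    base_b[idx["Prevotella"]] = 0.10
    base_b[idx["Bifidobacterium"]] = 0.05
    even = np.full(n, 1.0 / n)
    return base_a / base_a.sum(), base_b / base_b.sum(), even


#: age-dependent Dirichlet concentration and evenness mixing weight:
#: older guts are richer and more even
_CONCENTRATION_BY_AGE = {3: 25.0, 6: 50.0, 12: 100.0}
_EVENNESS_BY_AGE = {3: 0.10, 6: 0.25, 12: 0.45}


def simulate_microbiota(
    truth: SyntheticTruth,
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial taxa counts for every subject x age.

    Returns ``(counts, metadata)``: a taxa x samples integer table and a
    sample metadata frame.  Under ``mediation_mode`` other than ``none``
    the community evenness — and therefore Shannon diversity — is driven
    by the subject's latent regularity, and the realised mediator values
    are stored in ``truth.realized_mediator``.
    """
    config.validate()
    base_a, base_b, even = _base_compositions()
    a, b_ = config.regularity_beta_params
    r_mean = a / (a + b_)

    columns: dict[str, np.ndarray] = {}
    meta = []
    mediator = {}
    tendency = np.empty(len(truth.subject_ids))
    for i, sid in enumerate(truth.subject_ids):
        rng = _subject_rng(config.seed, i, stage=2)
        tendency[i] = rng.random()
        r = truth.regularity[i]
        for age in config.ages_months:
            etype = "B" if tendency[i] < _ENTEROTYPE_B_P.get(age, 0.5) else "A"
            base = base_b if etype == "B" else base_a
            w = _EVENNESS_BY_AGE.get(age, 0.3)
            if config.mediation_mode != "none":
                w = float(np.clip(w + 0.6 * (r - r_mean), 0.02, 0.95))
            comp = (1.0 - w) * base + w * even
            theta = _CONCENTRATION_BY_AGE.get(age, 50.0) * config.concentration_scale
            p = rng.dirichlet(np.maximum(theta * comp, 1e-8))
            counts = rng.multinomial(config.sequencing_depth, p)
            sample_id = f"{sid}_m{age:g}"
            columns[sample_id] = counts
            meta.append(dict(sample_id=sample_id, subject_id=sid, age=float(age)))
            if config.mediation_mode != "none":
                frac = counts[counts > 0] / counts.sum()
                mediator[(sid, float(age))] = float(-(frac * np.log(frac)).sum())

    counts_df = pd.DataFrame(columns, index=TAXON_LABELS)
    counts_df.index.name = "taxon"
    truth.enterotype_tendency = tendency
    if mediator:
        truth.realized_mediator = pd.Series(mediator)
    return counts_df, pd.DataFrame(meta)


def random_taxon_tree(seed: int = 7) -> "skbio.TreeNode":
    """A random rooted phylogeny over the simulated taxon panel.

    Genera coalesce within their phylum first, then phyla join, so the
    tree is taxonomically sensible; branch lengths are exponential.
    """
    import skbio

    rng = np.random.default_rng(seed)

    def join(nodes: list[str]) -> str:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            la, lb = rng.exponential(0.3, 2) + 0.05
            nodes.append(f"({left}:{la:.4f},{right}:{lb:.4f})")
        return nodes[0]

    phyla: dict[str, list[str]] = {}
    for phylum, genus in TAXA:
        phyla.setdefault(phylum, []).append(f"'{phylum}|{genus}'")
    clades = [join(tips) for tips in phyla.values()]
    newick = join(clades) + ";"
    return skbio.TreeNode.read([newick])


# ---------------------------------------------------------------------------
# orchestration


def simulate_cohort(config: CohortConfig) -> dict:
    """Generate a complete cohort: diaries, microbiota, sleep, covariates.

    Returns a dict with keys ``diaries`` (list of MealDiary), ``sleep``
    (composites + covariates table), ``taxa`` (counts), ``samples``
    (metadata), ``tree`` and ``truth``.
    """
    diaries, truth = simulate_diaries(config)
    taxa, samples = simulate_microbiota(truth, config)
    sleep = simulate_sleep_and_covariates(
        truth, config, mediator_by_sample=truth.realized_mediator
    )
    tree = random_taxon_tree(seed=7)
    return dict(
        diaries=diaries, sleep=sleep, taxa=taxa,
        samples=samples, tree=tree, truth=truth,
    )


def truth_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Ground truth as a table (for the clearly-marked sidecar file)."""
    return pd.DataFrame(
        dict(
            subject_id=truth.subject_ids,
            regularity=truth.regularity,
            jitter_sd=truth.jitter_sd,
            random_intercept=truth.random_intercepts,
        )
    )
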