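"""Baron & Kenny causal-steps mediation of microbiota markers.

For an exposure X (the ERI), a candidate mediator M (a microbiota
marker) and an outcome Y (a sleep composite), the four steps are

1. ``Y ~ X``  — the total effect; if X does not predict Y there is
   nothing to mediate and the analysis stops (``not_computed``);
2. ``M ~ X``  — the exposure must move the mediator;
3. ``Y ~ M + X`` — the mediator must predict the outcome with the
   exposure held fixed;
4. the X coefficient of the step-3 model, compared with step 1: a
   non-significant X term means *full* mediation, a significant but
   attenuated one *partial* mediation, and anything else no mediation.

All models include the control covariates (meal count, daytime meal
ratio, exact age, sex, breastfeeding, Structure score) and a per-subject
random intercept; step-1 fits are numerically identical to the
corresponding association model (same fitting code).  Verdicts are
judged at alpha = 0.05 without multiple-testing correction across the
screen; a Benjamini-Hochberg column can be requested as an extra, and a
Sobel test of the indirect effect is attached as a labelled optional
statistic (the verdict never depends on it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import COMPOSITE_COLUMNS
from .models import ModelResult, fit_multilevel

__all__ = [
    "DEFAULT_CONTROLS",
    "MediationResult",
    "baron_kenny",
    "mediation_screen",
]

#: control variables entering every mediation regression
DEFAULT_CONTROLS = [
    "mean_meals_per_day",
    "daytime_meal_ratio",
    "exact_age",
    "sex",
    "breastfeeding",
    "structure_score",
]


@dataclass
class StepResult:
    """The tested coefficient of one causal step."""

    model: str
    term: str
    estimate: float
    se: float
    t: float
    df: float
    p: float
    significant: bool


@dataclass
class MediationResult:
    x: str
    m: str
    y: str
    steps: dict[int, StepResult] = field(default_factory=dict)
    verdict: str = "not_computed"  # no_mediation | partial | full | not_computed
    stop_reason: str = ""
    sobel_z: float = float("nan")
    sobel_p: float = float("nan")

    @property
    def attenuation(self) -> float:
        """1 - |b_X(step 4)| / |b_X(step 1)|; NaN before step 4."""
        if 1 in self.steps and 4 in self.steps:
            b1, b4 = self.steps[1].estimate, self.steps[4].estimate
            if b1 != 0:
                return 1.0 - abs(b4) / abs(b1)
        return float("nan")


def _step(result: ModelResult, term: str, alpha: float) -> StepResult:
    row = result.term(term)
    return StepResult(
        model=result.outcome,
        term=term,
        estimate=float(row["estimate"]),
        se=float(row["se"]),
        t=float(row["t"]),
        df=float(row["df"]),
        p=float(row["p"]),
        significant=bool(row["p"] < alpha),
    )


def baron_kenny(
    data: pd.DataFrame,
    m: str,
    y: str,
    x: str = "eri",
    covariates: list[str] | None = None,
    group: str = "subject_id",
    alpha: float = 0.05,
    step1: ModelResult | None = None,
    step2: ModelResult | None = None,
) -> MediationResult:
    """Run the four causal steps for one (mediator, outcome) pair.

    ``step1``/``step2`` accept pre-computed fits (the screen reuses the
    step-1 model across mediators and the step-2 model across
    outcomes).  The mediator may be numeric or 0/1 coded; a constant or
    X-collinear mediator is rejected.
    """
    covs = list(DEFAULT_CONTROLS if covariates is None else covariates)
    mediator = data[m].dropna()
    if mediator.nunique() <= 1:
        raise ValueError(f"degenerate mediator {m!r}: constant")
    paired = data[[m, x]].dropna()
    if abs(np.corrcoef(paired[m], paired[x])[0, 1]) > 0.999:
        raise ValueError(f"mediator {m!r} is collinear with exposure {x!r}")

    res = MediationResult(x=x, m=m, y=y)

    if step1 is None:
        step1 = fit_multilevel(data, y, [x, *covs], group=group)
    res.steps[1] = _step(step1, x, alpha)
    if not res.steps[1].significant:
        res.verdict = "not_computed"
        res.stop_reason = f"step 1: no {x}-{y} association to mediate (p={res.steps[1].p:.3f})"
        return res

    if step2 is None:
        step2 = fit_multilevel(data, m, [x, *covs], group=group)
    res.steps[2] = _step(step2, x, alpha)
    if not res.steps[2].significant:
        res.verdict = "no_mediation"
        res.stop_reason = f"step 2: {x} does not predict mediator {m} (p={res.steps[2].p:.3f})"
        return res

    step34 = fit_multilevel(data, y, [x, m, *covs], group=group)
    res.steps[3] = _step(step34, m, alpha)
    res.steps[4] = _step(step34, x, alpha)

    # labelled extra: Sobel test of the indirect effect a*b
    a_, sa = res.steps[2].estimate, res.steps[2].se
    b_, sb = res.steps[3].estimate, res.steps[3].se
    denom = np.sqrt(a_**2 * sb**2 + b_**2 * sa**2)
    if denom > 0:
        res.sobel_z = a_ * b_ / denom
        res.sobel_p = 2.0 * scipy.stats.norm.sf(abs(res.sobel_z))

    if not res.steps[3].significant:
        res.verdict = "no_mediation"
        res.stop_reason = f"step 3: mediator {m} does not predict {y} given {x}"
        return res
    if not res.steps[4].significant:
        res.verdict = "full"
        res.stop_reason = ""
    elif abs(res.steps[4].estimate) < abs(res.steps[1].estimate):
        res.verdict = "partial"
    else:
        res.verdict = "no_mediation"
        res.stop_reason = "step 4: direct effect not attenuated"
    return res


def mediation_screen(
    data: pd.DataFrame,
    markers: list[str],
    composites: list[str] | None = None,
    x: str = "eri",
    covariates: list[str] | None = None,
    group: str = "subject_id",
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], MediationResult]]:
    """Cross every marker with every sleep composite.

    Step-1 models (one per composite) and step-2 models (one per marker)
    are fitted once and shared.  Returns a tidy summary frame — one row
    per (marker, composite), |markers| x |composites| rows in a fixed
    order — plus the full result objects.  With ``bh_correct`` a
    Benjamini-Hochberg adjusted step-3 p column is appended (the
    verdicts remain uncorrected).
    """
    if not markers:
        raise ValueError("empty marker set")
    comps = list(COMPOSITE_COLUMNS if composites is None else composites)
    covs = list(DEFAULT_CONTROLS if covariates is None else covariates)

    step1_cache = {
        yy: fit_multilevel(data, yy, [x, *covs], group=group) for yy in comps
    }
    step2_cache = {
        mm: fit_multilevel(data, mm, [x, *covs], group=group) for mm in markers
    }

    results: dict[tuple[str, str], MediationResult] = {}
    rows = []
    for mm in markers:
        for yy in comps:
            res = baron_kenny(
                data, mm, yy, x=x, covariates=covs, group=group, alpha=alpha,
                step1=step1_cache[yy], step2=step2_cache[mm],
            )
            results[(mm, yy)] = res
            rows.append(
                dict(
                    marker=mm,
                    composite=yy,
                    verdict=res.verdict,
                    stop_reason=res.stop_reason,
                    step1_p=res.steps[1].p if 1 in res.steps else np.nan,
                    step2_p=res.steps[2].p if 2 in res.steps else np.nan,
                    step3_p=res.steps[3].p if 3 in res.steps else np.nan,
                    step4_p=res.steps[4].p if 4 in res.steps else np.nan,
                    attenuation=res.attenuation,
                    sobel_p=res.sobel_p,
                )
            )
    table = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = table["step3_p"].notna()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                table.loc[mask, "step3_p"], method="fdr_bh"
            )[1]
        table["step3_p_bh"] = adj
    return table, results
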