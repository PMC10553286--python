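"""Association models linking eating regularity to sleep composites.

The workhorse is a linear mixed model of a sleep composite on the ERI
with the control covariates (sex, exact age, breastfeeding, mean meals
per day, daytime meal ratio, parental Structure score) and a per-subject
random intercept, optionally extended with a random ERI slope.  The
random structure is chosen by comparing AIC between the two variants
fitted by maximum likelihood (BIC is reported and any disagreement
flagged); the selected model is refit by REML for inference.

Degrees of freedom for the fixed-effect t-tests use a
Satterthwaite-style approximation: for each coefficient,
``df = 2 v^2 / Var(v)`` where ``v`` is the estimated coefficient
variance and ``Var(v)`` comes from the delta method — the gradient of
``v`` with respect to the variance parameters (numerical central
differences) combined with the inverse observed information of the REML
log-likelihood in those parameters.  With one observation per subject
this collapses to the usual residual df of ordinary least squares.

Per-age analyses use ordinary linear models (identity link) on the
single-age slices, dropping breastfeeding at 3 months where it is
constant (every infant primarily breastfed).  The age trend of the ERI
itself is a one-way ANOVA with Tukey HSD post-hoc comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import ConvergenceWarning

import warnings

__all__ = [
    "DEFAULT_FIXED_EFFECTS",
    "ModelResult",
    "StructureSelection",
    "AgeTrendResult",
    "fit_multilevel",
    "select_random_structure",
    "fit_age_glm",
    "age_trend_anova",
]

log = logging.getLogger(__name__)

#: fixed effects of every association model, ERI first
DEFAULT_FIXED_EFFECTS = [
    "eri",
    "sex",
    "exact_age",
    "breastfeeding",
    "mean_meals_per_day",
    "daytime_meal_ratio",
    "structure_score",
]


@dataclass
class ModelResult:
    """Tidy coefficient table plus fit metadata for one model."""

    outcome: str
    params: pd.DataFrame  # index: term; columns: estimate, se, t, df, p
    aic: float
    bic: float
    loglike: float
    n_obs: int
    n_subjects: int
    random_structure: str  # "intercept", "intercept+slope" or "none"
    converged: bool
    variance_components: dict[str, float] = field(default_factory=dict)
    n_dropped: int = 0

    def term(self, name: str) -> pd.Series:
        return self.params.loc[name]

    def report_line(self, term: str = "eri") -> str:
        """One-line summary in the conventional t(df) = x, b = y, p = z form."""
        row = self.params.loc[term]
        p = "<0.001" if row["p"] < 0.001 else f"= {row['p']:.3f}"
        return (
            f"{self.outcome} ~ {term}: t({row['df']:.3f}) = {row['t']:.3f}, "
            f"b = {row['estimate']:.3f}, p {p}"
        )


@dataclass
class StructureSelection:
    chosen: str
    criteria: pd.DataFrame  # index structure; columns aic, bic, converged
    bic_agrees: bool
    final: ModelResult


@dataclass
class AgeTrendResult:
    f: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, lower, upper, p_adj, reject


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _complete_cases(
    data: pd.DataFrame, columns: list[str], outcome: str
) -> tuple[pd.DataFrame, int]:
    cols = list(dict.fromkeys([outcome, *columns]))
    sub = data[cols]
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        log.info("%s: listwise deletion dropped %d row(s)", outcome, n_dropped)
    return kept, n_dropped


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")


# ---------------------------------------------------------------------------
# Satterthwaite machinery


class _LmmParts:
    """Per-group views of a fitted LMM, for REML/variance computations.

    theta packs the variance parameters: ``[sigma2] + lower triangle of
    the random-effect covariance G`` (1 entry for a random intercept,
    3 for intercept+slope).
    """

    def __init__(self, y, X, Z, groups):
        order = np.argsort(groups, kind="stable")
        y, X, Z, groups = y[order], X[order], Z[order], groups[order]
        _, starts = np.unique(groups, return_index=True)
        bounds = np.append(np.sort(starts), len(groups))
        self.blocks = [
            (y[a:b], X[a:b], Z[a:b]) for a, b in zip(bounds[:-1], bounds[1:])
        ]
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.n = len(y)

    def _unpack(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        sigma2 = theta[0]
        G = np.zeros((self.q, self.q))
        idx = np.tril_indices(self.q)
        G[idx] = theta[1:]
        G = G + np.tril(G, -1).T
        return sigma2, G

    def _group_solves(self, theta):
        sigma2, G = self._unpack(theta)
        for y_g, X_g, Z_g in self.blocks:
            V = sigma2 * np.eye(len(y_g)) + Z_g @ G @ Z_g.T
            c, lower = scipy.linalg.cho_factor(V)
            logdet = 2.0 * np.log(np.diag(c)).sum()
            Vi_X = scipy.linalg.cho_solve((c, lower), X_g)
            Vi_y = scipy.linalg.cho_solve((c, lower), y_g)
            yield y_g, X_g, Vi_X, Vi_y, logdet

    def xtvix(self, theta: np.ndarray) -> np.ndarray:
        A = np.zeros((self.p, self.p))
        for _, X_g, Vi_X, _, _ in self._group_solves(theta):
            A += X_g.T @ Vi_X
        return A

    def cov_beta(self, theta: np.ndarray) -> np.ndarray:
        return np.linalg.inv(self.xtvix(theta))

    def reml_loglike(self, theta: np.ndarray) -> float:
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        logdetV = 0.0
        parts = list(self._group_solves(theta))
        for y_g, X_g, Vi_X, Vi_y, logdet in parts:
            A += X_g.T @ Vi_X
            b += X_g.T @ Vi_y
            logdetV += logdet
        beta = np.linalg.solve(A, b)
        quad = 0.0
        for y_g, X_g, Vi_X, Vi_y, _ in parts:
            r = y_g - X_g @ beta
            # V^-1 r = Vi_y - Vi_X beta
            quad += r @ (Vi_y - Vi_X @ beta)
        sign, logdetA = np.linalg.slogdet(A)
        return -0.5 * (logdetV + logdetA + quad)


def _satterthwaite_dfs(parts: _LmmParts, theta: np.ndarray) -> np.ndarray:
    """Per-coefficient denominator df via the delta method on Var(beta_i)."""
    nq = len(theta)
    scale = max(theta[0], 1e-8)
    h = np.maximum(1e-4 * np.abs(theta), 1e-4 * scale)

    cov0 = parts.cov_beta(theta)
    v0 = np.diag(cov0)

    # gradient of each Var(beta_i) w.r.t. theta (central differences)
    grad = np.zeros((parts.p, nq))
    for j in range(nq):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        try:
            vp = np.diag(parts.cov_beta(tp))
            vm = np.diag(parts.cov_beta(tm))
        except np.linalg.LinAlgError:
            vp = vm = v0
        grad[:, j] = (vp - vm) / (2.0 * h[j])

    # observed information of the REML log-likelihood in theta
    H = np.zeros((nq, nq))

    def ll(t):
        try:
            return parts.reml_loglike(t)
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
            return np.nan

    l0 = ll(theta)
    for i in range(nq):
        for j in range(i, nq):
            ti = theta.copy()
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (ll(tp) - 2 * l0 + ll(tm)) / h[i] ** 2
            else:
                vals = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    t = theta.copy()
                    t[i] += si * h[i]
                    t[j] += sj * h[j]
                    vals.append(ll(t))
                H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * h[i] * h[j]
                )
    if not np.all(np.isfinite(H)):
        return np.full(parts.p, np.nan)
    W = np.linalg.pinv(-H)

    dfs = np.empty(parts.p)
    resid_df = parts.n - parts.p
    for i in range(parts.p):
        denom = grad[i] @ W @ grad[i]
        if denom <= 0 or not np.isfinite(denom):
            dfs[i] = resid_df
        else:
            dfs[i] = np.clip(2.0 * v0[i] ** 2 / denom, 1.0, resid_df)
    return dfs


# ---------------------------------------------------------------------------
# model fits


def fit_multilevel(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects: list[str] | None = None,
    group: str = "subject_id",
    random_structure: str = "intercept",
    reml: bool = True,
    df_method: str = "satterthwaite",
) -> ModelResult:
    """Linear mixed model of ``outcome`` on the fixed effects.

    ``random_structure`` is ``"intercept"`` or ``"intercept+slope"``
    (random ERI slope).  Complete cases only; dropped rows are counted
    and logged.  Two-sided p-values use Student's t with Satterthwaite
    df (or the residual df when ``df_method="residual"``).
    """
    fixed = list(DEFAULT_FIXED_EFFECTS if fixed_effects is None else fixed_effects)
    if random_structure not in ("intercept", "intercept+slope"):
        raise ValueError(f"unknown random structure {random_structure!r}")
    kept, n_dropped = _complete_cases(data, fixed + [group], outcome)
    y = kept[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(kept))] + [kept[c].to_numpy(float) for c in fixed])
    names = ["Intercept", *fixed]
    _check_rank(X, names)
    groups = kept[group].to_numpy()
    if random_structure == "intercept+slope":
        slope_col = fixed[0]
        Z = np.column_stack([np.ones(len(kept)), kept[slope_col].to_numpy(float)])
    else:
        Z = np.ones((len(kept), 1))

    n_subjects = len(np.unique(groups))
    counts = pd.Series(groups).value_counts()
    if (counts == 1).all():
        log.warning(
            "%s: single observation per subject; variance components "
            "unidentifiable, falling back to a fixed-effects model", outcome
        )
        return fit_age_glm(kept, outcome, fixed)

    model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
    with warnings.catch_warnings():
        # boundary-of-parameter-space warnings are informative, not fatal
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        result = model.fit(reml=reml)
    converged = bool(result.converged) and bool(
        np.all(np.isfinite(np.asarray(result.fe_params)))
    )

    est = np.asarray(result.fe_params, dtype=float)
    se = np.asarray(result.bse_fe, dtype=float)
    G = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    theta = np.concatenate([[float(result.scale)], G[np.tril_indices(G.shape[0])]])
    parts = _LmmParts(y, X, Z, groups)
    if df_method == "satterthwaite":
        dfs = _satterthwaite_dfs(parts, theta)
        if not np.all(np.isfinite(dfs)):
            dfs = np.full(len(est), parts.n - parts.p)
    else:
        dfs = np.full(len(est), parts.n - parts.p)
    tvals = est / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), dfs)

    params = pd.DataFrame(
        dict(estimate=est, se=se, t=tvals, df=dfs, p=pvals), index=names
    )
    vc = {"residual_var": float(result.scale)}
    vc["intercept_var"] = float(G[0, 0])
    if G.shape[0] > 1:
        vc["slope_var"] = float(G[1, 1])
        vc["intercept_slope_cov"] = float(G[0, 1])
    # AIC/BIC from the fitted objective; comparable across random
    # structures only for ML fits
    k_params = X.shape[1] + len(theta)
    llf = float(result.llf)
    n_eff = parts.n if not reml else parts.n - parts.p
    return ModelResult(
        outcome=outcome,
        params=params,
        aic=2 * k_params - 2 * llf,
        bic=k_params * np.log(n_eff) - 2 * llf,
        loglike=llf,
        n_obs=parts.n,
        n_subjects=n_subjects,
        random_structure=random_structure,
        converged=converged,
        variance_components=vc,
        n_dropped=n_dropped,
    )


def select_random_structure(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects: list[str] | None = None,
    group: str = "subject_id",
) -> StructureSelection:
    """Pick the random structure by ML-based AIC, then refit by REML.

    Both candidate structures (random intercept; random intercept +
    random ERI slope) are fitted under maximum likelihood so their AICs
    are comparable; a non-converging candidate is disqualified.  BIC is
    reported alongside and any disagreement with the AIC choice flagged.
    """
    rows = {}
    for structure in ("intercept", "intercept+slope"):
        try:
            res = fit_multilevel(
                data, outcome, fixed_effects, group,
                random_structure=structure, reml=False, df_method="residual",
            )
            rows[structure] = dict(aic=res.aic, bic=res.bic, converged=res.converged)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("%s: %s variant failed (%s)", outcome, structure, exc)
            rows[structure] = dict(aic=np.inf, bic=np.inf, converged=False)
    criteria = pd.DataFrame(rows).T.astype(
        {"aic": float, "bic": float, "converged": bool}
    )
    usable = criteria[criteria["converged"]]
    if usable.empty:
        usable = criteria
    chosen = str(usable["aic"].idxmin())
    bic_choice = str(usable["bic"].idxmin())
    final = fit_multilevel(
        data, outcome, fixed_effects, group, random_structure=chosen, reml=True
    )
    return StructureSelection(
        chosen=chosen,
        criteria=criteria,
        bic_agrees=bic_choice == chosen,
        final=final,
    )


def fit_age_glm(
    data: pd.DataFrame,
    outcome: str,
    fixed_effects: list[str] | None = None,
) -> ModelResult:
    """Ordinary linear model (identity link) for a single-age slice.

    Breastfeeding is removed from the design when constant — at
    3 months every infant is primarily breastfed, so the column carries
    no information and would be aliased with the intercept.
    """
    fixed = list(DEFAULT_FIXED_EFFECTS if fixed_effects is None else fixed_effects)
    kept, n_dropped = _complete_cases(data, fixed, outcome)
    if "breastfeeding" in fixed and kept["breastfeeding"].nunique() <= 1:
        fixed = [c for c in fixed if c != "breastfeeding"]
        log.info("%s: breastfeeding constant, dropped from design", outcome)
    names = ["Intercept", *fixed]
    X = np.column_stack([np.ones(len(kept))] + [kept[c].to_numpy(float) for c in fixed])
    if len(kept) <= X.shape[1]:
        raise ValueError(f"{outcome}: n={len(kept)} <= p={X.shape[1]} parameters")
    _check_rank(X, names)
    ols = sm.OLS(kept[outcome].to_numpy(float), X).fit()
    df = float(ols.df_resid)
    params = pd.DataFrame(
        dict(
            estimate=ols.params,
            se=ols.bse,
            t=ols.tvalues,
            df=np.full(len(names), df),
            p=ols.pvalues,
        ),
        index=names,
    )
    return ModelResult(
        outcome=outcome,
        params=params,
        aic=float(ols.aic),
        bic=float(ols.bic),
        loglike=float(ols.llf),
        n_obs=int(ols.nobs),
        n_subjects=int(ols.nobs),
        random_structure="none",
        converged=True,
        variance_components={"residual_var": float(ols.scale)},
        n_dropped=n_dropped,
    )


def age_trend_anova(values: pd.Series, ages: pd.Series) -> AgeTrendResult:
    """One-way ANOVA of a measure across age groups + Tukey HSD post-hocs."""
    mask = values.notna() & ages.notna()
    values, ages = values[mask], ages[mask]
    groups = [values[ages == a].to_numpy(float) for a in sorted(ages.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 age groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each age group needs at least 2 observations")
    f, p = scipy.stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    tukey = pairwise_tukeyhsd(values.to_numpy(float), ages.to_numpy())
    tk = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    )
    return AgeTrendResult(
        f=float(f),
        df_between=len(groups) - 1,
        df_within=n - len(groups),
        p=float(p),
        tukey=tk,
    )
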