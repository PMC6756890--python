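"""The statistical sequence: outlier screening, per-subject linear models
with Wald F tests, semi-partial R², collinearity diagnostics, BIC
interaction screening, summary t-tests and the regression sensitivity
analysis.

With one observation per subject, a Gaussian identity-link mixed model with
a subject random intercept has fixed effects identical to ordinary least
squares for *any* value of the intercept variance (the marginal covariance
is a multiple of the identity), and the Kenward-Roger denominator degrees of
freedom reduce to the residual df n - p - 1. Models are therefore fitted in
the collapsed linear form; :func:`fit_mixed_reference` exposes the explicit
mixed-model fit so the equivalence can be asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from ._errors import (
    CollinearityError,
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    NoSolutionError,
)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "OutlierScreen",
    "remove_outliers",
    "fit_model",
    "fit_mixed_reference",
    "semipartial_r2",
    "collinearity",
    "compare_interaction_bic",
    "welch_ttest",
    "ttest_summary",
    "SensitivityResult",
    "sensitivity_minimum_effect",
    "empirical_power",
    "run_model_sequence",
    "ModelSequenceReport",
    "ALPHA",
]

ALPHA = 0.05

REPORT_COLUMNS = [
    "term", "estimate", "se", "F", "df_num", "df_den", "p", "r_sp2", "n_used", "removed_ids",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model: outcome regressed on predictors, controlling for sex and age."""

    predictors: tuple[str, ...]
    outcome: str = "pacc5"
    covariates: tuple[str, ...] = ("sex", "age")

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if "sex" not in self.covariates or "age" not in self.covariates:
            raise DomainError("all models must control for sex and age")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.covariates) + self.predictors


@dataclass
class ModelFit:
    """Per-term estimates with Wald F statistics and effect sizes."""

    name: str
    terms: pd.DataFrame  # estimate, se, F, df_num, df_den, p, r_sp2 per term
    n_used: int
    df_den: int
    bic: float
    collinearity: pd.DataFrame | None
    removed_ids: tuple = ()
    missing_ids: tuple = ()

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    def to_table(self) -> pd.DataFrame:
        out = self.terms.reset_index(names="term")
        out["n_used"] = self.n_used
        out["removed_ids"] = ";".join(str(i) for i in self.removed_ids)
        return out[REPORT_COLUMNS]


@dataclass
class OutlierScreen:
    table: pd.DataFrame
    removed_ids: tuple
    missing_ids: tuple
    skipped_variables: tuple = ()


def _ids(table: pd.DataFrame, index) -> tuple:
    if "pid" in table.columns:
        return tuple(table.loc[index, "pid"])
    return tuple(index)


def remove_outliers(
    table: pd.DataFrame, variables: Sequence[str], k: float = 3.0
) -> OutlierScreen:
    """Single-pass ±k·SD screen with thresholds from pre-removal moments.

    Rows with missing values on any screened variable are dropped first
    (listwise) and reported separately; a row is then removed when any
    variable lies strictly outside mean ± k·SD, with mean/SD computed on the
    complete-case table before any removal. Zero-variance variables are
    skipped with a warning.
    """
    if len(table) < 3:
        raise InsufficientDataError("outlier screening needs at least 3 rows")
    missing_mask = table[list(variables)].isna().any(axis=1)
    complete = table[~missing_mask]
    skipped, outlier_mask = [], pd.Series(False, index=complete.index)
    for name in variables:
        col = complete[name].astype(float)
        sd = float(col.std(ddof=1))
        if not sd > 0:
            warnings.warn(f"variable {name!r} has zero variance; skipped in outlier screen")
            skipped.append(name)
            continue
        mean = float(col.mean())
        outlier_mask |= (col < mean - k * sd) | (col > mean + k * sd)
    return OutlierScreen(
        table=complete[~outlier_mask],
        removed_ids=_ids(complete, complete.index[outlier_mask]),
        missing_ids=_ids(table, table.index[missing_mask]),
        skipped_variables=tuple(skipped),
    )


def _design(
    table: pd.DataFrame, spec: ModelSpec, standardize: bool
) -> tuple[np.ndarray, list[str]]:
    cols = []
    for name in spec.terms:
        x = table[name].to_numpy(dtype=float)
        # sex is a 0/1 code; continuous terms are z-scored on the analysis sample
        if standardize and name != "sex":
            sd = x.std(ddof=1)
            if sd > 0:
                x = (x - x.mean()) / sd
        cols.append(x)
    X = np.column_stack([np.ones(len(table))] + cols)
    return X, ["intercept"] + list(spec.terms)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise CollinearityError(f"singular design; aliased terms: {', '.join(aliased) or '?'}")


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    standardize: bool = True,
    standardize_outcome: bool = False,
    name: str = "model",
) -> ModelFit:
    """Fit the per-subject linear model and report per-term Wald F tests.

    Each 1-df term's F equals (estimate/SE)², tested against F(1, n-p-1) —
    the denominator df the Kenward-Roger correction yields in this
    one-row-per-subject design. Semi-partial R² is reported for terms with
    p < .05, matching the published table convention.
    """
    y = table[spec.outcome].to_numpy(dtype=float)
    if standardize_outcome:
        y = (y - y.mean()) / y.std(ddof=1)
    X, names = _design(table, spec, standardize)
    _check_rank(X, names)
    fit = sm.OLS(y, X).fit()
    nu = int(fit.df_resid)

    rows = []
    for j, term in enumerate(names):
        if term == "intercept":
            continue
        est, se = fit.params[j], fit.bse[j]
        F = (est / se) ** 2
        p = float(stats.f.sf(F, 1, nu))
        rows.append(
            {
                "estimate": est,
                "se": se,
                "F": F,
                "df_num": 1,
                "df_den": nu,
                "p": p,
                "r_sp2": semipartial_r2(F, 1, nu) if p < ALPHA else np.nan,
            }
        )
    terms = pd.DataFrame(rows, index=list(spec.terms))
    vif = collinearity(table, list(spec.terms)) if len(spec.terms) >= 2 else None
    return ModelFit(
        name=name,
        terms=terms,
        n_used=len(table),
        df_den=nu,
        bic=float(fit.bic),
        collinearity=vif,
    )


def fit_mixed_reference(table: pd.DataFrame, spec: ModelSpec, standardize: bool = True):
    """Explicit subject-intercept mixed model (one group per subject).

    Used to assert that the collapsed linear formulation gives identical
    fixed effects; not the production fitting path.
    """
    y = table[spec.outcome].to_numpy(dtype=float)
    X, _ = _design(table, spec, standardize)
    groups = np.arange(len(table))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.MixedLM(y, X, groups=groups).fit()


def semipartial_r2(F: float, q: int, nu: int) -> float:
    """Effect size R²β = (q·F/ν) / (1 + q·F/ν) for an F(q, ν) Wald test."""
    if F < 0:
        raise DomainError(f"F statistic must be non-negative, got {F}")
    if q < 1 or nu < 1:
        raise DomainError(f"degrees of freedom must be positive, got ({q}, {nu})")
    ratio = q * F / nu
    return ratio / (1.0 + ratio)


def collinearity(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Tolerance and VIF per predictor from each-on-the-others regressions."""
    if len(predictors) < 2:
        raise DomainError("collinearity diagnosis needs at least 2 predictors")
    X = table[list(predictors)].to_numpy(dtype=float)
    rows = {}
    for j, name in enumerate(predictors):
        others = np.column_stack([np.ones(len(X))] + [X[:, i] for i in range(X.shape[1]) if i != j])
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        if r2 > 1.0 - 1e-12:
            rows[name] = {"tol": 0.0, "vif": np.inf}
        else:
            rows[name] = {"tol": 1.0 - r2, "vif": 1.0 / (1.0 - r2)}
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_interaction_bic(table: pd.DataFrame, spec: ModelSpec) -> dict:
    """BIC of the main-effects model vs the model adding all pairwise
    interactions among the focal predictors; lower BIC wins."""
    if len(spec.predictors) < 2:
        return {
            "bic_main": None,
            "bic_interaction": None,
            "preferred": "main",
            "message": "a single focal predictor admits no pairwise interaction; "
            "main-effects model retained",
        }
    main = fit_model(table, spec, name="main")
    work = table.copy()
    inter_names = []
    zs = {}
    for p in spec.predictors:
        x = work[p].astype(float)
        zs[p] = (x - x.mean()) / x.std(ddof=1)
    for i, a in enumerate(spec.predictors):
        for b in spec.predictors[i + 1 :]:
            name = f"{a}:{b}"
            work[name] = zs[a] * zs[b]
            inter_names.append(name)
    inter_spec = ModelSpec(
        predictors=spec.predictors + tuple(inter_names),
        outcome=spec.outcome,
        covariates=spec.covariates,
    )
    inter = fit_model(work, inter_spec, name="interaction")
    preferred = "main" if main.bic <= inter.bic else "interaction"
    return {"bic_main": main.bic, "bic_interaction": inter.bic, "preferred": preferred}


def welch_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    pooled: bool = False,
) -> dict:
    """Two-sample t-test from summary statistics (Welch by default)."""
    if n1 < 2 or n2 < 2:
        raise DomainError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both group SDs are zero")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled)
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return {"t": float(t), "df": float(df), "p": float(p)}


def ttest_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    var_select: str = "ftest", alpha: float = ALPHA,
) -> dict:
    """Summary t-test with the classical variance-based method selection.

    ``var_select='ftest'`` applies a folded-F equality-of-variance test and
    uses the pooled statistic when it is non-significant, the Welch
    (Satterthwaite) statistic otherwise — the convention of mainstream
    commercial statistics suites. ``'welch'`` / ``'pooled'`` force a method.
    """
    if var_select in ("welch", "pooled"):
        out = welch_ttest(mean1, sd1, n1, mean2, sd2, n2, pooled=var_select == "pooled")
        out["method"] = var_select
        return out
    if var_select != "ftest":
        raise DomainError(f"unknown var_select {var_select!r}")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both group SDs are zero")
    (s_hi, n_hi), (s_lo, n_lo) = sorted(
        [(sd1, n1), (sd2, n2)], key=lambda x: x[0], reverse=True
    )
    if s_lo == 0:
        p_var = 0.0
    else:
        p_var = 2.0 * float(stats.f.sf((s_hi / s_lo) ** 2, n_hi - 1, n_lo - 1))
    method = "pooled" if p_var > alpha else "welch"
    out = welch_ttest(mean1, sd1, n1, mean2, sd2, n2, pooled=method == "pooled")
    out["method"] = method
    out["p_variance_test"] = min(p_var, 1.0)
    return out


@dataclass(frozen=True)
class SensitivityResult:
    """Minimal detectable effect of a single regression coefficient.

    ``f2`` is the minimal Cohen's f² at the requested power; ``f`` its square
    root (Cohen's f, numerically ≈ the detectable correlation for small
    effects and the scale on which such minima are conventionally quoted);
    ``r2``/``r`` apply the exact conversion R² = f²/(1+f²).
    """

    f2: float
    f: float
    r2: float
    r: float
    df: int
    delta: float
    tails: int
    ncp: str


def _power_single_coef(
    f2: float, n: int, n_predictors: int, alpha: float, tails: int, ncp: str
) -> float:
    df = n - n_predictors - 1
    n_eff = n if ncp == "n" else df + 1
    delta = np.sqrt(f2 * n_eff)
    if tails == 1:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, delta))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta))


def sensitivity_minimum_effect(
    n: int,
    alpha: float = 0.05,
    power: float = 0.8,
    n_predictors: int = 3,
    tails: int = 1,
    ncp: str = "n",
) -> SensitivityResult:
    """Solve the minimal f² detectable for a single regression coefficient.

    The test statistic is noncentral t with df = n - n_predictors - 1 and
    noncentrality √(f²·n) (``ncp='n'``, the convention matching the actual
    distribution of the coefficient t statistic; ``ncp='df1'`` uses
    √(f²·(df+1)) instead).
    """
    if n <= n_predictors + 1:
        raise DomainError("need n > n_predictors + 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise DomainError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise DomainError("tails must be 1 or 2")
    if ncp not in ("n", "df1"):
        raise DomainError("ncp must be 'n' or 'df1'")

    def gap(f2: float) -> float:
        return _power_single_coef(f2, n, n_predictors, alpha, tails, ncp) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise NoSolutionError("requested power unattainable for any finite effect")
    f2 = float(optimize.brentq(gap, 1e-12, hi, xtol=1e-12))
    df = n - n_predictors - 1
    r2 = f2 / (1.0 + f2)
    return SensitivityResult(
        f2=f2,
        f=float(np.sqrt(f2)),
        r2=r2,
        r=float(np.sqrt(r2)),
        df=df,
        delta=float(np.sqrt(f2 * (n if ncp == "n" else df + 1))),
        tails=tails,
        ncp=ncp,
    )


def empirical_power(
    f2: float,
    n: int,
    n_predictors: int = 3,
    alpha: float = 0.05,
    tails: int = 1,
    n_sims: int = 100_000,
    seed: int = 0,
    batch: int = 10_000,
) -> float:
    """Monte-Carlo power of the fixed-design single-coefficient test at f².

    The sensitivity analysis models a *fixed* regression design, so the
    replay uses one fixed design matrix with orthogonalized unit-variance
    predictors (focal column scaled to sum of squares n) and draws fresh
    unit-variance residuals each replicate; y = √f²·x₁ + ε then gives the
    focal t statistic exactly the noncentral-t distribution with
    noncentrality √(n·f²) that the solver inverts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF2]))
    beta = np.sqrt(f2)
    df = n - n_predictors - 1
    tcrit = stats.t.ppf(1.0 - alpha, df) if tails == 1 else stats.t.ppf(1.0 - alpha / 2.0, df)

    raw = rng.standard_normal((n, n_predictors))
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), raw]))
    X = q * np.sqrt(n)  # orthogonal columns, each with sum of squares n
    x1 = X[:, 1]
    proj = X.T / n  # (p+1, n); beta_hat = proj @ y for orthogonal X

    hits = 0
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        y = beta * x1[None, :] + rng.standard_normal((b, n))
        coef = y @ proj.T
        resid = y - coef @ X.T
        sigma2 = np.einsum("bi,bi->b", resid, resid) / df
        t = coef[:, 1] / np.sqrt(sigma2 / n)
        hits += int(np.sum(t > tcrit) if tails == 1 else np.sum(np.abs(t) > tcrit))
        done += b
    return hits / n_sims


# --- the full model sequence -------------------------------------------------

GLOBAL_FAMILIES: dict[str, list[str]] = {
    "global_cr": ["cr_global"],
    "global_affective": ["affective_global"],
    "global_al": ["al_global"],
    "global_sleep": ["sleep_global"],
}
SUB_FAMILIES: dict[str, list[str]] = {
    "sub_cr": ["education", "fnart", "occupation", "sport", "leisure"],
    "sub_affective": ["bdi", "bai"],
    "sub_al": [
        "al_cardio", "al_parasymp", "al_lipid", "al_glucose",
        "al_inflam", "al_hpa", "al_symp",
    ],
    "sub_sleep": ["iv", "psqi", "ess"],
}


@dataclass
class ModelSequenceReport:
    """All fitted model families plus the carried-forward significant terms."""

    models: dict[str, ModelFit] = field(default_factory=dict)
    significant_global: tuple[str, ...] = ()
    significant_sub: tuple[str, ...] = ()
    notes: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: fit.to_table() for name, fit in self.models.items()}


def _screened_fit(
    scored: pd.DataFrame, name: str, predictors: Sequence[str], outlier_k: float = 3.0
) -> ModelFit:
    spec = ModelSpec(predictors=tuple(predictors))
    screen_vars = [spec.outcome, "age", *predictors]
    screen = remove_outliers(scored, screen_vars, k=outlier_k)
    fit = fit_model(screen.table, spec, name=name)
    fit.removed_ids = screen.removed_ids
    fit.missing_ids = screen.missing_ids
    return fit


def run_model_sequence(scored: pd.DataFrame, outlier_k: float = 3.0) -> ModelSequenceReport:
    """Run the staged regression sequence on a scored cohort.

    Stage 1 relates the outcome to each global factor (reserve, affective
    state, allostatic load, sleep-wake quality) in separate models; stage 2
    decomposes each factor into its sub-scores; stage 3 refits carrying
    forward only the predictors significant at p < .05, for globals and for
    sub-scores. Every model gets its own ±3 SD outlier pass on the variables
    it uses, so the analysed n varies across models. Deterministic.
    """
    report = ModelSequenceReport()
    for stage in (GLOBAL_FAMILIES, SUB_FAMILIES):
        for name, predictors in stage.items():
            report.models[name] = _screened_fit(scored, name, predictors, outlier_k)

    def significant(family: dict[str, list[str]]) -> tuple[str, ...]:
        keep = []
        for name, predictors in family.items():
            fit = report.models[name]
            keep += [p for p in predictors if fit.term(p)["p"] < ALPHA]
        return tuple(keep)

    report.significant_global = significant(GLOBAL_FAMILIES)
    report.significant_sub = significant(SUB_FAMILIES)

    for name, carried in (
        ("combined_global", report.significant_global),
        ("combined_sub", report.significant_sub),
    ):
        if carried:
            report.models[name] = _screened_fit(scored, name, carried, outlier_k)
        else:
            report.models[name] = _screened_fit(scored, name, (), outlier_k)
            report.notes.append(
                f"{name}: no significant predictors to carry forward; "
                "covariates-only model reported"
            )
    return report
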