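"""Inferential machinery: mixed models of age change, outcome regressions,
and the residualization procedure for collinear input predictors.

The residualization ("disentangle") procedure addresses a common problem
in input studies: two caregiver-input measures x1 and x2 (say, word length
and word frequency) are strongly correlated, so either could carry a
predictive effect on a child outcome y.  The procedure is:

1. regress x1 on x2; the residuals are the part of x1 not attributable
   to x2 (and vice versa);
2. fit ``y ~ resid(x1|x2) + x2 + covariates`` and
   ``y ~ resid(x2|x1) + x1 + covariates``;
3. a residual term that remains significant predicts y *above and beyond*
   the ambiguous shared variance.

By the Frisch–Waugh–Lovell theorem the coefficient on resid(x1|x2) in the
first model equals the coefficient on x1 in the joint model
``y ~ x1 + x2``; what the residualization buys is a clean significance
test for each variable's unique contribution, which the collinear joint
fit does not give.

OLS and the random-intercept model are fit via statsmodels (the mixed
model by REML); inference on mixed-model fixed effects uses a residual-df
t approximation rather than Satterthwaite.  Models mixing nested
(per-word-type) rows with session-level covariates mark those covariates'
standard errors and p-values as unreliable and suppress them.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("cdsbattery")


@dataclass
class ModelSpec:
    """Declarative model description for the config-driven CLI path."""

    response: str
    terms: list[str]
    group: str | None = None
    center: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group is not None and not isinstance(self.group, str):
            raise ValueError("at most one grouping factor, given by name")


@dataclass
class FitResult:
    """Coefficients and fit summaries for one model; unit of the ledger."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame           # columns: lower, upper
    resid: np.ndarray
    llf: float
    aic: float
    nobs: int
    k_params: int                    # parameters entering the AIC penalty
    df_resid: float
    group_var: float | None = None   # random-intercept variance (mixed only)
    resid_var: float | None = None
    inflated_alpha: bool = False
    cov_params: pd.DataFrame | None = None

    def term_names(self) -> list[str]:
        return list(self.params.index)


class RankDeficientError(ValueError):
    pass


def _design(X: pd.DataFrame | np.ndarray, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    X.columns = [str(c) for c in X.columns]
    if add_intercept and "Intercept" not in X.columns:
        X.insert(0, "Intercept", 1.0)
    return X.astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name a minimal set of columns involved in the dependency
        bad = []
        cols = list(X.columns)
        for i in range(len(cols)):
            sub = np.delete(mat, i, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[i])
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns involve "
            f"{bad or cols}"
        )


def fit_ols(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    add_intercept: bool = True,
    unnested_terms: list[str] | None = None,
) -> FitResult:
    """Ordinary least squares with residual-df t inference.

    ``unnested_terms`` names session-level covariates broadcast over nested
    (per-word-type) rows; their SE/p are suppressed (NaN) and the fit is
    flagged ``inflated_alpha``, since repeating a per-session value across
    rows understates its sampling variability.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of parameters")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    k_params = X.shape[1] + 1             # coefficients + error variance
    out = FitResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=ci,
        resid=np.asarray(res.resid),
        llf=float(res.llf),
        aic=float(2 * k_params - 2 * res.llf),
        nobs=int(res.nobs),
        k_params=k_params,
        df_resid=float(res.df_resid),
        resid_var=float(res.scale),
        cov_params=res.cov_params(),
    )
    if unnested_terms:
        missing = set(unnested_terms) - set(out.params.index)
        if missing:
            raise ValueError(f"unnested terms not in model: {sorted(missing)}")
        out.inflated_alpha = True
        for term in unnested_terms:
            out.bse[term] = np.nan
            out.pvalues[term] = np.nan
            out.tvalues[term] = np.nan
            out.conf_int.loc[term] = [np.nan, np.nan]
    return out


def fit_random_intercept(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    add_intercept: bool = True,
) -> FitResult:
    """Linear mixed model with a single random intercept, fit by REML.

    Fixed-effect t tests use a residual-df approximation
    (df = n - k - number of groups + 1); contrasts downstream are
    therefore approximate.
    """
    X = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if len(set(group)) < 2:
        raise ValueError("random-intercept model needs >= 2 groups")
    _check_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=group)
        res = model.fit(reml=True)
    if not res.converged:
        raise RuntimeError(
            f"mixed model did not converge; profile: {res.summary()}")
    k = X.shape[1]
    n_groups = len(set(group))
    df_resid = max(len(y) - k - (n_groups - 1), 1)
    params = res.fe_params
    bse = res.bse_fe
    tvals = params / bse
    pvals = pd.Series(
        2 * sps.t.sf(np.abs(tvals), df_resid), index=params.index)
    tcrit = sps.t.ppf(0.975, df_resid)
    ci = pd.DataFrame(
        {"lower": params - tcrit * bse, "upper": params + tcrit * bse})
    group_var = float(res.cov_re.iloc[0, 0])
    k_params = k + 2                      # fixed effects + 2 variances
    return FitResult(
        params=params,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        conf_int=ci,
        resid=np.asarray(res.resid),
        llf=float(res.llf),
        aic=float(2 * k_params - 2 * res.llf),
        nobs=len(y),
        k_params=k_params,
        df_resid=float(df_resid),
        group_var=group_var,
        resid_var=float(res.scale),
        cov_params=pd.DataFrame(
            np.asarray(res.cov_params())[:k, :k],
            index=params.index, columns=params.index),
    )


def timepoint_contrasts(
    fit: FitResult,
    timepoints: list[str],
    term_pattern: str = "timepoint[{}]",
    adjust: str = "holm",
) -> pd.DataFrame:
    """All pairwise timepoint differences with multiplicity adjustment.

    Assumes treatment coding: the first timepoint is the reference level
    and the remaining levels appear as dummy terms named by
    ``term_pattern``.  Adjustment is Holm by default ("none" disables it).
    """
    if fit.cov_params is None:
        raise ValueError("fit carries no parameter covariance")
    names = {tp: term_pattern.format(tp) for tp in timepoints[1:]}
    for term in names.values():
        if term not in fit.params.index:
            raise ValueError(f"term {term!r} not found in fit")
    rows = []
    k = len(fit.params)
    for a, b in itertools.combinations(timepoints, 2):
        vec = pd.Series(0.0, index=fit.params.index)
        if a in names:
            vec[names[a]] = -1.0
        if b in names:
            vec[names[b]] = 1.0
        est = float(vec @ fit.params)
        se = float(np.sqrt(vec @ fit.cov_params.to_numpy() @ vec))
        tval = est / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(tval), fit.df_resid) if se > 0 else 1.0
        rows.append({"contrast": f"{b} - {a}", "estimate": est,
                     "se": se, "t": tval, "p": p})
    table = pd.DataFrame(rows)
    if adjust == "holm":
        table["p_adj"] = multipletests(table["p"], method="holm")[1]
    elif adjust == "none":
        table["p_adj"] = table["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def residualize(
    x: np.ndarray | pd.Series,
    z: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Residuals of OLS of x on z (plus intercept and optional covariates).

    The result is orthogonal to z, to the constant, and to each covariate.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z lengths differ")
    if np.ptp(z) == 0:
        raise ValueError("z is constant; residualization is undefined")
    design = pd.DataFrame({"z": z})
    if covariates is not None:
        for col in pd.DataFrame(covariates).columns:
            design[str(col)] = np.asarray(covariates[col], dtype=float)
    return fit_ols(design, x).resid


@dataclass
class DisentangleReport:
    pair: tuple[str, str]
    p_resid_x1: float                # resid(x1|x2) in y ~ resid + x2 + cov
    p_resid_x2: float
    coef_resid_x1: float
    coef_resid_x2: float
    classification: str              # x1_direct | x2_direct | both | neither
    correlation: float
    alpha: float
    fits: dict[str, FitResult] = field(default_factory=dict)


def disentangle(
    x1: np.ndarray | pd.Series,
    x2: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    names: tuple[str, str] = ("x1", "x2"),
) -> DisentangleReport:
    """Classify which of two collinear predictors carries a direct effect.

    Fits ``y ~ resid(x1|x2) + x2 + covariates`` and the mirror model, and
    classifies by which residual terms reach significance at ``alpha``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    r = float(np.corrcoef(x1, x2)[0, 1])
    if abs(r) < 0.1:
        log.warning(
            "disentangle: |corr(%s, %s)| = %.3f < 0.1 — residualization "
            "is unnecessary for near-orthogonal predictors", *names, abs(r))
    cov = pd.DataFrame(covariates).astype(float) if covariates is not None \
        else None

    def _one(resid_of, other, resid_name, other_name):
        resid = residualize(resid_of, other, cov)
        design = pd.DataFrame({resid_name: resid, other_name: other})
        if cov is not None:
            for col in cov.columns:
                design[str(col)] = cov[col].to_numpy()
        return fit_ols(design, y), resid_name

    fit1, term1 = _one(x1, x2, f"resid_{names[0]}", names[1])
    fit2, term2 = _one(x2, x1, f"resid_{names[1]}", names[0])
    p1 = float(fit1.pvalues[term1])
    p2 = float(fit2.pvalues[term2])
    sig1, sig2 = p1 < alpha, p2 < alpha
    if sig1 and sig2:
        classification = "both"
    elif sig1:
        classification = f"{names[0]}_direct"
    elif sig2:
        classification = f"{names[1]}_direct"
    else:
        classification = "neither"
    return DisentangleReport(
        pair=names,
        p_resid_x1=p1,
        p_resid_x2=p2,
        coef_resid_x1=float(fit1.params[term1]),
        coef_resid_x2=float(fit2.params[term2]),
        classification=classification,
        correlation=r,
        alpha=alpha,
        fits={"x1_resid_model": fit1, "x2_resid_model": fit2},
    )


def unnest_by_median(
    per_type_values: dict[str, list[float]],
    comparator: str = "ge",
) -> pd.Series:
    """Condense nested per-type values to one per-caregiver count.

    The split point is the pooled median over all caregivers' types
    (one observation per caregiver-type).  ``ge`` counts values at or above
    the median (long words); ``lt`` counts values strictly below (low
    frequency words).
    """
    from .lexical_battery import pooled_median

    med = pooled_median(per_type_values)
    if comparator == "ge":
        counts = {cg: sum(1 for v in vals if v is not None and v >= med)
                  for cg, vals in per_type_values.items()}
    elif comparator == "lt":
        counts = {cg: sum(1 for v in vals if v is not None and v < med)
                  for cg, vals in per_type_values.items()}
    else:
        raise ValueError("comparator must be 'ge' or 'lt'")
    return pd.Series(counts, name=f"count_{comparator}_median")


def compare_models(fits: dict[str, FitResult]) -> pd.DataFrame:
    """ΔAIC ranking plus likelihood-ratio tests for nested pairs.

    All fits must share the response (same n); nesting is judged by
    parameter count and term-name subset.
    """
    ns = {f.nobs for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"models fit to differing n: {sorted(ns)}")
    table = pd.DataFrame(
        {
            "llf": {name: f.llf for name, f in fits.items()},
            "aic": {name: f.aic for name, f in fits.items()},
            "k": {name: f.k_params for name, f in fits.items()},
        }
    ).sort_values("aic")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    lrt_rows = []
    for (na, fa), (nb, fb) in itertools.combinations(fits.items(), 2):
        small, big = (fa, fb) if fa.k_params < fb.k_params else (fb, fa)
        sname, bname = (na, nb) if fa.k_params < fb.k_params else (nb, na)
        if not set(small.term_names()) <= set(big.term_names()):
            continue
        df = big.k_params - small.k_params
        if df == 0:
            continue
        stat = 2 * (big.llf - small.llf)
        lrt_rows.append({
            "restricted": sname, "full": bname, "lr_stat": stat,
            "df": df, "p": float(sps.chi2.sf(max(stat, 0.0), df)),
        })
    table.attrs["lrt"] = pd.DataFrame(lrt_rows)
    return table


def mean_center(
    df: pd.DataFrame, columns: list[str] | None = None,
) -> pd.DataFrame:
    """Subtract the column mean from each named (or every numeric) column."""
    out = df.copy()
    cols = columns if columns is not None else [
        c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    for col in cols:
        out[col] = df[col] - df[col].mean()
    return out
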