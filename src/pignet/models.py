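"""Null/full mixed-model comparison for centrality and lesion outcomes.

The null (partial) model explains an outcome with the non-cognitive fixed
effects sex, body weight and network size (number of non-littermates), and
random intercepts for pen and litter.  The full model adds cognitive test
performance; its contribution is assessed by a Wald test of the term, an ML
likelihood-ratio test against the null refitted on the same rows, and the
change in AIC.

Continuous outcomes are modelled as Gaussian linear mixed models, fitted by
REML for reporting and by ML for likelihood comparisons; skewed outcomes
are log(x + 1)-transformed first and least-squares means are back-
transformed with e^(m +/- se) - 1.  Count and binary outcomes use Poisson
and binomial mixed GLMs (variational Bayes), whose logit-scale contrasts
are reported as odds ratios e^(m +/- se); for these families only Wald
tests are available, not likelihood ratios.

The pen random effect is the primary grouping; the litter random effect
enters as a variance component nested within pen.  Singular litter
components (estimated at zero) trigger a refit without the component and a
flag on the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import (
    BinomialBayesMixedGLM,
    PoissonBayesMixedGLM,
)
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FAMILIES = ("gaussian", "poisson", "binomial")
TRANSFORMS = ("none", "log1p")

#: significance and tendency thresholds used in reporting
ALPHA = 0.05
TENDENCY = 0.1


@dataclass(frozen=True)
class ModelSpec:
    """What to model and how.

    ``outcome`` names a column of the analysis table; ``fixed`` lists the
    non-cognitive fixed effects; ``random`` the grouping columns (pen, then
    litter).  ``transform`` applies to Gaussian outcomes only.
    """

    outcome: str
    family: str = "gaussian"
    transform: str = "log1p"
    fixed: tuple[str, ...] = ("sex", "weight_kg", "network_size")
    random: tuple[str, ...] = ("pen_id", "litter_id")

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.family != "gaussian" and self.transform != "none":
            raise ValueError("transforms apply to Gaussian outcomes only")


@dataclass
class ModelFit:
    """A fitted model with the quantities the reporting needs."""

    spec: ModelSpec
    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n_obs: int
    df_resid: float
    aic: Optional[float]  # ML AIC (Gaussian only)
    llf: Optional[float]  # ML log-likelihood (Gaussian only)
    rmse: Optional[float]
    vif: Optional[pd.Series]
    singular_random_effects: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    result: object = field(default=None, repr=False)
    data: pd.DataFrame = field(default=None, repr=False)


@dataclass
class ModelComparison:
    """Full-vs-null comparison for one cognitive term."""

    term: str
    wald_stat: float  # squared t/z of the term (1-df Wald)
    wald_p: float
    lrt_stat: Optional[float]
    lrt_df: Optional[int]
    lrt_p: Optional[float]
    delta_aic: Optional[float]  # AIC(full) - AIC(null), ML
    inclusion: Optional[ModelFit] = None


def back_transform(
    mean: float, se: float, transform: str
) -> tuple[float, float, float]:
    """Back-transform a model-scale estimate to the response scale.

    ``log1p``: e^m - 1 with interval (e^(m-se) - 1, e^(m+se) - 1).
    ``logit``: odds ratio e^m with interval e^(m +/- se).
    ``none``: identity with interval m +/- se.
    """
    if transform == "log1p":
        return (
            float(np.expm1(mean)),
            float(np.expm1(mean - se)),
            float(np.expm1(mean + se)),
        )
    if transform == "logit":
        return (
            float(np.exp(mean)),
            float(np.exp(mean - se)),
            float(np.exp(mean + se)),
        )
    if transform == "none":
        return float(mean), float(mean - se), float(mean + se)
    raise ValueError(f"unknown transform {transform!r}")


def _is_categorical(data: pd.DataFrame, col: str) -> bool:
    return (
        pd.api.types.is_object_dtype(data[col])
        or pd.api.types.is_bool_dtype(data[col])
        or isinstance(data[col].dtype, pd.CategoricalDtype)
    )


def _term_expr(data: pd.DataFrame, col: str) -> str:
    return f"C({col})" if _is_categorical(data, col) else col


def _prepare(
    data: pd.DataFrame, spec: ModelSpec, extra_terms: Sequence[str] = ()
) -> pd.DataFrame:
    cols = [spec.outcome, *spec.fixed, *spec.random, *extra_terms]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing model columns: {missing}")
    d = data[list(dict.fromkeys(cols))].dropna().copy()
    if len(d) == 0:
        raise ValueError("no complete cases for the requested model")
    y = d[spec.outcome].astype(float)
    if float(y.var()) == 0.0:
        raise ValueError(f"outcome {spec.outcome!r} has zero variance")
    d["_y"] = np.log1p(y) if spec.transform == "log1p" else y
    for col in (*spec.fixed, *extra_terms):
        if _is_categorical(d, col):
            d[col] = d[col].astype(str)
    for col in spec.random:
        d[col] = d[col].astype(str)
    return d


def _fixed_formula(d: pd.DataFrame, spec: ModelSpec, extra_terms: Sequence[str]) -> str:
    terms = [_term_expr(d, c) for c in (*spec.fixed, *extra_terms)]
    return "_y ~ " + " + ".join(terms) if terms else "_y ~ 1"


def _check_grouping(d: pd.DataFrame, spec: ModelSpec) -> None:
    for col in spec.random:
        if d[col].nunique() < 2:
            raise ValueError(f"random effect {col!r} needs >= 2 levels")


def _fit_mixedlm(
    d: pd.DataFrame,
    formula: str,
    spec: ModelSpec,
    reml: bool,
    drop_litter: bool = False,
):
    pen_col = spec.random[0]
    vc = None
    if len(spec.random) > 1 and not drop_litter:
        vc = {"litter": f"0 + C({spec.random[1]})"}
    model = smf.mixedlm(formula, d, groups=d[pen_col], vc_formula=vc)
    result = None
    notes: tuple[str, ...] = ()
    last_err = None
    # the default optimisation schedule converges most reliably; explicit
    # single optimisers are fallbacks for numerically awkward fits
    for method in (None, "powell", "nm"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                if method is None:
                    result = model.fit(reml=reml)
                else:
                    result = model.fit(reml=reml, method=method, maxiter=2000)
            notes = tuple(
                str(w.message)
                for w in caught
                if issubclass(w.category, ConvergenceWarning)
            )
            break
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    if result is None:
        raise RuntimeError(f"mixed-model fit failed: {last_err}")
    return result, notes


def _litter_vc_singular(result) -> bool:
    vcomp = getattr(result, "vcomp", None)
    if vcomp is None or len(vcomp) == 0:
        return False
    scale = max(float(result.scale), 1e-12)
    return bool(np.any(np.asarray(vcomp) / scale < 1e-6))


def _gaussian_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    extra_terms: Sequence[str] = (),
    force_drop_litter: Optional[bool] = None,
) -> ModelFit:
    d = _prepare(data, spec, extra_terms)
    _check_grouping(d, spec)
    formula = _fixed_formula(d, spec, extra_terms)

    if force_drop_litter:
        result, notes = _fit_mixedlm(d, formula, spec, reml=True, drop_litter=True)
        singular: tuple[str, ...] = (spec.random[1],)
    else:
        result, notes = _fit_mixedlm(d, formula, spec, reml=True)
        singular = ()
        if force_drop_litter is None and _litter_vc_singular(result):
            # litter variance estimated at (numerically) zero: refit without it
            result, notes2 = _fit_mixedlm(
                d, formula, spec, reml=True, drop_litter=True
            )
            notes = notes + notes2
            singular = (spec.random[1],)
    ml_result, _ = _fit_mixedlm(
        d, formula, spec, reml=False, drop_litter=bool(singular)
    )

    k_fe = len(result.fe_params)
    df_resid = max(len(d) - k_fe, 1)
    tvals = result.fe_params / result.bse_fe
    pvals = pd.Series(
        2.0 * stats.t.sf(np.abs(tvals), df_resid), index=result.fe_params.index
    )
    resid = np.asarray(result.resid)
    rmse = float(np.sqrt(np.mean(resid**2)))

    exog = result.model.exog
    exog_names = list(result.model.exog_names)
    vif = None
    if exog.shape[1] > 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            vif = pd.Series(
                [
                    variance_inflation_factor(exog, i)
                    for i in range(1, exog.shape[1])
                ],
                index=exog_names[1:],
            )

    return ModelFit(
        spec=spec,
        terms=tuple(result.fe_params.index),
        params=result.fe_params.copy(),
        bse=result.bse_fe.copy(),
        pvalues=pvals,
        n_obs=len(d),
        df_resid=float(df_resid),
        aic=float(ml_result.aic),
        llf=float(ml_result.llf),
        rmse=rmse,
        vif=vif,
        singular_random_effects=singular,
        warnings=notes,
        result=result,
        data=d,
    )


def _bayes_glmm_fit(
    data: pd.DataFrame, spec: ModelSpec, extra_terms: Sequence[str] = ()
) -> ModelFit:
    d = _prepare(data, spec, extra_terms)
    _check_grouping(d, spec)
    formula = _fixed_formula(d, spec, extra_terms)
    vc_formulas = {"pen": f"0 + C({spec.random[0]})"}
    if len(spec.random) > 1:
        vc_formulas["litter"] = f"0 + C({spec.random[1]})"
    cls = PoissonBayesMixedGLM if spec.family == "poisson" else BinomialBayesMixedGLM
    if spec.family == "binomial":
        levels = set(d["_y"].unique())
        if not levels <= {0.0, 1.0}:
            raise ValueError("binomial outcomes must be 0/1")
    model = cls.from_formula(formula, vc_formulas, d)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit_vb()
    k = len(result.fe_mean)
    names = list(result.model.exog_names)
    params = pd.Series(result.fe_mean, index=names)
    bse = pd.Series(result.fe_sd, index=names)
    z = params / bse
    pvals = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names)
    return ModelFit(
        spec=spec,
        terms=tuple(names),
        params=params,
        bse=bse,
        pvalues=pvals,
        n_obs=len(d),
        df_resid=float(len(d) - k),
        aic=None,
        llf=None,
        rmse=None,
        vif=None,
        warnings=tuple(str(w.message) for w in caught),
        result=result,
        data=d,
    )


def fit_null(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the null (partial) model: non-cognitive fixed effects plus pen
    and litter random intercepts; no cognitive performance terms."""
    if spec.family == "gaussian":
        return _gaussian_fit(data, spec)
    return _bayes_glmm_fit(data, spec)


def _term_coef_names(fit: ModelFit, term: str) -> list[str]:
    expr = f"C({term})"
    return [
        name
        for name in fit.terms
        if name == term or name.startswith(expr + "[")
    ]


def fit_full_and_compare(
    data: pd.DataFrame,
    spec: ModelSpec,
    cognitive_term: str,
    inclusion_term: Optional[str] = None,
) -> tuple[ModelFit, ModelComparison]:
    """Add a cognitive term to the null model and test its contribution.

    The inclusion flag (tested vs not tested), when supplied, is evaluated
    first in a model over all pigs.  The cognitive term itself is defined
    only for tested pigs, so the full model and a null refit are compared
    on that subset: Wald test of the term, ML likelihood-ratio test and
    delta-AIC (Gaussian), or Wald only (mixed GLMs).
    """
    if cognitive_term not in data.columns:
        raise ValueError(f"unknown cognitive term {cognitive_term!r}")
    if data[cognitive_term].dropna().nunique() < 2:
        raise ValueError(
            f"cognitive term {cognitive_term!r} has fewer than two levels; "
            "comparison refused"
        )

    inclusion_fit = None
    if inclusion_term is not None:
        inclusion_fit = (
            _gaussian_fit(data, spec, extra_terms=(inclusion_term,))
            if spec.family == "gaussian"
            else _bayes_glmm_fit(data, spec, extra_terms=(inclusion_term,))
        )

    subset = data[data[cognitive_term].notna()]
    if spec.family == "gaussian":
        full = _gaussian_fit(subset, spec, extra_terms=(cognitive_term,))
        # the ML likelihood comparison requires the same random structure
        null = _gaussian_fit(
            subset, spec, force_drop_litter=bool(full.singular_random_effects)
        )
    else:
        full = _bayes_glmm_fit(subset, spec, extra_terms=(cognitive_term,))
        null = _bayes_glmm_fit(subset, spec)

    coef_names = _term_coef_names(full, cognitive_term)
    if not coef_names:
        raise ValueError(f"term {cognitive_term!r} absent from the full model")
    # 1-df Wald for a binary/continuous term; multi-level terms use the
    # largest single-coefficient statistic per level plus the LRT below
    stats_sq = []
    for c in coef_names:
        se = float(full.bse[c])
        z = float(full.params[c]) / se if se > 0 else float("inf")
        stats_sq.append((z**2, float(full.pvalues[c])))
    wald_stat, wald_p = max(stats_sq, key=lambda s: s[0])

    lrt_stat = lrt_df = lrt_p = delta_aic = None
    if spec.family == "gaussian" and full.llf is not None and null.llf is not None:
        lrt_stat = max(0.0, 2.0 * (full.llf - null.llf))
        lrt_df = len(full.terms) - len(null.terms)
        lrt_p = float(stats.chi2.sf(lrt_stat, lrt_df)) if lrt_df > 0 else float("nan")
        delta_aic = float(full.aic - null.aic)

    comparison = ModelComparison(
        term=cognitive_term,
        wald_stat=float(wald_stat),
        wald_p=float(wald_p),
        lrt_stat=lrt_stat,
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        delta_aic=delta_aic,
        inclusion=inclusion_fit,
    )
    return full, comparison


def ls_means(fit: ModelFit, factor: str) -> pd.DataFrame:
    """Back-transformed least-squares means per level of a fixed factor.

    Each level's mean is the average fixed-effect prediction over the
    observed covariate distribution with the factor set to that level; the
    interval is e^(m +/- se) - 1 on a log1p scale, the odds-ratio interval
    on a logit scale, and m +/- se otherwise.
    """
    if fit.result is None or fit.data is None:
        raise ValueError("fit carries no design information")
    d = fit.data
    if factor not in d.columns:
        raise ValueError(f"factor {factor!r} not in the model data")
    levels = sorted(d[factor].dropna().unique())
    if fit.spec.family == "gaussian":
        design_info = fit.result.model.data.design_info
        beta = fit.result.fe_params.to_numpy()
        cov = np.asarray(fit.result.cov_params())[: len(beta), : len(beta)]
        scale = fit.spec.transform
    else:
        design_info = fit.result.model.data.design_info
        beta = np.asarray(fit.params)
        cov = np.diag(np.asarray(fit.bse) ** 2)
        scale = "logit"
    from patsy import build_design_matrices

    rows = []
    for level in levels:
        d_level = d.copy()
        d_level[factor] = level
        (X,) = build_design_matrices([design_info], d_level)
        xbar = np.asarray(X).mean(axis=0)
        m = float(xbar @ beta)
        se = float(np.sqrt(xbar @ cov @ xbar))
        est, lo, hi = back_transform(m, se, scale)
        rows.append(
            {
                "factor": factor,
                "level": level,
                "mean_model_scale": m,
                "se_model_scale": se,
                "estimate": est,
                "lower": lo,
                "upper": hi,
            }
        )
    return pd.DataFrame(rows)


def fit_report(fit: ModelFit, comparison: Optional[ModelComparison] = None) -> str:
    """Human-readable single-model report."""
    lines = [
        f"outcome: {fit.spec.outcome} (family={fit.spec.family}, "
        f"transform={fit.spec.transform}), n={fit.n_obs}",
    ]
    if fit.singular_random_effects:
        lines.append(
            f"  NOTE: singular random effects dropped: "
            f"{', '.join(fit.singular_random_effects)}"
        )
    lines.append(f"{'term':<28}{'estimate':>10}{'se':>9}{'p':>9}")
    for name in fit.terms:
        lines.append(
            f"{name:<28}{fit.params[name]:>10.4f}{fit.bse[name]:>9.4f}"
            f"{fit.pvalues[name]:>9.4f}"
        )
    if fit.aic is not None:
        lines.append(f"AIC (ML): {fit.aic:.1f}   RMSE: {fit.rmse:.4f}")
    if comparison is not None:
        lines.append(
            f"cognitive term {comparison.term}: Wald={comparison.wald_stat:.2f} "
            f"(p={comparison.wald_p:.3f})"
        )
        if comparison.lrt_stat is not None:
            lines.append(
                f"  LRT chi2={comparison.lrt_stat:.2f} df={comparison.lrt_df} "
                f"(p={comparison.lrt_p:.3f}); delta AIC={comparison.delta_aic:+.1f}"
            )
    return "\n".join(lines)
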