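"""Mixed-effects inference for serial-addition accuracy and latency.

Accuracy (binary: genuine error on a list's first presentation) is
modelled with a logistic random-intercept model, fitted by maximum
likelihood with adaptive Gauss–Hermite quadrature over the participant
intercept.  Latency is modelled with a linear mixed model (participants as
a random intercept) via :class:`statsmodels` ``MixedLM``, fitted by ML so
that nested models can be compared with likelihood-ratio tests.  Pairwise
contrasts between factor levels use Tukey's studentized-range adjustment;
latency contrasts additionally report a partial eta-squared computed as
``t^2 / (t^2 + df)``.

Incremental pseudo-R² of an added fixed factor is, by default, the
increase in marginal R² — the share of total (fixed + random + residual)
variance attributable to the fixed effects — with a likelihood-based
(Cox–Snell) variant reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from . import measurement
from .measurement import _order_types

__all__ = [
    "ConvergenceError",
    "DegenerateDataError",
    "GlmmResult",
    "ModelFit",
    "ComparisonResult",
    "fit_logistic_glmm",
    "fit_accuracy_model",
    "fit_latency_model",
    "compare_models",
    "run_study_analysis",
]


class ConvergenceError(RuntimeError):
    """A model fit failed to converge; carries optimizer diagnostics."""


class DegenerateDataError(ValueError):
    """The outcome carries no information (e.g. zero-variance binary data)."""


# --------------------------------------------------------------------------
# design matrices


def _is_categorical(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s) or pd.api.types.is_bool_dtype(s)


def _build_design(
    data: pd.DataFrame, terms: list[str], cell_means_factor: str | None = None
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Intercept + treatment-coded dummies / numeric columns for ``terms``.

    With ``cell_means_factor`` set, that factor is coded with one column
    per level and no intercept, so its coefficients are directly the level
    means (at zero of the remaining covariates).
    """
    n = len(data)
    cols: list[np.ndarray] = []
    names: list[str] = []
    levels_map: dict[str, list] = {}
    if cell_means_factor is None:
        cols.append(np.ones(n))
        names.append("Intercept")
    else:
        levels = _order_types(data, cell_means_factor)
        levels_map[cell_means_factor] = levels
        for lvl in levels:
            cols.append((data[cell_means_factor] == lvl).to_numpy(dtype=float))
            names.append(f"{cell_means_factor}[{lvl}]")
    for term in terms:
        if term == cell_means_factor:
            continue
        s = data[term]
        if _is_categorical(s):
            levels = _order_types(data, term)
            levels_map[term] = levels
            for lvl in levels[1:]:
                cols.append((s == lvl).to_numpy(dtype=float))
                names.append(f"{term}[{lvl}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), names, levels_map


# --------------------------------------------------------------------------
# logistic mixed model (ML, Gauss-Hermite quadrature)


@dataclass
class GlmmResult:
    """ML fit of a logistic random-intercept model."""

    params: np.ndarray  # fixed effects
    se: np.ndarray
    cov: np.ndarray  # fixed-effects covariance
    sigma_u: float  # random-intercept SD (logit scale)
    llf: float
    exog_names: list[str]
    n_obs: int
    n_groups: int
    n_quad: int
    converged: bool
    grad_norm: float
    message: str


def fit_logistic_glmm(
    endog,
    exog: np.ndarray,
    groups,
    exog_names: list[str] | None = None,
    n_quad: int = 21,
) -> GlmmResult:
    """Fit ``logit P(y=1) = X b + u_g``, ``u_g ~ N(0, sigma^2)`` by ML.

    The marginal likelihood integrates the participant intercept with
    ``n_quad``-node Gauss–Hermite quadrature; the fixed-effects covariance
    comes from the inverse observed information.
    """
    y = np.asarray(endog, dtype=float)
    X = np.asarray(exog, dtype=float)
    codes, uniq = pd.factorize(np.asarray(groups))
    n_groups = len(uniq)
    if y.min() == y.max():
        raise DegenerateDataError(
            "binary outcome has zero variance (all "
            + ("successes" if y.max() == 1 else "failures")
            + "); the accuracy model is not identifiable"
        )
    p = X.shape[1]
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(wts) - 0.5 * np.log(np.pi)
    sq2_nodes = np.sqrt(2.0) * nodes

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        lp = (X @ beta)[:, None] + sigma * sq2_nodes[None, :]
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        ll_g = np.zeros((n_groups, n_quad))
        np.add.at(ll_g, codes, ll_obs)
        return -float(special.logsumexp(ll_g + log_w[None, :], axis=1).sum())

    start_glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.r_[start_glm.params, np.log(0.5)]
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    grad_norm = float(np.max(np.abs(res.jac)))
    # BFGS with numerical gradients often reports precision loss at the
    # optimum; accept solutions whose gradient is numerically flat.
    converged = bool(res.success) or grad_norm < 1.0
    if not converged:
        raise ConvergenceError(
            f"logistic mixed model did not converge: {res.message} "
            f"(max |grad| = {grad_norm:.3g}, nll = {res.fun:.3f})"
        )
    hess = approx_hess1(res.x, nll)
    cov_all = np.linalg.pinv(hess)
    cov = cov_all[:p, :p]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return GlmmResult(
        params=res.x[:p],
        se=se,
        cov=cov,
        sigma_u=float(np.exp(res.x[p])),
        llf=-float(res.fun),
        exog_names=exog_names or [f"x{i}" for i in range(p)],
        n_obs=len(y),
        n_groups=n_groups,
        n_quad=n_quad,
        converged=converged,
        grad_norm=grad_norm,
        message=str(res.message),
    )


# --------------------------------------------------------------------------
# shared contrast machinery


def _tukey_p(t_abs: float, k: int, df: float) -> float:
    return float(stats.studentized_range.sf(t_abs * np.sqrt(2.0), k, df))


def _pairwise_contrasts(
    levels: list,
    level_cols: dict,
    params: np.ndarray,
    cov: np.ndarray,
    df: float,
    scale: str,
) -> pd.DataFrame:
    """All pairwise level contrasts with Tukey-adjusted p-values.

    ``level_cols`` maps each level to its column index in the cell-means
    design.  ``df`` may be ``inf`` for Wald (z-based) contrasts.
    """
    k = len(levels)
    rows = []
    for i in range(1, k):
        for j in range(i):
            a, b = levels[i], levels[j]
            L = np.zeros(len(params))
            L[level_cols[a]] = 1.0
            L[level_cols[b]] = -1.0
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else np.nan
            tukey_df = df if np.isfinite(df) else 1e6
            p_adj = _tukey_p(abs(t), k, tukey_df)
            if np.isfinite(df):
                p_un = 2.0 * stats.t.sf(abs(t), df)
            else:
                p_un = 2.0 * stats.norm.sf(abs(t))
            row = {
                "contrast": f"{a} vs {b}",
                "estimate": est,
                "se": se,
                "stat": t,
                "df": df,
                "p_unadjusted": float(p_un),
                "p_tukey": p_adj,
                "adjustment": "tukey",
            }
            if scale == "logit":
                row["odds_ratio"] = float(np.exp(est))
            else:
                row["eta_p2"] = float(t**2 / (t**2 + df)) if np.isfinite(df) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelFit:
    """Summary of a fitted mixed model plus its pairwise contrasts."""

    formula: str
    family: str  # "gaussian" or "binomial"
    params: pd.Series
    se: pd.Series
    re_var: float  # participant random-intercept variance
    scale: float  # residual variance (gaussian) or pi^2/3 (binomial latent)
    llf: float
    n_obs: int
    n_groups: int
    df_resid: float
    marginal_means: pd.DataFrame
    contrasts: pd.DataFrame
    result: object = field(repr=False, default=None)


# --------------------------------------------------------------------------
# accuracy (logistic) model


def fit_accuracy_model(
    data: pd.DataFrame,
    outcome: str = "error",
    factor: str = "list_type",
    groups: str = "participant_id",
    n_quad: int = 21,
) -> ModelFit:
    """Logistic mixed model of first-presentation errors by list type.

    Returns level marginal means (logit scale) and all pairwise contrasts
    with odds ratios and Tukey-adjusted p-values.
    """
    X, names, levels_map = _build_design(data, [factor], cell_means_factor=factor)
    levels = levels_map[factor]
    fit = fit_logistic_glmm(data[outcome], X, data[groups], exog_names=names,
                            n_quad=n_quad)
    level_cols = {lvl: i for i, lvl in enumerate(levels)}
    mm = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.se,
            "prob": special.expit(fit.params),
        },
        index=pd.Index(levels, name=factor),
    )
    contrasts = _pairwise_contrasts(
        levels, level_cols, fit.params, fit.cov, np.inf, scale="logit"
    )
    return ModelFit(
        formula=f"{outcome} ~ {factor} + (1 | {groups})",
        family="binomial",
        params=pd.Series(fit.params, index=names),
        se=pd.Series(fit.se, index=names),
        re_var=fit.sigma_u**2,
        scale=float(np.pi**2 / 3.0),
        llf=fit.llf,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
        df_resid=np.inf,
        marginal_means=mm,
        contrasts=contrasts,
        result=fit,
    )


# --------------------------------------------------------------------------
# latency (linear) model


def fit_latency_model(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    covariates: tuple[str, ...] = (),
    groups: str = "participant_id",
    reml: bool = True,
) -> ModelFit:
    """Linear mixed model of latency by a factor, participants random.

    Fitted by REML by default (the variance estimates that calibrate the
    intervals are then unbiased with few participants); likelihood-ratio
    model comparisons refit by ML.  Marginal means are evaluated at the
    sample mean of any
    covariates; their confidence intervals use a t distribution with
    ``n_groups - 1`` degrees of freedom (the between-participant level at
    which a type mean is estimated).  Contrast p-values use the residual
    degrees of freedom with Tukey's studentized-range adjustment.
    """
    terms = [factor, *covariates]
    X, names, levels_map = _build_design(data, terms, cell_means_factor=factor)
    levels = levels_map[factor]
    codes, uniq = pd.factorize(data[groups])
    n_groups = len(uniq)
    if n_groups < 2:
        warnings.warn(
            "only one participant: the random-intercept variance is not "
            "identifiable and will be ~0",
            UserWarning,
            stacklevel=2,
        )
        reml = False  # REML's between-group correction is vacuous here
    y = data[outcome].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=codes)
        res = model.fit(reml=reml)
    k_fe = len(names)
    fe = np.asarray(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
    df_resid = max(len(y) - k_fe - n_groups, 1)
    level_cols = {lvl: i for i, lvl in enumerate(levels)}
    cov_means = np.array(
        [data[c].to_numpy(dtype=float).mean() for c in covariates], dtype=float
    )
    mm_rows = []
    t_crit = stats.t.ppf(0.975, max(n_groups - 1, 1))
    for lvl in levels:
        L = np.zeros(k_fe)
        L[level_cols[lvl]] = 1.0
        L[len(levels):] = cov_means
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov_fe @ L))
        mm_rows.append(
            {factor: lvl, "estimate": est, "se": se,
             "ci_low": est - t_crit * se, "ci_high": est + t_crit * se}
        )
    mm = pd.DataFrame(mm_rows).set_index(factor)
    contrasts = _pairwise_contrasts(
        levels, level_cols, fe, cov_fe, float(df_resid), scale="identity"
    )
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    if n_groups < 2 or re_var < 1e-10:
        if n_groups >= 2:
            warnings.warn(
                "estimated participant variance is ~0", UserWarning, stacklevel=2
            )
    return ModelFit(
        formula=f"{outcome} ~ {factor}"
        + ("".join(f" + {c}" for c in covariates))
        + f" + (1 | {groups})",
        family="gaussian",
        params=pd.Series(fe, index=names),
        se=pd.Series(np.sqrt(np.diag(cov_fe)), index=names),
        re_var=re_var,
        scale=float(res.scale),
        llf=float(res.llf),
        n_obs=len(y),
        n_groups=n_groups,
        df_resid=float(df_resid),
        marginal_means=mm,
        contrasts=contrasts,
        result=res,
    )


# --------------------------------------------------------------------------
# nested model comparison


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of nested fixed-effect structures."""

    chi2: float
    df: int
    p: float
    pseudo_r2: float  # incremental marginal R^2 of the added factor
    pseudo_r2_likelihood: float  # Cox-Snell style alternative
    llf_base: float
    llf_full: float
    formula_base: str
    formula_full: str


def _marginal_r2(
    X: np.ndarray, beta: np.ndarray, re_var: float, resid_var: float
) -> float:
    var_f = float(np.var(X @ beta))
    return var_f / (var_f + re_var + resid_var)


def _fit_ml(data, outcome, terms, groups, family):
    X, names, _ = _build_design(data, terms)
    if family == "gaussian":
        codes, _u = pd.factorize(data[groups])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(data[outcome].to_numpy(dtype=float), X, groups=codes).fit(
                reml=False
            )
        llf = float(res.llf)
        beta = np.asarray(res.fe_params)
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        resid_var = float(res.scale)
    elif family == "binomial":
        res = fit_logistic_glmm(data[outcome], X, data[groups], exog_names=names)
        llf = res.llf
        beta = res.params
        re_var = res.sigma_u**2
        resid_var = float(np.pi**2 / 3.0)
    else:
        raise ValueError(f"unknown family {family!r}")
    return X, names, llf, _marginal_r2(X, beta, re_var, resid_var)


def compare_models(
    data: pd.DataFrame,
    outcome: str,
    base_terms: list[str],
    added_term: str | None,
    groups: str = "participant_id",
    family: str = "gaussian",
) -> ComparisonResult:
    """Likelihood-ratio test for adding one fixed factor to a base model.

    Both models are fitted by maximum likelihood on the same rows with the
    same random-intercept structure.  ``added_term=None`` compares the base
    model with itself (chi2 = 0, df = 0).  Adding a term already present is
    refused, since the models would not be strictly nested.
    """
    if added_term is not None and added_term in base_terms:
        raise ValueError(
            f"{added_term!r} is already in the base model; "
            "the comparison would not be nested"
        )
    full_terms = list(base_terms) + ([added_term] if added_term else [])
    Xb, names_b, llf_b, r2_b = _fit_ml(data, outcome, list(base_terms), groups, family)
    if added_term is None:
        Xf, names_f, llf_f, r2_f = Xb, names_b, llf_b, r2_b
    else:
        Xf, names_f, llf_f, r2_f = _fit_ml(data, outcome, full_terms, groups, family)
    chi2 = 2.0 * (llf_f - llf_b)
    if chi2 < 0:
        if chi2 > -1e-4:
            chi2 = 0.0
        else:
            raise ConvergenceError(
                f"ML likelihood decreased when adding {added_term!r} "
                f"(2*dLL = {chi2:.4f}); a fit failed to converge"
            )
    df = len(names_f) - len(names_b)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    n = len(data)
    return ComparisonResult(
        chi2=float(chi2),
        df=int(df),
        p=p,
        pseudo_r2=float(r2_f - r2_b),
        pseudo_r2_likelihood=float(1.0 - np.exp(-chi2 / n)),
        llf_base=llf_b,
        llf_full=llf_f,
        formula_base=f"{outcome} ~ {' + '.join(base_terms) or '1'}",
        formula_full=f"{outcome} ~ {' + '.join(full_terms) or '1'}",
    )


# --------------------------------------------------------------------------
# orchestration


def _contrasts_records(fit: ModelFit) -> list[dict]:
    return fit.contrasts.to_dict(orient="records")


def run_study_analysis(
    log: pd.DataFrame,
    study: int | None = None,
    config: measurement.MeasurementConfig | None = None,
) -> dict:
    """Full analysis of one study's trial log.

    Produces the list-type accuracy and latency panels (tables plus
    Tukey-adjusted pairwise contrasts), the per-type addition latency
    table, and the nested model comparisons pitting addition type against
    problem size, as a JSON-ready dictionary.
    """
    config = config or measurement.MeasurementConfig()
    if study is None:
        study = int(log["study"].iloc[0])

    # list-level accuracy
    acc_table = measurement.first_presentation_accuracy(log, config)
    lists = measurement.list_table(log)
    first = lists[(lists["presentation_index"] == 1) & ~lists["late_entry"]].copy()
    first["error"] = (~first["list_correct"]).astype(int)
    acc_fit = fit_accuracy_model(first)

    # list-level latency
    list_tab = measurement.list_latency_table(log, config)
    list_data = measurement.screened_list_data(log, config)
    list_fit = fit_latency_model(list_data, outcome="latency", factor="list_type")

    # addition-level latency and the type-versus-size model comparisons
    add_tab = measurement.addition_latency_table(log, config, by="category")
    add_data = measurement.screened_addition_data(log, config)
    size_name = "addend" if study == 1 else "addend_sum"
    cmp_type = compare_models(add_data, "latency_ms", [size_name], "category")
    cmp_size = compare_models(add_data, "latency_ms", ["category"], size_name)
    add_fit = fit_latency_model(add_data, outcome="latency_ms", factor="category")

    report = {
        "study": study,
        "n_participants": int(log["participant_id"].nunique()),
        "accuracy": {
            "table": acc_table.reset_index().to_dict(orient="records"),
            "contrasts": _contrasts_records(acc_fit),
            "model": {"llf": acc_fit.llf, "re_var": acc_fit.re_var,
                      "formula": acc_fit.formula},
        },
        "list_latency": {
            "table": list_tab.reset_index().to_dict(orient="records"),
            "n_outliers": list_tab.attrs["n_outliers"],
            "contrasts": _contrasts_records(list_fit),
            "model": {"llf": list_fit.llf, "re_var": list_fit.re_var,
                      "formula": list_fit.formula},
        },
        "additions": {
            "table": add_tab.reset_index().to_dict(orient="records"),
            "n_outliers": add_tab.attrs["n_outliers"],
            "contrasts": _contrasts_records(add_fit),
        },
        "model_comparison": {
            "addition_type_over_size": vars(cmp_type),
            "size_over_addition_type": vars(cmp_size),
        },
    }
    if study == 2:
        fine = measurement.addition_latency_table(log, config, by="step_type")
        report["additions"]["fine_table"] = fine.reset_index().to_dict(orient="records")
    return report
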