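"""Linear mixed models with Wald chi-squared tables and Tukey LS-means.

Thin layer over ``statsmodels`` MixedLM.  Crossed random intercepts (e.g.
collection month and replicate-within-individual) are expressed as variance
components within a single all-encompassing group, which is equivalent to
crossed random effects for intercept-only terms.  A variance component
estimated at (numerically) zero marks a singular fit; the offending term is
dropped and the model refit, degrading gracefully to OLS when no random
structure remains — which also makes the OLS limit exact rather than
approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["LMMResult", "fit_lmm", "lsmeans_tukey"]

_SINGULAR_REL_TOL = 1e-6


@dataclass
class LMMResult:
    """REML mixed-model fit summary.

    ``wald_table`` holds a Wald chi-squared test per fixed-effect term
    (multi-df for factors).  ``pseudo_r2`` follows the Nakagawa
    decomposition: marginal (fixed effects only) and conditional (fixed +
    random) shares of the total variance.
    """

    params: pd.DataFrame  # estimate, se, z, p per fixed coefficient
    wald_table: pd.DataFrame
    vc: dict[str, float]
    scale: float
    pseudo_r2_marginal: float
    pseudo_r2_conditional: float
    dropped_random: list[str]
    is_ols: bool
    n_obs: int
    df_resid: float
    formula: str
    result: object = field(repr=False, default=None)


def _term_slices(design_info, exog_names):
    slices = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        slices[term] = sl
    return slices


def _wald_terms(params, cov, design_info) -> pd.DataFrame:
    rows = []
    for term, sl in _term_slices(design_info, None).items():
        b = params[sl]
        V = cov[sl, sl]
        try:
            w = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            w = np.nan
        df = len(b)
        rows.append({"term": term, "wald_chi2": w, "df": df,
                     "p": stats.chi2.sf(w, df) if np.isfinite(w) else np.nan})
    return pd.DataFrame(rows)


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    random_effects: tuple[str, ...] = (),
    reml: bool = True,
) -> LMMResult:
    """Fit ``formula`` with crossed random intercepts for ``random_effects``.

    Each name in ``random_effects`` must be a column of ``data``; it enters
    as an intercept-only variance component.  Singular components are
    dropped (with a warning) and the model refit.
    """
    data = data.copy()
    re_terms = list(random_effects)
    dropped: list[str] = []

    while True:
        if re_terms:
            data["_all"] = 1
            vcf = {g: f"0 + C({g})" for g in re_terms}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups="_all",
                                    re_formula="0", vc_formula=vcf)
                # the REML surface is flat near vcomp = 0; gradient methods
                # can stall at spurious points, so race Powell against the
                # default and keep the higher restricted likelihood
                fits = []
                for method in ("powell", None):
                    try:
                        fits.append(model.fit(reml=reml, method=method)
                                    if method else model.fit(reml=reml))
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if not fits:
                    raise RuntimeError(f"mixed model failed to fit: {formula}")
                res = max(fits, key=lambda f: f.llf)
            vcomp = dict(zip(re_terms, np.atleast_1d(res.vcomp)))
            singular = [g for g, v in vcomp.items()
                        if v <= _SINGULAR_REL_TOL * res.scale]
            if singular:
                warnings.warn(
                    f"singular random effect(s) {singular}; refitting without",
                    stacklevel=2)
                dropped += singular
                re_terms = [g for g in re_terms if g not in singular]
                continue
            params = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[: len(params), : len(params)]
            exog_names = list(res.model.exog_names)
            design_info = res.model.data.design_info
            scale = float(res.scale)
            var_random = float(sum(vcomp.values()))
            fitted_fixed = res.model.exog @ params
            df_resid = res.nobs - len(params)
            is_ols = False
            break
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(formula, data).fit()
            params = np.asarray(res.params)
            cov = np.asarray(res.cov_params())
            exog_names = list(res.params.index)
            design_info = res.model.data.design_info
            scale = float(res.scale)
            vcomp = {}
            var_random = 0.0
            fitted_fixed = res.fittedvalues.values
            df_resid = res.df_resid
            is_ols = True
            break

    se = np.sqrt(np.diag(cov))
    ptab = pd.DataFrame({
        "estimate": params, "se": se, "z": params / se,
        "p": 2 * stats.norm.sf(np.abs(params / se)),
    }, index=exog_names)

    var_fixed = float(np.var(fitted_fixed, ddof=0))
    denom = var_fixed + var_random + scale
    return LMMResult(
        params=ptab,
        wald_table=_wald_terms(params, cov, design_info),
        vc={k: float(v) for k, v in vcomp.items()},
        scale=scale,
        pseudo_r2_marginal=var_fixed / denom if denom > 0 else np.nan,
        pseudo_r2_conditional=(var_fixed + var_random) / denom
        if denom > 0 else np.nan,
        dropped_random=dropped,
        is_ols=is_ols,
        n_obs=int(res.nobs),
        df_resid=float(df_resid),
        formula=formula,
        result=res,
    )


def lsmeans_tukey(
    lmm: LMMResult, data: pd.DataFrame, factor: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-based LS-means of ``factor`` and Tukey-adjusted pairwise
    contrasts (studentized-range distribution).

    LS-means evaluate the fixed-effect design at each factor level with all
    other predictors held at their observed means (factors averaged over
    their level frequencies... continuous covariates at their mean).  Levels
    with fewer than 2 observations are excluded from contrasts.
    """
    res = lmm.result
    design_info = res.model.data.design_info
    levels = [lv for lv in pd.unique(data[factor])]
    counts = data[factor].value_counts()

    # build design rows: copy the data, force the factor level, average rows
    from patsy import dmatrix
    L_rows = {}
    for lv in levels:
        d = data.copy()
        d[factor] = lv
        X = np.asarray(dmatrix(design_info, d, return_type="dataframe"))
        L_rows[lv] = X.mean(axis=0)

    params = (np.asarray(res.fe_params) if hasattr(res, "fe_params")
              else np.asarray(res.params))
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    means = {lv: float(L_rows[lv] @ params) for lv in levels}
    se_m = {lv: float(np.sqrt(L_rows[lv] @ cov @ L_rows[lv])) for lv in levels}
    means_df = pd.DataFrame({
        "level": levels,
        "lsmean": [means[lv] for lv in levels],
        "se": [se_m[lv] for lv in levels],
        "n": [int(counts.get(lv, 0)) for lv in levels],
    })

    usable = [lv for lv in levels if counts.get(lv, 0) >= 2]
    if len(usable) < len(levels):
        warnings.warn("factor level(s) with n < 2 excluded from contrasts",
                      stacklevel=2)
    k = len(usable)
    df = max(lmm.df_resid, 2.0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = usable[i], usable[j]
            Ld = L_rows[a] - L_rows[b]
            diff = float(Ld @ params)
            se = float(np.sqrt(Ld @ cov @ Ld))
            if se > 0:
                q = abs(diff) / se * np.sqrt(2.0)
                p = float(stats.studentized_range.sf(q, k, df)) if k >= 2 else np.nan
            else:
                q, p = 0.0, 1.0
            rows.append({"contrast": f"{a} - {b}", "estimate": diff,
                         "se": se, "q": q, "p_tukey": min(p, 1.0)})
    return means_df, pd.DataFrame(rows)
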