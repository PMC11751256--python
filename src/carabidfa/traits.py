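"""Layer 2 — trait quality screening and head-width models.

Before any trait enters a model it must survive screening: low measurement
error (ME) relative to the biological between-side signal, significant
variability across treatments, and approximately normal variation among
individuals.  The ME screen is the classical sides x individuals two-way
mixed ANOVA on the replicate measurements: the side x individual interaction
mean square carries the asymmetry signal, the residual mean square the
digitising error, and asymmetry is resolvable only when the former
significantly exceeds the latter.

The retained response (head width) is then modelled against wing morphology
(ordinal score 1/2/3 treated as numeric), treatment and body size
(right-elytron length), with collection month and replicate-within-individual
as random intercepts — first a frequentist prestep and mixed model, then a
Bayesian Gaussian linear model whose conditional effects give per-treatment
wing-morphology slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from carabidfa.bayes import PosteriorSummary, fit_bayes_lm
from carabidfa.mixedmodels import LMMResult, fit_lmm

__all__ = [
    "MEAssessment",
    "assess_measurement_error",
    "remove_outliers",
    "grubbs_mask",
    "prestep_screen",
    "screen_trait",
    "fit_headwidth_lmm",
    "fit_headwidth_bglm",
    "headwidth_table",
]

MIN_INDIVIDUALS_ME = 5


# ---------------------------------------------------------------------------
# Measurement-error ANOVA (sides x individuals with replicates)


@dataclass
class MEAssessment:
    """Variance decomposition of replicated bilateral measurements.

    ``f_signal`` tests MS(side x individual) against MS(error); the signal
    verdict is "resolvable" when significant, "ME_dominated" otherwise.
    ``pct_me`` is the measurement-error share of the variance of the
    replicate-averaged side difference:
    ``100 * (sigma_e^2 / m) / (sigma_si^2 + sigma_e^2 / m)``.
    """

    species: str
    trait: str
    n_individuals: int
    ms_individual: float
    ms_side: float
    ms_interaction: float
    ms_error: float
    f_signal: float
    p_signal: float
    pct_me: float
    verdict: str  # resolvable | ME_dominated | low_n


def assess_measurement_error(
    measurements: pd.DataFrame,
    species: str | None = None,
    trait: str | None = None,
    individuals: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> MEAssessment:
    """Two-way mixed ANOVA (sides fixed, individuals random) on replicates.

    Only complete cases (both sides, both replicates) enter.  With fewer
    than 5 such individuals the assessment is emitted with a low-n verdict.
    """
    m = measurements
    if trait is not None:
        m = m[m["trait"] == trait]
    if species is not None and individuals is not None:
        keep = individuals.loc[individuals["species"] == species, "individual_id"]
        m = m[m["individual_id"].isin(set(keep))]
    trait = trait if trait is not None else (m["trait"].iloc[0] if len(m) else "?")
    species = species or "all"

    wide = m.pivot_table(index="individual_id", columns=["side", "replicate"],
                         values="value")
    need = [("L", 1), ("L", 2), ("R", 1), ("R", 2)]
    if not all(c in wide.columns for c in need):
        return MEAssessment(species, trait, 0, *[np.nan] * 7, verdict="low_n")
    wide = wide[need].dropna()
    n = len(wide)
    if n < MIN_INDIVIDUALS_ME:
        warnings.warn(f"{species}/{trait}: only {n} complete individuals; "
                      "no ME verdict", stacklevel=2)
        return MEAssessment(species, trait, n, *[np.nan] * 7, verdict="low_n")

    x = wide.values.reshape(n, 2, 2)  # individual x side x replicate
    m_reps = 2
    grand = x.mean()
    ind_means = x.mean(axis=(1, 2))
    side_means = x.mean(axis=(0, 2))
    cell_means = x.mean(axis=2)

    ss_ind = 2 * m_reps * np.sum((ind_means - grand) ** 2)
    ss_side = n * m_reps * np.sum((side_means - grand) ** 2)
    ss_int = m_reps * np.sum(
        (cell_means - ind_means[:, None] - side_means[None, :] + grand) ** 2)
    ss_err = np.sum((x - cell_means[:, :, None]) ** 2)

    df_ind, df_side = n - 1, 1
    df_int = (n - 1) * 1
    df_err = n * 2 * (m_reps - 1)
    ms_ind, ms_side = ss_ind / df_ind, ss_side / df_side
    ms_int, ms_err = ss_int / df_int, ss_err / df_err

    if ms_err <= 0:
        f = np.inf if ms_int > 0 else 0.0
        p = 0.0 if ms_int > 0 else 1.0
    else:
        f = ms_int / ms_err
        p = float(stats.f.sf(f, df_int, df_err))

    sigma_si2 = max(ms_int - ms_err, 0.0) / m_reps
    me_part = ms_err / m_reps
    pct_me = 100.0 * me_part / (sigma_si2 + me_part) if (sigma_si2 + me_part) > 0 else np.nan
    verdict = "resolvable" if p < alpha else "ME_dominated"
    return MEAssessment(species, trait, n, ms_ind, ms_side, ms_int, ms_err,
                        float(f), p, float(pct_me), verdict)


# ---------------------------------------------------------------------------
# Iterative Grubbs outlier masking


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_mask(values: np.ndarray | pd.Series, alpha: float = 0.05) -> np.ndarray:
    """Boolean keep-mask from iterative two-sided Grubbs testing.

    Repeatedly removes the single most extreme value while the Grubbs
    statistic exceeds its critical value at ``alpha``.  Deterministic (ties
    break on first index) and terminating; never mutates the input.  With
    n < 3 or zero variance nothing is removed.
    """
    v = np.asarray(values, float)
    keep = np.isfinite(v)
    if keep.sum() < 3:
        warnings.warn("fewer than 3 values; no outlier test", stacklevel=2)
        return keep
    while keep.sum() >= 3:
        idx = np.flatnonzero(keep)
        x = v[idx]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        g = dev.max() / sd
        if g > _grubbs_critical(len(x), alpha):
            keep[idx[int(np.argmax(dev))]] = False
        else:
            break
    return keep


def remove_outliers(values: pd.Series | np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Inclusion mask for a per-trait value vector (see :func:`grubbs_mask`)."""
    return grubbs_mask(values, alpha)


# ---------------------------------------------------------------------------
# Screening and the head-width analysis table


def headwidth_table(individuals: pd.DataFrame, measurements: pd.DataFrame,
                    response_trait: str = "head_width") -> pd.DataFrame:
    """Per-replicate response rows joined to individual covariates.

    Each replicate measurement keeps its own row; individual identity is the
    replicate grouping for the mixed model.
    """
    m = measurements[measurements["trait"] == response_trait]
    avg = (m.groupby(["individual_id", "replicate"])["value"].mean()
           .rename("response").reset_index())
    out = avg.merge(individuals, on="individual_id", how="inner")
    out["wing_morph_num"] = out["wing_morph_code"].astype(float)
    return out


def screen_trait(
    individuals: pd.DataFrame,
    measurements: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    relevance_allowlist: tuple[str, ...] | None = None,
) -> dict:
    """Apply the four screening criteria to one trait (pooled species).

    Returns flags: low ME (sides x individuals ANOVA), treatment
    variability (one-way ANOVA p < alpha), normal variation among
    individuals (Shapiro-Wilk p > alpha on individual means), and ecological
    relevance (config allowlist; not computable from data).
    """
    me = assess_measurement_error(measurements, trait=trait)
    m = measurements[measurements["trait"] == trait]
    ind_means = (m.groupby("individual_id")["value"].mean().rename("value")
                 .reset_index().merge(individuals, on="individual_id"))
    groups = [g["value"].values for _, g in ind_means.groupby("treatment")]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        f_trt, p_trt = stats.f_oneway(*groups)
    else:
        f_trt, p_trt = np.nan, np.nan
    vals = ind_means["value"].values
    p_norm = stats.shapiro(vals)[1] if 3 <= len(vals) <= 5000 else np.nan
    relevant = (trait in relevance_allowlist) if relevance_allowlist else True
    passed = (me.verdict == "resolvable" and (p_trt < alpha if np.isfinite(p_trt) else False)
              and (p_norm > alpha if np.isfinite(p_norm) else True) and relevant)
    return {
        "trait": trait, "me_verdict": me.verdict, "pct_me": me.pct_me,
        "treatment_F": float(f_trt) if np.isfinite(f_trt) else np.nan,
        "treatment_p": float(p_trt) if np.isfinite(p_trt) else np.nan,
        "shapiro_p": float(p_norm) if np.isfinite(p_norm) else np.nan,
        "ecologically_relevant": relevant, "passed": passed,
    }


def prestep_screen(data: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Prestep: full fixed-effects fit of the response on wing morphology,
    sex and body size; candidates with Wald p > alpha are dropped.

    Returns the retained predictor list plus the per-candidate decisions.
    """
    lmm = fit_lmm(data, "response ~ wing_morph_num + C(sex) + body_size",
                  random_effects=())
    wt = lmm.wald_table.set_index("term")
    mapping = {"wing_morph_num": "wing_morph_num", "C(sex)": "C(sex)",
               "body_size": "body_size"}
    decisions = {}
    retained = []
    for term, col in mapping.items():
        p = float(wt.loc[term, "p"])
        keep = p <= alpha
        decisions[term] = {"p": p, "retained": keep}
        if keep:
            retained.append(col)
    return {"retained": retained, "decisions": decisions, "prestep": lmm}


def fit_headwidth_lmm(
    data: pd.DataFrame,
    predictors: list[str] | None = None,
) -> LMMResult:
    """REML mixed model of head width with month and individual (replicate
    grouping) random intercepts; Wald chi-squared table for fixed effects."""
    fixed = predictors if predictors is not None else [
        "wing_morph_num", "body_size"]
    formula = "response ~ C(treatment)" + "".join(f" + {p}" for p in fixed)
    return fit_lmm(data, formula, random_effects=("month", "individual_id"))


def fit_headwidth_bglm(
    data: pd.DataFrame,
    chains: int = 4,
    iterations: int = 3000,
    seed: int = 0,
    backend: str = "conjugate",
    predictors: list[str] | None = None,
) -> tuple[PosteriorSummary, pd.DataFrame]:
    """Bayesian head-width model with wing-morph x treatment structure.

    Extends the mixed model with per-treatment wing-morphology slopes (the
    conditional-effects display: wing morph on the x-axis, one panel per
    treatment).  Returns the posterior summary and the conditional-effects
    grid (posterior mean and 95% interval of the fitted response on the
    standardized scale at wing morph 1..3 for each treatment).
    """
    X = pd.DataFrame(index=data.index)
    X["wing_morph_num"] = data["wing_morph_num"].astype(float)
    if predictors is None or "body_size" in predictors:
        X["body_size"] = data["body_size"].astype(float)
    treatments = sorted(data["treatment"].unique())
    for t in treatments[1:]:
        X[f"treatment[{t}]"] = (data["treatment"] == t).astype(float)
        X[f"wing_morph_num:treatment[{t}]"] = (
            X["wing_morph_num"] * X[f"treatment[{t}]"])
    groups = {"month": data["month"], "individual": data["individual_id"]}
    post = fit_bayes_lm(data["response"], X, groups=groups, chains=chains,
                        iterations=iterations, seed=seed, backend=backend)

    # conditional-effects grid on the fitted (standardized) scale
    idata = post.idata
    draws = {name: np.asarray(idata.posterior[name]).ravel()
             for name in X.columns}
    intercept = np.asarray(idata.posterior["Intercept"]).ravel()
    wm_sd = X["wing_morph_num"].std(ddof=0) or 1.0
    wm_mean = X["wing_morph_num"].mean()
    rows = []
    for t in treatments:
        for wm in (1.0, 2.0, 3.0):
            mu = intercept + draws["wing_morph_num"] * (wm - wm_mean) / wm_sd
            if t != treatments[0]:
                dcol = X[f"treatment[{t}]"]
                icol = X[f"wing_morph_num:treatment[{t}]"]
                dz = ((1.0 - dcol.mean()) / (dcol.std(ddof=0) or 1.0))
                iz = ((wm - icol.mean()) / (icol.std(ddof=0) or 1.0))
                mu = mu + draws[f"treatment[{t}]"] * dz \
                    + draws[f"wing_morph_num:treatment[{t}]"] * iz
            lo, hi = np.quantile(mu, [0.025, 0.975])
            rows.append({"treatment": t, "wing_morph": wm,
                         "mean": float(mu.mean()), "ci_2.5%": float(lo),
                         "ci_97.5%": float(hi)})
    return post, pd.DataFrame(rows)
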