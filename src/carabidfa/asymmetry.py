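"""Layer 3 — fluctuating asymmetry: index, trait gating, and models.

Fluctuating asymmetry (FA) — small random deviations from perfect bilateral
symmetry — indexes developmental instability, but only after the competing
sources of between-side variation are excluded trait by trait:

* **measurement error** (ME): replicate noise must be significantly smaller
  than the between-side signal (sides x individuals ANOVA, Layer-2 screen);
* **antisymmetry**: a platykurtic / bimodal side-difference distribution
  (either side may be the larger) — detected by a one-sided test for
  negative excess kurtosis of the signed asymmetry;
* **directional asymmetry** (DA): a systematic mean side difference —
  detected by a one-sample t-test of the signed asymmetry against zero;
* **size dependence**: |R - L| varying with body size — detected by the
  regression ANOVA of |R - L| on right-elytron length; this does not
  exclude a trait, it adds body size as a covariate downstream.

The per-individual index is the size-standardized signed asymmetry with the
cohort-level DA term removed:

    s_i = (R_i - L_i) / (0.5 (L_i + R_i)),   FA_i = s_i - (1/N) sum_j s_j

so the cohort mean of ``FA`` is zero by construction, ``s`` is dimensionless
(invariant to unit changes) and antisymmetric under a left/right swap.
Models of "FA size" use the magnitude |FA| by default (configurable to the
squared or signed value).

Verdict precedence when several tests flag: ME_dominated > antisymmetry >
DA > size_dependent > true_FA.  Only true_FA traits (with a size covariate
where flagged) proceed to treatment / interaction / environment models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from carabidfa.bayes import PosteriorSummary, fit_bayes_lm
from carabidfa.mixedmodels import LMMResult, fit_lmm, lsmeans_tukey
from carabidfa.traits import MEAssessment, assess_measurement_error

__all__ = [
    "signed_relative_asymmetry",
    "asymmetry_table",
    "corrected_fa",
    "test_directional_asymmetry",
    "test_antisymmetry",
    "test_size_dependence",
    "classify_trait",
    "gate_traits",
    "TraitAssessment",
    "fit_treatment_lmm",
    "fit_interaction_models",
    "kendall_w",
    "kendall_concordance",
    "fit_env_bglm",
    "ENV_PREDICTORS",
]

MIN_COHORT_N = 5
MIN_N_ANTISYMMETRY = 10

#: Environmental fixed effects of the FA model (grass coverage == herbs).
ENV_PREDICTORS = ("formica", "collembola", "litter", "canopy_openness",
                  "herbs", "air_temp", "soil_moisture")


# ---------------------------------------------------------------------------
# Index


def signed_relative_asymmetry(R, L):
    """Size-standardized signed asymmetry ``s = (R - L) / (0.5 (L + R))``.

    Dimensionless, antisymmetric under side swap, invariant to uniform
    rescaling of all lengths.  Undefined (NaN) when L + R == 0.
    """
    R = np.asarray(R, float)
    L = np.asarray(L, float)
    denom = 0.5 * (L + R)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, (R - L) / denom, np.nan)
    return s if s.shape else float(s)


def asymmetry_table(
    individuals: pd.DataFrame,
    measurements: pd.DataFrame,
    trait: str,
    species: str | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Per-individual asymmetry rows for one trait (one species' cohort).

    Replicates are averaged per (individual, side) before computing ``s``
    (the index convention); with ``per_replicate=True`` each replicate pair
    keeps its own row instead — the layout the mixed models use, where
    replicate-within-individual is a random-effect grouping.
    """
    ind = individuals
    if species is not None:
        ind = ind[ind["species"] == species]
    m = measurements[(measurements["trait"] == trait)
                     & measurements["individual_id"].isin(set(ind["individual_id"]))]
    keys = ["individual_id", "replicate"] if per_replicate else ["individual_id"]
    wide = m.pivot_table(index=keys, columns="side", values="value")
    if "L" not in wide.columns or "R" not in wide.columns:
        return pd.DataFrame(columns=[*keys, "L", "R", "s", "abs_diff"])
    wide = wide.dropna(subset=["L", "R"]).reset_index()
    wide["s"] = signed_relative_asymmetry(wide["R"], wide["L"])
    wide["abs_diff"] = (wide["R"] - wide["L"]).abs()
    cols = ["individual_id", "sex", "wing_morph", "wing_morph_code",
            "treatment", "site_id", "month", "body_size", "species"]
    out = wide.merge(ind[cols], on="individual_id", how="left")
    out["wing_morph_num"] = out["wing_morph_code"].astype(float)
    return out.dropna(subset=["s"]).reset_index(drop=True)


@dataclass
class FAIndex:
    """DA-corrected FA values for one species x trait cohort."""

    values: pd.Series  # FA_corrected per row (index-aligned to the cohort)
    da_term: float  # the subtracted cohort mean of s
    n: int
    trait: str = ""
    species: str = ""

    def magnitude(self, transform: str = "abs") -> pd.Series:
        """|FA|, FA^2 or signed FA, per the configured magnitude transform."""
        if transform == "abs":
            return self.values.abs()
        if transform == "square":
            return self.values ** 2
        if transform == "signed":
            return self.values
        raise ValueError(f"unknown magnitude transform {transform!r}")


def corrected_fa(s: pd.Series | np.ndarray, min_n: int = MIN_COHORT_N,
                 trait: str = "", species: str = "") -> FAIndex:
    """Mean-center the signed asymmetry over the cohort's N individuals.

    ``FA_i = s_i - (sum_j s_j) / N`` removes the directional-asymmetry term;
    the cohort sum of the result is zero to floating tolerance.  Cohorts
    below ``min_n`` raise (callers map this to a low_n verdict).
    """
    s = pd.Series(np.asarray(s, float))
    s = s.dropna()
    n = len(s)
    if n < min_n:
        raise ValueError(f"cohort of {n} below minimum N={min_n}")
    da = float(s.mean())
    return FAIndex(values=s - da, da_term=da, n=n, trait=trait, species=species)


# ---------------------------------------------------------------------------
# Gating tests


def test_directional_asymmetry(s, alpha: float = 0.05):
    """One-sample two-sided t-test of the *uncorrected* signed asymmetry
    against zero; a significant mean marks the trait DA-biased.

    Zero-variance cohorts cannot be tested parametrically: the flag is then
    mean != 0 with p forced to 0 or 1 (logged).
    """
    s = np.asarray(pd.Series(s).dropna(), float)
    if len(s) < 2:
        return np.nan, np.nan, False
    if np.ptp(s) == 0:
        warnings.warn("zero-variance cohort in DA test", stacklevel=2)
        biased = s[0] != 0
        return (np.inf if biased else 0.0), (0.0 if biased else 1.0), bool(biased)
    t, p = stats.ttest_1samp(s, 0.0)
    return float(t), float(p), bool(p < alpha)


def test_antisymmetry(s, alpha: float = 0.05):
    """One-sided platykurtosis test of the signed asymmetry.

    Antisymmetry (either side may be the larger) makes the side-difference
    distribution bimodal, hence negative excess kurtosis; the flag is a
    significant one-sided kurtosis test in the platykurtic direction.
    Requires n >= 10; degenerate (constant) cohorts give no verdict.
    """
    s = np.asarray(pd.Series(s).dropna(), float)
    if len(s) < MIN_N_ANTISYMMETRY or np.ptp(s) == 0:
        if len(s) and np.ptp(s) == 0:
            warnings.warn("constant asymmetry values; antisymmetry test "
                          "degenerate", stacklevel=2)
        else:
            warnings.warn("n < 10; antisymmetry not assessed", stacklevel=2)
        return np.nan, np.nan, False
    n = len(s)
    kurt = float(stats.kurtosis(s, fisher=True, bias=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z, _ = stats.kurtosistest(s)
    # the Anscombe-Glynn transform loses the statistic's sign for extreme
    # platykurtosis (cube root of a negative ratio); restore it from the
    # sample excess kurtosis relative to its null expectation -6/(n+1)
    g2 = float(stats.kurtosis(s, fisher=True, bias=True))
    if g2 < -6.0 / (n + 1):
        z = -abs(z)
    p = float(stats.norm.cdf(z))
    return kurt, p, bool(p < alpha)


def test_size_dependence(abs_diff, body_size, alpha: float = 0.05):
    """Regression ANOVA of |R - L| on body size (right-elytron length).

    A significant slope flags the trait size-dependent, which adds body size
    as a covariate in the downstream models (it does not exclude the trait).
    """
    d = pd.DataFrame({"y": np.asarray(abs_diff, float),
                      "x": np.asarray(body_size, float)}).dropna()
    if len(d) < 3:
        return np.nan, np.nan, False
    if np.ptp(d["x"].values) == 0:
        warnings.warn("constant body size; size-dependence not testable",
                      stacklevel=2)
        return np.nan, np.nan, False
    if np.ptp(d["y"].values) == 0:
        return 0.0, 1.0, False
    res = smf.ols("y ~ x", d).fit()
    f = float(res.fvalue)
    p = float(res.f_pvalue)
    return f, p, bool(p < alpha)


@dataclass
class TraitAssessment:
    """Gating verdict for one (species, trait) with all test statistics."""

    species: str
    trait: str
    n: int
    verdict: str  # true_FA | DA | antisymmetry | ME_dominated | size_dependent | low_n
    needs_size_covariate: bool
    usable_for_fa: bool
    me_f: float = np.nan
    me_p: float = np.nan
    pct_me: float = np.nan
    da_t: float = np.nan
    da_p: float = np.nan
    kurtosis: float = np.nan
    kurtosis_p: float = np.nan
    size_f: float = np.nan
    size_p: float = np.nan


def classify_trait(
    me: MEAssessment,
    da: tuple,
    anti: tuple,
    size: tuple,
    n: int,
    species: str = "",
    trait: str = "",
) -> TraitAssessment:
    """Combine the gate outcomes into a single verdict.

    Precedence: ME_dominated > antisymmetry > DA > size_dependent > true_FA.
    Size dependence annotates the covariate need rather than excluding the
    trait, so both size_dependent and true_FA verdicts are usable for FA
    modelling.
    """
    da_t, da_p, da_flag = da
    kurt, kurt_p, anti_flag = anti
    size_f, size_p, size_flag = size

    if n < MIN_COHORT_N or me.verdict == "low_n":
        verdict = "low_n"
    elif me.verdict == "ME_dominated":
        verdict = "ME_dominated"
    elif anti_flag:
        verdict = "antisymmetry"
    elif da_flag:
        verdict = "DA"
    elif size_flag:
        verdict = "size_dependent"
    else:
        verdict = "true_FA"
    return TraitAssessment(
        species=species, trait=trait, n=n, verdict=verdict,
        needs_size_covariate=bool(size_flag),
        usable_for_fa=verdict in ("true_FA", "size_dependent"),
        me_f=me.f_signal, me_p=me.p_signal, pct_me=me.pct_me,
        da_t=da_t, da_p=da_p, kurtosis=kurt, kurtosis_p=kurt_p,
        size_f=size_f, size_p=size_p,
    )


def gate_traits(
    individuals: pd.DataFrame,
    measurements: pd.DataFrame,
    species: list[str] | None = None,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    min_n: int = MIN_COHORT_N,
) -> pd.DataFrame:
    """Run the full gate battery per (species, trait) cohort."""
    if species is None:
        species = sorted(individuals["species"].unique())
    if traits is None:
        paired = measurements.groupby("trait")["side"].nunique()
        traits = sorted(paired[paired == 2].index)
    rows = []
    for sp in species:
        for tr in traits:
            cohort = asymmetry_table(individuals, measurements, tr, species=sp)
            n = len(cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                me = assess_measurement_error(measurements, species=sp,
                                              trait=tr, individuals=individuals,
                                              alpha=alpha)
                if n >= min_n:
                    da = test_directional_asymmetry(cohort["s"], alpha)
                    anti = test_antisymmetry(cohort["s"], alpha)
                    size = test_size_dependence(cohort["abs_diff"],
                                                cohort["body_size"], alpha)
                else:
                    da = anti = size = (np.nan, np.nan, False)
            rows.append(classify_trait(me, da, anti, size, n, sp, tr).__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Models on the FA index


def fa_model_table(
    individuals: pd.DataFrame,
    measurements: pd.DataFrame,
    trait: str,
    species: str,
    magnitude: str = "abs",
    min_n: int = MIN_COHORT_N,
) -> pd.DataFrame:
    """Per-replicate modelling rows: DA-corrected FA magnitude + covariates.

    The DA term is estimated from the replicate-averaged cohort (the index
    definition) and subtracted from each replicate's signed asymmetry, so
    replicate rows stay centered on the same cohort correction.
    """
    avg = asymmetry_table(individuals, measurements, trait, species=species)
    if len(avg) < min_n:
        raise ValueError(f"{species}/{trait}: cohort below minimum N={min_n}")
    idx = corrected_fa(avg["s"], min_n=min_n, trait=trait, species=species)
    rep = asymmetry_table(individuals, measurements, trait, species=species,
                          per_replicate=True)
    rep["fa_signed"] = rep["s"] - idx.da_term
    fa = FAIndex(values=rep["fa_signed"], da_term=idx.da_term, n=idx.n,
                 trait=trait, species=species)
    rep["fa"] = fa.magnitude(magnitude)
    return rep


def fit_treatment_lmm(
    fa_table: pd.DataFrame,
    include_size: bool = False,
) -> tuple[LMMResult, pd.DataFrame, pd.DataFrame]:
    """Mixed model of FA magnitude on treatment.

    Random intercepts: collection month and replicate-within-individual.
    Returns the fit, the treatment LS-means and the Tukey-adjusted pairwise
    contrasts.
    """
    formula = "fa ~ C(treatment)" + (" + body_size" if include_size else "")
    lmm = fit_lmm(fa_table, formula,
                  random_effects=("month", "individual_id"))
    means, contrasts = lsmeans_tukey(lmm, fa_table, "treatment")
    return lmm, means, contrasts


def fit_interaction_models(fa_table: pd.DataFrame) -> dict:
    """Staged wing-morph / sex / treatment models of FA plus Levene's test.

    Stage (i): wing morph x sex interaction; (ii) treatment x wing morph;
    (iii) the combined model adding the sex x treatment relationship.  Each
    stage reports a type-II ANOVA table.  Levene's test (median-centered)
    checks homogeneity of FA variance across sex x treatment groups.
    """
    d = fa_table.copy()
    stages = {}
    specs = [
        ("wing_sex", "fa ~ wing_morph_num * C(sex)"),
        ("treatment_wing", "fa ~ C(treatment) * wing_morph_num"),
        ("full", "fa ~ wing_morph_num * C(sex) + C(treatment) * wing_morph_num"
                 " + C(sex) * C(treatment)"),
    ]
    for name, formula in specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.ols(formula, d).fit()
                stages[name] = sm.stats.anova_lm(res, typ=2)
        except Exception as exc:  # empty interaction cells
            warnings.warn(f"stage {name} failed: {exc}", stacklevel=2)
            stages[name] = None

    groups = [g["fa"].values for _, g in d.groupby(["sex", "treatment"])
              if len(g) >= 2]
    if len(groups) >= 2:
        lev_stat, lev_p = stats.levene(*groups, center="median")
    else:
        lev_stat, lev_p = np.nan, np.nan
    return {"stages": stages, "levene_W": float(lev_stat),
            "levene_p": float(lev_p)}


# ---------------------------------------------------------------------------
# Concordance across traits


def kendall_w(rank_matrix: pd.DataFrame | np.ndarray) -> tuple[float, float, float]:
    """Kendall's coefficient of concordance W across traits (judges).

    ``rank_matrix``: individuals x traits values (complete cases); each
    column is rank-transformed with midranks for ties.  Returns (W,
    chi-squared, p) with the tie-corrected statistic; the chi-squared
    approximation uses m(n-1)W with n-1 degrees of freedom.
    """
    X = pd.DataFrame(rank_matrix).dropna()
    n, m = X.shape
    if n < 3 or m < 2:
        raise ValueError("need >= 3 complete individuals and >= 2 traits")
    ranks = X.rank(axis=0)
    R = ranks.sum(axis=1).values
    S = float(np.sum((R - m * (n + 1) / 2.0) ** 2))
    T = 0.0  # tie correction: sum of (t^3 - t) over tied groups per trait
    for c in X.columns:
        tied = X[c].value_counts().values
        T += float(np.sum(tied ** 3 - tied))
    denom = m ** 2 * (n ** 3 - n) - m * T
    if denom <= 0:
        return np.nan, np.nan, np.nan
    W = 12.0 * S / denom
    chi2 = m * (n - 1) * W
    p = float(stats.chi2.sf(chi2, n - 1))
    return float(W), float(chi2), p


def kendall_concordance(
    fa_by_trait: pd.DataFrame,
    n_species_tested: int = 1,
) -> dict:
    """Concordance of FA magnitudes across >= 3 true-FA traits of a species.

    Bonferroni adjustment multiplies the p-value by the number of species
    for which the analysis ran.
    """
    X = fa_by_trait.dropna()
    if X.shape[1] < 3:
        raise ValueError("concordance needs at least 3 true-FA traits")
    W, chi2, p = kendall_w(X)
    return {"W": W, "chi2": chi2, "p": p,
            "p_bonferroni": min(1.0, p * n_species_tested),
            "traits": list(X.columns), "n": int(X.shape[0])}


# ---------------------------------------------------------------------------
# Environmental Bayesian model


def fit_env_bglm(
    fa_table: pd.DataFrame,
    env: pd.DataFrame,
    predictors: tuple[str, ...] = ENV_PREDICTORS,
    chains: int = 4,
    iterations: int = 4000,
    seed: int = 0,
    backend: str = "conjugate",
    include_size: bool = False,
) -> PosteriorSummary:
    """Bayesian model of FA magnitude on standardized environmental factors.

    Fixed effects: Formica activity, Collembola activity, litter, canopy
    openness, herb (grass) coverage, air temperature and soil moisture;
    random intercepts for month, replicate-within-individual and sex.
    An effect is significant when its 95% credible interval excludes zero;
    convergence is accepted up to R-hat 1.2 and predictive reliability is
    the share of observations with a good Pareto-k.
    """
    d = fa_table.copy()
    d["sample_id"] = d["site_id"].astype(str) + "-m" + d["month"].astype(str)
    joined = d.merge(env[["sample_id", *predictors]], on="sample_id",
                     how="inner")
    if joined.empty:
        raise ValueError("no FA rows joined to environment samples")
    X = joined[list(predictors)].astype(float)
    if include_size:
        X = X.assign(body_size=joined["body_size"].astype(float))
    groups = {"month": joined["month"], "individual": joined["individual_id"],
              "sex": joined["sex"]}
    return fit_bayes_lm(joined["fa"], X, groups=groups, chains=chains,
                        iterations=iterations, seed=seed, backend=backend,
                        standardize=True, rhat_threshold=1.2)
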