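"""End-to-end orchestration of the three analysis layers.

``run_all`` executes Layer 1 (assemblage ordination with forward selection),
Layer 2 (head-width screening and models) and Layer 3 (FA gating and
models) from a single configuration, with one seed fanning out to each
stochastic stage.  Environmental variables found significant in Layer 1
feed the Layer-3 FA-environment model unless the configuration overrides
the list.  A stage failure marks that stage failed in the run report;
independent later stages still run.
"""

from __future__ import annotations

import time
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from carabidfa import __version__, asymmetry, ordination, traits
from carabidfa.datamodel import (
    Dataset,
    load_dataset,
    validate_dataset,
    write_dataset,
    write_results,
)
from carabidfa.synthetic import CommunitySpec, simulate_dataset, stage_rng

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Run-level settings; flags override the config file."""

    input_dir: str | None = None  # load tables from here, else simulate
    out_dir: str = "results"
    seed: int = 1
    alpha: float = 0.05
    n_perm: int = 999
    mcmc_chains: int = 4
    mcmc_iterations_headwidth: int = 3000
    mcmc_iterations_env: int = 4000
    magnitude: str = "abs"
    downweight: bool = True
    covariables: tuple[str, ...] = ("month", "air_temp")
    env_variables: tuple[str, ...] | None = None  # override Layer-1 selection
    layers: tuple[str, ...] = ("layer1", "layer2", "layer3")
    simulate_n_per_cell: int = 2
    min_cohort_n: int = 5
    backend: str = "conjugate"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.magnitude not in ("abs", "square", "signed"):
            raise ValueError("magnitude must be abs | square | signed")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("covariables", "env_variables", "layers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _candidate_constraints(env: pd.DataFrame) -> pd.DataFrame:
    """Treatment level dummies plus the continuous habitat variables."""
    cand = ordination.dummy_code(env["treatment"])
    cand.columns = [c.capitalize() for c in cand.columns]
    cand["Herbs"] = env["herbs"].values
    cand["Litter"] = env["litter"].values
    return cand


_ENV_BY_LABEL = {"Herbs": "herbs", "Litter": "litter"}


def _run_layer1(ds: Dataset, cfg: RunConfig, report: dict, out: Path) -> dict:
    env = ds.environment.set_index("sample_id").loc[ds.community.index].reset_index()
    Yt = ordination.transform_abundances(ds.community, log=True,
                                         downweight=cfg.downweight)
    Z = pd.concat([
        ordination.dummy_code(env["month"].astype(int), prefix="month")
        if "month" in env.columns and "month" in cfg.covariables
        else pd.DataFrame(index=env.index),
        env[["air_temp"]] if "air_temp" in cfg.covariables
        else pd.DataFrame(index=env.index),
    ], axis=1)
    blocks = env["sample_id"].str.rsplit("-", n=1).str[0].values
    cand = _candidate_constraints(env)

    seed = int(stage_rng(cfg.seed, "layer1").integers(2 ** 31 - 1))
    fs = ordination.forward_select(Yt, cand, Z, blocks, n_perm=cfg.n_perm,
                                   seed=seed, alpha=cfg.alpha)
    selected = fs.loc[fs["selected"], "variable"].tolist()
    X = cand[selected] if selected else cand
    fit = ordination.fit_pcca(Yt, X, Z)
    f_all, p_all = ordination.restricted_permutation_test(
        Yt, X, Z, blocks, n_perm=cfg.n_perm, seed=seed + 1)

    valence = (ds.species_traits.set_index("species")["ecological_valence"]
               == "specialist").astype(float)
    cwm_val = ordination.compute_cwm(ds.community, valence.rename("cwm_specialist"))
    D = ordination.gower_distance(ds.species_traits)
    raoq = ordination.compute_raoq(ds.community, D)
    proj = ordination.project_supplementary(
        fit, pd.DataFrame({"cwm_specialist": cwm_val, "raoq": raoq}))

    write_results(fs, out / "layer1_forward_selection.csv")
    write_results(fit.site_scores.reset_index(), out / "layer1_site_scores.csv")
    write_results(fit.species_scores.reset_index(), out / "layer1_species_scores.csv")
    write_results(proj.reset_index(), out / "layer1_projections.csv")

    sig_env = [_ENV_BY_LABEL[v] for v in selected if v in _ENV_BY_LABEL]
    report["layer1"] = {
        "status": "ok",
        "explained_variation_pct": 100 * fit.explained_fraction,
        "explained_adjusted_pct": 100 * fit.explained_adjusted,
        "pseudo_F_all_axes": f_all,
        "p_all_axes": p_all,
        "selected": selected,
        "significant_env_variables": sig_env,
    }
    return {"significant_env": sig_env}


def _run_layer2(ds: Dataset, cfg: RunConfig, report: dict, out: Path) -> None:
    data = traits.headwidth_table(ds.individuals, ds.measurements)
    pres = traits.prestep_screen(data, alpha=cfg.alpha)
    lmm = traits.fit_headwidth_lmm(data, predictors=pres["retained"])
    seed = int(stage_rng(cfg.seed, "layer2").integers(2 ** 31 - 1))
    post, cond = traits.fit_headwidth_bglm(
        data, chains=cfg.mcmc_chains,
        iterations=cfg.mcmc_iterations_headwidth, seed=seed,
        backend=cfg.backend,
        predictors=pres["retained"])

    write_results(lmm.wald_table, out / "layer2_lmm_wald.csv")
    write_results(lmm.params.reset_index(names="term"), out / "layer2_lmm_params.csv")
    write_results(post.to_frame(), out / "layer2_bglm_posterior.csv")
    write_results(cond, out / "layer2_conditional_effects.csv")
    report["layer2"] = {
        "status": "ok",
        "n_obs": int(len(data)),
        "prestep_retained": pres["retained"],
        "rhat_max": post.rhat_max,
        "pareto_k_good_pct": post.pareto_k_good_pct,
        "elpd_loo": post.elpd_loo,
    }


def _run_layer3(ds: Dataset, cfg: RunConfig, report: dict, out: Path,
                env_vars: list[str]) -> None:
    gates = asymmetry.gate_traits(ds.individuals, ds.measurements,
                                  alpha=cfg.alpha, min_n=cfg.min_cohort_n)
    write_results(gates, out / "layer3_trait_assessments.csv")
    usable = gates[gates["usable_for_fa"]]

    seed_rng = stage_rng(cfg.seed, "layer3")
    model_rows, fa_frames, concordance = [], {}, []
    for _, row in usable.iterrows():
        sp, tr = row["species"], row["trait"]
        try:
            fa_tab = asymmetry.fa_model_table(
                ds.individuals, ds.measurements, tr, sp,
                magnitude=cfg.magnitude, min_n=cfg.min_cohort_n)
        except ValueError:
            continue
        fa_frames.setdefault(sp, {})[tr] = (
            fa_tab.groupby("individual_id")["fa"].mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lmm, means, contrasts = asymmetry.fit_treatment_lmm(
                fa_tab, include_size=bool(row["needs_size_covariate"]))
            inter = asymmetry.fit_interaction_models(fa_tab)
        trt_row = lmm.wald_table.set_index("term")
        trt_p = float(trt_row.loc["C(treatment)", "p"]) \
            if "C(treatment)" in trt_row.index else np.nan
        model_rows.append({
            "species": sp, "trait": tr, "treatment_wald_p": trt_p,
            "pseudo_r2_marginal": lmm.pseudo_r2_marginal,
            "pseudo_r2_conditional": lmm.pseudo_r2_conditional,
            "levene_p": inter["levene_p"],
        })
        env_pred = tuple(env_vars) if env_vars else asymmetry.ENV_PREDICTORS
        try:
            post = asymmetry.fit_env_bglm(
                fa_tab, ds.environment, predictors=env_pred,
                chains=cfg.mcmc_chains, iterations=cfg.mcmc_iterations_env,
                seed=int(seed_rng.integers(2 ** 31 - 1)), backend=cfg.backend)
            write_results(post.to_frame(),
                          out / f"layer3_env_bglm_{sp}_{tr}.csv")
            model_rows[-1]["pareto_k_good_pct"] = post.pareto_k_good_pct
            model_rows[-1]["rhat_max"] = post.rhat_max
        except ValueError as exc:
            warnings.warn(f"env model skipped for {sp}/{tr}: {exc}",
                          stacklevel=2)

    n_tested = sum(1 for sp, d in fa_frames.items() if len(d) >= 3)
    for sp, d in fa_frames.items():
        if len(d) >= 3:
            mat = pd.DataFrame(d)
            try:
                concordance.append({"species": sp,
                                    **asymmetry.kendall_concordance(mat, n_tested)})
            except ValueError:
                pass

    write_results(pd.DataFrame(model_rows), out / "layer3_model_summary.csv")
    if concordance:
        write_results(pd.DataFrame(concordance), out / "layer3_concordance.csv")
    report["layer3"] = {
        "status": "ok",
        "n_traits_assessed": int(len(gates)),
        "n_true_fa": int((gates["verdict"] == "true_FA").sum()),
        "verdicts": gates["verdict"].value_counts().to_dict(),
        "env_variables_used": list(env_vars) if env_vars
        else list(asymmetry.ENV_PREDICTORS),
    }


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured layers; returns the machine-readable report."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                         for k, v in cfg.__dict__.items()},
                              "version": __version__, "warnings": []}

    if cfg.input_dir:
        ds = load_dataset(cfg.input_dir)
    else:
        ds = simulate_dataset(cfg.seed, n_per_cell=cfg.simulate_n_per_cell)
        write_dataset(ds, out / "simulated_input")
    vrep = validate_dataset(ds)
    report["validation"] = {"passed": vrep.passed,
                            "n_errors": len(vrep.errors),
                            "n_warnings": len(vrep.warnings)}
    if not vrep.passed:
        report["validation"]["detail"] = vrep.summary()

    env_vars: list[str] = list(cfg.env_variables or [])
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        for layer, fn in (("layer1", _run_layer1), ("layer2", _run_layer2),
                          ("layer3", _run_layer3)):
            if layer not in cfg.layers:
                report[layer] = {"status": "disabled"}
                continue
            try:
                if layer == "layer1":
                    res = fn(ds, cfg, report, out)
                    if not cfg.env_variables:
                        env_vars = res["significant_env"]
                elif layer == "layer3":
                    fn(ds, cfg, report, out, env_vars)
                else:
                    fn(ds, cfg, report, out)
            except Exception:
                report[layer] = {"status": "failed",
                                 "traceback": traceback.format_exc()}
        report["warnings"] = sorted({str(w.message) for w in wlog})

    report["elapsed_s"] = round(time.time() - t0, 2)
    write_results(report, out / "run_report.json")
    return report
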