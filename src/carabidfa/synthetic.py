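"""Synthetic datasets with known ground truth for every pipeline layer.

The generators emulate the structure of the field study — three forest
treatments (clearing / control / ecotone) sampled on paired transects over
six 25-day collection periods, ~26 carabid species with ecological-valence
and diet labels, and per-individual bilateral trait measurements photographed
twice per side — while keeping every statistical component separately
tunable:

* **fluctuating asymmetry** (FA): individual signed side difference
  ``FA_i ~ Normal(0, fa_sd^2)``;
* **directional asymmetry** (DA): additive mean shift ``da_shift`` on R - L;
* **antisymmetry**: symmetric two-point mixture ``A_i = +-antisym_amp``
  (either side may be the larger, rarely neither), whose excess kurtosis
  is -2 in the pure case — the platykurtic signature the gating tests hunt;
* **measurement error** (ME): independent ``Normal(0, me_sd^2)`` noise per
  side per replicate photograph;
* **size dependence**: the signed difference is scaled by
  ``1 + size_dep_slope * z(body_size)``;
* **allometry**: trait size scales with body size as
  ``base_size * (body / median_body) ** allometric_slope``.

The signed difference of an individual is therefore

    R - L = (da_shift + FA_i + A_i) * (1 + size_dep_slope * z_i)

and each recorded value adds replicate ME noise.  Moments used by the
property tests (no size dependence): ``E[R - L] = da_shift``;
``Var(R - L) = fa_sd^2 + antisym_amp^2 + 2 me_sd^2`` for single-replicate
sides and ``fa_sd^2 + antisym_amp^2 + me_sd^2`` after averaging the two
replicates per side.

All generators are pure functions of (specification, seed).  A single run
seed fans out to per-stage child seeds via a CRC-keyed ``SeedSequence`` so
each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from carabidfa.datamodel import (
    Dataset,
    PAIRED_TRAITS,
    SEXES,
    TREATMENTS,
    WING_MORPH_CODE,
)

N_PERIODS = 6  # six 25-day collection periods, mid-April to mid-October


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for a named stage, reproducible from the run seed."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([key, int(seed) & 0x7FFFFFFF]))


# ---------------------------------------------------------------------------
# Trait specification and the shipped parameter card


@dataclass(frozen=True)
class TraitSpec:
    """Generative components of one bilateral trait (lengths in mm)."""

    trait: str
    base_size: float = 0.40
    allometric_slope: float = 0.0
    fa_sd: float = 0.0
    da_shift: float = 0.0
    antisym_amp: float = 0.0
    me_sd: float = 0.0
    size_dep_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fa_sd", "antisym_amp", "me_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.base_size <= 0:
            raise ValueError("base_size must be > 0")


# Shipped archetype card.  Scales are realistic for small carabid antennal /
# palp segments (~0.4 mm): digitising error ~2 um, developmental noise
# ~12 um (3% of trait size).  Each archetype is pure in one component.
ARCHETYPE_CARD: dict[str, TraitSpec] = {
    "true_FA": TraitSpec("a2", fa_sd=0.012, me_sd=0.002),
    "DA": TraitSpec("a2", fa_sd=0.012, me_sd=0.002, da_shift=0.024),
    "antisymmetry": TraitSpec("a2", fa_sd=0.004, me_sd=0.002, antisym_amp=0.025),
    "ME_dominated": TraitSpec("a2", fa_sd=0.002, me_sd=0.012),
    "size_dependent": TraitSpec("a2", fa_sd=0.012, me_sd=0.002,
                                size_dep_slope=0.6),
}


# ---------------------------------------------------------------------------
# Individuals


def simulate_individuals(
    n_per_cell: int,
    seed: int,
    species: str = "NRUF",
    treatments: Sequence[str] = TREATMENTS,
    months: Sequence[int] = tuple(range(1, N_PERIODS + 1)),
    sexes: Sequence[str] = SEXES,
    wing_morph_probs: Sequence[float] = (0.25, 0.35, 0.40),
    body_size_median: float = 5.0,
    body_size_cv: float = 0.08,
    sites_per_treatment: int = 2,
    id_prefix: str = "ind",
) -> pd.DataFrame:
    """Balanced individuals over treatment x period x sex design cells.

    Body size (right-elytron length, mm) is log-normal with the given median
    and coefficient of variation; wing morphs are drawn from
    ``wing_morph_probs`` (A, B, M).  Individuals are assigned round-robin to
    the paired transects (sites) of their treatment and alternately to
    pitfall / emergence traps.
    """
    rng = stage_rng(seed, "individuals")
    rows = []
    k = 0
    morphs = list(WING_MORPH_CODE)
    for trt_i, trt in enumerate(treatments):
        for month in months:
            for sex in sexes:
                for j in range(n_per_cell):
                    site = f"{trt[:2]}{(j % sites_per_treatment) + 1}"
                    rows.append({
                        "individual_id": f"{id_prefix}{k:05d}",
                        "species": species,
                        "sex": sex,
                        "wing_morph": morphs[rng.choice(3, p=wing_morph_probs)],
                        "treatment": trt,
                        "site_id": site,
                        "month": int(month),
                        "trap_type": "pitfall" if k % 5 else "emergence",
                        "body_size": np.nan,
                        })
                    k += 1
    df = pd.DataFrame(rows, columns=[
        "individual_id", "species", "sex", "wing_morph", "treatment",
        "site_id", "month", "trap_type", "body_size"])
    if len(df):
        sigma = np.sqrt(np.log1p(body_size_cv ** 2))
        df["body_size"] = body_size_median * np.exp(
            rng.standard_normal(len(df)) * sigma)
    df["wing_morph_code"] = df["wing_morph"].map(WING_MORPH_CODE).astype("Int64")
    return df


# ---------------------------------------------------------------------------
# Bilateral measurements


def simulate_bilateral(
    individuals: pd.DataFrame,
    specs: Sequence[TraitSpec] | TraitSpec,
    seed: int,
) -> pd.DataFrame:
    """Two replicate measurements per side per trait for every individual.

    Negative generated lengths are resampled (truncation at zero); paired
    traits receive L and R rows, the elytron and head width only R.
    """
    if isinstance(specs, TraitSpec):
        specs = [specs]
    rng = stage_rng(seed, "bilateral")
    n = len(individuals)
    body = individuals["body_size"].to_numpy(float)
    z = np.zeros(n) if n < 2 or body.std() == 0 else (body - body.mean()) / body.std()
    rel = body / np.median(body) if n else body

    frames = []
    for spec in specs:
        base = spec.base_size * rel ** spec.allometric_slope
        fa = rng.normal(0.0, spec.fa_sd, n) if spec.fa_sd > 0 else np.zeros(n)
        anti = (rng.choice([-1.0, 1.0], n) * spec.antisym_amp
                if spec.antisym_amp > 0 else np.zeros(n))
        d = (spec.da_shift + fa + anti) * (1.0 + spec.size_dep_slope * z)
        paired = spec.trait in PAIRED_TRAITS
        sides = {"L": base - d / 2, "R": base + d / 2} if paired else {"R": base}
        for side, true_val in sides.items():
            for repl in (1, 2):
                vals = true_val + (rng.normal(0.0, spec.me_sd, n)
                                   if spec.me_sd > 0 else 0.0)
                vals = np.asarray(vals, float)
                bad = vals <= 0
                while bad.any() and spec.me_sd > 0:  # lengths must stay positive
                    vals[bad] = true_val[bad] + rng.normal(0.0, spec.me_sd, bad.sum())
                    bad = vals <= 0
                if (vals <= 0).any():
                    raise ValueError(
                        f"trait {spec.trait}: non-positive noiseless lengths; "
                        "check base_size against asymmetry amplitudes")
                frames.append(pd.DataFrame({
                    "individual_id": individuals["individual_id"].to_numpy(),
                    "trait": spec.trait,
                    "side": side,
                    "replicate": repl,
                    "value": vals,
                }))
    if not frames:
        return pd.DataFrame(columns=["individual_id", "trait", "side",
                                     "replicate", "value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["individual_id", "trait", "side", "replicate"],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Community / environment


@dataclass(frozen=True)
class CommunitySpec:
    """Design of the sample x species abundance simulation.

    Abundances are Poisson with a Gaussian niche response on a latent
    environmental axis: ``log mu_si = log(abundance_scale) -
    association * (g_s - niche_pos_i)^2 / (2 niche_width_i^2)`` where
    ``g_s`` is the sample's gradient score.  ``association = 0`` makes every
    species independent of the environment (the permutation-test null).
    """

    n_species: int = 26
    n_samples_per_treatment: int = 12  # 2 sites x 6 periods
    association: float = 1.0
    abundance_scale: float = 8.0
    niche_width: float = 0.6
    # month-to-month (within-site) movement of the latent gradient; without
    # it, cyclic-shift permutation tests would be conditional on structure
    # they can never disturb and the synthetic study would be untestable
    env_noise_sd: float = 0.4
    specialist_fraction: float = 0.35
    diets: Sequence[str] = ("predator", "seed", "gastropod", "collembola")
    # per-variable coupling of the environment table to the latent gradient
    gradient_strengths: dict = field(default_factory=lambda: {
        "herbs": 1.0, "canopy_openness": -0.8, "litter": -0.6,
        "air_temp": 0.5, "soil_moisture": -0.3, "collembola": 0.4,
        "formica": 0.2,
    })

    def __post_init__(self) -> None:
        if self.niche_width <= 0:
            raise ValueError("niche_width must be > 0")
        if self.abundance_scale <= 0:
            raise ValueError("abundance_scale must be > 0")


# treatment means of the latent open-canopy gradient (clearing most open)
_TREATMENT_GRADIENT = {"clearing": 1.0, "ecotone": 0.0, "control": -1.0}


def simulate_community(
    spec: CommunitySpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(community matrix, environment table, species trait table).

    Samples are site x month cells of the three treatments; each treatment
    pins the latent gradient near its mean (clearing open and herb-rich,
    control closed), plus sample-level noise so months differ.
    """
    rng = stage_rng(seed, "community")
    months = range(1, N_PERIODS + 1)
    sites_per_trt = max(1, spec.n_samples_per_treatment // N_PERIODS)

    samples, gradient, trt_col, month_col = [], [], [], []
    for trt in TREATMENTS:
        for s in range(sites_per_trt):
            for m in months:
                samples.append(f"{trt[:2]}{s + 1}-m{m}")
                gradient.append(_TREATMENT_GRADIENT[trt]
                                + rng.normal(0, spec.env_noise_sd))
                trt_col.append(trt)
                month_col.append(m)
    g = np.asarray(gradient)
    n_samp = len(samples)

    species = [f"sp{j + 1:02d}" for j in range(spec.n_species)]
    niche_pos = rng.uniform(-1.3, 1.3, spec.n_species)
    log_mu = (np.log(spec.abundance_scale)
              - spec.association * (g[:, None] - niche_pos[None, :]) ** 2
              / (2 * spec.niche_width ** 2))
    counts = rng.poisson(np.exp(log_mu))
    community = pd.DataFrame(counts.astype(float), index=pd.Index(samples, name="sample_id"),
                             columns=species)

    month_temp = {m: 12.0 + 8.0 * np.sin((m - 0.5) / N_PERIODS * np.pi)
                  for m in months}
    env = pd.DataFrame({"sample_id": samples, "treatment": trt_col})
    st = spec.gradient_strengths
    env["herbs"] = np.clip(50 + 35 * st["herbs"] * g
                           + rng.normal(0, 5, n_samp), 0, 100)
    env["canopy_openness"] = np.clip(50 - 35 * abs(st["canopy_openness"]) * -g
                                     + rng.normal(0, 5, n_samp), 0, 100)
    env["litter"] = np.clip(1.2 + 0.8 * st["litter"] * g
                            + rng.normal(0, 0.1, n_samp), 0, None)
    env["air_temp"] = ([month_temp[m] for m in month_col]
                       + 1.5 * st["air_temp"] * g + rng.normal(0, 0.5, n_samp))
    env["soil_moisture"] = np.clip(40 + 15 * st["soil_moisture"] * g
                                   + rng.normal(0, 4, n_samp), 0, None)
    env["collembola"] = rng.poisson(np.exp(3.0 + st["collembola"] * g)).astype(float)
    env["formica"] = rng.poisson(np.exp(2.0 + st["formica"] * g)).astype(float)
    env["month"] = month_col
    env = env[["sample_id", "herbs", "canopy_openness", "litter", "air_temp",
               "soil_moisture", "collembola", "formica", "treatment", "month"]]

    n_specialist = int(round(spec.specialist_fraction * spec.n_species))
    valence = (["specialist"] * n_specialist
               + ["generalist"] * (spec.n_species - n_specialist))
    traits = pd.DataFrame({
        "species": species,
        "ecological_valence": valence,
        "dietary_preference": [spec.diets[j % len(spec.diets)]
                               for j in range(spec.n_species)],
    })
    return community, env, traits


# ---------------------------------------------------------------------------
# Archetype suite for gating recovery


def make_archetype_suite(
    seed: int,
    n_individuals: int = 60,
    card: dict[str, TraitSpec] | None = None,
) -> list[tuple[str, pd.DataFrame, pd.DataFrame]]:
    """Labelled (truth, individuals, measurements) cohorts, one per archetype.

    Each cohort is pure in a single asymmetry component so the trait-gating
    battery has an unambiguous correct verdict.
    """
    card = dict(ARCHETYPE_CARD if card is None else card)
    suite = []
    for i, (label, spec) in enumerate(card.items()):
        child = (int(seed) * 37 + i) & 0x7FFFFFFF
        n_cell = max(1, int(np.ceil(n_individuals / (3 * N_PERIODS * 2))))
        ind = simulate_individuals(n_cell, seed=child, id_prefix=f"{label[:2]}")
        ind = ind.iloc[:n_individuals].reset_index(drop=True)
        meas = simulate_bilateral(ind, spec, seed=child)
        suite.append((label, ind, meas))
    return suite


# ---------------------------------------------------------------------------
# Full dataset for end-to-end runs


def simulate_dataset(
    seed: int,
    n_per_cell: int = 2,
    trait_specs: Sequence[TraitSpec] | None = None,
    community_spec: CommunitySpec | None = None,
    focal_species: Sequence[str] = ("NRUF", "TQUA", "PCUP", "BLAM"),
) -> Dataset:
    """A complete five-table dataset for pipeline end-to-end runs.

    Focal species (the locally abundant taxa with enough individuals for FA
    work) get individual and bilateral records; the community matrix covers
    the full simulated species pool plus the focal species.
    """
    if trait_specs is None:
        trait_specs = [
            TraitSpec("a2", base_size=0.40, fa_sd=0.012, me_sd=0.002,
                      allometric_slope=0.5),
            TraitSpec("a3", base_size=0.32, fa_sd=0.010, me_sd=0.002,
                      allometric_slope=0.5),
            TraitSpec("a4", base_size=0.28, fa_sd=0.009, me_sd=0.002,
                      allometric_slope=0.5),
            TraitSpec("f_femur", base_size=1.10, fa_sd=0.010, me_sd=0.003,
                      da_shift=0.02, allometric_slope=0.8),
            TraitSpec("head_width", base_size=1.20, me_sd=0.003,
                      allometric_slope=0.9),
            TraitSpec("elytron_r", base_size=5.0, me_sd=0.004,
                      allometric_slope=1.0),
        ]
    community_spec = community_spec or CommunitySpec()

    ind_frames, meas_frames = [], []
    for i, sp in enumerate(focal_species):
        child = (int(seed) * 101 + i) & 0x7FFFFFFF
        ind = simulate_individuals(n_per_cell, seed=child, species=sp,
                                   id_prefix=f"{sp}_", body_size_median=5.0 - 0.4 * i)
        ind_frames.append(ind)
        meas_frames.append(simulate_bilateral(ind, trait_specs, seed=child))
    individuals = pd.concat(ind_frames, ignore_index=True)
    measurements = pd.concat(meas_frames, ignore_index=True)

    community, env, sp_traits = simulate_community(community_spec, seed)
    extra = pd.DataFrame({
        "species": list(focal_species),
        "ecological_valence": ["specialist", "generalist", "generalist",
                               "generalist"][: len(focal_species)],
        "dietary_preference": ["collembola", "predator", "predator",
                               "seed"][: len(focal_species)],
    })
    rng = stage_rng(seed, "dataset-focal")
    for i, sp in enumerate(focal_species):
        community[sp] = rng.poisson(3.0, len(community)).astype(float)
    sp_traits = pd.concat([sp_traits, extra], ignore_index=True)

    return Dataset(individuals, measurements, community, env, sp_traits)


def assign_samples(individuals: pd.DataFrame) -> pd.Series:
    """Sample key (site x month) used to join individuals to the environment."""
    return individuals["site_id"].astype(str) + "-m" + individuals["month"].astype(str)
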