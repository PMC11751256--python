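"""Shared data types, table I/O and structural validation.

Five flat tables drive the pipeline:

``individuals``     one row per beetle: species code, sex, wing morph
                    (A/B/M, numerically 1/2/3), treatment, site, collection
                    period (month), trap type, and body size measured as the
                    right-elytron length in mm.
``measurements``    one row per (individual, trait, side, replicate) length
                    in mm; paired traits carry L and R rows, unpaired traits
                    (head width, right elytron) R only; every present
                    (individual, trait, side) has exactly two replicates.
``community``       wide sample x species abundance matrix (non-negative
                    integers); sample key encodes site x month x trap.
``environment``     one row per sample: herb cover %, canopy openness %,
                    litter kg/m^2, mean air temperature degC, soil moisture,
                    Collembola activity, Formica polyctena activity,
                    treatment.
``species_traits``  one row per species: ecological valence
                    (specialist/generalist) and dietary preference.

Tables are delimiter-separated text with a header row (comma by default).
Missing sides are absent rows, never zeros or sentinels.  Keys are
case-sensitive strings and are never trimmed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Controlled vocabularies

WING_MORPH_CODE: dict[str, int] = {"A": 1, "B": 2, "M": 3}
SEXES = ("F", "M")
TREATMENTS = ("clearing", "control", "ecotone")
TRAP_TYPES = ("pitfall", "emergence")
SIDES = ("L", "R")
REPLICATES = (1, 2)

#: Bilateral traits measured on both sides.
PAIRED_TRAITS = (
    "f_femur",
    "f_tibia",
    "h_femur",
    "metatrochanter",
    "a2",
    "a3",
    "a4",
    "pm2",
    "pm3l",
    "pm3w",
)
#: Traits measured once (right side only).
UNPAIRED_TRAITS = ("head_width", "elytron_r")
TRAITS = PAIRED_TRAITS + UNPAIRED_TRAITS

ECOLOGICAL_VALENCES = ("specialist", "generalist")

INDIVIDUAL_COLUMNS = [
    "individual_id",
    "species",
    "sex",
    "wing_morph",
    "treatment",
    "site_id",
    "month",
    "trap_type",
    "body_size",
]
MEASUREMENT_COLUMNS = ["individual_id", "trait", "side", "replicate", "value"]
ENVIRONMENT_COLUMNS = [
    "sample_id",
    "herbs",
    "canopy_openness",
    "litter",
    "air_temp",
    "soil_moisture",
    "collembola",
    "formica",
    "treatment",
]
SPECIES_TRAIT_COLUMNS = ["species", "ecological_valence", "dietary_preference"]

#: Default file names inside a dataset directory.
TABLE_FILES = {
    "individuals": "individuals.csv",
    "measurements": "measurements.csv",
    "community": "community.csv",
    "environment": "environment.csv",
    "species_traits": "species_traits.csv",
}


class DataError(ValueError):
    """Fatal problem in an input table (missing file, unknown enum level...)."""


# ---------------------------------------------------------------------------
# Validation report


@dataclass
class ValidationEntry:
    severity: str  # "error" | "warning"
    message: str
    keys: tuple = ()


@dataclass
class ValidationReport:
    """Findings from structural validation.  Fails iff any error entry."""

    entries: list[ValidationEntry] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(e.severity == "error" for e in self.entries)

    @property
    def errors(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.severity == "error"]

    @property
    def warnings(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.severity == "warning"]

    def add(self, severity: str, message: str, keys: Iterable = ()) -> None:
        self.entries.append(ValidationEntry(severity, message, tuple(keys)))

    def summary(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"validation: {status} ({len(self.errors)} errors, "
                 f"{len(self.warnings)} warnings)"]
        lines += [f"  [{e.severity}] {e.message}" for e in self.entries]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class Dataset:
    """All pipeline tables, cross-linked by individual, sample and species keys.

    ``community`` is stored wide with the sample key as index and species
    codes as columns; the other tables are tidy frames.
    """

    individuals: pd.DataFrame
    measurements: pd.DataFrame
    community: pd.DataFrame
    environment: pd.DataFrame
    species_traits: pd.DataFrame

    def __eq__(self, other: object) -> bool:  # field-wise frame equality
        if not isinstance(other, Dataset):
            return NotImplemented
        try:
            for name in TABLE_FILES:
                a, b = getattr(self, name), getattr(other, name)
                pd.testing.assert_frame_equal(a, b, check_like=True)
        except AssertionError:
            return False
        return True


def _read_table(path: Path, columns: list[str], delimiter: str) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     skipinitialspace=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def _coerce_enum(df: pd.DataFrame, col: str, levels: tuple, path: str) -> None:
    bad = ~df[col].isin([str(v) for v in levels])
    if bad.any():
        rows = df.index[bad].tolist()
        vals = sorted(df.loc[bad, col].unique())
        raise DataError(
            f"{path}: unknown {col} level(s) {vals} at row index {rows[:10]}"
        )


def load_dataset(
    path_or_dir: str | Path | Mapping[str, str | Path],
    delimiter: str = ",",
) -> Dataset:
    """Load the five standard tables from a directory or an explicit mapping.

    Raises :class:`DataError` on a missing file, missing columns or an
    unknown enumeration level (with the offending row indices).  Dangling
    foreign keys are *not* fatal here; :func:`validate_dataset` collects
    them into a report.
    """
    if isinstance(path_or_dir, (str, Path)):
        base = Path(path_or_dir)
        paths = {k: base / v for k, v in TABLE_FILES.items()}
    else:
        paths = {k: Path(v) for k, v in path_or_dir.items()}

    ind = _read_table(paths["individuals"], INDIVIDUAL_COLUMNS, delimiter)
    if len(ind):
        _coerce_enum(ind, "sex", SEXES, str(paths["individuals"]))
        _coerce_enum(ind, "wing_morph", tuple(WING_MORPH_CODE), str(paths["individuals"]))
        _coerce_enum(ind, "treatment", TREATMENTS, str(paths["individuals"]))
        _coerce_enum(ind, "trap_type", TRAP_TYPES, str(paths["individuals"]))
    ind = ind.astype({"month": int, "body_size": float}, errors="raise")
    ind["wing_morph_code"] = ind["wing_morph"].map(WING_MORPH_CODE).astype("Int64")

    meas = _read_table(paths["measurements"], MEASUREMENT_COLUMNS, delimiter)
    if len(meas):
        _coerce_enum(meas, "side", SIDES, str(paths["measurements"]))
        _coerce_enum(meas, "replicate", REPLICATES, str(paths["measurements"]))
    meas = meas.astype({"replicate": int, "value": float}, errors="raise")

    comm_path = paths["community"]
    if not comm_path.exists():
        raise DataError(f"missing input file: {comm_path}")
    comm = pd.read_csv(comm_path, sep=delimiter, index_col=0)
    comm.index = comm.index.astype(str)
    comm.index.name = "sample_id"
    comm = comm.astype(float)

    env = _read_table(paths["environment"], ENVIRONMENT_COLUMNS, delimiter)
    if len(env):
        _coerce_enum(env, "treatment", TREATMENTS, str(paths["environment"]))
    env = env.astype(
        {c: float for c in ENVIRONMENT_COLUMNS[1:-1]}, errors="raise"
    )
    for extra in set(env.columns) - set(ENVIRONMENT_COLUMNS):
        try:
            env[extra] = pd.to_numeric(env[extra])
        except (ValueError, TypeError):
            pass

    spt = _read_table(paths["species_traits"], SPECIES_TRAIT_COLUMNS, delimiter)
    if len(spt):
        _coerce_enum(spt, "ecological_valence", ECOLOGICAL_VALENCES,
                     str(paths["species_traits"]))

    return Dataset(ind.reset_index(drop=True), meas.reset_index(drop=True),
                   comm, env.reset_index(drop=True), spt.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Validation


def validate_dataset(d: Dataset) -> ValidationReport:
    """Enforce the structural invariants of every table.

    Pure function of the dataset: idempotent, no mutation.  Errors are
    collected into the report rather than raised, so a single pass surfaces
    every problem.
    """
    rep = ValidationReport()
    ind, meas = d.individuals, d.measurements

    for name, df in (("individuals", ind), ("measurements", meas),
                     ("environment", d.environment),
                     ("species_traits", d.species_traits)):
        if df.empty:
            rep.add("warning", f"{name}: no rows")

    if ind["individual_id"].duplicated().any():
        dups = ind.loc[ind["individual_id"].duplicated(), "individual_id"]
        rep.add("error", "duplicate individual_id", tuple(dups))
    if len(ind):
        bad = ~np.isfinite(ind["body_size"]) | (ind["body_size"] <= 0)
        if bad.any():
            rep.add("error", "body_size must be finite and > 0",
                    tuple(ind.loc[bad, "individual_id"]))
        if not ind["month"].between(1, 12).all():
            rep.add("error", "month outside 1..12",
                    tuple(ind.loc[~ind["month"].between(1, 12), "individual_id"]))
        codes = ind["wing_morph"].map(WING_MORPH_CODE)
        if not (ind["wing_morph_code"] == codes).all():
            rep.add("error", "wing_morph numeric coding must be A=1, B=2, M=3")

    if len(meas):
        bad = ~np.isfinite(meas["value"]) | (meas["value"] <= 0)
        if bad.any():
            rep.add("error", "measurement values must be finite and > 0",
                    tuple(map(tuple, meas.loc[bad, ["individual_id", "trait"]].values)))
        known = set(ind["individual_id"])
        dangling = sorted(set(meas["individual_id"]) - known)
        if dangling:
            rep.add("error",
                    "measurements reference unknown individual_id", tuple(dangling))
        counts = meas.groupby(["individual_id", "trait", "side"]).size()
        odd = counts[counts != 2]
        if len(odd):
            rep.add("error",
                    "every (individual, trait, side) present must have exactly "
                    "2 replicates", tuple(odd.index.tolist()))
        unknown_traits = sorted(set(meas["trait"]) - set(TRAITS))
        if unknown_traits:
            rep.add("warning", f"non-standard trait codes: {unknown_traits}")

    comm = d.community
    if (comm.values < 0).any():
        ii, jj = np.nonzero(comm.values < 0)
        keys = [(comm.index[i], comm.columns[j]) for i, j in zip(ii, jj)]
        rep.add("error", "negative abundance cells", tuple(keys))
    if comm.index.duplicated().any():
        rep.add("error", "duplicate sample keys in community matrix",
                tuple(comm.index[comm.index.duplicated()]))
    if comm.columns.duplicated().any():
        rep.add("error", "duplicate species columns in community matrix",
                tuple(comm.columns[comm.columns.duplicated()]))

    env = d.environment
    if len(env):
        if env["sample_id"].duplicated().any():
            rep.add("error", "duplicate sample_id in environment table",
                    tuple(env.loc[env["sample_id"].duplicated(), "sample_id"]))
        for col in ("herbs", "canopy_openness"):
            bad = ~env[col].between(0, 100)
            if bad.any():
                rep.add("error", f"{col} outside [0, 100]",
                        tuple(env.loc[bad, "sample_id"]))
        for col in ("litter", "soil_moisture", "collembola", "formica"):
            if (env[col] < 0).any():
                rep.add("error", f"{col} must be >= 0",
                        tuple(env.loc[env[col] < 0, "sample_id"]))
        missing_env = sorted(set(comm.index) - set(env["sample_id"]))
        if missing_env:
            rep.add("error", "community samples without environment rows",
                    tuple(missing_env))

    if len(comm.columns):
        missing_sp = sorted(set(comm.columns) - set(d.species_traits["species"]))
        if missing_sp:
            rep.add("error", "community species without species_traits rows",
                    tuple(missing_sp))

    return rep


# ---------------------------------------------------------------------------
# Output


def write_dataset(d: Dataset, out_dir: str | Path, delimiter: str = ",") -> None:
    """Write the five standard tables; ``load_dataset`` round-trips them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ind = d.individuals.drop(columns=["wing_morph_code"], errors="ignore")
    ind.to_csv(out / TABLE_FILES["individuals"], sep=delimiter, index=False)
    d.measurements.to_csv(out / TABLE_FILES["measurements"], sep=delimiter, index=False)
    d.community.to_csv(out / TABLE_FILES["community"], sep=delimiter)
    d.environment.to_csv(out / TABLE_FILES["environment"], sep=delimiter, index=False)
    d.species_traits.to_csv(out / TABLE_FILES["species_traits"], sep=delimiter,
                            index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj: Any, path: str | Path, delimiter: str = ",") -> Path:
    """Serialize a result table (CSV) or document (JSON) to ``path``.

    DataFrames go to delimited text with a header row; mappings and other
    structures to JSON.  Read-back equals written content.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=delimiter, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=2, default=str)
    return path
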