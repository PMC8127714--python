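"""Domain types, tabular I/O and configuration shared by every analysis stage.

An *experiment* is a directory of four plain CSV tables:

``populations.csv``
    one row per planted population: ``population_id, site, year, seed_source,
    proximity`` with ``proximity`` in ``{near, far}``.
``plants.csv``
    one row per plant: identifiers, fitness components (mean seeds per
    inflorescence, inflorescence count), stem size, the four
    inflorescence-level floral traits and the two seed-predator damage counts.
``flowers.csv``
    long table, one row per collected disk flower (up to five per plant) with
    the eight raw corolla measurements.
``stigmas.csv``
    long table, one row per collected stigma with its pollen-grain count
    (optional; may be empty).

Flower measurements are kept long so the raw data stay auditable; per-plant
composites are computed downstream by :mod:`heliosel.traits`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("heliosel")

PROXIMITY_LEVELS = ("near", "far")

#: inflorescence-level traits measured directly on each plant
INFLORESCENCE_TRAITS = ("DD", "RL", "RW", "NR")
#: per-plant composites derived from disk-flower measurements
DISK_TRAITS = ("CS", "DTW", "DTL", "PTS", "TS")
#: seed-predator damage proportions (antagonist traits)
ANTAGONIST_TRAITS = ("ISO", "NEO")
#: the eleven traits entering selection analyses
ALL_TRAITS = INFLORESCENCE_TRAITS + DISK_TRAITS + ANTAGONIST_TRAITS

#: raw per-flower corolla measurements (mm)
FLOWER_MEASURES = ("CL", "CW", "DTL", "DTW", "PTL", "PTW", "TL", "TW")

PLANT_COLUMNS = (
    "population_id",
    "plant_id",
    "seeds_per_infl_mean",
    "n_inflorescences",
    "height",
    "basal_diameter",
    "DD",
    "RL",
    "RW",
    "NR",
    "iso_damaged",
    "neo_damaged",
    "seeds_examined",
)
POPULATION_COLUMNS = ("population_id", "site", "year", "seed_source", "proximity")
FLOWER_COLUMNS = ("population_id", "plant_id", "flower") + FLOWER_MEASURES
STIGMA_COLUMNS = ("population_id", "plant_id", "stigma", "pollen_grains")

# fixed CSV dialect so that re-writing the same tables is byte-identical
_FLOAT_FORMAT = "%.10g"


class SchemaError(ValueError):
    """A mandatory column is missing or a table cannot be interpreted."""


class ValidationError(ValueError):
    """Row-level data violate an invariant that cannot be skipped."""


@dataclass
class ExperimentConfig:
    """Analysis-wide settings.

    Parameters
    ----------
    alpha
        Significance level for all term tests and the multigroup freeing
        criterion.
    vif_warn, vif_max
        Variance-inflation-factor thresholds: above ``vif_warn`` a drop-refit
        check is run; above ``vif_max`` the diagnostics flag fails.
    cond_index_max
        Condition-index failure threshold for the scaled design matrix.
    transform_policy
        ``"none"`` or ``"auto"`` (skew-triggered normalising transforms).
    fitness_measure
        ``"log"`` (log relative fitness, the default) or ``"relative"``
        (raw relative fitness) as the response of selection analyses.
    log_offset
        Offset ``c`` in ``log(w_rel + c)``; the default 1.0 keeps zero-seed
        plants in the analysis.  Set 0.0 for the classical ``log(w_rel)``.
    missing_seed_policy
        How plants with inflorescences but no seed sample enter fitness
        estimation: ``"exclude"`` (drop from fitness-based analyses) or
        ``"zero"`` (count as zero seeds).
    ddf_method
        Denominator-df method for mixed ANCOVA: ``"containment"`` or
        ``"residual"``.
    """

    alpha: float = 0.05
    vif_warn: float = 5.0
    vif_max: float = 10.0
    cond_index_max: float = 30.0
    transform_policy: str = "none"
    fitness_measure: str = "log"
    log_offset: float = 1.0
    missing_seed_policy: str = "exclude"
    ddf_method: str = "containment"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.vif_warn > self.vif_max:
            raise ValueError("vif_warn must not exceed vif_max")
        if self.transform_policy not in ("none", "auto"):
            raise ValueError(f"unknown transform_policy {self.transform_policy!r}")
        if self.fitness_measure not in ("log", "relative"):
            raise ValueError(f"unknown fitness_measure {self.fitness_measure!r}")
        if self.missing_seed_policy not in ("exclude", "zero"):
            raise ValueError(f"unknown missing_seed_policy {self.missing_seed_policy!r}")
        if self.ddf_method not in ("containment", "residual"):
            raise ValueError(f"unknown ddf_method {self.ddf_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the configuration (used in run manifests)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PlantRecord:
    """One plant's raw field measurements.

    Flower-level and stigma-level measurements live in the long companion
    tables of :class:`PopulationFrame`; this record holds plant-level fields.
    """

    plant_id: str
    seeds_per_infl_mean: float  # NaN = no seed sample (bag lost)
    n_inflorescences: int
    height: float  # cm, to tallest inflorescence
    basal_diameter: float  # mm, stem base
    DD: float
    RL: float
    RW: float
    NR: int
    iso_damaged: int
    neo_damaged: int
    seeds_examined: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty = valid)."""
        problems: list[str] = []
        if self.n_inflorescences < 0:
            problems.append("n_inflorescences < 0")
        if np.isfinite(self.seeds_per_infl_mean) and self.seeds_per_infl_mean < 0:
            problems.append("seeds_per_infl_mean < 0")
        for name in ("height", "basal_diameter", "DD", "RL", "RW"):
            v = getattr(self, name)
            if np.isfinite(v) and v <= 0:
                problems.append(f"{name} <= 0")
        if self.NR < 0:
            problems.append("NR < 0")
        for name in ("iso_damaged", "neo_damaged", "seeds_examined"):
            if getattr(self, name) < 0:
                problems.append(f"{name} < 0")
        if self.iso_damaged + self.neo_damaged > self.seeds_examined:
            problems.append("iso_damaged + neo_damaged > seeds_examined")
        return problems


@dataclass
class PopulationFrame:
    """All plants of one planted population plus its design metadata."""

    population_id: str
    site: str
    year: str
    seed_source: str
    proximity: str
    plants: pd.DataFrame = field(repr=False)
    flowers: pd.DataFrame = field(repr=False)
    stigmas: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.proximity not in PROXIMITY_LEVELS:
            raise ValidationError(
                f"population {self.population_id}: proximity must be one of "
                f"{PROXIMITY_LEVELS}, got {self.proximity!r}"
            )
        ids = self.plants["plant_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(
                f"population {self.population_id}: duplicate plant_id {dupes}"
            )

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    def metadata(self) -> dict:
        return {
            "population_id": self.population_id,
            "site": self.site,
            "year": self.year,
            "seed_source": self.seed_source,
            "proximity": self.proximity,
        }


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing mandatory column(s) {missing}")


def _read_csv(path: Path, table: str, required: Iterable[str]) -> pd.DataFrame:
    fp = path / f"{table}.csv"
    if not fp.exists():
        if table == "stigmas":  # pollen data are optional
            return pd.DataFrame(columns=list(required))
        raise SchemaError(f"experiment directory {path} lacks {table}.csv")
    df = pd.read_csv(fp, dtype={"population_id": str, "plant_id": str})
    _require_columns(df, required, table)
    return df


def read_experiment(
    path: str | Path, config: ExperimentConfig | None = None
) -> list[PopulationFrame]:
    """Read and validate an experiment directory into population frames.

    Rows violating plant-level invariants are rejected with a logged
    diagnostic; structural problems (missing columns, duplicate plant ids,
    unknown proximity levels) raise.  Output is ordered by ``population_id``,
    plants within each frame by ``plant_id``.
    """
    path = Path(path)
    pops = _read_csv(path, "populations", POPULATION_COLUMNS)
    plants = _read_csv(path, "plants", PLANT_COLUMNS)
    flowers = _read_csv(path, "flowers", FLOWER_COLUMNS)
    stigmas = _read_csv(path, "stigmas", STIGMA_COLUMNS)

    if pops["population_id"].duplicated().any():
        raise ValidationError("populations.csv: duplicate population_id")

    frames: list[PopulationFrame] = []
    for _, meta in pops.sort_values("population_id").iterrows():
        pid = meta["population_id"]
        sub = plants[plants["population_id"] == pid].copy()
        keep_rows = []
        for _, row in sub.iterrows():
            rec = PlantRecord(
                plant_id=row["plant_id"],
                seeds_per_infl_mean=float(row["seeds_per_infl_mean"]),
                n_inflorescences=int(row["n_inflorescences"]),
                height=float(row["height"]),
                basal_diameter=float(row["basal_diameter"]),
                DD=float(row["DD"]),
                RL=float(row["RL"]),
                RW=float(row["RW"]),
                NR=int(row["NR"]),
                iso_damaged=int(row["iso_damaged"]),
                neo_damaged=int(row["neo_damaged"]),
                seeds_examined=int(row["seeds_examined"]),
            )
            problems = rec.validate()
            if problems:
                logger.warning(
                    "rejecting plant %s/%s: %s", pid, row["plant_id"], "; ".join(problems)
                )
            else:
                keep_rows.append(row.name)
        sub = sub.loc[keep_rows].sort_values("plant_id").reset_index(drop=True)
        kept = set(sub["plant_id"])
        fl = flowers[
            (flowers["population_id"] == pid) & (flowers["plant_id"].isin(kept))
        ].sort_values(["plant_id", "flower"]).reset_index(drop=True)
        st = stigmas[
            (stigmas["population_id"] == pid) & (stigmas["plant_id"].isin(kept))
        ].sort_values(["plant_id", "stigma"]).reset_index(drop=True)
        frames.append(
            PopulationFrame(
                population_id=pid,
                site=str(meta["site"]),
                year=str(meta["year"]),
                seed_source=str(meta["seed_source"]),
                proximity=str(meta["proximity"]),
                plants=sub,
                flowers=fl,
                stigmas=st,
            )
        )
    return frames


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def write_experiment(frames: Iterable[PopulationFrame], path: str | Path) -> None:
    """Write population frames back to the four-table experiment layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = sorted(frames, key=lambda f: f.population_id)
    pops = pd.DataFrame([f.metadata() for f in frames], columns=list(POPULATION_COLUMNS))
    plants = pd.concat(
        [f.plants.assign(population_id=f.population_id) for f in frames],
        ignore_index=True,
    )[list(PLANT_COLUMNS)]
    flowers = pd.concat(
        [f.flowers.assign(population_id=f.population_id) for f in frames],
        ignore_index=True,
    )
    flowers = flowers[list(FLOWER_COLUMNS)] if len(flowers) else pd.DataFrame(
        columns=list(FLOWER_COLUMNS)
    )
    stigmas = pd.concat(
        [f.stigmas.assign(population_id=f.population_id) for f in frames],
        ignore_index=True,
    )
    stigmas = stigmas[list(STIGMA_COLUMNS)] if len(stigmas) else pd.DataFrame(
        columns=list(STIGMA_COLUMNS)
    )
    _write_csv(pops, path / "populations.csv")
    _write_csv(plants, path / "plants.csv")
    _write_csv(flowers, path / "flowers.csv")
    _write_csv(stigmas, path / "stigmas.csv")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    stage: str,
    config: ExperimentConfig,
) -> dict:
    """Write result tables as CSV plus a JSON manifest; returns the manifest.

    Re-running with identical tables and config reproduces byte-identical
    CSVs (fixed float format and line terminator) and an identical manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        fp = out_dir / f"{name}.csv"
        _write_csv(tables[name], fp)
        digest = hashlib.sha256(fp.read_bytes()).hexdigest()[:16]
        entries.append({"table": name, "file": fp.name, "sha256": digest, "rows": len(tables[name])})
    manifest = {
        "stage": stage,
        "config_hash": config.content_hash(),
        "rng_seed": config.rng_seed,
        "tables": entries,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
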