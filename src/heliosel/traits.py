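"""Per-plant analysis variables from raw field measurements.

Derives, for every plant: whole-plant seed production ``W`` (mean seeds per
inflorescence x inflorescence count), stem volume (pi r^2 h), the five
disk-flower composites (corolla lobe size CS = CL x CW, distal throat
width/length as measured, proximal throat size PTS = PTL x PTW, corolla tube
size TS = TL x TW — computed per flower, then averaged across a plant's
flowers), seed-predator attack proportions, and estimated pollen deposition.
Relative fitness is seed production divided by the population mean, optionally
log-transformed; traits are standardized (mean 0, SD 1) within populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ALL_TRAITS,
    DISK_TRAITS,
    FLOWER_MEASURES,
    ExperimentConfig,
    PopulationFrame,
    logger,
)

#: columns of the derived per-plant table
DERIVED_COLUMNS = list(ALL_TRAITS) + [
    "volume",
    "n_inflorescences",
    "W",
    "w_rel",
    "log_w",
    "pollen",
]

#: flowers per inflorescence assumed constant in the pollen-deposition estimate
FLOWERS_PER_INFLORESCENCE = 100


def whole_plant_seeds(seeds_per_infl_mean: float, n_inflorescences: float) -> float:
    """Whole-plant seed production: mean seeds/inflorescence x inflorescences."""
    if seeds_per_infl_mean < 0 or n_inflorescences < 0:
        raise ValueError("seed components must be nonnegative")
    return seeds_per_infl_mean * n_inflorescences


def stem_volume(basal_diameter: float, height: float) -> float:
    """Stem volume pi r^2 h in mm^3 (diameter in mm, height in cm)."""
    if basal_diameter <= 0 or height <= 0:
        raise ValueError("stem dimensions must be positive")
    r = basal_diameter / 2.0
    return np.pi * r * r * (height * 10.0)


def derive_flower_traits(flowers: pd.DataFrame) -> pd.Series:
    """Disk-flower composites for one plant's flowers (mean of per-flower values).

    Products (CS, PTS, TS) are computed per flower first and then averaged:
    the mean of products, not the product of means.  With no flowers every
    composite is missing (NaN), never zero.
    """
    if len(flowers) == 0:
        return pd.Series({t: np.nan for t in DISK_TRAITS})
    return pd.Series(
        {
            "CS": (flowers["CL"] * flowers["CW"]).mean(),
            "DTW": flowers["DTW"].mean(),
            "DTL": flowers["DTL"].mean(),
            "PTS": (flowers["PTL"] * flowers["PTW"]).mean(),
            "TS": (flowers["TL"] * flowers["TW"]).mean(),
        }
    )


def attack_proportion(damaged: float, examined: float) -> float:
    """Proportion of examined seeds damaged by one seed-predator taxon."""
    if examined == 0:
        logger.warning("attack_proportion: no seeds examined, returning missing")
        return np.nan
    if damaged < 0 or damaged > examined:
        raise ValueError("need 0 <= damaged <= examined")
    return damaged / examined


def pollen_deposition(grain_counts, n_inflorescences: float) -> float:
    """Estimated whole-plant pollen deposition.

    Mean grains per stigma x 100 flowers/inflorescence x inflorescence count;
    the flower count per inflorescence is assumed constant.
    """
    counts = np.asarray(grain_counts, dtype=float)
    if counts.size == 0:
        return np.nan
    return counts.mean() * FLOWERS_PER_INFLORESCENCE * n_inflorescences


def relativize_and_log(
    W: np.ndarray | pd.Series, offset: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Relative fitness w = W / mean(W) and log fitness ln(w + offset).

    Missing W propagate as missing.  With ``offset = 0`` zero-fitness plants
    get ``-inf`` and are excluded downstream with a warning.
    """
    W = np.asarray(W, dtype=float)
    mean_W = np.nanmean(W)
    if not np.isfinite(mean_W) or mean_W <= 0:
        raise ValueError("population mean fitness must be positive")
    w_rel = W / mean_W
    with np.errstate(divide="ignore"):
        log_w = np.log(w_rel + offset)
    return w_rel, log_w


@dataclass
class StandardizedMatrix:
    """Within-population standardized variables with a transform record."""

    z: pd.DataFrame
    transform_log: dict[str, str] = field(default_factory=dict)


def _auto_transform(x: pd.Series, name: str, is_proportion: bool) -> tuple[pd.Series, str]:
    vals = x.dropna()
    if len(vals) < 3:
        return x, "none"
    if is_proportion:
        # arcsine-square-root is the standard variance stabilizer for proportions
        return np.arcsin(np.sqrt(x.clip(0.0, 1.0))), "arcsine-sqrt"
    if abs(stats.skew(vals)) > 1.0:
        if (vals < 0).any():
            return x, "none"
        return np.log1p(x), "log1p"
    return x, "none"


def standardize(
    data: pd.DataFrame,
    transform_policy: str = "none",
    proportion_columns: tuple[str, ...] = ("ISO", "NEO"),
) -> StandardizedMatrix:
    """Optionally transform, then z-score each column (mean 0, SD 1, ddof=1).

    Standardization is within whatever group ``data`` represents — callers
    pass one population at a time.  Columns with fewer than three non-missing
    values or zero variance are excluded with a warning.
    """
    if transform_policy not in ("none", "auto"):
        raise ValueError(f"unknown transform_policy {transform_policy!r}")
    out = {}
    tlog: dict[str, str] = {}
    for col in data.columns:
        x = data[col].astype(float)
        applied = "none"
        if transform_policy == "auto":
            x, applied = _auto_transform(x, col, col in proportion_columns)
        n_ok = x.notna().sum()
        if n_ok < 3:
            logger.warning("standardize: %s has <3 values, excluded", col)
            continue
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("standardize: %s has zero variance, excluded", col)
            continue
        out[col] = (x - x.mean()) / sd
        tlog[col] = applied
    return StandardizedMatrix(z=pd.DataFrame(out, index=data.index), transform_log=tlog)


def derive_population(
    pop: PopulationFrame, config: ExperimentConfig | None = None
) -> pd.DataFrame:
    """Full derived-variable table for one population (one row per plant).

    Columns: the eleven selection traits, stem volume, inflorescence count,
    whole-plant seed estimate ``W``, relative fitness ``w_rel``, log fitness
    ``log_w`` and pollen deposition (NaN where stigmas were not collected).
    """
    config = config or ExperimentConfig()
    plants = pop.plants.set_index("plant_id")
    if (plants["basal_diameter"] <= 0).any() or (plants["height"] <= 0).any():
        raise ValueError("stem dimensions must be positive")

    df = plants[["DD", "RL", "RW", "NR", "n_inflorescences"]].astype(float).copy()

    # disk-flower composites: per-flower products, then per-plant means
    fl = pop.flowers
    if len(fl):
        per_flower = pd.DataFrame(
            {
                "plant_id": fl["plant_id"],
                "CS": fl["CL"] * fl["CW"],
                "DTW": fl["DTW"],
                "DTL": fl["DTL"],
                "PTS": fl["PTL"] * fl["PTW"],
                "TS": fl["TL"] * fl["TW"],
            }
        )
        disk = per_flower.groupby("plant_id").mean()
    else:
        disk = pd.DataFrame(columns=list(DISK_TRAITS))
    for t in DISK_TRAITS:
        df[t] = disk[t] if t in disk else np.nan

    examined = plants["seeds_examined"].astype(float)
    no_seeds = examined == 0
    if no_seeds.any():
        logger.warning(
            "population %s: %d plants with no seeds examined, attack missing",
            pop.population_id,
            int(no_seeds.sum()),
        )
    df["ISO"] = (plants["iso_damaged"] / examined.where(~no_seeds)).astype(float)
    df["NEO"] = (plants["neo_damaged"] / examined.where(~no_seeds)).astype(float)

    r = plants["basal_diameter"] / 2.0
    df["volume"] = np.pi * r * r * plants["height"] * 10.0

    spi = plants["seeds_per_infl_mean"]
    W = spi * plants["n_inflorescences"]
    if config.missing_seed_policy == "zero":
        W = W.fillna(0.0)
    df["W"] = W

    st = pop.stigmas
    if len(st):
        mean_grains = st.groupby("plant_id")["pollen_grains"].mean()
        df["pollen"] = (
            mean_grains.reindex(df.index)
            * FLOWERS_PER_INFLORESCENCE
            * plants["n_inflorescences"]
        )
    else:
        df["pollen"] = np.nan
    df = df[
        ["DD", "RL", "RW", "NR"]
        + list(DISK_TRAITS)
        + ["ISO", "NEO", "volume", "n_inflorescences", "W", "pollen"]
    ]
    w_rel, log_w = relativize_and_log(df["W"], offset=config.log_offset)
    df["w_rel"] = w_rel
    df["log_w"] = log_w
    n_neg_inf = np.isneginf(df["log_w"]).sum()
    if n_neg_inf:
        logger.warning(
            "population %s: %d zero-fitness plants undefined under log offset 0",
            pop.population_id,
            n_neg_inf,
        )
        df.loc[np.isneginf(df["log_w"]), "log_w"] = np.nan
    return df


def fitness_response(derived: pd.DataFrame, config: ExperimentConfig) -> pd.Series:
    """The fitness variable selection analyses regress on, per config."""
    return derived["log_w"] if config.fitness_measure == "log" else derived["w_rel"]
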