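"""Synthetic paired-population experiments with known selection gradients.

Emulates the structure of a crop-proximity field experiment: for every
site x year x seed-source combination, one population planted near a crop
field and one far from it, each with 80-155 plants.  Nine correlated floral
traits are drawn multivariate-normal; seed-predator attack counts are
beta-binomial with trait- and proximity-linked rates (far arms receive more
attack); pollen deposition is Poisson-lognormal with floral-trait and
proximity links (near arms receive more pollen); and expected seed production
is log-linear in the standardized traits with known ground-truth gradients,
realized as negative-binomial counts.

Every generated dataset carries its :class:`GroundTruth` so downstream
estimators can be checked for parameter recovery, and regeneration from the
same seed is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import (
    ALL_TRAITS,
    DISK_TRAITS,
    INFLORESCENCE_TRAITS,
    PopulationFrame,
)

FLORAL_TRAITS = INFLORESCENCE_TRAITS + DISK_TRAITS  # the nine measured traits

#: plausible field scales (trait mean, SD) for raw measurement generation;
#: selection acts on standardized values, so these set units only
TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "DD": (22.0, 4.0),  # disk diameter, mm
    "RL": (28.0, 5.0),  # ray length, mm
    "RW": (9.0, 1.8),  # ray width, mm
    "NR": (16.0, 3.0),  # number of rays
    "CS": (2.6, 0.5),  # corolla lobe size, mm^2
    "DTW": (1.3, 0.2),  # distal throat width, mm
    "DTL": (2.2, 0.35),  # distal throat length, mm
    "PTS": (1.8, 0.35),  # proximal throat size, mm^2
    "TS": (3.2, 0.6),  # corolla tube size, mm^2
}

#: mean length/width aspect ratio used to split composite areas into the raw
#: per-flower length and width measurements
_ASPECT = {"CS": 2.6, "PTS": 1.6, "TS": 2.2}


def default_trait_corr() -> pd.DataFrame:
    """Block correlation among the nine floral traits.

    Inflorescence traits correlate 0.4 among themselves, disk-flower traits
    0.5, and traits across the two blocks 0.2 — floral morphology is
    integrated within organ classes more than between them.
    """
    traits = list(FLORAL_TRAITS)
    corr = pd.DataFrame(0.2, index=traits, columns=traits)
    for block, rho in ((INFLORESCENCE_TRAITS, 0.4), (DISK_TRAITS, 0.5)):
        for a in block:
            for b in block:
                corr.loc[a, b] = rho
    np.fill_diagonal(corr.values, 1.0)
    return corr


def default_beta_true() -> dict[str, float]:
    """Ground-truth direct selection on the nine floral traits.

    Stronger positive selection on the pollinator display traits
    (inflorescence scale) than on disk-flower dimensions, the pattern this
    kind of field experiment is designed to detect.
    """
    return {
        "DD": 0.20,
        "RL": 0.15,
        "RW": 0.10,
        "NR": 0.15,
        "CS": 0.05,
        "DTW": 0.00,
        "DTL": 0.00,
        "PTS": 0.05,
        "TS": 0.05,
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the paired near/far field design."""

    n_sites: int = 2
    n_years: int = 2
    n_seed_sources: int = 2
    n_plants_range: tuple[int, int] = (80, 155)
    trait_corr: pd.DataFrame = field(default_factory=default_trait_corr)
    beta_true: dict[str, float] = field(default_factory=default_beta_true)
    #: optional far-arm override of beta_true (near/far selection differences)
    beta_true_far: dict[str, float] | None = None
    #: direct selection against seed-predator attack (standardized scale)
    iso_penalty: float = 0.15
    neo_penalty: float = 0.10
    #: direct selection on stem volume (standardized log-volume scale)
    volume_effect: float = 0.30
    #: baseline attack rates (proportion of seeds damaged) in the near arm
    iso_rate: float = 0.15
    neo_rate: float = 0.10
    #: per-arm rate multipliers; far populations see more seed predators,
    #: near populations more pollinators
    proximity_shift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "iso_rate": {"near": 1.0, "far": 1.5},
            "neo_rate": {"near": 1.0, "far": 1.5},
            "pollinator_rate": {"near": 1.3, "far": 1.0},
        }
    )
    #: logit-scale trait links of attack propensity (errors stay in (0,1))
    iso_linkage: dict[str, float] = field(default_factory=lambda: {"DD": 0.25, "RL": 0.15})
    neo_linkage: dict[str, float] = field(default_factory=lambda: {"DD": 0.20, "CS": 0.15})
    attack_dispersion: float = 30.0  # beta-binomial precision
    seeds_examined: int = 80
    #: log-scale trait links of per-stigma pollen arrival
    pollen_linkage: dict[str, float] = field(default_factory=lambda: {"DD": 0.2, "CS": 0.2})
    pollen_base_grains: float = 6.0  # grains per stigma, near-arm baseline
    #: environmental noise SD on log expected seeds
    noise_sd: float = 0.3
    nb_dispersion: float = 10.0  # negative-binomial k; np.inf = deterministic
    base_seeds: float = 600.0  # expected whole-plant seeds at average phenotype
    mean_inflorescences: float = 25.0
    #: fraction of bagged plants losing their seed sample (missing fitness)
    missing_bag_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.trait_corr, dtype=float)
        if corr.shape != (9, 9) or not np.allclose(corr, corr.T):
            raise ValueError("trait_corr must be a symmetric 9x9 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("trait_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("trait_corr must be positive definite")
        lo, hi = self.n_plants_range
        if not (0 < lo <= hi):
            raise ValueError("n_plants_range must be a positive interval")
        for key in ("iso_rate", "neo_rate"):
            for arm, mult in self.proximity_shift[key].items():
                r = getattr(self, key) * mult
                if not 0.0 < r < 1.0:
                    raise ValueError(f"{key} x {arm} shift leaves (0,1): {r}")


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic dataset."""

    beta_true: dict[str, float]
    beta_true_far: dict[str, float] | None
    iso_penalty: float
    neo_penalty: float
    volume_effect: float
    iso_linkage: dict[str, float]
    neo_linkage: dict[str, float]
    pollen_linkage: dict[str, float]
    #: per population: latent standardized traits, expected and realized seeds
    per_population: dict[str, pd.DataFrame] = field(default_factory=dict)


def _population_rng(rng_seed: int, population_id: str) -> np.random.Generator:
    """Sub-stream per population via stable hashing of its identifier.

    Populations are therefore independent of the order in which they are
    generated.
    """
    tag = zlib.crc32(population_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([rng_seed, tag]))


def _linked_logit(base: float, linkage: dict[str, float], z: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(z), logit(base))
    for trait, coef in linkage.items():
        eta = eta + coef * z[trait].to_numpy()
    return eta


def _make_flowers(
    pid: str, plant_ids: list[str], latent: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Five disk flowers per plant whose per-flower products average to the
    plant-level composite (up to ~3% flower-to-flower noise)."""
    n = len(plant_ids)
    noise = rng.normal(1.0, 0.03, size=(n, 5, 5))  # plant x flower x trait
    rep = np.repeat  # each plant's latent value repeated over its 5 flowers
    cs = rep(latent["CS"].to_numpy(), 5) * noise[:, :, 0].ravel()
    pts = rep(latent["PTS"].to_numpy(), 5) * noise[:, :, 1].ravel()
    ts = rep(latent["TS"].to_numpy(), 5) * noise[:, :, 2].ravel()
    return pd.DataFrame(
        {
            "population_id": pid,
            "plant_id": rep(np.asarray(plant_ids, dtype=object), 5),
            "flower": np.tile(np.arange(1, 6), n),
            "CL": np.sqrt(cs * _ASPECT["CS"]),
            "CW": np.sqrt(cs / _ASPECT["CS"]),
            "DTL": rep(latent["DTL"].to_numpy(), 5) * noise[:, :, 3].ravel(),
            "DTW": rep(latent["DTW"].to_numpy(), 5) * noise[:, :, 4].ravel(),
            "PTL": np.sqrt(pts * _ASPECT["PTS"]),
            "PTW": np.sqrt(pts / _ASPECT["PTS"]),
            "TL": np.sqrt(ts * _ASPECT["TS"]),
            "TW": np.sqrt(ts / _ASPECT["TS"]),
        }
    )


def _generate_population(
    pid: str,
    site: str,
    year: str,
    source: str,
    proximity: str,
    cfg: SyntheticConfig,
    collect_pollen: bool,
) -> tuple[PopulationFrame, pd.DataFrame]:
    rng = _population_rng(cfg.rng_seed, pid)
    lo, hi = cfg.n_plants_range
    n = int(rng.integers(lo, hi + 1))
    plant_ids = [f"{pid}-p{i + 1:03d}" for i in range(n)]

    corr = np.asarray(cfg.trait_corr, dtype=float)
    z = rng.multivariate_normal(np.zeros(9), corr, size=n, method="cholesky")
    z = pd.DataFrame(z, columns=list(FLORAL_TRAITS), index=plant_ids)

    # raw trait values on field scales; NR is an integer count
    raw = pd.DataFrame(index=plant_ids)
    for t in FLORAL_TRAITS:
        mean, sd = TRAIT_SCALES[t]
        raw[t] = np.maximum(mean + sd * z[t].to_numpy(), 0.05 * mean)
    raw["NR"] = np.maximum(np.round(raw["NR"]), 3).astype(int)

    # stem size: one latent size axis drives height, diameter and volume
    z_vol = rng.normal(size=n)
    diameter = np.exp(np.log(8.0) + 0.20 * z_vol + rng.normal(0, 0.05, n))
    height = np.exp(np.log(120.0) + 0.25 * z_vol + rng.normal(0, 0.08, n))

    # seed-predator attack: beta-binomial counts, trait/proximity-linked rates
    shift = cfg.proximity_shift
    p_iso = expit(
        _linked_logit(cfg.iso_rate * shift["iso_rate"][proximity], cfg.iso_linkage, z)
    )
    p_neo = expit(
        _linked_logit(cfg.neo_rate * shift["neo_rate"][proximity], cfg.neo_linkage, z)
    )
    phi = cfg.attack_dispersion
    p_iso_draw = rng.beta(p_iso * phi, (1.0 - p_iso) * phi)
    p_neo_draw = rng.beta(p_neo * phi, (1.0 - p_neo) * phi)
    total = p_iso_draw + p_neo_draw
    over = total > 0.95
    p_iso_draw[over] *= 0.95 / total[over]
    p_neo_draw[over] *= 0.95 / total[over]
    counts = np.array(
        [
            rng.multinomial(cfg.seeds_examined, [pi, pn, 1.0 - pi - pn])
            for pi, pn in zip(p_iso_draw, p_neo_draw)
        ]
    )
    iso_damaged, neo_damaged = counts[:, 0], counts[:, 1]
    iso_obs = iso_damaged / cfg.seeds_examined
    neo_obs = neo_damaged / cfg.seeds_examined

    def _std(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=1)

    # fitness: log-linear in standardized traits + size - attack + noise.
    # The penalty acts on the realized, measured damage proportion (it is the
    # destroyed seeds that cost fitness), which also makes beta_true the exact
    # estimand of the downstream gradient regression.
    eta = np.log(cfg.base_seeds) + cfg.noise_sd * rng.normal(size=n)
    beta = cfg.beta_true
    if proximity == "far" and cfg.beta_true_far is not None:
        beta = cfg.beta_true_far
    for t, b in beta.items():
        eta += b * z[t].to_numpy()
    eta += cfg.volume_effect * _std(z_vol)
    eta -= cfg.iso_penalty * _std(iso_obs)
    eta -= cfg.neo_penalty * _std(neo_obs)
    mu_W = np.exp(eta)
    if np.isfinite(cfg.nb_dispersion):
        lam = rng.gamma(cfg.nb_dispersion, mu_W / cfg.nb_dispersion)
        W = rng.poisson(lam).astype(float)
    else:
        W = np.round(mu_W)

    n_infl = np.maximum(
        np.round(np.exp(np.log(cfg.mean_inflorescences) + 0.4 * z_vol + rng.normal(0, 0.3, n))),
        1,
    ).astype(int)
    seeds_per_infl = W / n_infl
    if cfg.missing_bag_rate > 0:
        lost = rng.random(n) < cfg.missing_bag_rate
        seeds_per_infl = np.where(lost, np.nan, seeds_per_infl)

    plants = pd.DataFrame(
        {
            "population_id": pid,
            "plant_id": plant_ids,
            "seeds_per_infl_mean": seeds_per_infl,
            "n_inflorescences": n_infl,
            "height": height,
            "basal_diameter": diameter,
            "DD": raw["DD"].to_numpy(),
            "RL": raw["RL"].to_numpy(),
            "RW": raw["RW"].to_numpy(),
            "NR": raw["NR"].to_numpy(),
            "iso_damaged": iso_damaged,
            "neo_damaged": neo_damaged,
            "seeds_examined": cfg.seeds_examined,
        }
    )
    flowers = _make_flowers(pid, plant_ids, raw, rng)

    if collect_pollen:
        rate = cfg.pollen_base_grains * shift["pollinator_rate"][proximity]
        log_rate = np.log(rate) + rng.normal(0, 0.3, n)
        for t, coef in cfg.pollen_linkage.items():
            log_rate += coef * z[t].to_numpy()
        srows = []
        for i, plant in enumerate(plant_ids):
            for s in range(int(rng.integers(2, 9))):
                srows.append(
                    {
                        "population_id": pid,
                        "plant_id": plant,
                        "stigma": s + 1,
                        "pollen_grains": int(rng.poisson(np.exp(log_rate[i]))),
                    }
                )
        stigmas = pd.DataFrame(srows)
    else:
        stigmas = pd.DataFrame(
            columns=["population_id", "plant_id", "stigma", "pollen_grains"]
        )

    frame = PopulationFrame(
        population_id=pid,
        site=site,
        year=year,
        seed_source=source,
        proximity=proximity,
        plants=plants,
        flowers=flowers,
        stigmas=stigmas,
    )
    truth = z.copy()
    truth["z_volume"] = z_vol
    truth["p_iso_true"] = p_iso_draw
    truth["p_neo_true"] = p_neo_draw
    truth["mu_W"] = mu_W
    truth["W"] = W
    truth.index.name = "plant_id"
    return frame, truth.reset_index()


def generate_experiment(
    config: SyntheticConfig | None = None,
) -> tuple[list[PopulationFrame], GroundTruth]:
    """Generate one full paired experiment.

    One near and one far population per site x year x seed-source cell;
    pollen deposition collected (as in the field study) only for the pairs of
    the first seed source at the first two sites.
    """
    cfg = config or SyntheticConfig()
    truth = GroundTruth(
        beta_true=dict(cfg.beta_true),
        beta_true_far=dict(cfg.beta_true_far) if cfg.beta_true_far else None,
        iso_penalty=cfg.iso_penalty,
        neo_penalty=cfg.neo_penalty,
        volume_effect=cfg.volume_effect,
        iso_linkage=dict(cfg.iso_linkage),
        neo_linkage=dict(cfg.neo_linkage),
        pollen_linkage=dict(cfg.pollen_linkage),
    )
    frames: list[PopulationFrame] = []
    for s in range(cfg.n_sites):
        for y in range(cfg.n_years):
            for src in range(cfg.n_seed_sources):
                collect_pollen = s < 2 and src == 0
                for prox in ("near", "far"):
                    pid = f"S{s + 1}-Y{y + 1}-{chr(ord('B') + src)}-{prox}"
                    frame, pop_truth = _generate_population(
                        pid,
                        site=f"site{s + 1}",
                        year=f"year{y + 1}",
                        source=chr(ord("B") + src),
                        proximity=prox,
                        cfg=cfg,
                        collect_pollen=collect_pollen,
                    )
                    frames.append(frame)
                    truth.per_population[pid] = pop_truth
    return frames, truth


def generate_dag_consistent(
    dag, coeffs: dict[tuple[str, str], float], n: int, rng_seed: int = 0
) -> pd.DataFrame:
    """Ancestral sampling of a linear-Gaussian system faithful to ``dag``.

    Each node is the coefficient-weighted sum of its parents plus unit-variance
    Gaussian noise, so every conditional-independence claim implied by the
    graph holds exactly in the generating process.
    """
    import networkx as nx

    g = dag.graph if not isinstance(dag, nx.DiGraph) else dag
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("graph must be acyclic")
    rng = np.random.default_rng(rng_seed)
    data: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        x = rng.normal(size=n)
        for parent in g.predecessors(node):
            x = x + coeffs.get((parent, node), 0.0) * data[parent]
        data[node] = x
    return pd.DataFrame(data)


def worked_fixture() -> tuple[list[PopulationFrame], pd.DataFrame]:
    """A deterministic 12-plant, 2-population dataset with hand-checkable
    selection coefficients.

    Trait values and seed counts are small round numbers so the selection
    differential (a covariance) and the two-trait gradients (a 2x2
    normal-equations solve) can be verified by hand; returns the frames plus
    a tidy table of the plant-level values used in those checks.
    """
    # population A: DD and fitness rise together; RL correlates with DD
    specs = {
        "POPA-near": {
            "site": "site1",
            "year": "year1",
            "seed_source": "B",
            "proximity": "near",
            "DD": [18.0, 20.0, 22.0, 24.0, 26.0, 28.0],
            "RL": [24.0, 25.0, 27.0, 26.0, 29.0, 31.0],
            "seeds": [120.0, 180.0, 240.0, 300.0, 390.0, 570.0],
        },
        "POPB-far": {
            "site": "site1",
            "year": "year1",
            "seed_source": "B",
            "proximity": "far",
            "DD": [17.0, 19.0, 21.0, 23.0, 25.0, 27.0],
            "RL": [22.0, 26.0, 24.0, 28.0, 27.0, 30.0],
            "seeds": [90.0, 150.0, 210.0, 330.0, 420.0, 600.0],
        },
    }
    frames = []
    tidy_rows = []
    for pid, sp in specs.items():
        n = len(sp["DD"])
        plant_ids = [f"{pid}-p{i + 1}" for i in range(n)]
        plants = pd.DataFrame(
            {
                "population_id": pid,
                "plant_id": plant_ids,
                "seeds_per_infl_mean": [s / 10.0 for s in sp["seeds"]],
                "n_inflorescences": 10,
                "height": 120.0,
                "basal_diameter": 8.0,
                "DD": sp["DD"],
                "RL": sp["RL"],
                "RW": 9.0,
                "NR": 16,
                "iso_damaged": [2, 4, 6, 8, 10, 12],
                "neo_damaged": [1, 2, 3, 4, 5, 6],
                "seeds_examined": 80,
            }
        )
        flowers = pd.DataFrame(
            [
                {
                    "population_id": pid,
                    "plant_id": plant,
                    "flower": 1,
                    "CL": 2.6,
                    "CW": 1.0,
                    "DTL": 2.2,
                    "DTW": 1.3,
                    "PTL": 1.7,
                    "PTW": 1.1,
                    "TL": 2.7,
                    "TW": 1.2,
                }
                for plant in plant_ids
            ]
        )
        stigmas = pd.DataFrame(
            columns=["population_id", "plant_id", "stigma", "pollen_grains"]
        )
        frames.append(
            PopulationFrame(
                population_id=pid,
                site=sp["site"],
                year=sp["year"],
                seed_source=sp["seed_source"],
                proximity=sp["proximity"],
                plants=plants,
                flowers=flowers,
                stigmas=stigmas,
            )
        )
        for plant, dd, rl, w in zip(plant_ids, sp["DD"], sp["RL"], sp["seeds"]):
            tidy_rows.append(
                {"population_id": pid, "plant_id": plant, "DD": dd, "RL": rl, "W": w}
            )
    return frames, pd.DataFrame(tidy_rows)
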