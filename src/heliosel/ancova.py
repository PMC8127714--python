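"""Mixed-effects ANCOVA: does selection differ by crop proximity, site, year?

The response is (log) relative fitness at the plant level; the covariate of
interest is a within-population standardized trait, so the trait main effect
estimates the average selection gradient/differential and its interactions
with the design factors test whether selection varies with them.  A
significant trait x proximity interaction indicates selection that
consistently differs near versus far from the crop; higher-order
interactions (trait x site x proximity, trait x year x proximity, ...) flag
context-dependent proximity effects.  Population enters as a random
intercept; term tests are marginal (Type III) Wald F tests under sum-to-zero
contrasts.

Total-selection models take one trait at a time; the direct-selection model
includes all nine floral traits, the two attack traits and stem volume
simultaneously, each with its full set of design interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data_model import ExperimentConfig, PopulationFrame, logger
from .selection import GRADIENT_COVARIATES
from .traits import derive_population, fitness_response, standardize


@dataclass
class AncovaResult:
    model_id: str
    terms: pd.DataFrame  # term, ndf, ddf, F, p
    formula: str
    n_obs: int
    n_populations: int
    converged: bool
    used_ols_fallback: bool
    ddf_method: str
    random_effect_var: float = np.nan

    def term_p(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in model {self.model_id}")
        return float(row["p"].iloc[0])


def assemble_dataset(
    frames: list[PopulationFrame],
    config: ExperimentConfig | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Plant-level analysis table across populations.

    Derives each population, standardizes the covariates within it, computes
    the fitness response per config, and attaches the design metadata.
    """
    config = config or ExperimentConfig()
    covariates = covariates or GRADIENT_COVARIATES
    parts = []
    for frame in frames:
        derived = derive_population(frame, config)
        std = standardize(derived[covariates], config.transform_policy)
        block = std.z.reindex(columns=covariates)
        block["fitness"] = fitness_response(derived, config)
        for key, val in frame.metadata().items():
            block[key] = val
        parts.append(block.reset_index())
    return pd.concat(parts, ignore_index=True)


def _containment_ddf(
    design: pd.DataFrame, groups: pd.Series, term_cols: dict[str, list[str]]
) -> dict[str, float]:
    """Containment-style denominator df.

    A term whose design columns are all constant within populations is tested
    at the between-population level (df = m - number of between columns);
    all other terms at the plant level (df = N - m - number of within
    columns).  This is the between/within split used by classical nested
    mixed ANOVA software.
    """
    const_within: dict[str, bool] = {}
    grouped = design.groupby(groups.to_numpy(), sort=False)
    for col in design.columns:
        const_within[col] = bool((grouped[col].nunique(dropna=False) <= 1).all())
    n_between = sum(const_within.values())  # includes the intercept column
    n_within = design.shape[1] - n_between
    N = len(design)
    m = groups.nunique()
    ddf = {}
    for term, cols in term_cols.items():
        if all(const_within[c] for c in cols):
            ddf[term] = max(m - n_between, 1)
        else:
            ddf[term] = max(N - m - n_within, 1)
    return ddf


def _fit_and_test(
    formula: str,
    data: pd.DataFrame,
    model_id: str,
    config: ExperimentConfig,
) -> AncovaResult:
    """Fit the random-intercept model and run Type III Wald term tests.

    Singular or non-converged mixed fits fall back to ordinary least squares
    on the pooled data with a logged warning.
    """
    data = data.dropna(subset=["fitness"])
    groups = data["population_id"]
    used_fallback = False
    converged = True
    re_var = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=groups)
            result = model.fit(reml=True, method=["lbfgs", "powell"])
            converged = bool(result.converged)
            re_var = float(np.squeeze(result.cov_re.to_numpy()))
            scale = float(result.scale)
            if not converged or re_var < 1e-8 * max(scale, 1e-12):
                raise ValueError("singular or non-converged random-effect fit")
            params = result.fe_params
            cov = result.cov_params().iloc[: len(params), : len(params)]
            design_info = model.data.design_info
            exog = pd.DataFrame(model.exog, columns=design_info.column_names)
        except Exception as exc:  # fall back to pooled OLS
            logger.warning("%s: mixed fit failed (%s); using OLS fallback", model_id, exc)
            used_fallback = True
            model = smf.ols(formula, data)
            result = model.fit()
            params = result.params
            cov = result.cov_params()
            design_info = model.data.design_info
            exog = pd.DataFrame(model.exog, columns=design_info.column_names)

    term_cols = {
        name: design_info.column_names[sl]
        for name, sl in design_info.term_name_slices.items()
        if name != "Intercept"
    }
    # align groups to rows actually used by the model
    used_index = pd.Index(model.data.row_labels)
    groups_used = data.loc[used_index, "population_id"]
    exog.index = used_index

    if config.ddf_method == "containment" and not used_fallback:
        ddf_map = _containment_ddf(exog, groups_used, term_cols)
    elif config.ddf_method == "containment":
        ddf_map = _containment_ddf(exog, groups_used, term_cols)
    else:
        resid_df = len(exog) - exog.shape[1]
        ddf_map = {t: max(resid_df, 1) for t in term_cols}

    rows = []
    cov_np = np.asarray(cov)
    name_idx = {n: i for i, n in enumerate(design_info.column_names)}
    for term, cols in term_cols.items():
        idx = [name_idx[c] for c in cols]
        b = params.to_numpy()[idx]
        V = cov_np[np.ix_(idx, idx)]
        q = len(idx)
        try:
            F = float(b @ np.linalg.solve(V, b) / q)
        except np.linalg.LinAlgError:
            F = np.nan
        ddf = ddf_map[term]
        p = float(stats.f.sf(F, q, ddf)) if np.isfinite(F) else np.nan
        rows.append({"term": term, "ndf": q, "ddf": ddf, "F": F, "p": p})
    return AncovaResult(
        model_id=model_id,
        terms=pd.DataFrame(rows),
        formula=formula,
        n_obs=len(exog),
        n_populations=int(groups_used.nunique()),
        converged=converged,
        used_ols_fallback=used_fallback,
        ddf_method=config.ddf_method,
        random_effect_var=re_var,
    )


def _check_design(data: pd.DataFrame, include_year: bool) -> None:
    arms = set(data["proximity"].dropna().unique())
    missing = set(("near", "far")) - arms
    if missing:
        raise ValueError(f"proximity arm(s) missing from data: {sorted(missing)}")
    if data["site"].nunique() < 2:
        raise ValueError("need >= 2 sites for the site factor")
    if include_year and data["year"].nunique() < 2:
        raise ValueError("include_year requires >= 2 years")


def ancova_total(
    data: pd.DataFrame,
    trait: str,
    include_year: bool = False,
    config: ExperimentConfig | None = None,
) -> AncovaResult:
    """Total-selection ANCOVA for one trait.

    Fixed effects: site x proximity x trait (all interactions; plus year and
    its interactions when ``include_year``), random intercept per population.
    """
    config = config or ExperimentConfig()
    _check_design(data, include_year)
    if data[trait].std(skipna=True) == 0 or data[trait].dropna().empty:
        raise ValueError(f"trait {trait!r} is constant or empty; trait terms undefined")
    factors = "C(site, Sum) * C(proximity, Sum)"
    if include_year:
        factors = "C(year, Sum) * " + factors
    formula = f"fitness ~ {factors} * {trait}"
    return _fit_and_test(formula, data.dropna(subset=[trait]), f"total-{trait}", config)


def ancova_direct(
    data: pd.DataFrame,
    include_year: bool = False,
    config: ExperimentConfig | None = None,
    covariates: list[str] | None = None,
) -> AncovaResult:
    """Direct-selection ANCOVA: one model with every covariate.

    All nine floral traits, the two attack traits and stem volume enter
    simultaneously, each crossed with the design factors, so each
    covariate x proximity term tests a proximity difference in that trait's
    gradient.
    """
    config = config or ExperimentConfig()
    covariates = covariates or GRADIENT_COVARIATES
    _check_design(data, include_year)
    factors = "C(site, Sum) * C(proximity, Sum)"
    if include_year:
        factors = "C(year, Sum) * " + factors
    covsum = " + ".join(covariates)
    formula = f"fitness ~ {factors} * ({covsum})"
    return _fit_and_test(
        formula, data.dropna(subset=covariates), "direct", config
    )


def classify_effects(
    result: AncovaResult, trait: str, alpha: float = 0.05
) -> str:
    """Label one trait's proximity evidence from a fitted ANCOVA.

    ``consistent-proximity`` if the plain trait x proximity interaction is
    significant; ``context-dependent`` if only a higher-order interaction
    involving proximity and the trait is; else ``no-proximity-effect``.
    """
    plain_p = None
    higher = []
    for _, row in result.terms.iterrows():
        name = row["term"]
        if trait not in name.split(":"):
            continue
        if "proximity" not in name:
            continue
        parts = name.split(":")
        design_parts = [p for p in parts if p != trait]
        if all("proximity" in p for p in design_parts) and len(design_parts) == 1:
            plain_p = row["p"]
        else:
            higher.append(row["p"])
    if plain_p is not None and plain_p < alpha:
        return "consistent-proximity"
    if any(p < alpha for p in higher):
        return "context-dependent"
    return "no-proximity-effect"
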