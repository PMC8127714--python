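"""Per-population phenotypic selection analysis.

Total selection on a trait is the selection differential s' = cov(z, w),
the covariance between the within-population standardized trait and relative
fitness (log-transformed by default); its significance comes from the Pearson
correlation test of trait against fitness.  Direct selection is the selection
gradient beta, the trait's partial coefficient when fitness is regressed on
all traits simultaneously (the nine floral traits, the two seed-predator
attack proportions, and stem volume).  Collinearity of the multiple
regression is screened with variance inflation factors and condition indices,
with a drop-the-worst refit check when any VIF exceeds the warning threshold.

Individual trait x population p-values are reported descriptively and are
deliberately not corrected for multiple comparisons; the summary instead
compares the count of significant cases with the count expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import (
    ALL_TRAITS,
    ANTAGONIST_TRAITS,
    DISK_TRAITS,
    INFLORESCENCE_TRAITS,
    ExperimentConfig,
    logger,
)
from .traits import StandardizedMatrix, fitness_response, standardize

#: covariates of the gradient regression, in canonical order
GRADIENT_COVARIATES = list(ALL_TRAITS) + ["volume"]

TRAIT_CLASSES = {
    "inflorescence": INFLORESCENCE_TRAITS,
    "disk_flower": DISK_TRAITS,
    "antagonist": ANTAGONIST_TRAITS,
}


@dataclass
class DiagnosticsReport:
    """Collinearity screen for one gradient regression."""

    vif: dict[str, float]
    condition_indices: list[float]  # sorted descending
    flag: str  # pass | warn | fail
    #: present when any VIF > warn threshold: whether each remaining gradient
    #: stays inside its original 95% CI after dropping the worst covariate
    refit_within_ci: dict[str, bool] | None = None
    dropped_covariate: str | None = None

    @property
    def max_vif(self) -> float:
        return max(self.vif.values()) if self.vif else np.nan

    @property
    def max_condition_index(self) -> float:
        return self.condition_indices[0] if self.condition_indices else np.nan


def selection_differentials(
    z: pd.DataFrame | StandardizedMatrix, fitness: pd.Series
) -> pd.DataFrame:
    """Selection differentials s' = cov(z_trait, fitness) with Pearson tests.

    Each trait uses its own pairwise-complete observations, so per-trait n
    may vary.  Zero-variance fitness yields s' = 0, p = 1 (no evidence of
    selection); fewer than three pairs flags the estimate undefined.
    """
    if isinstance(z, StandardizedMatrix):
        z = z.z
    rows = []
    for trait in z.columns:
        pair = pd.concat([z[trait], fitness], axis=1, keys=["z", "w"]).dropna()
        n = len(pair)
        if n < 3:
            rows.append({"trait": trait, "s_prime": np.nan, "p_s": np.nan, "n": n})
            continue
        if pair["w"].std(ddof=1) == 0 or pair["z"].std(ddof=1) == 0:
            rows.append({"trait": trait, "s_prime": 0.0, "p_s": 1.0, "n": n})
            continue
        s = pair["z"].cov(pair["w"])  # n-1 denominator
        r, p = stats.pearsonr(pair["z"], pair["w"])
        rows.append({"trait": trait, "s_prime": s, "p_s": p, "n": n})
    return pd.DataFrame(rows)


def diagnose_collinearity(
    X: pd.DataFrame,
    vif_warn: float = 5.0,
    vif_max: float = 10.0,
    cond_index_max: float = 30.0,
) -> DiagnosticsReport:
    """VIFs and condition indices for a design matrix (without intercept).

    VIF_j = 1/(1 - R^2_j) from regressing covariate j on the others;
    condition indices are sqrt(lambda_max/lambda_i) of the cross-product of
    the unit-length-scaled design (intercept included, Belsley convention).
    Rank-deficient designs report infinite VIF and fail.
    """
    Xv = X.to_numpy(dtype=float)
    n, k = Xv.shape
    vif: dict[str, float] = {}
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(Xv, j, axis=1)])
        y = Xv[:, j]
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        ss_tot = np.sum((y - y.mean()) ** 2)
        ss_res = np.sum(resid**2)
        if ss_tot == 0 or ss_res <= 1e-12 * ss_tot:
            vif[name] = np.inf
        else:
            vif[name] = ss_tot / ss_res

    D = np.column_stack([np.ones(n), Xv])
    D = D / np.linalg.norm(D, axis=0)
    sv = np.linalg.svd(D, compute_uv=False)
    smax = sv[0]
    cond = sorted(
        (np.inf if s < 1e-12 * smax else smax / s for s in sv), reverse=True
    )

    if any(not np.isfinite(v) or v > vif_max for v in vif.values()) or (
        cond and cond[0] > cond_index_max
    ):
        flag = "fail"
    elif any(v > vif_warn for v in vif.values()):
        flag = "warn"
    else:
        flag = "pass"
    return DiagnosticsReport(vif=vif, condition_indices=[float(c) for c in cond], flag=flag)


def selection_gradients(
    z: pd.DataFrame | StandardizedMatrix,
    fitness: pd.Series,
    config: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, DiagnosticsReport]:
    """Selection gradients from the all-covariate multiple regression.

    OLS of fitness on every standardized covariate simultaneously; returns
    partial coefficients with SEs and t-test p-values, plus the collinearity
    report.  When any VIF exceeds the warning threshold an additional model
    dropping the highest-VIF covariate is fitted, recording whether the
    remaining gradients stay inside the original 95% confidence intervals.
    """
    config = config or ExperimentConfig()
    if isinstance(z, StandardizedMatrix):
        z = z.z
    data = pd.concat([z, fitness.rename("_w")], axis=1).dropna()
    covs = list(z.columns)
    n = len(data)
    if n < len(covs) + 2:
        raise ValueError(
            f"need n >= {len(covs) + 2} complete observations for {len(covs)} "
            f"covariates, got {n}"
        )
    X = sm.add_constant(data[covs])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        report = diagnose_collinearity(
            data[covs], config.vif_warn, config.vif_max, config.cond_index_max
        )
        report.flag = "fail"
        logger.warning("selection_gradients: singular design, no estimates")
        return pd.DataFrame(
            columns=["trait", "beta", "se_beta", "p_beta", "n"]
        ), report

    fit = sm.OLS(data["_w"], X).fit()
    est = pd.DataFrame(
        {
            "trait": covs,
            "beta": fit.params[covs].to_numpy(),
            "se_beta": fit.bse[covs].to_numpy(),
            "p_beta": fit.pvalues[covs].to_numpy(),
            "n": n,
        }
    )
    report = diagnose_collinearity(
        data[covs], config.vif_warn, config.vif_max, config.cond_index_max
    )
    if report.flag in ("warn", "fail") and all(np.isfinite(v) for v in report.vif.values()):
        worst = max(report.vif, key=report.vif.get)
        kept = [c for c in covs if c != worst]
        refit = sm.OLS(data["_w"], sm.add_constant(data[kept])).fit()
        ci = fit.conf_int(alpha=0.05)
        report.refit_within_ci = {
            c: bool(ci.loc[c, 0] <= refit.params[c] <= ci.loc[c, 1]) for c in kept
        }
        report.dropped_covariate = worst
    return est, report


def population_selection(
    derived: pd.DataFrame,
    config: ExperimentConfig | None = None,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, DiagnosticsReport]:
    """Differentials and gradients for one population's derived table.

    Differentials are computed for the eleven selection traits; the gradient
    regression additionally includes stem volume.  Returns one tidy table of
    per-trait estimates and the gradient diagnostics.
    """
    config = config or ExperimentConfig()
    covariates = covariates or GRADIENT_COVARIATES
    w = fitness_response(derived, config)
    std = standardize(derived[covariates], config.transform_policy)
    diff = selection_differentials(std.z[[c for c in ALL_TRAITS if c in std.z]], w)
    grad, report = selection_gradients(std.z, w, config)
    out = diff.merge(
        grad.rename(columns={"n": "n_beta"}), on="trait", how="outer"
    )
    return out, report


def summarize_selection(
    estimates: pd.DataFrame, alpha: float = 0.05, kind: str = "s"
) -> dict:
    """Counts and percentages of significant selection across populations.

    ``estimates`` stacks per-population trait rows; ``kind`` selects the
    differential (``"s"``) or gradient (``"beta"``) p-values.  Percentages
    are rounded to integers; the expected-by-chance count is
    ``round(alpha x n_cases)``.
    """
    pcol = "p_s" if kind == "s" else "p_beta"
    cases = estimates.dropna(subset=[pcol])
    n_cases = len(cases)
    n_sig = int((cases[pcol] < alpha).sum())
    out = {
        "n_cases": n_cases,
        "n_significant": n_sig,
        "percent_significant": int(round(100.0 * n_sig / n_cases)) if n_cases else 0,
        "expected_by_chance": int(round(alpha * n_cases)),
        "by_class": {},
    }
    for cls, traits in TRAIT_CLASSES.items():
        sub = cases[cases["trait"].isin(traits)]
        n_c = len(sub)
        n_s = int((sub[pcol] < alpha).sum())
        out["by_class"][cls] = {
            "n_cases": n_c,
            "n_significant": n_s,
            "percent_significant": int(round(100.0 * n_s / n_c)) if n_c else 0,
        }
    return out
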