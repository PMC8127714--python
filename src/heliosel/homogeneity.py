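"""Homogeneity of selection near versus far from the crop.

Selection is more homogeneous in one arm of the experiment if the
population-to-population spread of its selection coefficients is smaller.
The comparison is a variance-ratio F-test, F = s2_far / s2_near, two-sided by
default.  For the pooled all-trait test the coefficients are first recentered
to mean zero within each trait across all populations, so that between-trait
differences in the typical direction of selection do not masquerade as
heterogeneity; per-trait tests use the raw coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VarianceComparison:
    scope: str  # pooled-differentials | pooled-gradients | trait-specific
    trait: str | None
    ratio: float  # var(far) / var(near)
    F: float
    df_far: int
    df_near: int
    p: float
    sided: str = "two"

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "trait": self.trait,
            "ratio": self.ratio,
            "F": self.F,
            "df_far": self.df_far,
            "df_near": self.df_near,
            "p": self.p,
            "sided": self.sided,
        }


def f_two_sided_p(F: float, df1: int, df2: int, sided: str = "two") -> float:
    """Tail probability of the central F distribution.

    Two-sided: 2 * min(P(F' <= F), P(F' >= F)), capped at 1; one-sided: the
    upper tail.
    """
    if F <= 0 or df1 < 1 or df2 < 1:
        raise ValueError("need F > 0 and df >= 1")
    if sided == "one":
        return float(stats.f.sf(F, df1, df2))
    if sided != "two":
        raise ValueError(f"unknown sidedness {sided!r}")
    lower = stats.f.cdf(F, df1, df2)
    upper = stats.f.sf(F, df1, df2)
    return float(min(1.0, 2.0 * min(lower, upper)))


def variance_ratio_test(
    far: np.ndarray | pd.Series,
    near: np.ndarray | pd.Series,
    sided: str = "two",
    scope: str = "trait-specific",
    trait: str | None = None,
) -> VarianceComparison:
    """F-test of var(far) against var(near) with (n-1) denominators."""
    far = np.asarray(far, dtype=float)
    near = np.asarray(near, dtype=float)
    far = far[np.isfinite(far)]
    near = near[np.isfinite(near)]
    if len(far) < 2 or len(near) < 2:
        raise ValueError("need >= 2 values per arm")
    v_far = far.var(ddof=1)
    v_near = near.var(ddof=1)
    if v_far == 0 or v_near == 0:
        raise ValueError("zero variance in one arm, F undefined")
    F = v_far / v_near
    df_far, df_near = len(far) - 1, len(near) - 1
    p = f_two_sided_p(F, df_far, df_near, sided=sided)
    return VarianceComparison(
        scope=scope, trait=trait, ratio=F, F=F, df_far=df_far, df_near=df_near, p=p, sided=sided
    )


def recenter_by_trait(
    coefficients: pd.DataFrame,
    value_col: str,
    per_arm: bool = False,
) -> pd.DataFrame:
    """Recenter coefficients to mean zero within each trait.

    ``coefficients`` is long: one row per population x trait with columns
    ``trait``, ``proximity`` and ``value_col``.  By default the per-trait
    mean is taken across all populations (both arms pooled); ``per_arm``
    recenters within each proximity arm instead.  Traits with a single
    observation are dropped with a warning.
    """
    from .data_model import logger

    df = coefficients.dropna(subset=[value_col]).copy()
    counts = df.groupby("trait")[value_col].count()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        logger.warning("recenter_by_trait: dropping single-observation traits %s", singletons)
        df = df[~df["trait"].isin(singletons)]
    keys = ["trait", "proximity"] if per_arm else ["trait"]
    df[value_col] = df[value_col] - df.groupby(keys)[value_col].transform("mean")
    return df


def homogeneity_suite(
    estimates: pd.DataFrame,
    sided: str = "two",
    per_arm_recentering: bool = False,
) -> dict:
    """Pooled and per-trait variance comparisons of selection coefficients.

    ``estimates`` stacks per-population selection tables and must carry
    ``trait``, ``proximity``, ``s_prime`` and ``beta`` columns.  Pooled tests
    act on recentered coefficients of all traits stacked together (traits
    weighted equally); per-trait tests use raw coefficients.  Also reports,
    per coefficient kind, how many traits have greater far-arm variance.
    """
    results: dict = {"pooled": [], "per_trait": [], "n_traits_far_greater": {}}
    for kind, col in (("differentials", "s_prime"), ("gradients", "beta")):
        rec = recenter_by_trait(estimates, col, per_arm=per_arm_recentering)
        far = rec.loc[rec["proximity"] == "far", col]
        near = rec.loc[rec["proximity"] == "near", col]
        results["pooled"].append(
            variance_ratio_test(far, near, sided=sided, scope=f"pooled-{kind}")
        )
        n_far_greater = 0
        n_traits = 0
        for trait, sub in estimates.dropna(subset=[col]).groupby("trait"):
            f_vals = sub.loc[sub["proximity"] == "far", col]
            n_vals = sub.loc[sub["proximity"] == "near", col]
            if len(f_vals) < 2 or len(n_vals) < 2:
                continue
            try:
                comp = variance_ratio_test(f_vals, n_vals, sided=sided, trait=str(trait))
            except ValueError:
                continue
            comp.scope = f"trait-{kind}"
            results["per_trait"].append(comp)
            n_traits += 1
            if comp.ratio > 1:
                n_far_greater += 1
        results["n_traits_far_greater"][kind] = {
            "n_far_greater": n_far_greater,
            "n_traits": n_traits,
        }
    return results


def comparisons_table(results: dict) -> pd.DataFrame:
    """Flatten a homogeneity_suite result into one tidy table."""
    rows = [c.to_dict() for c in results["pooled"]] + [
        c.to_dict() for c in results["per_trait"]
    ]
    return pd.DataFrame(rows)


def pooled_histogram(
    estimates: pd.DataFrame, value_col: str, bins: int = 20
) -> pd.DataFrame:
    """Binned recentered coefficients per arm (plot-ready summary)."""
    rec = recenter_by_trait(estimates, value_col)
    lo = rec[value_col].min()
    hi = rec[value_col].max()
    edges = np.linspace(lo, hi, bins + 1)
    rows = []
    for arm, sub in rec.groupby("proximity"):
        counts, _ = np.histogram(sub[value_col], bins=edges)
        for i, c in enumerate(counts):
            rows.append(
                {
                    "proximity": arm,
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)
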