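"""Selection differentials, gradients, diagnostics and summaries."""

import numpy as np
import pandas as pd
import pytest

import heliosel as hs
from heliosel.selection import diagnose_collinearity, selection_differentials, selection_gradients

# hand-computed (normal equations / covariance by hand) for the worked
# fixture's POPA-near population, fitness = ln(w_rel + 1)
HAND_S_DD = 0.258456026234
HAND_S_RL = 0.251724815470
HAND_BETA_DD = 0.190243732000
HAND_BETA_RL = 0.072342465120


def _popa_zw(worked):
    frames, tidy = worked
    popa = tidy[tidy.population_id == "POPA-near"].set_index("plant_id")
    z = popa[["DD", "RL"]].apply(lambda c: (c - c.mean()) / c.std(ddof=1))
    w_rel = popa["W"] / popa["W"].mean()
    return z, np.log(w_rel + 1.0)


def test_worked_fixture_differential_matches_hand_value(worked):
    z, log_w = _popa_zw(worked)
    est = selection_differentials(z, log_w)
    assert est.set_index("trait").loc["DD", "s_prime"] == pytest.approx(HAND_S_DD, abs=1e-9)
    assert est.set_index("trait").loc["RL", "s_prime"] == pytest.approx(HAND_S_RL, abs=1e-9)


def test_worked_fixture_gradients_match_normal_equations(worked):
    z, log_w = _popa_zw(worked)
    est, _ = selection_gradients(z, log_w)
    got = est.set_index("trait")
    assert got.loc["DD", "beta"] == pytest.approx(HAND_BETA_DD, abs=1e-9)
    assert got.loc["RL", "beta"] == pytest.approx(HAND_BETA_RL, abs=1e-9)


def test_differential_equals_r_times_sd_fitness(rng):
    """With unit-variance traits, s' = r * SD(w) (algebraic identity)."""
    z = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    z = (z - z.mean()) / z.std(ddof=1)
    w = pd.Series(rng.normal(2, 1.5, 40))
    est = selection_differentials(z, w).set_index("trait")
    for t in "abc":
        r = np.corrcoef(z[t], w)[0, 1]
        assert est.loc[t, "s_prime"] == pytest.approx(r * w.std(ddof=1), abs=1e-10)


def test_constant_fitness_gives_zero_differential(rng):
    z = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
    est = selection_differentials(z, pd.Series(np.full(10, 2.0)))
    assert (est.s_prime == 0).all()
    assert (est.p_s == 1).all()


def test_orthogonal_design_gradients_equal_differentials(rng):
    """When covariates are exactly uncorrelated in-sample, direct selection
    equals total selection trait by trait."""
    raw = rng.normal(size=(24, 4))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    z = pd.DataFrame(q, columns=list("abcd"))
    z = (z - z.mean()) / z.std(ddof=1)  # orthogonal and standardized
    w = pd.Series(rng.normal(size=24) + z["a"] * 0.4 - z["c"] * 0.2)
    diff = selection_differentials(z, w).set_index("trait")
    grad, _ = selection_gradients(z, w)
    grad = grad.set_index("trait")
    for t in z.columns:
        assert grad.loc[t, "beta"] == pytest.approx(diff.loc[t, "s_prime"], abs=1e-10)


def test_single_covariate_beta_equals_differential(rng):
    z = pd.DataFrame({"a": rng.normal(size=30)})
    z = (z - z.mean()) / z.std(ddof=1)
    w = pd.Series(rng.normal(size=30))
    d = selection_differentials(z, w).set_index("trait").loc["a", "s_prime"]
    g, _ = selection_gradients(z, w)
    assert g.set_index("trait").loc["a", "beta"] == pytest.approx(d, abs=1e-10)


def test_ols_matches_normal_equations_oracle(rng):
    for _ in range(5):
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        w = pd.Series(rng.normal(size=20))
        est, _ = selection_gradients(X, w)
        Xd = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ w.to_numpy())
        np.testing.assert_allclose(est.beta.to_numpy(), beta[1:], atol=1e-10)


def test_vif_orthogonal_columns_are_one(rng):
    raw = rng.normal(size=(30, 3))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    rep = diagnose_collinearity(pd.DataFrame(q, columns=list("abc")))
    for v in rep.vif.values():
        assert v == pytest.approx(1.0, abs=1e-8)
    assert rep.flag == "pass"


def test_vif_duplicate_column_fails(rng):
    x = rng.normal(size=25)
    rep = diagnose_collinearity(pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=25)}))
    assert np.isinf(rep.vif["a"])
    assert rep.flag == "fail"


def test_vif_matches_rsquared_oracle(rng):
    import statsmodels.api as sm

    X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    X["d"] = X["a"] * 0.8 + rng.normal(scale=0.5, size=50)
    rep = diagnose_collinearity(X)
    for j, col in enumerate(X.columns):
        others = X.drop(columns=col)
        r2 = sm.OLS(X[col], sm.add_constant(others)).fit().rsquared
        assert rep.vif[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


def test_condition_indices_sorted_and_scaled(rng):
    X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    rep = diagnose_collinearity(X)
    assert rep.condition_indices == sorted(rep.condition_indices, reverse=True)
    assert rep.condition_indices[-1] == pytest.approx(1.0, abs=1e-10)


def test_refit_check_runs_above_warn_threshold(rng):
    x = rng.normal(size=60)
    X = pd.DataFrame(
        {"a": x, "b": x + rng.normal(scale=0.25, size=60), "c": rng.normal(size=60)}
    )
    w = pd.Series(x * 0.3 + rng.normal(size=60))
    est, rep = selection_gradients(X, w)
    assert rep.max_vif > 5.0
    assert rep.dropped_covariate in ("a", "b")
    assert set(rep.refit_within_ci) == set(X.columns) - {rep.dropped_covariate}


def _fake_estimates(n_cases, n_sig, trait="DD"):
    p = np.full(n_cases, 0.5)
    p[:n_sig] = 0.01
    return pd.DataFrame({"trait": trait, "p_s": p, "p_beta": p, "s_prime": 0.1, "beta": 0.1})


def test_summary_percentages_and_chance_counts():
    summary = hs.summarize_selection(_fake_estimates(253, 74), alpha=0.05, kind="s")
    assert summary["percent_significant"] == 29
    assert summary["expected_by_chance"] == 13
    summary_b = hs.summarize_selection(_fake_estimates(242, 30), alpha=0.05, kind="beta")
    assert summary_b["percent_significant"] == 12
    assert summary_b["expected_by_chance"] == 12
    none = hs.summarize_selection(_fake_estimates(40, 0), alpha=0.05, kind="s")
    assert none["percent_significant"] == 0


def test_summary_splits_trait_classes():
    est = pd.concat(
        [
            _fake_estimates(10, 5, trait="DD"),
            _fake_estimates(10, 1, trait="CS"),
            _fake_estimates(10, 2, trait="ISO"),
        ],
        ignore_index=True,
    )
    s = hs.summarize_selection(est, kind="s")
    assert s["by_class"]["inflorescence"]["n_significant"] == 5
    assert s["by_class"]["disk_flower"]["n_significant"] == 1
    assert s["by_class"]["antagonist"]["n_significant"] == 2


def test_gradient_needs_enough_observations(rng):
    z = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
    with pytest.raises(ValueError, match="complete observations"):
        selection_gradients(z, pd.Series(rng.normal(size=5)))
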