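"""PCA composites, basis sets, Fisher's C, path fitting, multigroup SEM."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import heliosel as hs
from heliosel.sem import IndependenceClaim, basis_set, fisher_c, pca_composite
from heliosel.sem import test_claims as run_claim_tests


def _random_dag(rng, n_nodes, p_edge=0.4):
    names = [f"v{i}" for i in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            g.add_edge(names[i], names[j])  # i<j keeps it acyclic
    return hs.DAGSpec(graph=g)


# ---------- PCA composites ----------


def test_pca_two_perfect_traits(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": 2 * x + 5})
    comp = pca_composite(df)
    assert comp.variance_explained == pytest.approx(1.0, abs=1e-10)
    assert comp.loadings["a"] == pytest.approx(comp.loadings["b"], abs=1e-10)


def test_pca_sign_alignment(rng):
    df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    df = df.add(df["a"] * 0.8, axis=0)  # one dominant shared axis
    base = pca_composite(df)
    flipped = df.copy()
    flipped["b"] = -flipped["b"]
    comp = pca_composite(flipped)
    np.testing.assert_allclose(base.scores, comp.scores, atol=1e-10)
    for col in df:
        assert np.corrcoef(df[col], base.scores)[0, 1] >= -1e-12


def test_pca_loadings_match_eigh_oracle(rng):
    df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    comp = pca_composite(df)
    z = (df - df.mean()) / df.std(ddof=1)
    vals, vecs = np.linalg.eigh(np.corrcoef(z.to_numpy(), rowvar=False))
    lead = vecs[:, -1]
    got = np.array([comp.loadings[c] for c in df.columns])
    assert np.allclose(got, lead, atol=1e-8) or np.allclose(got, -lead, atol=1e-8)


def test_pca_excludes_constant_trait(rng):
    df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30), "c": 1.0})
    comp = pca_composite(df)
    assert "c" not in comp.loadings


# ---------- basis sets and d-separation ----------


def test_chain_basis_set():
    dag = hs.DAGSpec.from_edges([("X", "Y"), ("Y", "Z")])
    claims = basis_set(dag)
    assert len(claims) == 1
    assert (claims[0].a, claims[0].b, claims[0].conditioning) == ("X", "Z", ("Y",))


def test_complete_dag_empty_basis():
    dag = hs.DAGSpec.from_edges([("A", "B"), ("A", "C"), ("B", "C")])
    assert basis_set(dag) == []
    assert fisher_c([]) == (0.0, 0, 1.0)


def test_basis_set_matches_dseparation_oracle(rng):
    """Every claim is conditionally d-separated (independent path-blocking
    oracle) and every non-adjacent pair is claimed exactly once."""
    for n_nodes in (3, 4, 5, 6):
        for _ in range(40):
            dag = _random_dag(rng, n_nodes)
            g = dag.graph
            claims = basis_set(dag)
            pairs = {frozenset((c.a, c.b)) for c in claims}
            expected = {
                frozenset((u, v))
                for u, v in itertools.combinations(g.nodes, 2)
                if not g.has_edge(u, v) and not g.has_edge(v, u)
            }
            assert pairs == expected
            assert len(claims) == len(pairs)
            for c in claims:
                assert nx.is_d_separator(g, {c.a}, {c.b}, set(c.conditioning))
                assert not nx.has_path(g, c.b, c.a)  # response never an ancestor


def test_basis_set_conditioning_is_parent_union(rng):
    dag = _random_dag(rng, 6, p_edge=0.5)
    g = dag.graph
    for c in basis_set(dag):
        expected = (set(g.predecessors(c.a)) | set(g.predecessors(c.b))) - {c.a, c.b}
        assert set(c.conditioning) == expected


def test_basis_set_deterministic_order(rng):
    dag = _random_dag(rng, 6)
    assert [c.label() for c in basis_set(dag)] == [c.label() for c in basis_set(dag)]


# ---------- Fisher's C ----------


def test_fisher_c_closed_form():
    C, df, p = fisher_c([0.5, 0.1])
    assert C == pytest.approx(-2 * (np.log(0.5) + np.log(0.1)), abs=1e-12)
    assert C == pytest.approx(5.991464547, abs=1e-6)
    assert df == 4
    assert p == pytest.approx(stats.chi2.sf(C, 4), abs=1e-12)


def test_fisher_c_boundaries():
    C, df, p = fisher_c([1.0, 1.0, 1.0])
    assert (C, df, p) == (0.0, 6, 1.0)
    C, df, p = fisher_c([0.0, 0.5])
    assert np.isinf(C) and p == 0.0


def test_fisher_c_permutation_and_monotonicity(rng):
    ps = list(rng.uniform(0.01, 1, 6))
    assert fisher_c(ps)[0] == pytest.approx(fisher_c(ps[::-1])[0], abs=1e-12)
    lowered = list(ps)
    lowered[2] /= 10
    assert fisher_c(lowered)[2] < fisher_c(ps)[2]


# ---------- claim testing ----------


def test_claims_null_uniform_and_violation():
    dag = hs.DAGSpec.from_edges([("X", "Y"), ("Y", "Z")])
    coeffs = {("X", "Y"): 0.6, ("Y", "Z"): 0.6}
    null_ps = []
    viol_ps = []
    for rep in range(120):
        data = hs.generate_dag_consistent(dag, coeffs, 150, rng_seed=rep)
        null_ps.append(run_claim_tests(basis_set(dag), data)[0].p)
        bad = data.copy()
        bad["Z"] = bad["Z"] + 0.6 * bad["X"]  # direct X->Z effect
        viol_ps.append(run_claim_tests(basis_set(dag), bad)[0].p)
    assert stats.kstest(null_ps, "uniform").pvalue > 0.01
    assert np.median(viol_ps) < 0.001


def test_claim_untestable_when_sample_tiny():
    claims = [IndependenceClaim(a="X", b="Z", conditioning=("Y",))]
    data = pd.DataFrame({"X": [1.0, 2], "Y": [0.5, 1], "Z": [3.0, 4]})
    out = run_claim_tests(claims, data)
    assert not out[0].testable and out[0].p is None


def test_good_fit_rate_on_faithful_data():
    """Fisher's C retains ~95% acceptance when the model is true."""
    dag = hs.DAGSpec.from_edges([("X", "M"), ("M", "Y"), ("Z", "Y")])
    coeffs = {("X", "M"): 0.5, ("M", "Y"): 0.5, ("Z", "Y"): 0.3}
    good = 0
    reps = 300
    for rep in range(reps):
        data = hs.generate_dag_consistent(dag, coeffs, 200, rng_seed=10_000 + rep)
        tested = run_claim_tests(basis_set(dag), data)
        _, _, p = fisher_c([c.p for c in tested])
        good += p > 0.05
    assert 0.91 <= good / reps <= 0.99


# ---------- path fitting and multigroup ----------


def test_single_parent_path_is_pearson_r(rng):
    dag = hs.DAGSpec.from_edges([("X", "Y")])
    x = rng.normal(size=80)
    y = 0.5 * x + rng.normal(size=80)
    z = pd.DataFrame({"X": x, "Y": y})
    z = (z - z.mean()) / z.std(ddof=1)
    paths = hs.fit_paths(dag, z)
    assert paths[0].coefficient == pytest.approx(np.corrcoef(z.X, z.Y)[0, 1], abs=1e-10)


def test_fit_paths_recovers_generating_coefficients():
    dag = hs.DAGSpec.from_edges([("X", "M"), ("M", "Y"), ("Z", "Y")])
    coeffs = {("X", "M"): 0.5, ("M", "Y"): 0.7, ("Z", "Y"): -0.3}
    data = hs.generate_dag_consistent(dag, coeffs, 3_000, rng_seed=42)
    for p in hs.fit_paths(dag, data):
        assert abs(p.coefficient - coeffs[(p.source, p.target)]) < 2 * p.se


def test_no_edge_dag_has_no_paths():
    g = nx.DiGraph()
    g.add_nodes_from(["A", "B"])
    assert hs.fit_paths(hs.DAGSpec(graph=g), pd.DataFrame({"A": [1.0, 2, 3], "B": [2.0, 1, 3]})) == []


def test_multigroup_requires_two_groups():
    dag = hs.DAGSpec.from_edges([("X", "Y")], group_variable="g")
    data = hs.generate_dag_consistent(dag, {("X", "Y"): 0.5}, 50, 1)
    data["g"] = "near"
    with pytest.raises(ValueError, match="2 levels"):
        hs.multigroup_fit(dag, data)


def test_multigroup_frees_differing_path_keeps_others():
    dag = hs.DAGSpec.from_edges([("X", "M"), ("M", "Y"), ("Z", "Y")], group_variable="g")
    coeffs = {("X", "M"): 0.5, ("M", "Y"): 0.5, ("Z", "Y"): 0.3}
    altered = dict(coeffs)
    altered[("M", "Y")] = 1.0  # differs by 0.5
    freed_target = 0
    others_ok = 0
    reps = 60
    for rep in range(reps):
        d1 = hs.generate_dag_consistent(dag, coeffs, 100, rng_seed=rep)
        d2 = hs.generate_dag_consistent(dag, altered, 100, rng_seed=77_000 + rep)
        d1["g"], d2["g"] = "near", "far"
        fit = hs.multigroup_fit(dag, pd.concat([d1, d2], ignore_index=True))
        status = {(p.source, p.target): p.status for p in fit.paths}
        freed_target += status[("M", "Y")] == "free"
        others_ok += all(
            s == "constrained" for k, s in status.items() if k != ("M", "Y")
        )
    assert freed_target / reps >= 0.8
    assert others_ok / reps >= 0.8
    # structural checks on one fit
    free_paths = [p for p in fit.paths if p.status == "free"]
    if free_paths:
        assert set(free_paths[0].by_group) == {"near", "far"}


def test_dag_text_and_yaml_parsing(tmp_path):
    text = "X -> Y\nY -> Z  # chain\n\n"
    dag = hs.DAGSpec.from_text(text)
    assert dag.edges == [("X", "Y"), ("Y", "Z")]
    yml = tmp_path / "dag.yaml"
    yml.write_text("edges:\n  - [X, Y]\n  - [Y, Z]\ngroup_variable: proximity\n")
    dag2 = hs.DAGSpec.from_yaml(yml)
    assert dag2.edges == dag.edges and dag2.group_variable == "proximity"


def test_default_dag_structure():
    dag = hs.default_dag(with_pollen=True)
    assert ("inflorescence_PC", "ISO") in dag.edges
    assert ("pollen", "w_rel") in dag.edges
    assert ("volume", "w_rel") in dag.edges
    no_pollen = hs.default_dag(with_pollen=False)
    assert "pollen" not in no_pollen.nodes


def test_population_pair_dataset_and_fit(paired_experiment):
    frames, _ = paired_experiment
    pair = [f for f in frames if f.site == "site1" and f.seed_source == "B"]
    near = next(f for f in pair if f.proximity == "near")
    far = next(f for f in pair if f.proximity == "far")
    data, comps = hs.population_pair_dataset(near, far)
    assert {"inflorescence_PC", "flower_PC", "w_rel", "proximity"} <= set(data.columns)
    assert comps["inflorescence_PC"].variance_explained > 0.25
    dag = hs.default_dag(with_pollen="pollen" in data.columns)
    fit = hs.multigroup_fit(dag, data)
    assert fit.df == 2 * len([c for c in fit.claims if c.testable])  # df = 2k
    assert 0.0 <= fit.p_model <= 1.0
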