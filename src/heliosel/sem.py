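"""Piecewise structural equation modeling with local estimation.

The causal model links composite floral traits (first principal components of
the inflorescence and disk-flower trait blocks) to the activity of
interactors — seed-predator attack and, where measured, pollen deposition —
and links the interactors, stem volume and inflorescence number to relative
fitness.  Each structural equation is an ordinary linear regression
("local estimation"); overall goodness-of-fit comes from Shipley's test of
d-separation: every conditional-independence claim the graph implies is
tested by regression, and the claim p-values combine into Fisher's
C = -2 * sum(ln p), referred to a chi-square with 2k degrees of freedom.
A model-wide p > 0.05 indicates good fit (the data do not contradict the
claimed absences of paths).

The multigroup analysis asks, path by path, whether a coefficient differs
between the near and far populations of a pair: a significant
parent x group interaction frees that path (per-group coefficients), an
insignificant one constrains it to a common pooled coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from .data_model import (
    DISK_TRAITS,
    INFLORESCENCE_TRAITS,
    ExperimentConfig,
    PopulationFrame,
    logger,
)
from .traits import derive_population, standardize


@dataclass
class DAGSpec:
    """A causal DAG over observed variables, optionally grouped."""

    graph: nx.DiGraph
    group_variable: str | None = None

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("model graph must be acyclic")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], group_variable: str | None = None
    ) -> "DAGSpec":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        return cls(graph=g, group_variable=group_variable)

    @classmethod
    def from_text(cls, text: str, group_variable: str | None = None) -> "DAGSpec":
        """Parse ``A -> B`` lines (blank lines and ``#`` comments ignored)."""
        edges = []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" not in line:
                raise ValueError(f"cannot parse edge line {line!r}")
            src, dst = (part.strip() for part in line.split("->", 1))
            edges.append((src, dst))
        return cls.from_edges(edges, group_variable)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DAGSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_edges(
            [tuple(e) for e in raw["edges"]], raw.get("group_variable")
        )

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def parents(self, node: str) -> list[str]:
        return sorted(self.graph.predecessors(node))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))


def default_dag(with_pollen: bool = False) -> DAGSpec:
    """The a priori model: composite traits -> interactors -> fitness,
    with stem volume and inflorescence number as direct fitness parents."""
    interactors = ["ISO", "NEO"] + (["pollen"] if with_pollen else [])
    edges: list[tuple[str, str]] = []
    for comp in ("inflorescence_PC", "flower_PC"):
        for inter in interactors:
            edges.append((comp, inter))
    for inter in interactors:
        edges.append((inter, "w_rel"))
    edges += [("volume", "w_rel"), ("n_inflorescences", "w_rel")]
    return DAGSpec.from_edges(edges, group_variable="proximity")


@dataclass
class CompositeTrait:
    """First-PC summary of a trait block, sign-aligned and standardized."""

    name: str
    loadings: dict[str, float]
    scores: pd.Series
    variance_explained: float


def pca_composite(traits: pd.DataFrame, name: str = "PC1") -> CompositeTrait:
    """First principal component of the correlation matrix of ``traits``.

    Constant columns are excluded with a warning.  Loadings are sign-flipped
    so every constituent trait correlates nonnegatively with the scores
    (larger composite = larger traits); scores are re-standardized to unit
    sample SD.
    """
    df = traits.dropna()
    keep = [c for c in df.columns if df[c].std(ddof=1) > 0]
    dropped = set(df.columns) - set(keep)
    if dropped:
        logger.warning("pca_composite: excluding constant trait(s) %s", sorted(dropped))
    df = df[keep]
    if df.shape[1] < 2 or len(df) < 3:
        raise ValueError("need >= 2 varying traits and >= 3 plants")
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v1 = eigvecs[:, -1]
    scores = z.to_numpy() @ v1
    # sign alignment: every trait positively correlated with the component
    corr_with = np.array([np.corrcoef(z[c], scores)[0, 1] for c in z.columns])
    if corr_with.sum() < 0:
        v1, scores, corr_with = -v1, -scores, -corr_with
    if (corr_with < -1e-12).any():
        bad = [c for c, r in zip(z.columns, corr_with) if r < 0]
        logger.warning("pca_composite(%s): traits %s load against the component", name, bad)
    scores = scores / scores.std(ddof=1)
    return CompositeTrait(
        name=name,
        loadings=dict(zip(z.columns, v1)),
        scores=pd.Series(scores, index=df.index, name=name),
        variance_explained=float(eigvals[-1] / eigvals.sum()),
    )


@dataclass
class IndependenceClaim:
    """One basis-set claim: a independent of b given the conditioning set."""

    a: str  # predictor whose coefficient is tested
    b: str  # response of the test regression
    conditioning: tuple[str, ...]
    p: float | None = None
    group: str | None = None  # set when tested within one group
    testable: bool = True

    def label(self) -> str:
        cond = ", ".join(self.conditioning)
        return f"{self.a} _||_ {self.b} | {{{cond}}}"


def basis_set(dag: DAGSpec) -> list[IndependenceClaim]:
    """Shipley's directed-graph basis set.

    One claim per unordered non-adjacent pair, conditioned on the union of
    both variables' parents.  The pair is ordered so the regression response
    is not an ancestor of the predictor (causal order preserved); ties —
    neither an ancestor — resolve by topological, then lexicographic order.
    Claims are returned in a deterministic canonical ordering.
    """
    g = dag.graph
    order = {node: i for i, node in enumerate(dag.topological_order())}
    claims = []
    nodes = sorted(g.nodes, key=lambda v: (order[v], v))
    for i, x in enumerate(nodes):
        for y in nodes[i + 1 :]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            # x precedes y topologically, so y cannot be an ancestor of x:
            # regress y (response) on x (predictor) plus both parent sets
            cond = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(
                IndependenceClaim(a=x, b=y, conditioning=tuple(sorted(cond)))
            )
    return claims


def test_claims(
    claims: list[IndependenceClaim],
    data: pd.DataFrame,
    group: str | None = None,
) -> list[IndependenceClaim]:
    """Test each claim by linear regression of b on a + conditioning set.

    The claim p-value is the two-sided t-test of a's partial coefficient.
    Claims whose design is collinear or whose sample is too small are flagged
    untestable (p left missing).
    """
    out = []
    for claim in claims:
        cols = [claim.a, *claim.conditioning, claim.b]
        sub = data[cols].dropna()
        tested = IndependenceClaim(
            a=claim.a, b=claim.b, conditioning=claim.conditioning, group=group
        )
        X = sm.add_constant(sub[[claim.a, *claim.conditioning]])
        if len(sub) < len(claim.conditioning) + 3 or np.linalg.matrix_rank(
            X.to_numpy()
        ) < X.shape[1]:
            tested.testable = False
            logger.warning("claim %s untestable (n or collinearity)", claim.label())
            out.append(tested)
            continue
        fit = sm.OLS(sub[claim.b], X).fit()
        tested.p = float(fit.pvalues[claim.a])
        out.append(tested)
    return out


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p), df = 2k, and the chi-square upper tail.

    An empty claim list gives (0, 0, 1); any p = 0 gives C = inf, p = 0.
    """
    ps = np.asarray(list(p_values), dtype=float)
    k = ps.size
    if k == 0:
        return 0.0, 0, 1.0
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("fisher_c: zero p-value, C is infinite")
        return np.inf, 2 * k, 0.0
    C = float(-2.0 * np.log(ps).sum())
    df = 2 * k
    return C, df, float(stats.chi2.sf(C, df))


@dataclass
class PathEstimate:
    source: str
    target: str
    status: str = "constrained"  # constrained | free
    coefficient: float | None = None  # pooled (constrained paths)
    se: float | None = None
    p: float | None = None
    by_group: dict[str, dict[str, float]] = field(default_factory=dict)
    interaction_p: float | None = None


@dataclass
class SEMFit:
    paths: list[PathEstimate]
    fisher_C: float
    df: int
    p_model: float
    claims: list[IndependenceClaim] = field(default_factory=list)

    @property
    def good_fit(self) -> bool:
        return self.p_model > 0.05

    def paths_table(self) -> pd.DataFrame:
        rows = []
        for p in self.paths:
            row = {
                "source": p.source,
                "target": p.target,
                "status": p.status,
                "coefficient": p.coefficient,
                "se": p.se,
                "p": p.p,
                "interaction_p": p.interaction_p,
            }
            for gname, est in p.by_group.items():
                row[f"coef_{gname}"] = est["coefficient"]
                row[f"p_{gname}"] = est["p"]
            rows.append(row)
        return pd.DataFrame(rows)


def fit_paths(dag: DAGSpec, data: pd.DataFrame) -> list[PathEstimate]:
    """Standardized path coefficients: per endogenous node, OLS on its parents."""
    out = []
    for node in dag.topological_order():
        parents = dag.parents(node)
        if not parents:
            continue
        sub = data[[node, *parents]].dropna()
        X = sm.add_constant(sub[parents])
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"singular parent set for node {node!r}")
        fit = sm.OLS(sub[node], X).fit()
        for par in parents:
            out.append(
                PathEstimate(
                    source=par,
                    target=node,
                    coefficient=float(fit.params[par]),
                    se=float(fit.bse[par]),
                    p=float(fit.pvalues[par]),
                )
            )
    return out


def _canonical_paths(dag: DAGSpec) -> list[tuple[str, str]]:
    """Paths ordered by topological position of the child, then lexicographic."""
    order = {node: i for i, node in enumerate(dag.topological_order())}
    return sorted(dag.graph.edges, key=lambda e: (order[e[1]], e[1], e[0]))


def multigroup_fit(
    dag: DAGSpec,
    data: pd.DataFrame,
    group_variable: str | None = None,
    alpha: float = 0.05,
    min_group_n: int = 10,
) -> SEMFit:
    """Multigroup piecewise SEM over exactly two groups (near vs far).

    Iterates the paths in canonical order: for each, the focal response is
    regressed on its parents plus a parent x group interaction for the focal
    path (and for every path into the same response already freed); a focal
    interaction p < alpha frees the path.  Constrained paths report the
    pooled coefficient (group main effect retained), free paths report
    per-group coefficients.  Fisher's C combines claim tests run per group
    where a freed path touches the claim's variables and pooled otherwise.
    """
    gvar = group_variable or dag.group_variable
    if gvar is None:
        raise ValueError("no group variable specified")
    levels = sorted(data[gvar].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group variable {gvar!r} must have exactly 2 levels, got {levels}")
    for lev in levels:
        n = int((data[gvar] == lev).sum())
        if n < min_group_n:
            raise ValueError(f"group {lev!r} has n = {n} < {min_group_n}")
    gcode = (data[gvar] == levels[1]).astype(float)  # 0/1 indicator

    # pass 1: decide per-path constrained/free status
    freed: set[tuple[str, str]] = set()
    interaction_p: dict[tuple[str, str], float] = {}
    for src, dst in _canonical_paths(dag):
        parents = dag.parents(dst)
        inter_terms = [e[0] for e in freed if e[1] == dst] + [src]
        cols = pd.DataFrame({p: data[p] for p in parents})
        cols["_g"] = gcode
        for term in sorted(set(inter_terms)):
            cols[f"{term}:_g"] = data[term] * gcode
        cols["_y"] = data[dst]
        sub = cols.dropna()
        X = sm.add_constant(sub.drop(columns="_y"))
        fit = sm.OLS(sub["_y"], X).fit()
        p_int = float(fit.pvalues[f"{src}:_g"])
        interaction_p[(src, dst)] = p_int
        if p_int < alpha:
            freed.add((src, dst))

    # pass 2: report coefficients under the final constraint pattern
    paths: list[PathEstimate] = []
    for src, dst in _canonical_paths(dag):
        est = PathEstimate(source=src, target=dst, interaction_p=interaction_p[(src, dst)])
        parents = dag.parents(dst)
        if (src, dst) in freed:
            est.status = "free"
            for lev in levels:
                sub = data.loc[data[gvar] == lev, [dst, *parents]].dropna()
                fit = sm.OLS(sub[dst], sm.add_constant(sub[parents])).fit()
                est.by_group[str(lev)] = {
                    "coefficient": float(fit.params[src]),
                    "se": float(fit.bse[src]),
                    "p": float(fit.pvalues[src]),
                }
        else:
            cols = data[[dst, *parents]].copy()
            cols["_g"] = gcode
            for fsrc, fdst in freed:
                if fdst == dst:
                    cols[f"{fsrc}:_g"] = data[fsrc] * gcode
            sub = cols.dropna()
            fit = sm.OLS(sub[dst], sm.add_constant(sub.drop(columns=dst))).fit()
            est.coefficient = float(fit.params[src])
            est.se = float(fit.bse[src])
            est.p = float(fit.pvalues[src])
        paths.append(est)

    # goodness of fit: claims touched by a freed path are tested per group
    freed_nodes = {v for e in freed for v in e}
    claims = basis_set(dag)
    tested: list[IndependenceClaim] = []
    for claim in claims:
        if {claim.a, claim.b} & freed_nodes:
            for lev in levels:
                tested += test_claims([claim], data[data[gvar] == lev], group=str(lev))
        else:
            tested += test_claims([claim], data)
    ps = [c.p for c in tested if c.testable and c.p is not None]
    C, df, p_model = fisher_c(ps)
    return SEMFit(paths=paths, fisher_C=C, df=df, p_model=p_model, claims=tested)


def population_pair_dataset(
    near: PopulationFrame,
    far: PopulationFrame,
    config: ExperimentConfig | None = None,
    include_pollen: bool | None = None,
) -> tuple[pd.DataFrame, dict[str, CompositeTrait]]:
    """Assemble the SEM dataset for one population-pair.

    Traits are standardized within population, the two composite PCs are
    extracted from the pair's combined (site-year) data, and relative fitness
    is kept on its population-relative scale.  Pollen deposition enters only
    when both arms measured it (or when ``include_pollen`` forces the choice).
    """
    config = config or ExperimentConfig()
    parts = []
    for frame in (near, far):
        derived = derive_population(frame, config)
        cols = list(INFLORESCENCE_TRAITS + DISK_TRAITS) + [
            "ISO",
            "NEO",
            "volume",
            "n_inflorescences",
            "pollen",
        ]
        std = standardize(derived[cols], config.transform_policy)
        block = std.z.reindex(columns=cols)
        block["w_rel"] = derived["w_rel"]
        block["proximity"] = frame.proximity
        block["population_id"] = frame.population_id
        parts.append(block)
    combined = pd.concat(parts, axis=0)

    if include_pollen is None:
        include_pollen = bool(combined.groupby("proximity")["pollen"].count().min() > 0)

    composites = {}
    infl = pca_composite(
        combined[list(INFLORESCENCE_TRAITS)].astype(float), name="inflorescence_PC"
    )
    disk = pca_composite(combined[list(DISK_TRAITS)].astype(float), name="flower_PC")
    composites["inflorescence_PC"] = infl
    composites["flower_PC"] = disk
    combined["inflorescence_PC"] = infl.scores.reindex(combined.index)
    combined["flower_PC"] = disk.scores.reindex(combined.index)
    if not include_pollen:
        combined = combined.drop(columns="pollen")
    return combined, composites
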