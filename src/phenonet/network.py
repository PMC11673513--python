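"""Target-proximity-weighted correlation network and eigenvector centrality.

Selected metabolites become nodes of an undirected graph together with one
designated target node (the BMI phenotype).  Edges join pairs whose Pearson
correlation is significant (two-sided p < alpha); the metabolite-target
edges use the correlation between each feature's processed abundances and
the subjects' continuous BMI.

Every edge then receives a *connection degree*: 1 for edges touching the
target, otherwise 1 + the geodesic distance of the nearer endpoint to the
target.  The edge weight is |r| * 0.5^(degree - 1), so first-degree edges
keep their full |r|, second-degree edges half of it, then 0.25, 0.125,
0.0625, continuing geometrically (negative correlations count by magnitude).
Eigenvector centrality of the weighted adjacency, computed by power
iteration on the target's connected component, ranks the metabolites most
proximal -- directly or through strongly correlated neighbours -- to the
phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import ProcessedTable

logger = logging.getLogger(__name__)

DEFAULT_TARGET = "BMI"
DEFAULT_ALPHA = 0.05
DEFAULT_TOP_K = 25

#: Per-degree halving factor of the proximity weighting.
PROXIMITY_FACTOR = 0.5


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value via the t transform.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` against Student's t with n-2 df;
    |r| = 1 yields p = 0.  Constant input is undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    sx = x - x.mean()
    sy = y - y.mean()
    denom = np.sqrt((sx @ sx) * (sy @ sy))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip((sx @ sy) / denom, -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class TargetedNetwork:
    """Correlation graph of metabolites plus one phenotype target node.

    Wraps a ``networkx.Graph`` whose edges carry ``r``, ``p`` and ``sign``,
    and -- after :func:`assign_degrees_and_weights` -- ``degree`` and
    ``weight``; nodes carry ``kind`` and (when assigned) ``distance`` to the
    target (-1 when unreachable).
    """

    graph: nx.Graph
    target: str = DEFAULT_TARGET

    @property
    def metabolites(self) -> list:
        return [n for n in self.graph.nodes if n != self.target]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @classmethod
    def from_edges(
        cls, edges, target: str = DEFAULT_TARGET, nodes=None
    ) -> "TargetedNetwork":
        """Build directly from ``(node_a, node_b, r)`` triples.

        Convenient for worked examples and for checking the weighting rule on
        hand-constructed topologies.
        """
        g = nx.Graph()
        g.add_node(target, kind="target")
        if nodes is not None:
            for n in nodes:
                if n != target:
                    g.add_node(n, kind="metabolite")
        for a, b, r in edges:
            for n in (a, b):
                if n not in g:
                    g.add_node(n, kind="metabolite")
            g.add_edge(a, b, r=float(r), p=np.nan,
                       sign="negative" if r < 0 else "positive")
        return cls(g, target)


def _corr_and_p_matrix(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and two-sided p for the columns of ``M``."""
    n = M.shape[0]
    R = np.corrcoef(M, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(T), n - 2)
    P[np.abs(R) >= 1.0] = 0.0
    return R, P


def build_network(
    processed: ProcessedTable,
    selected,
    meta: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    target: str = DEFAULT_TARGET,
    target_values: pd.Series | None = None,
) -> TargetedNetwork:
    """Correlation network over ``selected`` features plus the target node.

    Metabolite-metabolite edges appear where the pairwise correlation has
    p < alpha; metabolite-target edges where the correlation with the
    subjects' continuous BMI (or ``target_values``) has p < alpha.  Constant
    features cannot be correlated and are kept as isolated nodes.
    """
    selected = list(selected)
    unknown = set(selected) - set(processed.feature_ids)
    if unknown:
        raise ValueError(f"selected features not in table: {sorted(unknown)[:5]}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    if target_values is None:
        target_values = meta.set_index("subject_id")["bmi_value"]
    tv = target_values.loc[processed.sample_ids].to_numpy(dtype=float)

    g = nx.Graph()
    g.add_node(target, kind="target")
    for fid in selected:
        g.add_node(fid, kind="metabolite")

    M = processed.data[selected].to_numpy(dtype=float)
    variable = M.std(axis=0) > 0
    if not variable.all():
        logger.warning(
            "%d constant feature(s) kept as isolated nodes", int((~variable).sum())
        )

    cols = [j for j in range(len(selected)) if variable[j]]
    if cols:
        R, P = _corr_and_p_matrix(M[:, cols])
        for ai in range(len(cols)):
            for bi in range(ai + 1, len(cols)):
                if P[ai, bi] < alpha:
                    r = R[ai, bi]
                    g.add_edge(
                        selected[cols[ai]], selected[cols[bi]],
                        r=float(r), p=float(P[ai, bi]),
                        sign="negative" if r < 0 else "positive",
                    )
        for ai in range(len(cols)):
            r, p = pearson_with_p(M[:, cols[ai]], tv)
            if p < alpha:
                g.add_edge(
                    selected[cols[ai]], target, r=r, p=p,
                    sign="negative" if r < 0 else "positive",
                )

    net = TargetedNetwork(g, target)
    if g.degree(target) == 0:
        logger.warning(
            "no metabolite is directly correlated with the target node; "
            "centrality will be zero outside the target"
        )
    return net


def assign_degrees_and_weights(net: TargetedNetwork) -> TargetedNetwork:
    """Breadth-first distances to the target, connection degrees, edge weights.

    degree(e) = 1 + min(dist(a), dist(b)); weight(e) = |r| * 0.5^(degree-1).
    Edges in components not containing the target get weight 0 and degree 0;
    unreachable nodes get distance -1.
    """
    g = net.graph
    dist = nx.single_source_shortest_path_length(g, net.target)
    for node in g.nodes:
        g.nodes[node]["distance"] = int(dist.get(node, -1))
    for a, b, data in g.edges(data=True):
        da, db = dist.get(a), dist.get(b)
        if da is None or db is None:
            data["degree"] = 0
            data["weight"] = 0.0
        else:
            degree = 1 + min(da, db)
            data["degree"] = int(degree)
            data["weight"] = abs(data["r"]) * PROXIMITY_FACTOR ** (degree - 1)
    return net


@dataclass
class CentralityRanking:
    """Eigenvector scores over all nodes plus the dominant eigenvalue.

    ``scores`` is L2-normalized over the target's connected component; nodes
    outside that component score exactly 0.
    """

    scores: pd.Series
    eigenvalue: float
    target: str
    n_iterations: int
    converged: bool

    def residual(self, net: TargetedNetwork) -> float:
        """||A x - lambda x||_2 on the target's component."""
        comp = sorted(
            nx.node_connected_component(net.graph, net.target), key=str
        )
        A = nx.to_numpy_array(net.graph, nodelist=comp, weight="weight")
        x = self.scores.loc[comp].to_numpy()
        return float(np.linalg.norm(A @ x - self.eigenvalue * x))


def eigenvector_centrality(
    net: TargetedNetwork,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> CentralityRanking:
    """Power iteration on the weighted adjacency of the target's component.

    Starts from the uniform positive vector, L2-normalizes each iterate, and
    stops when successive iterates differ by < ``tol`` in max-norm; the
    eigenvalue is the Rayleigh quotient.  The iteration cap is generous
    because convergence slows as the two leading eigenvalues approach each
    other.  If iteration still fails (possible for bipartite-like spectra
    where they coincide in magnitude), it restarts once on A + eps*I with
    eps = 0.1 * max weight, a diagonal shift that separates the magnitudes
    while preserving every eigenvector.
    """
    g = net.graph
    comp = sorted(nx.node_connected_component(g, net.target), key=str)
    scores = pd.Series(0.0, index=pd.Index(sorted(g.nodes, key=str)))

    A = nx.to_numpy_array(g, nodelist=comp, weight="weight")
    if len(comp) < 2 or A.max() == 0:
        logger.warning("degenerate network: target component has no weighted edges")
        scores.loc[net.target] = 1.0
        return CentralityRanking(scores, 0.0, net.target, 0, True)

    x, lam, iters, ok = _power_iteration(A, tol, max_iter)
    if not ok:
        eps = 0.1 * A.max()
        x, lam_shift, iters2, ok = _power_iteration(
            A + eps * np.eye(len(A)), tol, max_iter
        )
        lam = lam_shift - eps
        iters += iters2
        if not ok:
            resid = float(np.linalg.norm(A @ x - lam * x))
            raise RuntimeError(
                f"power iteration failed to converge in {max_iter} iterations "
                f"(residual {resid:.3e})"
            )
    scores.loc[comp] = np.abs(x)
    return CentralityRanking(scores, float(lam), net.target, iters, True)


def _power_iteration(A: np.ndarray, tol: float, max_iter: int):
    n = len(A)
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(1, max_iter + 1):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x, 0.0, it, True
        x_new = y / norm
        if np.max(np.abs(x_new - x)) < tol:
            lam = float(x_new @ A @ x_new)
            return x_new, lam, it, True
        x = x_new
    return x, float(x @ A @ x), max_iter, False


def rank_top_k(ranking: CentralityRanking, k: int = DEFAULT_TOP_K) -> list:
    """The k highest-scoring metabolite nodes (target excluded).

    Sorted by score descending, ties broken by node id ascending; returns
    all metabolites when fewer than k exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    metabolites = ranking.scores.drop(ranking.target)
    order = sorted(metabolites.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [node for node, _ in order[:k]]


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_graphml(
    net: TargetedNetwork, path: str | Path, ranking: CentralityRanking | None = None
) -> None:
    """GraphML export with node distance/score and edge r/p/sign/degree/weight."""
    g = net.graph.copy()
    if ranking is not None:
        for node in g.nodes:
            g.nodes[node]["score"] = float(ranking.scores.get(node, 0.0))
    for _, _, data in g.edges(data=True):
        if "p" in data and (data["p"] is None or np.isnan(data["p"])):
            data["p"] = -1.0  # GraphML has no NaN
    nx.write_graphml(g, str(path))


def edge_list(net: TargetedNetwork) -> pd.DataFrame:
    """Flat edge table: node_a, node_b, r, p, sign, degree, weight."""
    rows = []
    for a, b, data in sorted(
        net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
    ):
        rows.append(
            {
                "node_a": a, "node_b": b,
                "r": data.get("r"), "p": data.get("p"),
                "sign": data.get("sign"),
                "degree": data.get("degree"), "weight": data.get("weight"),
            }
        )
    return pd.DataFrame(
        rows, columns=["node_a", "node_b", "r", "p", "sign", "degree", "weight"]
    )


def ranking_table(
    ranking: CentralityRanking,
    k: int = DEFAULT_TOP_K,
    records: pd.DataFrame | None = None,
    sets=None,
) -> pd.DataFrame:
    """Top-k table (rank, node, score), optionally joined with ANOVA p-values
    and the feature's Venn-region category."""
    top = rank_top_k(ranking, k)
    rows = []
    for rank, node in enumerate(top, start=1):
        row = {"rank": rank, "node": node,
               "score": float(ranking.scores[node])}
        if records is not None and node in records.index:
            rec = records.loc[node]
            row["p_bmi"] = rec["p_bmi"]
            row["p_ipaq"] = rec["p_ipaq"]
            row["p_interaction"] = rec["p_interaction"]
        if sets is not None:
            row["venn_region"] = next(
                (name for name, members in sets.venn.items() if node in members),
                "none",
            )
        rows.append(row)
    return pd.DataFrame(rows)
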