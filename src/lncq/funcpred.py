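"""lncRNA function prediction by network propagation and enrichment.

A heterogeneous meta-network joins lncRNA and gene nodes through four edge
types: lncRNA-lncRNA transcriptional similarity, lncRNA-gene transcriptional
similarity, experimentally validated lncRNA-target edges, and gene-gene
protein-protein interactions.  From each lncRNA of interest a random walk
with restart is run to steady state — the score of a node is the stationary
probability of the walker visiting it — and the propagated gene scores are
fed to a gene set enrichment analysis whose null comes from random same-size
gene draws.  Gene sets with FDR < 0.1 are called the lncRNA's predicted
functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("lncq")

EDGE_TYPES = ("lnc_lnc_similarity", "lnc_gene_similarity", "validated_target", "ppi")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, universe, min_size: int, max_size: int) -> "GeneSetCollection":
        universe = set(universe)
        kept = {
            name: genes
            for name, genes in self.sets.items()
            if min_size <= len(set(genes) & universe) <= max_size
        }
        return GeneSetCollection(
            sets=kept,
            descriptions={k: self.descriptions.get(k, "") for k in kept},
        )

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *genes]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets, desc = {}, {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = parts[2:]
                desc[parts[0]] = parts[1]
        return cls(sets=sets, descriptions=desc)


# ---------------------------------------------------------------------------
# meta-network construction
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneousNetwork:
    """Typed undirected lncRNA-gene graph (a networkx Graph with node attr
    ``node_type`` in {lncRNA, gene} and edge attrs ``weight`` > 0 and
    ``edge_types``)."""

    graph: nx.Graph

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["node_type"] == node_type]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _spearman_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlations between the rows of x and the rows of y."""
    rx = np.apply_along_axis(stats.rankdata, 1, x)
    ry = np.apply_along_axis(stats.rankdata, 1, y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx_ = np.sqrt((rx**2).sum(axis=1))
    ny_ = np.sqrt((ry**2).sum(axis=1))
    nx_[nx_ == 0] = 1.0
    ny_[ny_ == 0] = 1.0
    return (rx @ ry.T) / np.outer(nx_, ny_)


def _add_edge(g: nx.Graph, a: str, b: str, weight: float, edge_type: str) -> None:
    # duplicate edges across types: keep max weight, record all types
    if g.has_edge(a, b):
        data = g.edges[a, b]
        data["weight"] = max(data["weight"], weight)
        if edge_type not in data["edge_types"]:
            data["edge_types"].append(edge_type)
    else:
        g.add_edge(a, b, weight=weight, edge_types=[edge_type])


def build_meta_network(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    target_edges: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    sim_threshold: float = 0.5,
) -> HeterogeneousNetwork:
    """Assemble the heterogeneous network from expression and edge lists.

    Similarity edges join node pairs whose expression profiles (over the
    shared sample columns) have ``|Spearman rho| >= sim_threshold``, weighted
    by |rho|; validated-target and PPI edges carry their listed weight
    (default 1).  Isolated nodes are retained, so the node count is always
    n_lnc + n_genes.
    """
    shared = [s for s in lnc_expr.columns if s in set(gene_expr.columns)]
    if not shared:
        raise ValueError("no overlapping samples between lncRNA and gene expression")
    lncs, genes = list(lnc_expr.index), list(gene_expr.index)
    if not lncs and not genes:
        raise ValueError("empty node set")
    g = nx.Graph()
    for n in lncs:
        g.add_node(n, node_type="lncRNA")
    for n in genes:
        g.add_node(n, node_type="gene")

    L = lnc_expr[shared].to_numpy(float)
    G = gene_expr[shared].to_numpy(float)
    ll = _spearman_matrix(L, L)
    for i in range(len(lncs)):
        for j in range(i + 1, len(lncs)):
            if abs(ll[i, j]) >= sim_threshold:
                _add_edge(g, lncs[i], lncs[j], abs(ll[i, j]), "lnc_lnc_similarity")
    lg = _spearman_matrix(L, G)
    for i in range(len(lncs)):
        for j in range(len(genes)):
            if abs(lg[i, j]) >= sim_threshold:
                _add_edge(g, lncs[i], genes[j], abs(lg[i, j]), "lnc_gene_similarity")

    for df, etype in ((target_edges, "validated_target"), (ppi_edges, "ppi")):
        for _, row in df.iterrows():
            a, b = str(row.iloc[0]), str(row.iloc[1])
            w = float(row.iloc[2]) if len(row) > 2 else 1.0
            if a not in g or b not in g:
                raise ValueError(f"edge endpoint not in node universe: {(a, b)}")
            if etype == "ppi":
                if {g.nodes[a]["node_type"], g.nodes[b]["node_type"]} != {"gene"}:
                    raise ValueError(f"PPI edge joins non-gene nodes: {(a, b)}")
            if w <= 0:
                raise ValueError(f"non-positive edge weight for {(a, b)}")
            _add_edge(g, a, b, w, etype)
    logger.info(
        "meta-network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges()
    )
    return HeterogeneousNetwork(graph=g)


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------


@dataclass
class PropagationScores:
    seeds: list[str]
    restart: float
    score: pd.Series  # node -> stationary probability, sums to 1
    iterations: int
    converged: bool


def rwr(
    network: HeterogeneousNetwork,
    seeds: list[str],
    r: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> PropagationScores:
    """Random walk with restart on the weighted network.

    Iterates ``p <- (1-r) W p + r e`` with W the column-normalized weighted
    adjacency and ``e`` uniform over the seeds; dangling (degree-0) nodes
    teleport back to ``e``.  Stops when the L1 change falls below ``tol``.
    """
    if not 0 < r <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    g = network.graph
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("empty network")
    index = {n: i for i, n in enumerate(nodes)}
    for s in seeds:
        if s not in index:
            raise ValueError(f"seed {s!r} not in network")
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    col_sums = A.sum(axis=0)
    dangling = col_sums == 0
    W = np.divide(A, col_sums, out=np.zeros_like(A), where=~dangling)
    e = np.zeros(len(nodes))
    for s in seeds:
        e[index[s]] = 1.0 / len(seeds)
    p = e.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dangling_mass = p[dangling].sum()
        p_new = (1.0 - r) * (W @ p + dangling_mass * e) + r * e
        delta = np.abs(p_new - p).sum()
        p = p_new
        if delta < tol:
            converged = True
            break
    return PropagationScores(
        seeds=list(seeds),
        restart=r,
        score=pd.Series(p, index=nodes),
        iterations=it,
        converged=converged,
    )


def rwr_direct(network: HeterogeneousNetwork, seeds: list[str], r: float = 0.5) -> pd.Series:
    """Closed-form stationary distribution ``p = r (I - (1-r) W')^-1 e`` with
    dangling columns replaced by ``e`` — the dense-solve counterpart of
    :func:`rwr` for cross-checking on small graphs."""
    g = network.graph
    nodes = list(g.nodes)
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    col_sums = A.sum(axis=0)
    dangling = col_sums == 0
    W = np.divide(A, col_sums, out=np.zeros_like(A), where=~dangling)
    e = np.zeros(len(nodes))
    for s in seeds:
        e[nodes.index(s)] = 1.0 / len(seeds)
    W[:, dangling] = e[:, None]
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1.0 - r) * W, e)
    return pd.Series(p, index=nodes)


# ---------------------------------------------------------------------------
# gene set enrichment on propagated scores
# ---------------------------------------------------------------------------


def rank_scores(gene_scores: pd.Series) -> pd.Series:
    """Sort descending by score with lexicographic gene-id tie-break."""
    df = pd.DataFrame({"score": gene_scores})
    df = df.sort_index().sort_values("score", ascending=False, kind="stable")
    return df["score"]


def gsea_es(
    gene_scores: pd.Series, gene_set, weight_exp: float = 1.0
) -> tuple[float, np.ndarray]:
    """Running-sum enrichment score over the ranked gene list.

    Hits increment by ``score**weight_exp`` normalized by the hit total;
    misses decrement by ``1/(N - n_set)``.  ES is the signed maximum
    deviation of the running sum from zero.
    """
    ranked = rank_scores(gene_scores)
    in_set = ranked.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("no gene of the set is in the scored universe")
    scores = ranked.to_numpy(float)
    n = len(scores)
    k = int(in_set.sum())
    weights = np.where(in_set, np.abs(scores) ** weight_exp, 0.0)
    total = weights.sum()
    if total == 0:  # all hit scores zero: fall back to equal hit weights
        weights = in_set.astype(float)
        total = float(k)
    steps = np.where(in_set, weights / total, -1.0 / (n - k) if n > k else 0.0)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    return float(es), running


def _es_from_positions(
    hit_pos: np.ndarray, weights: np.ndarray, n: int
) -> float:
    """ES evaluated only at hit positions (the running sum is piecewise
    linear between hits, so its extrema occur at hit boundaries)."""
    k = len(hit_pos)
    order = np.argsort(hit_pos)
    pos = hit_pos[order]
    w = weights[order]
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    cumw = np.cumsum(w) / total
    miss = 1.0 / (n - k) if n > k else 0.0
    misses_before = pos - np.arange(k)  # misses strictly before each hit
    after = cumw - misses_before * miss
    before = np.concatenate(([0.0], cumw[:-1])) - misses_before * miss
    es_pos = after.max()
    es_neg = min(before.min(), 0.0)
    return float(es_pos) if es_pos >= -es_neg else float(es_neg)


def gsea(
    gene_scores: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight_exp: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Permutation GSEA over non-negative gene scores.

    The null for each set is the ES of ``n_perm`` random same-size gene
    draws; NES divides ES by the mean |null ES| of matching sign; the nominal
    p is the matching-sign null tail fraction, and the FDR compares each NES
    against the pooled null NES distribution across all sets
    (Subramanian-style).  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = rank_scores(gene_scores)
    universe = list(ranked.index)
    n = len(universe)
    filtered = sets.filtered(universe, min_size, max_size)
    if not filtered.sets:
        raise ValueError("all gene sets filtered out by size bounds")
    rng = np.random.default_rng(seed)
    abs_scores = np.abs(ranked.to_numpy(float)) ** weight_exp

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name in sorted(filtered.sets):
        genes = set(filtered.sets[name]) & set(universe)
        k = len(genes)
        es, _ = gsea_es(ranked, genes, weight_exp)
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            pos = rng.choice(n, size=k, replace=False)
            null_es[i] = _es_from_positions(pos, abs_scores[pos], n)
        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        if es >= 0:
            denom = pos_null.mean() if len(pos_null) else np.nan
            p = (1 + (pos_null >= es).sum()) / (1 + len(pos_null)) if len(pos_null) else 1.0
        else:
            denom = np.abs(neg_null).mean() if len(neg_null) else np.nan
            p = (1 + (neg_null <= es).sum()) / (1 + len(neg_null)) if len(neg_null) else 1.0
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(
                null_es >= 0,
                null_es / (pos_null.mean() if len(pos_null) else np.nan),
                null_es / (np.abs(neg_null).mean() if len(neg_null) else np.nan),
            )
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        rows.append({"set": name, "size": k, "ES": es, "NES": nes, "p": float(p)})
    table = pd.DataFrame(rows).set_index("set")
    pool = np.concatenate(null_nes_pool)
    obs = table["NES"].to_numpy(float)
    fdr = np.empty(len(obs))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            null_frac_all = (pool >= 0).mean()
            null_frac = (pool >= nes).mean() / null_frac_all if null_frac_all else 1.0
            obs_pos = obs[np.isfinite(obs) & (obs >= 0)]
            obs_frac = (obs_pos >= nes).mean() if len(obs_pos) else 1.0
        else:
            null_frac_all = (pool < 0).mean()
            null_frac = (pool <= nes).mean() / null_frac_all if null_frac_all else 1.0
            obs_neg = obs[np.isfinite(obs) & (obs < 0)]
            obs_frac = (obs_neg <= nes).mean() if len(obs_neg) else 1.0
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    table["FDR"] = fdr
    table["significant"] = table["FDR"] < fdr_alpha
    return table


# ---------------------------------------------------------------------------
# end-to-end prediction
# ---------------------------------------------------------------------------


def predict_functions(
    network: HeterogeneousNetwork,
    seed_lncs: list[str],
    sets: GeneSetCollection,
    restart: float = 0.5,
    n_perm: int = 1000,
    weight_exp: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Per-lncRNA propagation + enrichment; long table keyed by (lncRNA, set).

    A seed disconnected from every gene yields a ``no prediction`` record
    rather than an exception.
    """
    lnc_nodes = set(network.nodes_of_type("lncRNA"))
    genes = network.nodes_of_type("gene")
    frames = []
    for lnc in seed_lncs:
        if lnc not in lnc_nodes:
            raise ValueError(f"seed {lnc!r} is not an lncRNA node")
        prop = rwr(network, [lnc], r=restart)
        gene_scores = prop.score.loc[genes]
        mass = gene_scores.sum()
        if mass <= 0:
            frames.append(
                pd.DataFrame(
                    [{"lncRNA": lnc, "set": "", "ES": np.nan, "NES": np.nan,
                      "p": np.nan, "FDR": np.nan, "significant": False,
                      "note": "no prediction (seed disconnected from genes)"}]
                )
            )
            continue
        gene_scores = gene_scores / mass
        table = gsea(
            gene_scores, sets, n_perm=n_perm, weight_exp=weight_exp, seed=seed,
            min_size=min_size, max_size=max_size, fdr_alpha=fdr_alpha,
        ).reset_index()
        table.insert(0, "lncRNA", lnc)
        table["note"] = ""
        frames.append(table[["lncRNA", "set", "ES", "NES", "p", "FDR",
                             "significant", "note"]])
    return pd.concat(frames, ignore_index=True)
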