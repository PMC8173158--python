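"""Aging-acceleration differential network construction and graph analysis.

For every candidate CpG pair, Pearson correlation and the first-order
partial correlation given the aging score are computed separately in the
disease group and the control-aged group.  Each group contributes one
"difference value" delta_g = r_g - pr_g (how much conditioning on the aging
score reshapes the pair's association).  An edge is retained when the two
deltas have opposite signs and the correlation statistics survive a
Benjamini-Hochberg FDR gate, yielding a network of pairs whose coupling to
the aging axis differs qualitatively between disease and control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation machinery
# ---------------------------------------------------------------------------

def pairwise_pearson(X) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r with two-sided p from the t-transform (n-2 df).

    Zero-variance columns yield NaN rows/columns (excluded downstream).
    """
    X = pd.DataFrame(X)
    n = len(X)
    if n < 4:
        raise ValueError("need at least 4 samples")
    M = X.to_numpy(dtype=float)
    sd = M.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(M, rowvar=False)
    dead = sd == 0
    if dead.any():
        logger.warning("%d zero-variance columns excluded from correlations", int(dead.sum()))
        r[dead, :] = np.nan
        r[:, dead] = np.nan
    np.fill_diagonal(r, 1.0)
    p = _r_to_p(r, df=n - 2)
    cols = X.columns
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rr) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rr), np.nan, p)
    np.fill_diagonal(p, 0.0)
    return p


def partial_correlation(X, z) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-order partial correlation of every pair given the score vector z.

        pr_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    with two-sided p from the t-transform on n-3 df.  Pairs where a member
    is perfectly correlated with z are undefined (NaN).
    """
    X = pd.DataFrame(X)
    zarr = np.asarray(z, dtype=float)
    n = len(X)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if zarr.std() == 0:
        raise ValueError("conditioning vector has zero variance")
    M = X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(M, rowvar=False)
        rz = np.array([_corr1(M[:, j], zarr) for j in range(M.shape[1])])
        denom = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
        pr = (r - np.outer(rz, rz)) / denom
    sat = np.abs(rz) >= 1.0 - 1e-12
    if sat.any():
        logger.warning("%d columns perfectly correlated with the score; pairs undefined", int(sat.sum()))
        pr[sat, :] = np.nan
        pr[:, sat] = np.nan
    np.fill_diagonal(pr, 1.0)
    p = _r_to_p(pr, df=n - 3)
    cols = X.columns
    return (
        pd.DataFrame(pr, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def _corr1(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (shared implementation).

    NaN entries propagate as NaN and do not enter the adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Pair statistics and the retention rule
# ---------------------------------------------------------------------------

def compute_pair_stats(
    X_ctrl, X_nd, z_ctrl, z_nd, sites: list[str] | None = None
) -> pd.DataFrame:
    """Per-pair correlation/partial-correlation statistics for both groups.

    BH adjustment runs per statistic family (four families) across all
    candidate pairs.  Returns one row per unordered pair with columns
    ``site_a, site_b, r_ctrl, r_nd, pr_ctrl, pr_nd``, the four ``q_*``
    values, and ``delta_ctrl = r_ctrl - pr_ctrl``, ``delta_nd = r_nd - pr_nd``.
    """
    X_ctrl = pd.DataFrame(X_ctrl)
    X_nd = pd.DataFrame(X_nd)
    if sites is not None:
        X_ctrl = X_ctrl[list(sites)]
        X_nd = X_nd[list(sites)]
    if list(X_ctrl.columns) != list(X_nd.columns):
        raise ValueError("control and disease matrices must share the same sites")
    cols = list(X_ctrl.columns)
    iu = np.triu_indices(len(cols), k=1)

    r_c, p_r_c = pairwise_pearson(X_ctrl)
    r_n, p_r_n = pairwise_pearson(X_nd)
    pr_c, p_pr_c = partial_correlation(X_ctrl, z_ctrl)
    pr_n, p_pr_n = partial_correlation(X_nd, z_nd)

    def flat(df: pd.DataFrame) -> np.ndarray:
        return df.to_numpy()[iu]

    frame = pd.DataFrame(
        {
            "site_a": np.asarray(cols)[iu[0]],
            "site_b": np.asarray(cols)[iu[1]],
            "r_ctrl": flat(r_c),
            "r_nd": flat(r_n),
            "pr_ctrl": flat(pr_c),
            "pr_nd": flat(pr_n),
            "q_r_ctrl": bh_fdr(flat(p_r_c)),
            "q_r_nd": bh_fdr(flat(p_r_n)),
            "q_pr_ctrl": bh_fdr(flat(p_pr_c)),
            "q_pr_nd": bh_fdr(flat(p_pr_n)),
        }
    )
    frame["delta_ctrl"] = frame["r_ctrl"] - frame["pr_ctrl"]
    frame["delta_nd"] = frame["r_nd"] - frame["pr_nd"]
    frame["min_q"] = frame[["q_r_ctrl", "q_r_nd", "q_pr_ctrl", "q_pr_nd"]].min(axis=1)
    return frame


@dataclass
class DifferentialNetwork:
    """Undirected CpG graph whose edges pass the differential retention rule."""

    graph: nx.Graph
    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def degree(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree), dtype=int).sort_index()

    @property
    def betweenness(self) -> pd.Series:
        return pd.Series(nx.betweenness_centrality(self.graph, normalized=False)).sort_index()

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_differential_network(
    pair_stats: pd.DataFrame,
    fdr_threshold: float = 0.1,
    rule: str = "per-group-delta",
    fdr_mode: str = "min",
    provenance: dict | None = None,
) -> DifferentialNetwork:
    """Retain pairs with opposite-signed difference values under the FDR gate.

    ``rule='per-group-delta'`` (default) opposes sign(delta_nd) to
    sign(delta_ctrl); ``rule='between-group'`` opposes the between-group
    change of r to that of pr.  ``fdr_mode`` gates on the minimum of the
    four adjusted p-values (``'min'``, inclusive default) or on all four
    (``'all'``).
    """
    s = pair_stats
    if rule == "per-group-delta":
        opposite = np.sign(s["delta_nd"]) * np.sign(s["delta_ctrl"]) < 0
    elif rule == "between-group":
        opposite = np.sign(s["r_nd"] - s["r_ctrl"]) * np.sign(s["pr_nd"] - s["pr_ctrl"]) < 0
    else:
        raise ValueError(f"unknown rule {rule!r}")
    qcols = ["q_r_ctrl", "q_r_nd", "q_pr_ctrl", "q_pr_nd"]
    if fdr_mode == "min":
        gate = s[qcols].min(axis=1) < fdr_threshold
    elif fdr_mode == "all":
        gate = (s[qcols] < fdr_threshold).all(axis=1)
    else:
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")
    keep = (opposite & gate).fillna(False)
    edges = s.loc[keep].copy()

    g = nx.Graph()
    for _, row in edges.iterrows():
        if row["site_a"] != row["site_b"]:
            g.add_edge(row["site_a"], row["site_b"])
    if g.number_of_edges() == 0:
        logger.warning("empty differential network; path analysis will be skipped")
    return DifferentialNetwork(graph=g, edges=edges, provenance=provenance or {})


# ---------------------------------------------------------------------------
# Network-level statistics
# ---------------------------------------------------------------------------

def power_law_check(network: DifferentialNetwork | nx.Graph) -> tuple[float, float]:
    """Least-squares slope and Pearson r of log10 P(degree) vs log10 degree."""
    g = network.graph if isinstance(network, DifferentialNetwork) else network
    degs = np.array([d for _, d in g.degree if d > 0])
    if degs.size == 0:
        raise ValueError("no positive-degree nodes")
    values, counts = np.unique(degs, return_counts=True)
    if values.size < 3:
        raise ValueError("fewer than 3 distinct degrees: power law not testable")
    if values.size < 10:
        logger.warning("only %d distinct degrees; power-law fit is weak", values.size)
    prob = counts / counts.sum()
    fit = stats.linregress(np.log10(values), np.log10(prob))
    return float(fit.slope), float(fit.rvalue)


def network_similarity_fisher(
    net_a: DifferentialNetwork,
    net_b: DifferentialNetwork,
    universe: list[tuple[str, str]],
) -> tuple[float, float]:
    """One-sided Fisher exact test for edge overlap over the candidate universe.

    Returns ``(odds_ratio, p)``; degenerate margins give p = 1 with a warning.
    """
    ea, eb = net_a.edge_set, net_b.edge_set
    uni = {tuple(sorted(u)) for u in universe}
    both = len(ea & eb & uni)
    only_a = len((ea & uni) - eb)
    only_b = len((eb & uni) - ea)
    neither = len(uni) - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]])
    if table[0].sum() == 0 or table[:, 0].sum() == 0:
        logger.warning("degenerate Fisher margins; returning p = 1")
        return np.nan, 1.0
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def shortest_paths(
    network: DifferentialNetwork | nx.Graph,
    sources: list[str],
    targets: list[str],
) -> dict[tuple[str, str], list[str]]:
    """One hop-count-shortest path per connected (source, target) pair.

    Edges are unweighted, so Dijkstra reduces to BFS; among equal-length
    paths the lexicographically smallest node sequence is returned, which
    makes the output deterministic.  Unreachable or absent pairs are
    omitted.
    """
    g = network.graph if isinstance(network, DifferentialNetwork) else network
    out: dict[tuple[str, str], list[str]] = {}
    for t in targets:
        if t not in g:
            continue
        dist = _bfs_distances(g, t)
        for sname in sources:
            if sname == t or sname not in g or sname not in dist:
                continue
            path = [sname]
            cur = sname
            while cur != t:
                nxt = min(n for n in g.neighbors(cur) if dist.get(n, -1) == dist[cur] - 1)
                path.append(nxt)
                cur = nxt
            out[(sname, t)] = path
    return out


def _bfs_distances(g: nx.Graph, source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def path_betweenness(
    paths: dict[tuple[str, str], list[str]], nodes=None
) -> pd.Series:
    """Count, per node, the source->target paths passing through it
    (interior positions only; endpoints do not count for their own path)."""
    counts: dict[str, int] = {}
    for (s, t), path in paths.items():
        for node in path[1:-1]:
            counts[node] = counts.get(node, 0) + 1
    if nodes is not None:
        return pd.Series({n: counts.get(n, 0) for n in nodes}, dtype=int).sort_index()
    return pd.Series(counts, dtype=int).sort_index()


def betweenness_permutation_test(
    network: DifferentialNetwork | nx.Graph,
    sources: list[str],
    targets: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Path-restricted betweenness with a marker-relabeling permutation p.

    The null redraws ``len(sources)`` source and ``len(targets)`` target
    labels uniformly (without replacement, disjointly) among network nodes
    ``n_perm`` times; p = (1 + #{perm betweenness >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    g = network.graph if isinstance(network, DifferentialNetwork) else network
    obs_paths = shortest_paths(g, sources, targets)
    obs = path_betweenness(obs_paths, nodes=sorted(g.nodes))

    rng = np.random.default_rng(seed)
    node_list = sorted(g.nodes)
    n_src = min(len(sources), len(node_list) // 2)
    n_tgt = min(len(targets), len(node_list) - n_src)
    exceed = pd.Series(0, index=obs.index, dtype=int)
    for _ in range(n_perm):
        draw = rng.choice(len(node_list), size=n_src + n_tgt, replace=False)
        ps = [node_list[i] for i in draw[:n_src]]
        pt = [node_list[i] for i in draw[n_src:]]
        perm_b = path_betweenness(shortest_paths(g, ps, pt), nodes=obs.index)
        exceed += (perm_b >= obs).astype(int)
    p = (1 + exceed) / (n_perm + 1)
    return pd.DataFrame({"betweenness": obs, "p": p})
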