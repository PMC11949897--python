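"""Co-occurrence networks, modules, Zi-Pi node roles and facilitator ranking.

The default edge-inference backend is a compositional correlation method:
counts get a 0.5 pseudocount, are closed to proportions and centered-log-ratio
transformed; Spearman correlation is computed per ASV pair; p-values come from
column-independent permutations and are Benjamini-Hochberg adjusted across all
pairs; edges with q <= q_max are kept with the signed correlation as weight.
Backends are pluggable through ``register_backend``.

Node roles follow the Zi-Pi convention: within-module degree z-score (Zi) and
among-module participation coefficient (Pi), with strict thresholds 2.5 / 0.62
separating network hubs, module hubs, connectors and peripherals. Community
detection and Zi-Pi use unweighted degrees over all edges regardless of sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AsvCountTable, SampleMetadata, TaxonomyTable

logger = logging.getLogger(__name__)


@dataclass
class CategoryDef:
    """A dataset category: which species/tissues feed one network."""

    name: str
    species: tuple[str, ...]
    tissues: tuple[str, ...]
    producer_plant: bool = True


@dataclass
class CoocNetwork:
    """Signed co-occurrence graph over ASVs for one category."""

    graph: nx.Graph
    category: str = ""

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-edge in network")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v,
             "weight": d.get("weight", 1.0), "q": d.get("q", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "q"])


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    modularity_Q: float

    def members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out


@dataclass
class NodeRole:
    node: str
    zi: float
    pi: float
    role: str = ""


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    modularity_Q: float
    avg_clustering: float
    null_Q_mean: float
    null_Q_sd: float
    null_clustering_mean: float
    null_clustering_sd: float
    n_random: int

    @property
    def z_modularity(self) -> float:
        return (self.modularity_Q - self.null_Q_mean) / self.null_Q_sd \
            if self.null_Q_sd > 0 else np.inf

    @property
    def z_clustering(self) -> float:
        return (self.avg_clustering - self.null_clustering_mean) / self.null_clustering_sd \
            if self.null_clustering_sd > 0 else np.inf


# ---------------------------------------------------------------------------
# category filtering


def filter_category_asvs(
    table: AsvCountTable,
    meta: SampleMetadata,
    category: CategoryDef,
    min_reads: int = 25,
) -> AsvCountTable:
    """Restrict to a category's samples, keeping ASVs with total reads > min_reads."""
    md = meta.table.loc[[s for s in table.counts.index if s in meta.table.index]]
    sel = md.index[
        md["species"].isin(category.species) & md["tissue"].isin(category.tissues)
    ]
    if len(sel) == 0:
        raise ValueError(f"category {category.name!r} selects no samples")
    sub = table.counts.loc[sel]
    keep = sub.sum(axis=0) > min_reads  # strict: "more than min_reads"
    sub = sub.loc[:, keep]
    empty = sub.sum(axis=1) == 0
    if empty.any():
        logger.warning("category %s: dropping %d sample(s) emptied by the read filter",
                       category.name, int(empty.sum()))
        sub = sub.loc[~empty]
    return AsvCountTable(sub.copy())


# ---------------------------------------------------------------------------
# inference backends


def clr_transform(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Pseudocount, closure and centered log-ratio per sample (row)."""
    x = counts.to_numpy(dtype=float) + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def _clr_spearman_perm(
    table: AsvCountTable,
    n_perm: int = 1000,
    q_max: float = 0.05,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> nx.Graph:
    counts = table.counts
    n, p = counts.shape
    if n < 8:
        raise ValueError("need at least 8 samples for network inference")
    if p < 2:
        raise ValueError("need at least 2 ASVs for network inference")
    clr = clr_transform(counts, pseudocount).to_numpy()
    # column-standardized ranks: pairwise Spearman via one matmul
    ranks = np.apply_along_axis(stats.rankdata, 0, clr)
    ranks -= ranks.mean(axis=0)
    norms = np.sqrt((ranks**2).sum(axis=0))
    norms[norms == 0] = 1.0
    ranks /= norms
    rho_obs = ranks.T @ ranks
    abs_obs = np.abs(rho_obs) - 1e-12
    rng = np.random.default_rng(seed)
    exceed = np.zeros((p, p), dtype=np.int64)
    for _ in range(n_perm):
        # independent row-permutation per column keeps marginals, breaks coupling
        order = np.argsort(rng.random((n, p)), axis=0)
        perm = np.take_along_axis(ranks, order, axis=0)
        exceed += np.abs(perm.T @ perm) >= abs_obs
    iu = np.triu_indices(p, k=1)
    pvals = (1.0 + exceed[iu]) / (n_perm + 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    g = nx.Graph()
    g.add_nodes_from(counts.columns)
    keep = qvals <= q_max
    for (i, j), q, rho in zip(
        zip(iu[0][keep], iu[1][keep]), qvals[keep], rho_obs[iu][keep]
    ):
        g.add_edge(counts.columns[i], counts.columns[j],
                   weight=float(rho), sign=1 if rho >= 0 else -1, q=float(q))
    return g


_BACKENDS = {"clr-spearman-perm": _clr_spearman_perm}


def register_backend(name: str, fn) -> None:
    """Register an alternative edge-inference backend."""
    _BACKENDS[name] = fn


def infer_network(
    table: AsvCountTable,
    method: str = "clr-spearman-perm",
    n_perm: int = 1000,
    q_max: float = 0.05,
    seed: int = 0,
    category: str = "",
    **kwargs,
) -> CoocNetwork:
    """Infer a signed co-occurrence network with the chosen backend."""
    if method not in _BACKENDS:
        raise ValueError(
            f"unknown method {method!r}; registered backends: {sorted(_BACKENDS)}"
        )
    graph = _BACKENDS[method](table, n_perm=n_perm, q_max=q_max, seed=seed, **kwargs)
    return CoocNetwork(graph=graph, category=category)


def annotate_nodes(
    net: CoocNetwork, taxonomy: TaxonomyTable | None = None, php_ids=frozenset()
) -> None:
    """Attach genus and PHP flags as node attributes (in place)."""
    php_ids = set(php_ids)
    for node in net.graph.nodes:
        genus = taxonomy.genus_of(node) if taxonomy is not None else ""
        net.graph.nodes[node]["genus"] = genus or "unclassified"
        net.graph.nodes[node]["php"] = node in php_ids


# ---------------------------------------------------------------------------
# modules and roles


def fast_greedy_modules(net: CoocNetwork) -> ModulePartition:
    """Clauset-Newman-Moore greedy modularity on the unweighted graph."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        return ModulePartition({n: i for i, n in enumerate(sorted(g.nodes))}, 0.0)
    communities = nx.community.greedy_modularity_communities(g, weight=None)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    assignment = {n: i for i, c in enumerate(communities) for n in c}
    q = nx.community.modularity(g, [set(c) for c in communities], weight=None)
    return ModulePartition(assignment, float(q))


def zi_pi(net: CoocNetwork, partition: ModulePartition) -> list[NodeRole]:
    """Within-module degree z-score and among-module participation per node."""
    g = net.graph
    missing = set(g.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    members = partition.members()
    # within-module degree of every node of every module
    kappa = {
        node: sum(
            1 for nb in g.neighbors(node)
            if partition.assignment[nb] == partition.assignment[node]
        )
        for node in g.nodes
    }
    mod_stats = {}
    for mod, nodes in members.items():
        vals = np.array([kappa[n] for n in nodes if n in g.nodes], dtype=float)
        mod_stats[mod] = (vals.mean(), vals.std(ddof=0)) if vals.size else (0.0, 0.0)
    roles = []
    for node in g.nodes:
        k = g.degree(node)
        if k == 0:
            roles.append(NodeRole(node, 0.0, 0.0))
            continue
        mean, sd = mod_stats[partition.assignment[node]]
        zi = (kappa[node] - mean) / sd if sd > 0 else 0.0
        per_module: dict[int, int] = {}
        for nb in g.neighbors(node):
            t = partition.assignment[nb]
            per_module[t] = per_module.get(t, 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        roles.append(NodeRole(node, float(zi), float(pi)))
    return roles


def classify_roles(
    roles: list[NodeRole], zi_thresh: float = 2.5, pi_thresh: float = 0.62
) -> list[NodeRole]:
    """Label each node; boundary values fall on the peripheral side."""
    out = []
    for r in roles:
        hi_z = r.zi > zi_thresh
        hi_p = r.pi > pi_thresh
        if hi_z and hi_p:
            role = "network_hub"
        elif hi_z:
            role = "module_hub"
        elif hi_p:
            role = "connector"
        else:
            role = "peripheral"
        out.append(NodeRole(r.node, r.zi, r.pi, role))
    return out


def roles_frame(roles: list[NodeRole]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"node": r.node, "zi": r.zi, "pi": r.pi, "role": r.role} for r in roles]
    ).set_index("node")


# ---------------------------------------------------------------------------
# comparisons and fits


def random_graph_baseline(net: CoocNetwork, R: int = 100, seed: int = 0) -> NetworkSummary:
    """Observed modularity/clustering against uniform G(n, m) random graphs."""
    if R < 1:
        raise ValueError("R must be >= 1")
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("edge count exceeds simple-graph maximum")
    part = fast_greedy_modules(net)
    obs_clust = nx.average_clustering(g) if n else 0.0
    rng = np.random.default_rng(seed)
    qs, cs = [], []
    for _ in range(R):
        rg = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        rnet = CoocNetwork(rg, category="random")
        qs.append(fast_greedy_modules(rnet).modularity_Q)
        cs.append(nx.average_clustering(rg) if n else 0.0)
    qs, cs = np.asarray(qs), np.asarray(cs)
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        modularity_Q=part.modularity_Q,
        avg_clustering=float(obs_clust),
        null_Q_mean=float(qs.mean()),
        null_Q_sd=float(qs.std(ddof=1)) if R > 1 else 0.0,
        null_clustering_mean=float(cs.mean()),
        null_clustering_sd=float(cs.std(ddof=1)) if R > 1 else 0.0,
        n_random=R,
    )


def degree_powerlaw_fit(net: CoocNetwork) -> dict[str, float | None]:
    """OLS of log10 degree frequency vs log10 degree; gamma = -slope."""
    degrees = np.array([d for _, d in net.graph.degree], dtype=int)
    degrees = degrees[degrees >= 1]
    if degrees.size == 0:
        return {"gamma": None, "R2": None}
    ks, freqs = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        return {"gamma": None, "R2": None}
    x = np.log10(ks.astype(float))
    y = np.log10(freqs.astype(float))
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return {"gamma": float(-slope), "R2": float(r**2)}


# ---------------------------------------------------------------------------
# facilitators


def facilitator_ranking(
    networks: dict[str, tuple[CoocNetwork, ModulePartition]],
    php_ids,
    taxonomy: TaxonomyTable,
    producer_networks,
    flag_min: int = 4,
) -> pd.DataFrame:
    """Rank genera by co-membership with PHP ASVs across networks.

    A module is PHP-containing iff at least one member is a PHP call; a genus
    supports facilitation in a network through the number of such modules
    holding at least one of its non-PHP members. Flagged: >= flag_min modules
    in at least one producer-plant network. Cautioned: support only in
    non-producer networks. Unclassified genera are reported but never flagged.
    """
    php_ids = set(php_ids)
    producer_networks = set(producer_networks)
    support: dict[str, dict[str, int]] = {}
    for label, (net, part) in networks.items():
        members = part.members()
        php_modules = [mod for mod, nodes in members.items() if nodes & php_ids]
        for mod in php_modules:
            genera_here = set()
            for node in members[mod]:
                if node in php_ids:
                    continue
                genus = taxonomy.genus_of(node) or "unclassified"
                genera_here.add(genus)
            for genus in genera_here:
                support.setdefault(genus, {}).setdefault(label, 0)
                support[genus][label] += 1
    rows = []
    for genus, per_net in sorted(support.items()):
        max_producer = max(
            (v for lab, v in per_net.items() if lab in producer_networks), default=0
        )
        any_producer = any(lab in producer_networks for lab in per_net)
        rows.append(
            {
                "genus": genus,
                "n_php_modules": max(per_net.values()),
                "networks_supporting": ",".join(sorted(per_net)),
                "flagged": genus != "unclassified" and max_producer >= flag_min,
                "cautioned": not any_producer,
            }
        )
    return pd.DataFrame(
        rows, columns=["genus", "n_php_modules", "networks_supporting", "flagged", "cautioned"]
    )


# ---------------------------------------------------------------------------
# export


def export_graph(
    net: CoocNetwork,
    path,
    partition: ModulePartition | None = None,
    roles: list[NodeRole] | None = None,
    fmt: str = "graphml",
) -> None:
    """Write the network with node/edge attributes (GraphML, GEXF or edge TSV)."""
    g = net.graph.copy()
    if partition is not None:
        nx.set_node_attributes(g, partition.assignment, "module")
    if roles is not None:
        for r in roles:
            if r.node in g.nodes:
                g.nodes[r.node]["zi"] = r.zi
                g.nodes[r.node]["pi"] = r.pi
                g.nodes[r.node]["role"] = r.role
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt in ("tsv", "edge-tsv"):
        net.edge_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r} (graphml, gexf, tsv)")
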