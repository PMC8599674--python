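"""Graph-theoretical analysis of binarized MC networks.

A weighted MC matrix is binarized at a sparsity threshold s — the fraction
of retained edges among all N(N-1)/2 possible ones — and characterized by
the five classical properties: nodal degree, clustering coefficient C,
characteristic path length L, network efficiency (global and local), and
small-worldness sigma against degree-preserving rewired null networks.
Because no automated rule fixes a single sparsity, networks are swept over
a range of thresholds (default 0.05 to 0.40 in steps of 0.02, yielding
0.05, 0.07, ..., 0.39).

Conventions (recorded in output metadata):
* edge count k = round-half-away-from-zero of s * N(N-1)/2; ties at the
  weight cutoff are broken by ascending (i, j) lexicographic index, which
  makes the sweep's edge sets nested across thresholds;
* L is averaged over connected node pairs only (GRETNA-compatible);
  efficiency handles disconnection natively via 1/inf = 0;
* sigma = (C/C_rand)/(L/L_rand) with null means over Maslov-Sneppen
  double-edge-swap rewirings (10 * |E| swaps per null, 100 nulls default);
  a degree sequence that cannot be rewired (e.g. a complete graph) keeps
  C_rand = C, L_rand = L so sigma = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import MCMatrix
from .exceptions import ConfigError

DEFAULT_SPARSITY_MIN = 0.05
DEFAULT_SPARSITY_MAX = 0.40
DEFAULT_SPARSITY_STEP = 0.02
DEFAULT_N_NULLS = 100
NULL_SWAP_FACTOR = 10


@dataclass
class BinaryNetwork:
    """Binarized MC network at one sparsity threshold."""

    roi_ids: list[int]
    adjacency: np.ndarray
    sparsity: float
    n_edges: int

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        n = len(self.roi_ids)
        if self.adjacency.shape != (n, n):
            raise ConfigError("adjacency shape does not match node count")
        if np.any(self.adjacency != self.adjacency.T):
            raise ConfigError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ConfigError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.roi_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g


@dataclass
class NetworkProperties:
    """The five graph properties at one sparsity threshold."""

    sparsity: float
    degree: np.ndarray
    clustering_coefficient: float | None = None
    characteristic_path_length: float | None = None
    global_efficiency: float | None = None
    local_efficiency: float | None = None
    small_worldness: float | None = None
    null_metadata: dict = field(default_factory=dict)


def _edge_count(sparsity: float, n_nodes: int) -> int:
    max_edges = n_nodes * (n_nodes - 1) // 2
    # round half away from zero (sparsity > 0 so plain floor(x + 0.5))
    return int(np.floor(sparsity * max_edges + 0.5))


def binarize_by_sparsity(mc: MCMatrix, sparsity: float) -> BinaryNetwork:
    """Keep the k strongest off-diagonal weights, k = round(s * N(N-1)/2).

    Ties at the cutoff are broken deterministically by ascending
    (row, column) index of the upper triangle, so edge sets are nested
    across increasing sparsity.
    """
    if not 0.0 < sparsity < 1.0:
        raise ConfigError(f"sparsity must be in (0, 1), got {sparsity}")
    n = mc.n_rois
    k = _edge_count(sparsity, n)
    if k == 0:
        warnings.warn(
            f"sparsity {sparsity} yields zero edges on {n} nodes", stacklevel=2
        )
    iu, ju = np.triu_indices(n, k=1)
    w = mc.values[iu, ju]
    # primary key: weight descending; then (i, j) ascending
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[keep], ju[keep]] = 1
    adj = np.maximum(adj, adj.T)
    return BinaryNetwork(roi_ids=list(mc.roi_ids), adjacency=adj,
                         sparsity=sparsity, n_edges=k)


def sparsity_thresholds(
    s_min: float = DEFAULT_SPARSITY_MIN,
    s_max: float = DEFAULT_SPARSITY_MAX,
    step: float = DEFAULT_SPARSITY_STEP,
) -> np.ndarray:
    """Inclusive arithmetic sequence s_min, s_min+step, ... <= s_max.

    The endpoint appears only if the sequence hits it exactly (within
    floating tolerance): the default range ends at 0.39 (18 thresholds).
    """
    if not s_min <= s_max:
        raise ConfigError("require s_min <= s_max")
    n_steps = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    return np.round(s_min + step * np.arange(n_steps), 10)


def degree(net: BinaryNetwork) -> np.ndarray:
    """Per-node degree: row sums of the adjacency."""
    return net.adjacency.sum(axis=1).astype(int)


def _require_graph(net: BinaryNetwork) -> nx.Graph:
    if net.n_nodes < 2:
        raise ConfigError("graph metrics need at least 2 nodes")
    return net.to_networkx()


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean Watts-Strogatz local clustering over all nodes."""
    return float(nx.average_clustering(_require_graph(net)))


def characteristic_path_length(net: BinaryNetwork) -> float:
    """Mean shortest-path length over *connected* node pairs.

    Returns inf when no pair is connected (edgeless graph).
    """
    g = _require_graph(net)
    total, count = 0.0, 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst > src:
                total += d
                count += 1
    return total / count if count else float("inf")


def efficiency(net: BinaryNetwork, scope: str = "global") -> float:
    """Network efficiency: mean inverse shortest-path length.

    ``global``: over all distinct pairs, with 1/inf = 0 for disconnected
    pairs. ``local``: mean over nodes of the global efficiency of each
    node's neighborhood subgraph.
    """
    g = _require_graph(net)
    if scope == "global":
        return float(nx.global_efficiency(g))
    if scope == "local":
        return float(nx.local_efficiency(g))
    raise ConfigError(f"efficiency scope must be 'global' or 'local', got {scope!r}")


def _rewired_null(g: nx.Graph, rng_seed: int) -> nx.Graph | None:
    """One Maslov-Sneppen degree-preserving rewiring; None if not rewireable."""
    n_edges = g.number_of_edges()
    if n_edges < 2:
        return None
    h = g.copy()
    try:
        nx.double_edge_swap(
            h,
            nswap=NULL_SWAP_FACTOR * n_edges,
            max_tries=100 * NULL_SWAP_FACTOR * n_edges + 100,
            seed=rng_seed,
        )
    except nx.NetworkXException:
        # covers both unswappable graphs and exhausted swap attempts
        return None
    return h


def small_worldness(
    net: BinaryNetwork,
    n_nulls: int = DEFAULT_N_NULLS,
    seed: int | None = None,
) -> tuple[float, dict]:
    """Small-worldness sigma = (C/C_rand) / (L/L_rand).

    C_rand and L_rand are means over ``n_nulls`` degree-preserving
    rewired networks whose seeds are derived deterministically from
    ``seed``. If the degree sequence cannot be rewired (complete graph,
    fewer than two edges) the nulls degenerate to the network itself and
    sigma = 1, with a note in the metadata.
    """
    if n_nulls < 1:
        raise ConfigError("n_nulls must be >= 1")
    c_obs = clustering_coefficient(net)
    l_obs = characteristic_path_length(net)
    g = net.to_networkx()
    child_seeds = np.random.SeedSequence(seed).spawn(n_nulls)
    c_rand_vals, l_rand_vals = [], []
    degenerate = 0
    for cs in child_seeds:
        null = _rewired_null(g, int(cs.generate_state(1)[0] % (2**31)))
        if null is None:
            degenerate += 1
            continue
        null_net = BinaryNetwork(
            roi_ids=net.roi_ids,
            adjacency=nx.to_numpy_array(null, dtype=np.int8),
            sparsity=net.sparsity,
            n_edges=net.n_edges,
        )
        c_rand_vals.append(clustering_coefficient(null_net))
        l_rand_vals.append(characteristic_path_length(null_net))
    meta = {"n_nulls": n_nulls, "seed": seed, "swap_factor": NULL_SWAP_FACTOR}
    if not c_rand_vals:
        meta["note"] = "degree sequence not rewireable; nulls identical to input"
        return 1.0, meta
    if degenerate:
        meta["n_failed_nulls"] = degenerate
    c_rand = float(np.mean(c_rand_vals))
    l_rand = float(np.mean(l_rand_vals))
    meta["c_rand"] = c_rand
    meta["l_rand"] = l_rand
    def _ratio(obs: float, rand: float) -> float:
        if rand > 0 and np.isfinite(rand):
            return obs / rand
        return 1.0 if obs == rand else float("inf")

    gamma = _ratio(c_obs, c_rand)
    lam = _ratio(l_obs, l_rand)
    sigma = gamma / lam if np.isfinite(lam) and lam > 0 else float("inf")
    return float(sigma), meta


def compute_properties(
    net: BinaryNetwork,
    n_nulls: int = 0,
    seed: int | None = None,
    include_global: bool = True,
) -> NetworkProperties:
    """All requested properties of one binarized network.

    ``n_nulls`` = 0 skips the (costly) small-worldness null ensemble;
    ``include_global`` = False computes degree only.
    """
    props = NetworkProperties(sparsity=net.sparsity, degree=degree(net))
    if include_global:
        props.clustering_coefficient = clustering_coefficient(net)
        props.characteristic_path_length = characteristic_path_length(net)
        props.global_efficiency = efficiency(net, "global")
        props.local_efficiency = efficiency(net, "local")
        if n_nulls > 0:
            sigma, meta = small_worldness(net, n_nulls=n_nulls, seed=seed)
            props.small_worldness = sigma
            props.null_metadata = meta
    return props


def sparsity_sweep(
    mc: MCMatrix,
    s_min: float = DEFAULT_SPARSITY_MIN,
    s_max: float = DEFAULT_SPARSITY_MAX,
    step: float = DEFAULT_SPARSITY_STEP,
    n_nulls: int = 0,
    seed: int | None = None,
    include_global: bool = True,
) -> list[tuple[float, BinaryNetwork, NetworkProperties]]:
    """Binarize and characterize one MC matrix over the sparsity range."""
    out = []
    for i, s in enumerate(sparsity_thresholds(s_min, s_max, step)):
        net = binarize_by_sparsity(mc, float(s))
        null_seed = None if seed is None else seed + i
        props = compute_properties(
            net, n_nulls=n_nulls, seed=null_seed, include_global=include_global
        )
        out.append((float(s), net, props))
    return out
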