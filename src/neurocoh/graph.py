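"""Global measures of weighted undirected networks.

Thirteen whole-network measures characterize a subject's coherence network:
size/connectivity (average degree, strength), distance-based integration
(characteristic path length, global efficiency, eccentricity, radius,
diameter), segregation (clustering coefficient, transitivity, local
efficiency, modularity), mixing (assortativity) and small-worldness against
degree-preserving random surrogates.

Conventions (configurable via :class:`GraphMetricConfig`):

* edge lengths are inverse weights, ``l_ij = 1 / w_ij`` (``-log w`` exposed
  as an option); absent edges have infinite length;
* disconnected pairs are excluded from the characteristic-path-length mean
  and contribute 0 to global efficiency;
* degree counts edges above a threshold ``tau`` (default 0.5, appropriate
  for dense coherence networks); strength sums all weights unthresholded;
* weighted clustering uses the geometric-mean (Onnela-type) triangle
  intensity; transitivity is total triangle intensity over total triplets;
* modularity is the weighted Newman-Girvan functional optimized by a seeded
  multi-restart Louvain heuristic;
* small-worldness sigma = (C / C_rand) / (L / L_rand) with the null built
  by Maslov-Sneppen degree-preserving rewiring of the suprathreshold
  topology, original weights shuffled onto the rewired edges.

All measures are deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "GraphMetricConfig",
    "GraphMeasures",
    "DegenerateGraphError",
    "validate_weights",
    "weights_to_lengths",
    "shortest_path_matrix",
    "path_measures",
    "degree_and_strength",
    "clustering_and_transitivity",
    "modularity_value",
    "modularity_louvain",
    "assortativity",
    "small_worldness",
    "compute_all",
    "MEASURE_NAMES",
]

MEASURE_NAMES = (
    "average_degree", "strength", "radius", "diameter", "eccentricity",
    "characteristic_path_length", "global_efficiency", "local_efficiency",
    "clustering_coefficient", "transitivity", "modularity", "assortativity",
    "small_worldness",
)


class DegenerateGraphError(ValueError):
    """A measure is undefined on this graph (e.g. zero variance)."""


@dataclass(frozen=True)
class GraphMetricConfig:
    """Conventions and null-model settings for the measure suite."""

    tau: float = 0.5                 # edge threshold for degree/topology
    distance: str = "inverse"        # "inverse" (1/w) or "log" (-log w)
    louvain_restarts: int = 10
    gamma: float = 1.0               # modularity resolution
    n_random: int = 10               # small-world surrogates
    rewires_per_edge: int = 10
    seed: int = 0
    on_degenerate: str = "nan"       # "nan" or "raise" for undefined measures

    def __post_init__(self) -> None:
        if not 0 <= self.tau < 1:
            raise ValueError("tau must lie in [0, 1)")
        if self.distance not in ("inverse", "log"):
            raise ValueError("distance must be 'inverse' or 'log'")
        if self.on_degenerate not in ("nan", "raise"):
            raise ValueError("on_degenerate must be 'nan' or 'raise'")


@dataclass
class GraphMeasures:
    """The 13 global measures for one network."""

    average_degree: float
    strength: float
    radius: float
    diameter: float
    eccentricity: float
    characteristic_path_length: float
    global_efficiency: float
    local_efficiency: float
    clustering_coefficient: float
    transitivity: float
    modularity: float
    assortativity: float
    small_worldness: float
    band: str = ""
    subject_id: str = ""
    group_label: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GraphMeasures":
        return cls(**d)


def validate_weights(W: np.ndarray, *, max_one: bool = False) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape != (n, n):
        raise ValueError("W must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    if W.min() < 0:
        raise ValueError("W must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    if max_one and W.max() > 1 + 1e-12:
        raise ValueError("weights must lie in [0, 1] for this measure")
    return W


def weights_to_lengths(W: np.ndarray, method: str = "inverse") -> np.ndarray:
    """Map connection weights to edge lengths (stronger = shorter).

    ``inverse``: l = 1/w; ``log``: l = -log(w) (requires w <= 1). Absent
    edges (w = 0) get infinite length; the diagonal stays zero.
    """
    W = validate_weights(W, max_one=(method == "log"))
    with np.errstate(divide="ignore"):
        if method == "inverse":
            L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
        elif method == "log":
            L = np.where(W > 0, -np.log(np.where(W > 0, W, 1.0)), np.inf)
        else:
            raise ValueError(f"unknown length mapping {method!r}")
    np.fill_diagonal(L, 0.0)
    return L


def shortest_path_matrix(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances (Floyd-Warshall on the lengths)."""
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if np.any(L < 0):
        raise ValueError("edge lengths must be non-negative")
    D = L.copy()
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        np.minimum(D, D[:, k:k + 1] + D[k:k + 1, :], out=D)
    return D


def path_measures(D: np.ndarray) -> dict[str, float]:
    """Distance-derived global measures from a shortest-path matrix.

    Returns characteristic path length (mean over finite off-diagonal
    distances), global efficiency (mean inverse distance, 0 for
    disconnected pairs), mean eccentricity, radius and diameter.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    if not finite.any():
        raise DegenerateGraphError("graph has no connected pairs")
    lchar = float(d[finite].mean())
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    eglob = float(inv.mean())
    ecc = np.max(np.where(off, D, -np.inf), axis=1)
    return {
        "characteristic_path_length": lchar,
        "global_efficiency": eglob,
        "eccentricity": float(ecc.mean()),
        "radius": float(ecc.min()),
        "diameter": float(ecc.max()),
    }


def degree_and_strength(W: np.ndarray, tau: float = 0.0) -> dict[str, float]:
    """Average binary degree above threshold ``tau`` and mean strength.

    Degree counts edges with w > tau; strength sums all weights
    (unthresholded).
    """
    W = validate_weights(W)
    if not 0 <= tau < 1:
        raise ValueError("tau must lie in [0, 1)")
    k = (W > tau).sum(axis=1)
    s = W.sum(axis=1)
    return {"average_degree": float(k.mean()), "strength": float(s.mean())}


def _triangle_terms(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node geometric-mean triangle intensity and triplet count."""
    cube = np.cbrt(W)
    tri = np.einsum("ij,jk,ki->i", cube, cube, cube)
    k = (W > 0).sum(axis=1)
    triplets = k * (k - 1)
    return tri, triplets


def _lengths_unchecked(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def _clustering_value(W: np.ndarray) -> float:
    tri, triplets = _triangle_terms(W)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_i = np.where(triplets > 0, tri / np.where(triplets > 0, triplets, 1), 0.0)
    return float(c_i.mean())


def _lchar_value(W: np.ndarray) -> float:
    D = shortest_path_matrix(_lengths_unchecked(W))
    off = ~np.eye(W.shape[0], dtype=bool)
    d = D[off]
    finite = np.isfinite(d)
    if not finite.any():
        raise DegenerateGraphError("graph has no connected pairs")
    return float(d[finite].mean())


def clustering_and_transitivity(W: np.ndarray) -> dict[str, float]:
    """Weighted clustering coefficient, transitivity and local efficiency.

    Clustering per node is the Onnela geometric-mean triangle intensity over
    its triplets, averaged over all nodes; transitivity pools triangles and
    triplets before dividing; local efficiency is the mean (over nodes with
    at least two neighbors) of the global efficiency of the neighborhood
    subgraph. Nodes with degree < 2 contribute 0 to all three. Weights must
    lie in [0, 1].
    """
    W = validate_weights(W, max_one=True)
    n = W.shape[0]
    tri, triplets = _triangle_terms(W)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_i = np.where(triplets > 0, tri / np.where(triplets > 0, triplets, 1), 0.0)
    clustering = float(c_i.mean())
    denom = triplets.sum()
    transitivity = float(tri.sum() / denom) if denom > 0 else 0.0

    eloc = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        if nbrs.size < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        D = shortest_path_matrix(_lengths_unchecked(sub))
        off = ~np.eye(nbrs.size, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1), 0.0)
        eloc += float(inv[off].mean())
    return {
        "clustering_coefficient": clustering,
        "transitivity": transitivity,
        "local_efficiency": eloc / n,
    }


def modularity_value(
    W: np.ndarray, partition: np.ndarray, gamma: float = 1.0
) -> float:
    """Weighted Newman-Girvan modularity of a given partition.

    Q = (1/2m) * sum_ij [w_ij - gamma * s_i s_j / (2m)] * [c_i == c_j],
    with s the node strengths and 2m the total weight.
    """
    W = np.asarray(W, dtype=float)
    partition = np.asarray(partition)
    two_m = W.sum()
    if two_m <= 0:
        raise DegenerateGraphError("modularity undefined for an all-zero graph")
    s = W.sum(axis=1)
    same = partition[:, None] == partition[None, :]
    return float(((W - gamma * np.outer(s, s) / two_m) * same).sum() / two_m)


def _louvain_local_moves(
    W: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One level of Louvain local moves on a graph that may carry self-loops.

    Starts from singleton communities, or from ``init`` when refining an
    existing partition.
    """
    n = W.shape[0]
    s = W.sum(axis=1)  # strengths including loops
    two_m = W.sum()
    comm = np.arange(n) if init is None else np.asarray(init).copy()
    sigma_tot = np.zeros(n)
    np.add.at(sigma_tot, comm, s)  # total strength per community
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            sigma_tot[ci] -= s[i]
            # links from i to each community (excluding the self-loop)
            w_i = W[i].copy()
            w_i[i] = 0.0
            k_i_to = np.zeros(n)
            np.add.at(k_i_to, comm, w_i)
            candidates = np.unique(comm[w_i > 0])
            best_c, best_gain = ci, 0.0
            base = k_i_to[ci] - gamma * s[i] * sigma_tot[ci] / two_m
            for c in candidates:
                gain = (k_i_to[c] - gamma * s[i] * sigma_tot[c] / two_m) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            comm[i] = best_c
            sigma_tot[best_c] += s[i]
            if best_c != ci:
                improved = True
    return comm


def _aggregate(W: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, inverse = np.unique(comm, return_inverse=True)
    k = labels.size
    M = np.zeros((k, k))
    np.add.at(M, (inverse[:, None], inverse[None, :]), W)
    return M, inverse


def modularity_louvain(
    W: np.ndarray,
    gamma: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Best-of-restarts Louvain community detection on a weighted graph.

    Runs the two-phase Louvain heuristic (local moves, then community
    aggregation, repeated to a fixed point) ``n_restarts`` times with
    seeded node orders and returns the partition with the highest weighted
    modularity Q, together with Q itself. Q is recomputed from the returned
    partition, so the pair is always self-consistent.
    """
    W = validate_weights(W)
    if W.sum() <= 0:
        raise DegenerateGraphError("modularity undefined for an all-zero graph")
    n = W.shape[0]
    best_q, best_part = -np.inf, np.arange(n)
    master = np.random.default_rng(seed)
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(2**31))
        # first restart from singletons (classic Louvain); later restarts
        # from random partitions to escape the singleton-start basin
        if restart == 0:
            init = None
        else:
            init = rng.integers(0, max(2, n // 2) + 1, size=n)
        assignment = _louvain_local_moves(W, gamma, rng, init=init)
        G, inverse = _aggregate(W, assignment)
        assignment = inverse[assignment]
        while True:
            comm = _louvain_local_moves(G, gamma, rng)
            no_merge = np.unique(comm).size == comm.size
            G, inverse = _aggregate(G, comm)
            assignment = inverse[assignment]
            if no_merge:
                break
        # refinement pass: single-node moves on the original graph starting
        # from the coarse partition, escaping aggregation lock-in
        assignment = _louvain_local_moves(W, gamma, rng, init=assignment)
        q = modularity_value(W, assignment, gamma)
        if q > best_q + 1e-15:
            best_q, best_part = q, assignment
    # canonical labels 0..k-1 in order of first appearance
    _, relabeled = np.unique(best_part, return_inverse=True)
    return best_q, relabeled


def assortativity(W: np.ndarray, tau: float = 0.0) -> float:
    """Strength assortativity: Pearson correlation of end-node strengths.

    Over both orientations of every edge with w > tau, correlates the
    strength of one end with the strength of the other. Raises
    :class:`DegenerateGraphError` when every edge end has the same strength
    (e.g. a complete unit-weight graph), where the correlation is undefined.
    """
    W = validate_weights(W)
    s = W.sum(axis=1)
    ii, jj = np.nonzero(np.triu(W > tau, k=1))
    if ii.size == 0:
        raise DegenerateGraphError("no edges above threshold")
    x = np.concatenate([s[ii], s[jj]])
    y = np.concatenate([s[jj], s[ii]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateGraphError(
            "assortativity undefined: zero variance of end-node strengths"
        )
    return float(np.corrcoef(x, y)[0, 1])


def _maslov_sneppen(
    adj: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> np.ndarray:
    """Degree-preserving edge swaps on a binary topology.

    Attempts up to 8x the requested number of swaps; a graph on which no
    legal swap exists (a complete graph in particular) is returned
    unchanged.
    """
    A = adj.copy()
    n = A.shape[0]
    edges = np.argwhere(np.triu(A, k=1))
    m = len(edges)
    if m < 2 or m == n * (n - 1) // 2:
        return A
    src = edges[:, 0].copy()
    dst = edges[:, 1].copy()
    done = attempts = 0
    max_attempts = 8 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        chunk = min(4096, max_attempts - attempts)
        e1 = rng.integers(m, size=chunk)
        e2 = rng.integers(m, size=chunk)
        flip = rng.random(chunk) < 0.5
        for t in range(chunk):
            attempts += 1
            i, j = e1[t], e2[t]
            if i == j:
                continue
            a, b = src[i], dst[i]
            c, d = (dst[j], src[j]) if flip[t] else (src[j], dst[j])
            # propose (a,b),(c,d) -> (a,d),(c,b)
            if a == c or a == d or b == c or b == d or A[a, d] or A[c, b]:
                continue
            A[a, b] = A[b, a] = False
            A[c, d] = A[d, c] = False
            A[a, d] = A[d, a] = True
            A[c, b] = A[b, c] = True
            src[i], dst[i] = (a, d) if a < d else (d, a)
            src[j], dst[j] = (c, b) if c < b else (b, c)
            done += 1
            if done >= n_swaps:
                break
    return A


def small_worldness(
    W: np.ndarray,
    n_random: int = 10,
    rewires_per_edge: int = 10,
    seed: int = 0,
    tau: float = 0.0,
    return_details: bool = False,
):
    """Small-world index sigma against degree-preserving random surrogates.

    sigma = (C / C_rand) / (L / L_rand), where C is the weighted clustering
    coefficient, L the characteristic path length, and the null values are
    means over ``n_random`` surrogates built by Maslov-Sneppen rewiring of
    the suprathreshold topology with the original edge weights shuffled
    onto the rewired edges. Deterministic given ``seed``. A complete graph
    admits no rewiring, so its surrogates equal the original and sigma = 1.
    """
    W = validate_weights(W, max_one=True)
    Wt = np.where(W > tau, W, 0.0)
    adj = Wt > 0
    weights = Wt[np.triu(adj, k=1)]
    if weights.size < 1:
        raise DegenerateGraphError("no edges above threshold for small-worldness")
    C = _clustering_value(Wt)
    L = _lchar_value(Wt)
    rng = np.random.default_rng(seed)
    n_edges = int(weights.size)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    surrogates = []
    for r in range(n_random):
        A = _maslov_sneppen(adj, rewires_per_edge * n_edges, rng)
        Wr = np.zeros_like(Wt)
        iu = np.where(np.triu(A, k=1))
        Wr[iu] = rng.permutation(weights)
        Wr = Wr + Wr.T
        surrogates.append(Wr)
        c_rand[r] = _clustering_value(Wr)
        l_rand[r] = _lchar_value(Wr)
    c_bar, l_bar = c_rand.mean(), l_rand.mean()
    if c_bar <= 0 or L <= 0 or not np.isfinite([c_bar, l_bar, C, L]).all():
        raise DegenerateGraphError("small-worldness undefined (degenerate null)")
    sigma = float((C / c_bar) / (L / l_bar))
    if return_details:
        return sigma, {
            "C": C, "L": L, "C_rand": c_rand, "L_rand": l_rand,
            "thresholded": Wt, "surrogates": surrogates,
        }
    return sigma


def compute_all(
    W: np.ndarray,
    config: GraphMetricConfig = GraphMetricConfig(),
    *,
    band: str = "",
    subject_id: str = "",
    group_label: str = "",
) -> GraphMeasures:
    """All 13 global measures of one weighted network.

    Component errors are re-raised with the measure name attached; an
    undefined assortativity or small-worldness becomes NaN when
    ``config.on_degenerate == "nan"``.
    """
    W = validate_weights(W, max_one=True)
    values: dict[str, float] = {}

    def run(name: str, fn):
        try:
            return fn()
        except DegenerateGraphError:
            if config.on_degenerate == "nan":
                return np.nan
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise type(exc)(f"{name}: {exc}") from exc

    values.update(degree_and_strength(W, config.tau))
    D = shortest_path_matrix(weights_to_lengths(W, config.distance))
    values.update(path_measures(D))
    values.update(clustering_and_transitivity(W))
    q, _ = modularity_louvain(
        W, gamma=config.gamma, n_restarts=config.louvain_restarts,
        seed=config.seed,
    )
    values["modularity"] = q
    values["assortativity"] = run(
        "assortativity", lambda: assortativity(W, config.tau))
    values["small_worldness"] = run(
        "small_worldness",
        lambda: small_worldness(
            W, n_random=config.n_random,
            rewires_per_edge=config.rewires_per_edge,
            seed=config.seed, tau=config.tau,
        ),
    )
    return GraphMeasures(
        band=band, subject_id=subject_id, group_label=group_label, **values
    )
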