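"""Topological metrics of a binary brain network.

Global: clustering coefficient Cp, characteristic path length Lp, global
and local efficiency, hierarchy coefficient β, modularity Q (γ and λ — the
small-world ratios — need a null ensemble and are filled in by
``nullmodels``). Nodal: degree, nodal efficiency, normalised betweenness.

Conventions (fixed across the package, recorded in every result):

* Lp is the mean shortest-path length over *connected* node pairs only;
  the fraction of disconnected pairs is reported alongside. Efficiency
  metrics handle disconnection natively (a disconnected pair contributes
  zero inverse distance).
* Nodes of degree < 2 contribute 0 (they are not excluded) to the Cp and
  Eloc averages, keeping the denominator at N across sparsity levels.
* Betweenness uses exact Brandes fractional counting, normalised by
  (N−1)(N−2)/2.
* The hierarchy fit C(k) ∝ k^−β bins nodes by degree (mean C per k),
  drops k < 2 and C = 0 points (log undefined), and reports the fit R²
  and point count; a per-node (unbinned) fit is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "ModulePartition",
    "HierarchyFit",
    "PathLengthResult",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "hierarchy_coefficient",
    "fit_hierarchy",
    "modularity_partition",
    "partition_modularity",
    "nodal_degree",
    "nodal_betweenness",
    "compute_all",
    "compute_global",
    "GLOBAL_METRIC_NAMES",
]

#: Ensemble-comparable global metrics (γ, λ derive from these + a null).
GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eglob", "Eloc", "beta", "Q")


class PathLengthResult(NamedTuple):
    lp: float
    frac_disconnected_pairs: float


class HierarchyFit(NamedTuple):
    beta: float
    r2: float
    n_points: int
    defined: bool


@dataclass
class GlobalMetrics:
    """The global metric set of one binary network."""

    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    beta: float
    Q: float
    gamma: float | None = None
    lam: float | None = None
    frac_disconnected_pairs: float = 0.0
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in GLOBAL_METRIC_NAMES}
        if self.gamma is not None:
            d["gamma"] = self.gamma
        if self.lam is not None:
            d["lambda"] = self.lam
        return d


@dataclass
class NodalMetrics:
    """Per-node degree k_i, efficiency E_i and normalised betweenness b_i."""

    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "efficiency": self.efficiency,
            "betweenness": self.betweenness,
        }


@dataclass
class ModulePartition:
    """A module assignment with its modularity and provenance."""

    labels: np.ndarray  # contiguous integers from 1
    Q: float
    method: str
    seed: int | None = None
    restart_qs: tuple[float, ...] = ()
    defined: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def _adj(g: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(g, BinaryNetwork):
        return g.adjacency.astype(float)
    return np.asarray(g, dtype=float)


def _distances(a: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf for disconnected)."""
    if a.sum() == 0:
        d = np.full(a.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def clustering_coefficient(g: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Watts–Strogatz clustering: per-node triangle density among
    neighbours, averaged over all N nodes (degree-<2 nodes contribute 0)."""
    a = _adj(g)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 × triangles per node ... (A³)_ii
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c.mean()) if c.size else float("nan"), c


def characteristic_path_length(g: BinaryNetwork | np.ndarray) -> PathLengthResult:
    """Mean shortest-path length over connected off-diagonal pairs."""
    d = _distances(_adj(g))
    n = d.shape[0]
    if n < 2:
        return PathLengthResult(float("nan"), 0.0)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_off = n * (n - 1)
    frac_disc = 1.0 - finite.sum() / n_off
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    return PathLengthResult(lp, float(frac_disc))


def nodal_efficiency(g: BinaryNetwork | np.ndarray) -> np.ndarray:
    """E_i = mean over j≠i of 1/d_ij, with 0 for disconnected pairs."""
    a = _adj(g)
    n = a.shape[0]
    if n < 2:
        return np.zeros(n)
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(g: BinaryNetwork | np.ndarray) -> float:
    """Latora–Marchiori global efficiency: mean of the nodal efficiencies."""
    e = nodal_efficiency(g)
    return float(e.mean()) if e.size else float("nan")


def local_efficiency(g: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (0 for nodes with fewer than 2 neighbours)."""
    a = _adj(g)
    n = a.shape[0]
    e = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        e[i] = global_efficiency(a[np.ix_(nbrs, nbrs)])
    return float(e.mean()) if n else float("nan"), e


def fit_hierarchy(k: np.ndarray, c: np.ndarray, bin_by_degree: bool = True) -> HierarchyFit:
    """Least-squares fit of log C against log k; β is the negative slope.

    Only nodes with k ≥ 2 and C > 0 enter; with ``bin_by_degree`` the mean
    C per distinct degree value is fitted (the standard Ravasz treatment).
    """
    k = np.asarray(k, dtype=float)
    c = np.asarray(c, dtype=float)
    use = (k >= 2) & (c > 0)
    k, c = k[use], c[use]
    if bin_by_degree and k.size:
        ks = np.unique(k)
        c = np.array([c[k == kv].mean() for kv in ks])
        k = ks
    if np.unique(k).size < 2:
        return HierarchyFit(float("nan"), float("nan"), int(k.size), False)
    x, y = np.log(k), np.log(c)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return HierarchyFit(float(-slope), r2, int(k.size), True)


def hierarchy_coefficient(
    g: BinaryNetwork | np.ndarray, bin_by_degree: bool = True
) -> HierarchyFit:
    """Hierarchy coefficient β from the degree–clustering scaling
    C(k) ∝ k^−β."""
    a = _adj(g)
    _, c = clustering_coefficient(a)
    k = a.sum(axis=1)
    return fit_hierarchy(k, c, bin_by_degree=bin_by_degree)


def partition_modularity(g: BinaryNetwork | np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = Σ_m [e_mm − a_m²] of a given labelling."""
    a = _adj(g)
    labels = np.asarray(labels)
    two_m = a.sum()
    if two_m == 0:
        return float("nan")
    q = 0.0
    for m in np.unique(labels):
        idx = labels == m
        e_mm = a[np.ix_(idx, idx)].sum() / two_m
        a_m = a[idx, :].sum() / two_m
        q += e_mm - a_m**2
    return float(q)


def _communities_to_labels(comms, n: int) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    # stable order: communities sorted by their smallest node
    for lab, comm in enumerate(sorted(map(sorted, comms)), start=1):
        labels[list(comm)] = lab
    return labels


def modularity_partition(
    g: BinaryNetwork | np.ndarray,
    method: str = "deterministic",
    seed: int = 0,
    n_restarts: int = 10,
) -> ModulePartition:
    """Maximise Newman modularity.

    ``deterministic`` uses seed-free greedy agglomeration
    (Clauset–Newman–Moore); ``multistart`` runs Louvain ``n_restarts``
    times from derived seeds and keeps the best Q, logging all restart Qs.
    The reported Q is always recomputed from the returned labels.
    """
    a = _adj(g)
    n = a.shape[0]
    if a.sum() == 0:
        return ModulePartition(
            labels=np.arange(1, n + 1), Q=float("nan"), method=method, defined=False
        )
    G = nx.from_numpy_array(a)
    if method == "deterministic":
        comms = nx.community.greedy_modularity_communities(G)
        labels = _communities_to_labels(comms, n)
        return ModulePartition(labels=labels, Q=partition_modularity(a, labels), method=method)
    if method == "multistart":
        best_labels, qs = None, []
        for r in range(n_restarts):
            comms = nx.community.louvain_communities(G, seed=seed + r)
            labels = _communities_to_labels(comms, n)
            q = partition_modularity(a, labels)
            qs.append(q)
            if best_labels is None or q > max(qs[:-1], default=-np.inf):
                best_labels = labels
        return ModulePartition(
            labels=best_labels, Q=max(qs), method=method, seed=seed, restart_qs=tuple(qs)
        )
    raise ValueError(f"unknown method {method!r}")


def nodal_degree(g: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _adj(g).sum(axis=1).astype(int)


def nodal_betweenness(g: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Exact shortest-path betweenness with fractional counting,
    normalised by (N−1)(N−2)/2."""
    a = _adj(g)
    G = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(G, normalized=True)
    return np.array([bc[i] for i in range(a.shape[0])])


def compute_global(
    g: BinaryNetwork | np.ndarray,
    include: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    modularity_method: str = "deterministic",
    seed: int = 0,
) -> GlobalMetrics:
    """All requested ensemble-comparable global metrics in one pass
    (shared distance matrix). γ and λ are left unset."""
    a = _adj(g)
    n = a.shape[0]
    k = a.sum(axis=1)
    flags: list[str] = []

    cp = eloc = lp = eg = beta = q = float("nan")
    frac_disc = 0.0
    c_nodes = None
    if "Cp" in include or "beta" in include:
        cp, c_nodes = clustering_coefficient(a)
    if "Lp" in include or "Eglob" in include:
        d = _distances(a)
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(d) & off
        frac_disc = float(1.0 - finite.sum() / (n * (n - 1))) if n > 1 else 0.0
        if frac_disc > 0:
            flags.append("disconnected")
        if "Lp" in include:
            lp = float(d[finite].mean()) if finite.any() else float("nan")
        if "Eglob" in include:
            with np.errstate(divide="ignore"):
                inv = 1.0 / d
            np.fill_diagonal(inv, 0.0)
            inv[~np.isfinite(inv)] = 0.0
            eg = float(inv.sum() / (n * (n - 1))) if n > 1 else float("nan")
    if "Eloc" in include:
        eloc, _ = local_efficiency(a)
    if "beta" in include:
        fit = fit_hierarchy(k, c_nodes)
        beta = fit.beta
        if not fit.defined:
            flags.append("hierarchy_undefined")
    if "Q" in include:
        part = modularity_partition(a, method=modularity_method, seed=seed)
        q = part.Q
        if not part.defined:
            flags.append("modularity_undefined")

    return GlobalMetrics(
        Cp=cp, Lp=lp, Eglob=eg, Eloc=eloc, beta=beta, Q=q,
        frac_disconnected_pairs=frac_disc, flags=tuple(flags),
    )


def compute_all(
    g: BinaryNetwork | np.ndarray,
    modularity_method: str = "deterministic",
    seed: int = 0,
) -> tuple[GlobalMetrics, NodalMetrics]:
    """Global metrics (without γ, λ) and the three nodal metrics."""
    gm = compute_global(g, modularity_method=modularity_method, seed=seed)
    nm = NodalMetrics(
        degree=nodal_degree(g),
        efficiency=nodal_efficiency(g),
        betweenness=nodal_betweenness(g),
    )
    return gm, nm
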