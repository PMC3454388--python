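"""Correlation matrices and sparsity-thresholded binary networks.

The functional connectome is built channel-wise: Pearson correlation
between every pair of hemoglobin time series, averaged across subjects,
then binarised by keeping the K = round(S·N(N−1)/2) strongest edges by
*absolute* correlation at each sparsity S on a 0.01-spaced grid. Edge sets
are nested along the grid by construction (top-K rule), and thresholding
is invariant to any per-channel positive rescaling of the time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .preprocess import HemoglobinTimeSeries

__all__ = [
    "CorrelationMatrix",
    "BinaryNetwork",
    "SparsityGrid",
    "correlation_matrix",
    "group_mean",
    "threshold_at_sparsity",
    "sparsity_sweep",
]


@dataclass
class CorrelationMatrix:
    """Symmetric channel × channel Pearson matrix with its node order."""

    values: np.ndarray
    channel_ids: list[str]
    level: str = "subject"  # "subject" | "group-mean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise ValueError("correlation entries must satisfy |r| <= 1")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != v.shape[0]:
            raise ValueError("channel_ids length does not match matrix size")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at one sparsity level.

    ``sparsity`` is the requested S; ``threshold`` the realised |r| cutoff
    (smallest retained absolute correlation, None for constructed toy
    graphs); ``K`` the edge count.
    """

    adjacency: np.ndarray
    sparsity: float
    threshold: float | None = None
    channel_ids: list[str] | None = None
    n_ties: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = (a != 0).astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, 0)
        self.adjacency = a
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i+1}" for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def K(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def max_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def realized_sparsity(self) -> float:
        return self.K / self.max_edges

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu] != 0
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity values, default 0.01 … 0.99 step 0.01."""

    values: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.01, 1.0, 0.01), 2))
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("grid must be a non-empty 1-d sequence")
        if np.any(np.diff(v) <= 0):
            raise ValueError("grid must be strictly increasing")
        if v[0] <= 0 or v[-1] >= 1:
            raise ValueError("grid values must lie in (0, 1)")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @classmethod
    def from_range(cls, start: float, stop: float, step: float = 0.01) -> "SparsityGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(tuple(np.round(start + step * np.arange(n), 10)))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def correlation_matrix(
    ts: HemoglobinTimeSeries | np.ndarray,
    contrast: str = "oxy",
    channel_ids: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation between every pair of channels.

    Accepts a :class:`HemoglobinTimeSeries` (``contrast`` selects the
    series) or a bare (n_channels, n_samples) array. A constant channel has
    undefined correlation and raises, naming the channel.
    """
    if isinstance(ts, HemoglobinTimeSeries):
        data = ts.contrast(contrast)
        ids = ts.channel_ids
    else:
        data = np.atleast_2d(np.asarray(ts, dtype=float))
        ids = list(channel_ids) if channel_ids is not None else [
            f"ch{i+1}" for i in range(data.shape[0])
        ]
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlation")
    sd = data.std(axis=1)
    # constant up to float cancellation error in the mean subtraction
    bad = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=1)))
    if bad.size:
        raise ValueError(
            f"constant channel(s) {[ids[i] for i in bad]}: correlation undefined"
        )
    r = np.corrcoef(data)
    return CorrelationMatrix(values=np.clip(r, -1.0, 1.0), channel_ids=ids, level="subject")


def group_mean(mats: Iterable[CorrelationMatrix]) -> CorrelationMatrix:
    """Elementwise arithmetic mean of subject correlation matrices.

    A Fisher-z averaged alternative would shrink less toward zero; the
    plain mean is the default convention here.
    """
    mats = list(mats)
    if not mats:
        raise ValueError("no matrices to average")
    ids = mats[0].channel_ids
    for m in mats[1:]:
        if m.channel_ids != ids:
            raise ValueError("channel order differs between matrices")
    mean = np.mean([m.values for m in mats], axis=0)
    return CorrelationMatrix(values=mean, channel_ids=ids, level="group-mean")


def _ranked_edges(mat: CorrelationMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs ordered by (−|r|, i, j): strongest first with a
    deterministic lexicographic tie-break."""
    n = mat.n_channels
    iu, ju = np.triu_indices(n, k=1)
    strength = np.abs(mat.values[iu, ju])
    order = np.lexsort((ju, iu, -strength))
    return iu[order], ju[order], strength[order]


def threshold_at_sparsity(mat: CorrelationMatrix, S: float) -> BinaryNetwork:
    """Binarise by keeping the K = round(S·N(N−1)/2) strongest |r| edges.

    The realised threshold T is the smallest retained |r|. Ties straddling
    rank K are resolved lexicographically on (i, j); the size of the tie
    group at the cut is recorded in ``n_ties``.
    """
    if not (0.0 < S < 1.0):
        raise ValueError("sparsity must lie in (0, 1)")
    n = mat.n_channels
    m = n * (n - 1) // 2
    K = int(round(S * m))
    iu, ju, strength = _ranked_edges(mat)
    adj = np.zeros((n, n), dtype=np.int8)
    if K > 0:
        adj[iu[:K], ju[:K]] = 1
        adj[ju[:K], iu[:K]] = 1
    T = float(strength[K - 1]) if K > 0 else float("inf")
    n_ties = int(np.sum(strength == T)) if K > 0 else 0
    n_ties = n_ties if n_ties > 1 else 0
    return BinaryNetwork(
        adjacency=adj, sparsity=float(S), threshold=T, channel_ids=mat.channel_ids,
        n_ties=n_ties,
    )


def sparsity_sweep(
    mat: CorrelationMatrix, grid: SparsityGrid | None = None
) -> list[BinaryNetwork]:
    """One binary network per grid value; edge sets nested along the grid."""
    grid = grid or SparsityGrid()
    n = mat.n_channels
    m = n * (n - 1) // 2
    iu, ju, strength = _ranked_edges(mat)
    nets = []
    adj = np.zeros((n, n), dtype=np.int8)
    k_prev = 0
    for S in grid:
        K = int(round(S * m))
        if K > k_prev:
            adj[iu[k_prev:K], ju[k_prev:K]] = 1
            adj[ju[k_prev:K], iu[k_prev:K]] = 1
            k_prev = K
        T = float(strength[K - 1]) if K > 0 else float("inf")
        n_ties = int(np.sum(strength == T)) if K > 0 else 0
        nets.append(
            BinaryNetwork(
                adjacency=adj.copy(), sparsity=float(S), threshold=T,
                channel_ids=mat.channel_ids, n_ties=n_ties if n_ties > 1 else 0,
            )
        )
    return nets
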