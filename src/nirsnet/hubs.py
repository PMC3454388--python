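"""Hub identification from nodal-metric curves over sparsity.

Each nodal metric (degree, nodal efficiency, betweenness) traced along the
sparsity grid is collapsed to a threshold-independent scalar — the
trapezoidal area under the curve — and a node is a hub candidate for a
metric when its AUC is at least one standard deviation above the network
mean (sample SD by default, "≥" at the boundary). The union set ("any one
metric"), the per-metric sets, and the three-metric consensus
(intersection) are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netbuild import SparsityGrid

__all__ = ["MetricCurve", "HubProfile", "curve_auc", "identify_hubs"]


@dataclass
class MetricCurve:
    """A metric traced along the sparsity grid.

    ``values`` has one row per grid point; for nodal metrics it is
    (n_grid, n_nodes), for global metrics (n_grid,). NaN marks flagged
    degenerate points.
    """

    grid: SparsityGrid
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.grid):
            raise ValueError("values length must match grid length")


def curve_auc(
    curve: MetricCurve, s_range: tuple[float, float] | None = None
) -> np.ndarray | float:
    """Trapezoidal area under the curve over the grid (or a sub-range).

    Degenerate (NaN) grid points are dropped before integration; the
    integral is then renormalised to the width of the requested range so
    that AUCs stay comparable across nodes with different flagged points.
    """
    s = curve.grid.as_array()
    v = curve.values
    if s_range is not None:
        keep = (s >= s_range[0] - 1e-12) & (s <= s_range[1] + 1e-12)
        s, v = s[keep], v[keep]
    if s.size < 2:
        raise ValueError("need at least 2 grid points to integrate")
    width = s[-1] - s[0]

    def _one(col: np.ndarray) -> float:
        ok = np.isfinite(col)
        if ok.sum() < 2:
            return float("nan")
        if ok.all():
            return float(np.trapezoid(col, s))
        su, cu = s[ok], col[ok]
        return float(np.trapezoid(cu, su) * width / (su[-1] - su[0]))

    if v.ndim == 1:
        return _one(v)
    return np.array([_one(v[:, j]) for j in range(v.shape[1])])


@dataclass
class HubProfile:
    """Per-metric AUCs, hub sets and the cross-metric consensus."""

    auc: dict[str, np.ndarray]  # metric -> per-node AUC
    hub_sets: dict[str, set[int]]  # metric -> hub node indices
    union: set[int]
    consensus: set[int]
    normalized: dict[str, np.ndarray] = field(default_factory=dict)  # auc / mean
    sd_zero: bool = False

    def is_hub(self, node: int) -> bool:
        return node in self.union


def identify_hubs(
    auc_by_metric: dict[str, np.ndarray], sd_ddof: int = 1
) -> HubProfile:
    """Apply the mean + 1 SD rule per metric and combine across metrics.

    ``sd_ddof=1`` (sample SD) is the default convention; 0 switches to the
    population SD. An all-equal metric (SD = 0) yields an empty hub set,
    flagged.
    """
    hub_sets: dict[str, set[int]] = {}
    normalized: dict[str, np.ndarray] = {}
    sd_zero = False
    for metric, auc in auc_by_metric.items():
        auc = np.asarray(auc, dtype=float)
        if auc.size < 3:
            raise ValueError("need at least 3 nodes to identify hubs")
        mean = np.nanmean(auc)
        sd = np.nanstd(auc, ddof=sd_ddof)
        normalized[metric] = auc / mean if mean != 0 else auc.copy()
        if sd == 0 or not np.isfinite(sd):
            hub_sets[metric] = set()
            sd_zero = True
        else:
            hub_sets[metric] = set(np.flatnonzero(auc >= mean + sd).tolist())
    sets = list(hub_sets.values())
    union = set().union(*sets) if sets else set()
    consensus = set.intersection(*sets) if sets else set()
    return HubProfile(
        auc={m: np.asarray(v, dtype=float) for m, v in auc_by_metric.items()},
        hub_sets=hub_sets,
        union=union,
        consensus=consensus,
        normalized=normalized,
        sd_zero=sd_zero,
    )
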