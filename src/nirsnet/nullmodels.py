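"""Degree-preserving null ensembles and z-score significance.

Each null replicate is produced by Maslov–Sneppen double-edge swaps:
pick two edges (a,b), (c,d), rewire to (a,d), (c,b), reject the move if it
would create a self-loop or duplicate edge. Degree sequences are preserved
exactly — this is a hard invariant, asserted per replicate. A metric x of
the real network is compared with the ensemble by
z = (x − μ_rand) / σ_rand, significant when |z| > 1.96 (two-tailed 0.05).
σ_rand is the population (n) standard deviation by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import GLOBAL_METRIC_NAMES, GlobalMetrics, compute_global
from .netbuild import BinaryNetwork

__all__ = [
    "NullEnsemble",
    "NullComparison",
    "rewire_preserving_degree",
    "build_ensemble",
    "compare",
    "normalized_smallworld",
    "significance_range",
    "SignificanceInterval",
]


@dataclass
class NullComparison:
    """One metric of the real network against its null ensemble."""

    metric: str
    x_real: float
    mu_rand: float
    sigma_rand: float
    z: float
    significant: bool
    sigma_zero: bool = False


@dataclass
class NullEnsemble:
    """Degree-matched random replicates of a source network, with their
    per-replicate global metrics."""

    source: BinaryNetwork
    n_random: int
    swap_factor: float
    seed: int
    samples: dict[str, np.ndarray]  # metric name -> (n_random,) values
    degenerate: bool = False  # no valid swap existed; replicates = source

    def mean(self, metric: str) -> float:
        x = self.samples[metric]
        x = x[np.isfinite(x)]
        return float(x.mean()) if x.size else float("nan")

    def std(self, metric: str, ddof: int = 0) -> float:
        x = self.samples[metric]
        x = x[np.isfinite(x)]
        return float(x.std(ddof=ddof)) if x.size > ddof else float("nan")


def rewire_preserving_degree(
    g: BinaryNetwork, swap_factor: float = 10.0, seed: int = 0
) -> tuple[BinaryNetwork, bool]:
    """One randomised replicate via double-edge swaps.

    Attempts ``swap_factor × K`` swaps (K = edge count), rejecting moves
    that would create self-loops or multi-edges. Returns (network,
    changed); a graph admitting no valid swap (e.g. a triangle) is
    returned unchanged with ``changed=False``.
    """
    edges = g.edges()
    K = len(edges)
    if K < 2:
        return g, False
    rng = np.random.default_rng(seed)
    adj = g.adjacency.copy()
    edges = [tuple(e) for e in edges]
    n_attempts = int(np.ceil(swap_factor * K))
    picks = rng.integers(0, K, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    changed = False
    for (i1, i2), flip in zip(picks, flips):
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if flip:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[i1] = (a, d)
        edges[i2] = (c, b)
        changed = True
    out = BinaryNetwork(
        adjacency=adj, sparsity=g.sparsity, threshold=None, channel_ids=g.channel_ids
    )
    assert np.array_equal(out.degree(), g.degree()), "degree sequence not preserved"
    return out, changed


def build_ensemble(
    g: BinaryNetwork,
    n_random: int = 1000,
    swap_factor: float = 10.0,
    seed: int = 0,
    include: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    modularity_method: str = "deterministic",
) -> NullEnsemble:
    """``n_random`` independent rewired replicates with derived seeds,
    scored by the requested global metrics."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_random)]
    samples: dict[str, list[float]] = {m: [] for m in include}
    any_changed = False
    for rs in rep_seeds:
        rep, changed = rewire_preserving_degree(g, swap_factor=swap_factor, seed=rs)
        any_changed = any_changed or changed
        gm = compute_global(rep, include=include, modularity_method=modularity_method)
        for m in include:
            samples[m].append(getattr(gm, m))
    return NullEnsemble(
        source=g,
        n_random=n_random,
        swap_factor=swap_factor,
        seed=seed,
        samples={m: np.asarray(v) for m, v in samples.items()},
        degenerate=not any_changed,
    )


def compare(
    x_real: float, ensemble: NullEnsemble, metric: str, ddof: int = 0
) -> NullComparison:
    """z-score of the real metric against the ensemble distribution."""
    mu = ensemble.mean(metric)
    sigma = ensemble.std(metric, ddof=ddof)
    if sigma == 0 or not np.isfinite(sigma):
        return NullComparison(
            metric=metric, x_real=x_real, mu_rand=mu, sigma_rand=sigma,
            z=float("nan"), significant=False, sigma_zero=True,
        )
    z = (x_real - mu) / sigma
    return NullComparison(
        metric=metric, x_real=x_real, mu_rand=mu, sigma_rand=sigma,
        z=float(z), significant=bool(abs(z) > 1.96),
    )


def normalized_smallworld(
    real: GlobalMetrics, ensemble: NullEnsemble, lam_tol: float = 0.1
) -> tuple[float, float, bool]:
    """Small-world ratios γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩, plus the
    verdict γ > 1 ∧ |λ − 1| ≤ ``lam_tol``."""
    cp_rand = ensemble.mean("Cp")
    lp_rand = ensemble.mean("Lp")
    gamma = real.Cp / cp_rand if cp_rand > 0 else float("nan")
    lam = real.Lp / lp_rand if lp_rand > 0 else float("nan")
    small_world = (
        np.isfinite(gamma) and np.isfinite(lam) and gamma > 1 and abs(lam - 1) <= lam_tol
    )
    return float(gamma), float(lam), bool(small_world)


@dataclass
class SignificanceInterval:
    """A maximal contiguous sparsity interval of significant z-scores."""

    s_lo: float
    s_hi: float
    mean_z: float
    n_points: int


def significance_range(
    s_values: np.ndarray, z_values: np.ndarray, z_crit: float = 1.96
) -> list[SignificanceInterval]:
    """Maximal contiguous grid intervals where |z| > z_crit, with the mean
    z over each interval (NaN z counts as non-significant)."""
    s = np.asarray(s_values, dtype=float)
    z = np.asarray(z_values, dtype=float)
    if s.shape != z.shape:
        raise ValueError("sparsity and z arrays must have the same length")
    sig = np.abs(z) > z_crit
    sig &= np.isfinite(z)
    out: list[SignificanceInterval] = []
    i = 0
    while i < len(s):
        if sig[i]:
            j = i
            while j + 1 < len(s) and sig[j + 1]:
                j += 1
            out.append(
                SignificanceInterval(
                    s_lo=float(s[i]), s_hi=float(s[j]),
                    mean_z=float(z[i : j + 1].mean()), n_points=j - i + 1,
                )
            )
            i = j + 1
        else:
            i += 1
    return out
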