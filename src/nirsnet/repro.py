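"""Split-half reproducibility and cross-contrast comparisons.

Two complementary splits probe the stability of the connectome: a
*by-subject* split into two independent subgroups (seeded balanced
randomisation; 15 subjects → 7 + 8) tests stability across participants,
and a *by-time* split of every subject's series into two contiguous
non-overlapping halves (12000 post-discard samples → 2 × 6000) tests
stability over time. Similarity is measured as the Pearson correlation of
the unique off-diagonal entries of the two group matrices, and as the
across-node correlation of nodal-metric profiles at each sparsity
(summarised mean ± SD over the grid).

Cross-contrast comparison: per-subject metric AUCs for oxy/deoxy/total-Hb
enter a one-way repeated-measures ANOVA (uncorrected F by default,
Greenhouse–Geisser available) with two-sided paired t-tests for the three
contrast pairs (raw p-values, with optional Bonferroni/FDR columns kept
clearly separate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .netbuild import CorrelationMatrix

__all__ = [
    "SplitDesign",
    "ContrastComparison",
    "split_by_subject",
    "split_by_time",
    "split",
    "matrix_similarity",
    "nodal_profile_correlation",
    "contrast_anova",
]

CONTRASTS = ("oxy", "deoxy", "total")


@dataclass(frozen=True)
class SplitDesign:
    """How a cohort is halved: mode 'by_subject' (seeded balanced random
    assignment) or 'by_time' (contiguous first/second half of samples)."""

    mode: str = "by_subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("by_subject", "by_time"):
            raise ValueError("mode must be 'by_subject' or 'by_time'")


def split_by_subject(items: Sequence, seed: int = 0) -> tuple[list, list]:
    """Seeded balanced random split; odd counts put the smaller half first
    (15 → 7 + 8). Halves are disjoint and exhaustive."""
    items = list(items)
    n = len(items)
    if n < 4:
        raise ValueError("need at least 4 subjects for a by-subject split")
    order = np.random.default_rng(seed).permutation(n)
    n1 = n // 2
    g1 = [items[i] for i in sorted(order[:n1])]
    g2 = [items[i] for i in sorted(order[n1:])]
    return g1, g2


def split_by_time(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second contiguous halves along the last (sample) axis."""
    x = np.asarray(series)
    n = x.shape[-1]
    if n % 2:
        raise ValueError("by-time split needs an even sample count")
    return x[..., : n // 2], x[..., n // 2 :]


def split(cohort: Sequence, design: SplitDesign):
    """Dispatch on the design mode.

    by_subject: ``cohort`` is a sequence of per-subject objects → two
    sub-cohorts. by_time: ``cohort`` is a sequence of per-subject arrays
    (..., n_samples) → two lists of half-length arrays, order preserved.
    """
    if design.mode == "by_subject":
        return split_by_subject(cohort, seed=design.seed)
    halves = [split_by_time(x) for x in cohort]
    return [h[0] for h in halves], [h[1] for h in halves]


def matrix_similarity(a: CorrelationMatrix, b: CorrelationMatrix) -> float:
    """Pearson r between the unique off-diagonal entries of two matrices."""
    if a.channel_ids != b.channel_ids:
        raise ValueError("matrices must share channel order")
    return float(np.corrcoef(a.upper_triangle(), b.upper_triangle())[0, 1])


def nodal_profile_correlation(
    values1: np.ndarray, values2: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Across-node Pearson r of two nodal profiles at each sparsity.

    ``values*`` are (n_grid, n_nodes). Returns (r per grid point, mean,
    SD over the grid); grid points where either half is constant across
    nodes (undefined r) are excluded from the summary as NaN.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("profiles must share grid and node dimensions")
    rs = np.full(v1.shape[0], np.nan)
    for i in range(v1.shape[0]):
        x, y = v1[i], v2[i]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            continue
        rs[i] = np.corrcoef(x[ok], y[ok])[0, 1]
    return rs, float(np.nanmean(rs)), float(np.nanstd(rs))


@dataclass
class ContrastComparison:
    """Repeated-measures comparison of per-subject AUCs across the three
    hemoglobin contrasts, for one metric."""

    metric: str
    f_stat: float
    p_value: float
    df: tuple[float, float]
    pairwise: pd.DataFrame  # columns: pair, t, p, p_bonferroni, p_fdr
    gg_corrected: bool = False


def _rm_anova(table: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """One-way repeated-measures F from a subjects × conditions table."""
    n, k = table.shape
    grand = table.mean()
    ss_cond = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else float("inf")
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), p, (df1, df2)


def contrast_anova(
    auc_table: pd.DataFrame, metric: str = "", gg_correct: bool = False
) -> ContrastComparison:
    """One-way repeated-measures ANOVA across contrasts plus post-hoc
    paired t-tests.

    ``auc_table``: one row per subject, columns exactly
    ('oxy', 'deoxy', 'total'); every cell must be present (repeated
    measures). Raw two-sided paired-t p-values are primary; Bonferroni and
    Benjamini–Hochberg columns are reported alongside.
    """
    missing = [c for c in CONTRASTS if c not in auc_table.columns]
    if missing:
        raise ValueError(f"missing contrast column(s): {missing}")
    tab = auc_table.loc[:, list(CONTRASTS)].to_numpy(dtype=float)
    if np.isnan(tab).any():
        raise ValueError("missing cells in the subject × contrast table")
    if tab.shape[0] < 3:
        raise ValueError("need at least 3 subjects")

    f, p, (df1, df2) = _rm_anova(tab)
    if gg_correct:
        eps = _greenhouse_geisser_epsilon(tab)
        p = float(stats.f.sf(f, eps * df1, eps * df2))
        df1, df2 = eps * df1, eps * df2

    rows = []
    pairs = [("oxy", "deoxy"), ("oxy", "total"), ("deoxy", "total")]
    for c1, c2 in pairs:
        x = auc_table[c1].to_numpy(dtype=float)
        y = auc_table[c2].to_numpy(dtype=float)
        if np.allclose(x, y):
            t, pv = 0.0, 1.0
        else:
            t, pv = stats.ttest_rel(x, y)
        rows.append({"pair": f"{c1}-{c2}", "t": float(t), "p": float(pv)})
    pw = pd.DataFrame(rows)
    pw["p_bonferroni"] = np.minimum(pw["p"] * len(pairs), 1.0)
    pw["p_fdr"] = _bh_fdr(pw["p"].to_numpy())
    return ContrastComparison(
        metric=metric, f_stat=f, p_value=p, df=(df1, df2), pairwise=pw,
        gg_corrected=gg_correct,
    )


def _greenhouse_geisser_epsilon(table: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity correction factor ε."""
    k = table.shape[1]
    s = np.cov(table, rowvar=False)
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj
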