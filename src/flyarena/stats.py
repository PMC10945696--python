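"""Rank-based screen statistics, implemented from first principles.

Genotype screens compare many driver lines to one empty-driver control with
small, non-normal per-line samples, so the global test is Kruskal-Wallis
(tie-corrected)

    H = [ 12/(N(N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2 ] / [ 1 - sum(t^3-t)/(N^3-N) ]

with mid-ranks for ties and a chi-square reference with k-1 degrees of
freedom, followed by Dunn's many-to-one post-test against the control:

    z_i = (Rbar_i - Rbar_c) / sqrt[ (N(N+1)/12 - sum(t^3-t)/(12(N-1))) * (1/n_i + 1/n_c) ]

with a two-sided normal p-value and (by default) Bonferroni adjustment over
the number of control comparisons.  Both tests depend on the data only
through ranks and are therefore invariant under strictly monotone
transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalResult",
    "StatResult",
    "midranks",
    "kruskal_wallis",
    "dunn_vs_control",
    "screen_stats",
    "stars",
]


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p_global: float


@dataclass(frozen=True)
class StatResult:
    H: float
    df: int
    p_global: float
    comparisons: pd.DataFrame  # group, n, mean_rank, z, p_uncorrected, p_adjusted


def midranks(values) -> np.ndarray:
    """Mid-ranks (ties averaged), 1-based."""
    a = np.asarray(values, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_sum(pooled: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _validate_groups(groups):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("empty group")
    if any(np.isnan(g).any() for g in gs):
        raise ValueError("NaN in group data")
    if sum(g.size for g in gs) < 3:
        raise ValueError("need total N >= 3")
    return gs


def kruskal_wallis(groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis test over a list of samples."""
    gs = _validate_groups(groups)
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = midranks(pooled)
    tie = _tie_sum(pooled)
    denom = 1.0 - tie / (N**3 - N)
    k = len(gs)
    if denom <= 0.0:  # all values identical across all groups
        return KruskalResult(H=0.0, df=k - 1, p_global=1.0)
    num = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        start += g.size
        num += g.size * (r.mean() - (N + 1) / 2.0) ** 2
    H = (12.0 / (N * (N + 1)) * num) / denom
    p = float(sps.chi2.sf(H, k - 1))
    return KruskalResult(H=float(H), df=k - 1, p_global=p)


def dunn_vs_control(
    groups,
    control_index: int = 0,
    adjust: str = "bonferroni",
    group_names=None,
) -> pd.DataFrame:
    """Dunn's many-to-one post-test of every group against the control.

    Ranks are pooled over all groups (empty groups dropped with a warning);
    ``adjust`` is ``bonferroni`` (multiply by the number of control
    comparisons, capped at 1) or ``none``.  Returns one row per non-control
    group: ``group, n, mean_rank, z, p_uncorrected, p_adjusted``; positive z
    means the group ranks above the control.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"adjust must be 'bonferroni' or 'none', got {adjust!r}")
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if group_names is None:
        group_names = list(range(len(gs)))
    if not gs[control_index].size:
        raise ValueError("control group is empty")
    keep = [i for i, g in enumerate(gs) if g.size > 0]
    if len(keep) < len(gs):
        dropped = [group_names[i] for i in range(len(gs)) if i not in keep]
        warnings.warn(f"empty group(s) excluded: {dropped}", stacklevel=2)
    gs = [gs[i] for i in keep]
    group_names = [group_names[i] for i in keep]
    control_index = keep.index(control_index)

    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = midranks(pooled)
    tie = _tie_sum(pooled)
    sigma2 = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    n_c = gs[control_index].size
    rbar_c = mean_ranks[control_index]
    m = len(gs) - 1  # number of many-to-one comparisons
    rows = []
    for i, g in enumerate(gs):
        if i == control_index:
            continue
        if sigma2 <= 0.0:
            z = 0.0
        else:
            se = np.sqrt(sigma2 * (1.0 / g.size + 1.0 / n_c))
            z = (mean_ranks[i] - rbar_c) / se
        p_unc = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_unc) if adjust == "bonferroni" else p_unc
        rows.append(
            {
                "group": group_names[i],
                "n": g.size,
                "mean_rank": float(mean_ranks[i]),
                "z": float(z),
                "p_uncorrected": p_unc,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows)


def screen_stats(
    groups,
    control_index: int = 0,
    adjust: str = "bonferroni",
    group_names=None,
) -> StatResult:
    """Kruskal-Wallis plus Dunn's many-to-one comparisons in one result.

    Both are always computed and reported; the post-test is not gated on the
    global test.
    """
    kw = kruskal_wallis(groups)
    comp = dunn_vs_control(groups, control_index, adjust, group_names)
    comp = comp.assign(stars=comp["p_adjusted"].map(stars))
    return StatResult(H=kw.H, df=kw.df, p_global=kw.p_global, comparisons=comp)


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
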