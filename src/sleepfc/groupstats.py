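"""Group-level inference on Fisher-z connectivity.

Edgewise and voxelwise two-sample comparisons use a two-tailed unpaired
t test on the subjects' Fisher-z values with Benjamini-Hochberg FDR
correction over the edge (or masked-voxel) family; one-sample group maps
test z against zero.  Also provides the significant-edge graph rendering
(line width proportional to the mean correlation difference, color class
by p band) and the small lesioned-vs-intact concentration-ratio utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix
from .core import State

__all__ = ["GroupComparisonResult", "edgewise_compare", "fdr_bh",
           "group_map_vs_zero", "voxelwise_compare", "build_edge_graph",
           "lesion_ratio"]

DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparisonResult:
    """Per-edge two-sample comparison of Fisher-z connectivity.

    ``table`` has one row per upper-triangle edge with columns
    roi_i, roi_j, mean_z_a, mean_z_b, diff (= mean_a - mean_b),
    t, p, q, significant.
    """

    table: pd.DataFrame
    roi_labels: list[str]
    state: State
    n_a: int
    n_b: int
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_edges(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].copy()


def fdr_bh(pvals: np.ndarray,
           alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (q values, reject flags).

    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / j; reject iff
    q <= alpha.  NaN p values are excluded from the family and returned
    as NaN q / non-rejected.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    if valid.sum() == 0:
        return q, reject
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, q_valid, *_ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
    q[valid] = q_valid
    reject[valid] = q_valid <= alpha
    return q, reject


def _two_sample_t(a: np.ndarray, b: np.ndarray,
                  welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed unpaired t along axis 0; zero pooled variance -> NaN."""
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # degenerate (zero-variance) cells are masked below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=not welch,
                              nan_policy="omit")
        scale = np.maximum(np.abs(np.nanmean(a, axis=0))
                           + np.abs(np.nanmean(b, axis=0)), 1.0)
        no_var = ((np.nanstd(a, axis=0) <= 1e-10 * scale)
                  & (np.nanstd(b, axis=0) <= 1e-10 * scale))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    t[no_var] = np.nan
    p[no_var | ~np.isfinite(t)] = np.nan
    return t, p


def edgewise_compare(group_a: list[ConnectivityMatrix],
                     group_b: list[ConnectivityMatrix],
                     alpha: float = DEFAULT_ALPHA,
                     welch: bool = False) -> GroupComparisonResult:
    """Edgewise two-sample t test with BH-FDR over all edges.

    Subjects' Fisher-z values are compared per upper-triangle edge with
    a pooled-variance Student t (Welch optional); p values are two-tailed
    and corrected over the full R(R-1)/2 edge family.  Edges with
    undefined variance are flagged and excluded from the FDR family.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    ref = group_a[0]
    for m in group_a + group_b:
        if m.roi_labels != ref.roi_labels:
            raise ValueError("ROI sets differ across subjects")
        if m.state is not ref.state:
            raise ValueError("states differ across subjects")
    r = len(ref.roi_labels)
    iu, ju = np.triu_indices(r, k=1)
    za = np.stack([m.z[iu, ju] for m in group_a])    # n_a x n_edges
    zb = np.stack([m.z[iu, ju] for m in group_b])
    t, p = _two_sample_t(za, zb, welch)
    if np.any(~np.isfinite(p)):
        warnings.warn("edges with undefined t excluded from the FDR "
                      "family", RuntimeWarning, stacklevel=2)
    q, reject = fdr_bh(p, alpha)
    mean_a = np.nanmean(za, axis=0)
    mean_b = np.nanmean(zb, axis=0)
    table = pd.DataFrame({
        "roi_i": [ref.roi_labels[i] for i in iu],
        "roi_j": [ref.roi_labels[j] for j in ju],
        "mean_z_a": mean_a,
        "mean_z_b": mean_b,
        "diff": mean_a - mean_b,
        "t": t,
        "p": p,
        "q": q,
        "significant": reject,
    })
    return GroupComparisonResult(table, list(ref.roi_labels), ref.state,
                                 n_a=len(group_a), n_b=len(group_b),
                                 alpha=alpha)


def group_map_vs_zero(maps: list[np.ndarray], mask: np.ndarray,
                      alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Voxelwise one-sample t of subject z maps against zero.

    BH-FDR is computed within the mask; the returned map holds the mean
    z where significant and NaN elsewhere (including outside the mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if len(maps) < 2:
        raise ValueError("need at least 2 subject maps")
    stack = np.stack([np.asarray(m, dtype=float)[mask] for m in maps])
    out = np.full(mask.shape, np.nan)
    if stack.shape[1] == 0:
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_1samp(stack, 0.0, axis=0, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(np.asarray(res.statistic, dtype=float))] = np.nan
    _, reject = fdr_bh(p, alpha)
    mean_z = np.nanmean(stack, axis=0)
    vals = np.full(stack.shape[1], np.nan)
    vals[reject] = mean_z[reject]
    out[mask] = vals
    return out


def voxelwise_compare(maps_a: list[np.ndarray], maps_b: list[np.ndarray],
                      mask: np.ndarray, alpha: float = DEFAULT_ALPHA,
                      welch: bool = False) -> np.ndarray:
    """Voxelwise two-sample difference map (mean_a - mean_b where
    significant after BH-FDR within the mask; NaN elsewhere)."""
    mask = np.asarray(mask, dtype=bool)
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("each group needs at least 2 subject maps")
    a = np.stack([np.asarray(m, dtype=float)[mask] for m in maps_a])
    b = np.stack([np.asarray(m, dtype=float)[mask] for m in maps_b])
    out = np.full(mask.shape, np.nan)
    if a.shape[1] == 0:
        return out
    _, p = _two_sample_t(a, b, welch)
    _, reject = fdr_bh(p, alpha)
    diff = np.nanmean(a, axis=0) - np.nanmean(b, axis=0)
    vals = np.full(a.shape[1], np.nan)
    vals[reject] = diff[reject]
    out[mask] = vals
    return out


def build_edge_graph(result: GroupComparisonResult,
                     width_range: tuple[float, float] = (1.0, 6.0),
                     strong_p: float = 0.01) -> nx.Graph:
    """Graph of significant edges, styled for rendering.

    Every ROI is a node; each significant edge carries ``diff``,
    ``width`` (linear in |diff|, mapped onto ``width_range``) and
    ``p_band`` / ``color`` ("strong"/red for p < ``strong_p``,
    "moderate"/yellow for p in [``strong_p``, alpha]).
    """
    g = nx.Graph(state=result.state.value, alpha=result.alpha)
    g.add_nodes_from(result.roi_labels)
    sig = result.significant_edges()
    if sig.empty:
        return g
    mags = sig["diff"].abs()
    lo, hi = width_range
    span = mags.max() - mags.min()
    for _, row in sig.iterrows():
        mag = abs(row["diff"])
        width = lo + (hi - lo) * ((mag - mags.min()) / span
                                  if span > 0 else 1.0)
        strong = row["p"] < strong_p
        g.add_edge(row["roi_i"], row["roi_j"],
                   diff=float(row["diff"]), p=float(row["p"]),
                   q=float(row["q"]), width=float(width),
                   p_band="p<0.01" if strong else "0.01-0.05",
                   color="red" if strong else "yellow")
    return g


def lesion_ratio(conc_lesioned: float,
                 conc_intact: float) -> tuple[float, float]:
    """Lesioned/intact concentration ratio and percent change.

    Returns ``(ratio, percent_change)`` with
    ``percent_change = 100 * (1 - ratio)``: positive for a depletion on
    the lesioned side, negative for an increase.
    """
    if conc_lesioned <= 0 or conc_intact <= 0:
        raise ValueError("concentrations must be positive")
    ratio = conc_lesioned / conc_intact
    return ratio, 100.0 * (1.0 - ratio)
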