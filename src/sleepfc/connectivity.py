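"""Nuisance-regressed partial correlation and windowed Fisher-z summaries.

"Partial correlation" here means the Pearson correlation of two series
after both are regressed on the nuisance design (the six motion
parameters plus an intercept) — not a full partial correlation
conditioning on the remaining ROIs.  State-resolved connectivity is
computed in non-overlapping 30-volume windows that lie entirely inside
one contiguous same-state run; each window's correlations are
variance-stabilized with Fisher's z = atanh(r) and averaged within the
subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (MotionParams, RoiTimeSeriesSet, State, StateLabels)

__all__ = ["Window", "WindowSet", "ConnectivityMatrix", "partial_corr",
           "partition_windows", "state_connectivity",
           "whole_scan_connectivity", "fisher_z", "seed_map",
           "R_CLIP", "DEFAULT_WINDOW"]

DEFAULT_WINDOW = 30
# |r| >= 1 (degenerate windows) is clipped here before atanh
R_CLIP = 0.999999
# residual SD below this fraction of the input scale counts as zero
_ZERO_RTOL = 1e-8
_TINY = 1e-300


@dataclass(frozen=True)
class Window:
    start: int
    length: int
    state: State


@dataclass
class WindowSet:
    """Non-overlapping fixed-length windows, each inside one state run."""

    windows: list[Window]
    width: int = DEFAULT_WINDOW

    def of_state(self, state: State) -> list[Window]:
        state = State(state)
        return [w for w in self.windows if w.state is state]

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class ConnectivityMatrix:
    """R x R Fisher-z matrix for one subject in one state."""

    z: np.ndarray
    roi_labels: list[str]
    state: State
    subject_id: str = ""
    n_windows_used: int = 0
    n_per_edge: np.ndarray | None = None   # windows contributing per edge

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        r = len(self.roi_labels)
        if self.z.shape != (r, r):
            raise ValueError("z matrix shape must match roi_labels")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.z.shape[0], k=1)
        return self.z[iu]


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing z = atanh(r).

    Values with |r| >= 1 (possible in degenerate windows) are clipped to
    +/-R_CLIP with a warning so the transform stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1.0):
        warnings.warn("correlation magnitude >= 1 clipped before atanh",
                      RuntimeWarning, stacklevel=2)
        arr = np.clip(arr, -R_CLIP, R_CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def _design(nuisance: np.ndarray | None, t: int) -> np.ndarray:
    """[intercept | nuisance] design matrix; warns on rank deficiency."""
    if nuisance is None or (hasattr(nuisance, "size") and nuisance.size == 0):
        return np.ones((t, 1))
    z = np.asarray(nuisance, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != t:
        raise ValueError(
            f"nuisance has {z.shape[0]} rows, series has {t}")
    d = np.column_stack([np.ones(t), z])
    if np.linalg.matrix_rank(d) < d.shape[1]:
        warnings.warn("rank-deficient nuisance design; dependent columns "
                      "contribute nothing to the projection",
                      RuntimeWarning, stacklevel=3)
    return d


def _residualize(x: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of x on the design."""
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def partial_corr(x: np.ndarray, y: np.ndarray,
                 nuisance: np.ndarray | None = None) -> float:
    """Correlation of x and y after projecting out [intercept | nuisance].

    With an empty nuisance set this is the plain Pearson correlation
    (the intercept only mean-centers).  A zero-variance residual makes
    the correlation undefined; NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    d = _design(nuisance, x.size)
    if x.size <= d.shape[1] + 2:
        raise ValueError(
            f"need T > p + 2 samples (T={x.size}, p={d.shape[1] - 1})")
    res = _residualize(np.column_stack([x, y]), d)
    sx = np.sqrt(res[:, 0] @ res[:, 0])
    sy = np.sqrt(res[:, 1] @ res[:, 1])
    # residuals that are numerically zero relative to the input scale
    tol_x = _ZERO_RTOL * max(np.linalg.norm(x - x.mean()), _TINY)
    tol_y = _ZERO_RTOL * max(np.linalg.norm(y - y.mean()), _TINY)
    if sx <= tol_x or sy <= tol_y:
        warnings.warn("zero-variance residual: partial correlation "
                      "undefined (NaN)", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.clip(res[:, 0] @ res[:, 1] / (sx * sy), -1.0, 1.0))


def partition_windows(labels: StateLabels,
                      width: int = DEFAULT_WINDOW) -> WindowSet:
    """Divide each maximal same-state run into floor(L/W) windows.

    Windows start at the run's first volume, do not overlap, and the
    remainder volumes at the end of each run are discarded.  Unlabeled
    stretches contribute no windows.
    """
    if width < 2:
        raise ValueError("window width must be at least 2 volumes")
    out: list[Window] = []
    for start, length, state in labels.runs():
        if state not in (State.REM_LIKE, State.NREM_LIKE):
            continue
        for k in range(length // width):
            out.append(Window(start + k * width, width, state))
    return WindowSet(out, width)


def _window_corr(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of the columns of one window.

    Residualizing every column on the shared design and correlating the
    residuals is equivalent to the pairwise partial correlation.
    Zero-variance residual columns yield NaN rows/columns.
    """
    res = _residualize(values, design)
    sd = np.sqrt(np.einsum("ij,ij->j", res, res))
    centered = values - values.mean(axis=0)
    scale = np.sqrt(np.einsum("ij,ij->j", centered, centered))
    good = sd > _ZERO_RTOL * np.maximum(scale, _TINY)
    corr = np.full((values.shape[1],) * 2, np.nan)
    if good.any():
        r = res[:, good] / sd[good]
        sub = np.clip(r.T @ r, -1.0, 1.0)
        corr[np.ix_(good, good)] = sub
    return corr


def state_connectivity(ts: RoiTimeSeriesSet, motion: MotionParams | None,
                       windows: WindowSet, state: State,
                       subject_id: str = "") -> ConnectivityMatrix:
    """Within-subject mean of per-window Fisher-z partial correlations.

    For each window of the requested state, partial correlations between
    all ROI pairs are computed on that window's rows (nuisance regressors
    subset to the same rows), z-transformed, then averaged across
    windows.  Degenerate (NaN) edges are excluded pairwise, with the
    contributing window count per edge recorded.
    """
    state = State(state)
    wins = (windows.of_state(state) if state is not State.WHOLE_SCAN
            else list(windows.windows))
    if not wins:
        raise ValueError(f"no windows of state {state.value}")
    r = ts.n_rois
    zsum = np.zeros((r, r))
    count = np.zeros((r, r), dtype=int)
    clipped = False
    for w in wins:
        sl = slice(w.start, w.start + w.length)
        if w.start + w.length > ts.n_volumes:
            raise ValueError("window extends past the end of the series")
        nuis = motion.values[sl] if motion is not None else None
        corr = _window_corr(ts.values[sl], _design(nuis, w.length))
        finite = np.isfinite(corr)
        off_diag = finite & ~np.eye(r, dtype=bool)
        if np.any(np.abs(corr[off_diag]) >= 1.0):
            clipped = True
        with np.errstate(invalid="ignore"):
            z = np.arctanh(np.clip(corr, -R_CLIP, R_CLIP))
        zsum[finite] += z[finite]
        count[finite] += 1
    if clipped:
        warnings.warn("|r| = 1 in at least one window; z clipped at "
                      f"atanh({R_CLIP})", RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore"):
        zmean = np.where(count > 0, zsum / np.maximum(count, 1), np.nan)
    np.fill_diagonal(zmean, np.nan)
    return ConnectivityMatrix(zmean, list(ts.roi_labels), state,
                              subject_id=subject_id,
                              n_windows_used=len(wins), n_per_edge=count)


def whole_scan_connectivity(ts: RoiTimeSeriesSet,
                            motion: MotionParams | None,
                            subject_id: str = "") -> ConnectivityMatrix:
    """Single-window connectivity over the entire scan (state-agnostic)."""
    windows = WindowSet([Window(0, ts.n_volumes, State.WHOLE_SCAN)],
                        width=ts.n_volumes)
    return state_connectivity(ts, motion, windows, State.WHOLE_SCAN,
                              subject_id=subject_id)


def seed_map(seed_series: np.ndarray, volume_4d: np.ndarray,
             motion: MotionParams | None, windows: WindowSet, state: State,
             mask: np.ndarray) -> np.ndarray:
    """Voxelwise windowed Fisher-z map of seed-to-voxel connectivity.

    The same windowed partial-correlation / Fisher-z / within-subject
    average as :func:`state_connectivity`, seed against every voxel in
    the mask.  Returns a 3-D map, NaN outside the mask.
    """
    state = State(state)
    volume_4d = np.asarray(volume_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume_4d.ndim != 4:
        raise ValueError("volume_4d must be 4-D")
    if mask.shape != volume_4d.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    seed = np.asarray(seed_series, dtype=float).ravel()
    if seed.size != volume_4d.shape[3]:
        raise ValueError("seed series length must equal the volume count")
    wins = (windows.of_state(state) if state is not State.WHOLE_SCAN
            else list(windows.windows))
    if not wins:
        raise ValueError(f"no windows of state {state.value}")
    vox = volume_4d[mask].T          # T x V
    v = vox.shape[1]
    zsum = np.zeros(v)
    count = np.zeros(v, dtype=int)
    clipped = False
    for w in wins:
        sl = slice(w.start, w.start + w.length)
        nuis = motion.values[sl] if motion is not None else None
        d = _design(nuis, w.length)
        res = _residualize(np.column_stack([seed[sl], vox[sl]]), d)
        s = res[:, 0]
        s_norm = np.sqrt(s @ s)
        v_norm = np.sqrt(np.einsum("ij,ij->j", res[:, 1:], res[:, 1:]))
        vc = vox[sl] - vox[sl].mean(axis=0)
        v_scale = np.sqrt(np.einsum("ij,ij->j", vc, vc))
        sc = seed[sl] - seed[sl].mean()
        good = ((v_norm > _ZERO_RTOL * np.maximum(v_scale, _TINY))
                & (s_norm > _ZERO_RTOL * max(np.linalg.norm(sc), _TINY)))
        r = np.full(v, np.nan)
        if s_norm > 0:
            r[good] = np.clip((s @ res[:, 1:][:, good])
                              / (s_norm * v_norm[good]), -1.0, 1.0)
        if np.any(np.abs(r[good]) >= 1.0):
            clipped = True
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
        zsum[good] += z[good]
        count[good] += 1
    if clipped:
        warnings.warn("|r| = 1 in at least one window; z clipped at "
                      f"atanh({R_CLIP})", RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore"):
        zmean = np.where(count > 0, zsum / np.maximum(count, 1), np.nan)
    out = np.full(mask.shape, np.nan)
    out[mask] = zmean
    return out
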