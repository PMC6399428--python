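"""Temporal and spatial conditioning of BOLD data.

The pipeline owns three conditioning steps: a 0.01-0.08 Hz zero-phase
Butterworth bandpass applied to each time series (removing drift and
high-frequency physiological noise), slice-wise 2-D Gaussian smoothing
with a 2-voxel FWHM in-plane kernel, and ROI time-series extraction as
the unweighted mean over each region's voxels.  Realignment and
coregistration happen upstream; their outputs (aligned volumes plus
six motion parameters) are inputs here.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfiltfilt

from .core import RoiTimeSeriesSet

__all__ = ["bandpass", "smooth_spatial", "extract_roi_timeseries",
           "FWHM_TO_SIGMA"]

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493

_FILTER_ORDER = 4


def bandpass(series: np.ndarray, tr_seconds: float,
             low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Zero-phase Butterworth bandpass of each column.

    Order-4 Butterworth applied forward-backward (``sosfiltfilt``), so the
    effective magnitude response is the squared filter response and the
    phase is zero.  DC is removed; the output has the input's length.
    """
    series = np.asarray(series, dtype=float)
    squeeze = series.ndim == 1
    if squeeze:
        series = series[:, None]
    if series.ndim != 2:
        raise ValueError("series must be 1-D or 2-D (time x channels)")
    nyquist = 0.5 / tr_seconds
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for TR={tr_seconds}s")
    sos = butter(_FILTER_ORDER, [low_hz, high_hz], btype="bandpass",
                 fs=1.0 / tr_seconds, output="sos")
    # sosfiltfilt pads by edge reflection; require enough samples
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series too short for the filter: {series.shape[0]} samples, "
            f"need more than {padlen}")
    out = sosfiltfilt(sos, series, axis=0)
    return out[:, 0] if squeeze else out


def smooth_spatial(volume: np.ndarray,
                   fwhm_voxels: float = 2.0) -> np.ndarray:
    """Slice-wise in-plane Gaussian smoothing.

    A 2-D Gaussian kernel with the given FWHM (in voxels) is applied to
    each axial slice of each volume; the through-slice axis is untouched,
    matching an in-plane "2 x 2 voxel" kernel on thick slices.  Edges use
    nearest-neighbor replication, so interior intensity sums are
    conserved.
    """
    if fwhm_voxels <= 0:
        raise ValueError("fwhm_voxels must be positive")
    volume = np.asarray(volume, dtype=float)
    if volume.ndim not in (2, 3, 4):
        raise ValueError("expected a 2-D slice, 3-D volume or 4-D series")
    sigma_inplane = fwhm_voxels * FWHM_TO_SIGMA
    sigma = [sigma_inplane, sigma_inplane] + [0.0] * (volume.ndim - 2)
    return gaussian_filter(volume, sigma=sigma, mode="nearest")


def extract_roi_timeseries(volume_4d: np.ndarray, label_map: np.ndarray,
                           roi_labels: list[str], tr_seconds: float,
                           label_codes: dict[str, int] | None = None,
                           ) -> RoiTimeSeriesSet:
    """Unweighted mean over each ROI's voxels, per volume.

    ``label_map`` holds integer codes on the same grid as the first three
    axes of ``volume_4d``; ``label_codes`` maps ROI name to code
    (default: position in ``roi_labels``, 1-based; 0 = background).
    """
    volume_4d = np.asarray(volume_4d)
    label_map = np.asarray(label_map)
    if volume_4d.ndim != 4:
        raise ValueError("volume_4d must be 4-D (x, y, z, time)")
    if label_map.shape != volume_4d.shape[:3]:
        raise ValueError("label map grid does not match the volume grid")
    if label_codes is None:
        label_codes = {name: i + 1 for i, name in enumerate(roi_labels)}
    t = volume_4d.shape[3]
    flat = volume_4d.reshape(-1, t)
    flat_map = label_map.reshape(-1)
    out = np.empty((t, len(roi_labels)))
    for j, name in enumerate(roi_labels):
        code = label_codes[name]
        idx = np.flatnonzero(flat_map == code)
        if idx.size == 0:
            raise ValueError(f"ROI {name!r} (code {code}) has no voxels")
        out[:, j] = flat[idx].mean(axis=0)
    return RoiTimeSeriesSet(out, tr_seconds, list(roi_labels))
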