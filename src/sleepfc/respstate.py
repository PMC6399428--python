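"""Breathing-rate estimation and sleep-like state segmentation.

Under urethane anesthesia, breathing rate is an indirect marker of the
alternating sleep-like brain states: the high-rate state is REM-like, the
low-rate state NREM-like.  This module estimates a per-volume breathing
rate from the raw respiration waveform, splits the rate distribution into
two clusters (an automated stand-in for the manual high-vs-low labeling
used with real recordings), and applies the cohort inclusion rules: a
subject enters the state-resolved analysis only if each state covers at
least 90 volumes and at least one state transition occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (BreathingRateSeries, NREM_CODE, REM_CODE,
                   RespirationTrace, State, StateLabels, UNLABELED_CODE)

__all__ = ["estimate_breathing_rate", "label_states", "apply_inclusion",
           "InclusionDecision", "MIN_VOLUMES_PER_STATE"]

# inclusion threshold: at least this many volumes in each state
MIN_VOLUMES_PER_STATE = 90


@dataclass
class InclusionDecision:
    """Whether a subject enters the state-resolved analysis, and why not."""

    included: bool
    reason: str
    volumes_rem: int
    volumes_nrem: int
    n_transitions: int


def estimate_breathing_rate(trace: RespirationTrace, tr_seconds: float,
                            n_volumes: int,
                            window_s: float = 30.0) -> BreathingRateSeries:
    """Per-volume breathing rate by peak counting in a centered window.

    Each BOLD volume gets the rate ``60 * n_peaks / window`` where peaks
    are breath maxima (prominence-based detection) inside a window of
    ``window_s`` seconds centered on the volume's midpoint; windows are
    truncated at the recording edges with proportional scaling.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    scan_dur = n_volumes * tr_seconds
    if trace.time_s[-1] < scan_dur - tr_seconds:
        raise ValueError(
            f"respiration trace ({trace.time_s[-1]:.1f} s) does not cover "
            f"the scan ({scan_dur:.1f} s)")
    sig = trace.signal
    span = sig.max() - sig.min()
    if span <= 0 or sig.std() == 0:
        raise ValueError("no breaths detected: respiration signal is flat")
    # breaths are < 300/min, so successive peaks are >= 0.2 s apart
    min_dist = max(1, int(0.2 * trace.sampling_rate_hz))
    peaks, _ = find_peaks(sig, prominence=0.3 * sig.std(),
                          distance=min_dist)
    if peaks.size == 0:
        raise ValueError("no breaths detected in respiration signal")
    peak_times = trace.time_s[peaks]
    slowest_period = 60.0 / max(1.0, 60.0 * peaks.size / trace.duration_s)
    if window_s < slowest_period:
        raise ValueError(
            f"window_s={window_s} shorter than one breath period "
            f"(~{slowest_period:.1f} s)")
    centers = (np.arange(n_volumes) + 0.5) * tr_seconds
    lo = np.clip(centers - window_s / 2.0, trace.time_s[0], None)
    hi = np.clip(centers + window_s / 2.0, None, trace.time_s[-1])
    counts = (np.searchsorted(peak_times, hi, side="right")
              - np.searchsorted(peak_times, lo, side="left"))
    width = hi - lo
    rates = 60.0 * counts / width
    return BreathingRateSeries(rates, tr_seconds, window_s)


def _two_means_1d(values: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Exact 1-D two-means: best threshold minimizing within-cluster SS.

    Returns (threshold, boolean high-cluster mask, pooled within SD).
    Deterministic: evaluates every split of the sorted values.
    """
    x = np.sort(values)
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)                  # low cluster sizes
    ss_lo = csq[k - 1] - csum[k - 1] ** 2 / k
    sum_hi = csum[-1] - csum[k - 1]
    ss_hi = (csq[-1] - csq[k - 1]) - sum_hi ** 2 / (n - k)
    total = ss_lo + ss_hi
    best = int(np.argmin(total))
    thresh = 0.5 * (x[best] + x[best + 1])
    mask_hi = values > thresh
    df = max(n - 2, 1)
    pooled_sd = float(np.sqrt(total[best] / df))
    return thresh, mask_hi, pooled_sd


def label_states(rates: BreathingRateSeries,
                 min_dwell_volumes: int = 15,
                 separation_factor: float = 3.0,
                 min_gap_bpm: float = 10.0,
                 single_state_ref_bpm: tuple[float, float] = (128.0, 100.0),
                 ) -> StateLabels:
    """Two-cluster split of the breathing-rate distribution.

    The higher-rate cluster is labeled REM-like.  Declaring two states
    requires the cluster-mean gap to exceed both ``separation_factor``
    times the pooled within-cluster SD and an absolute ``min_gap_bpm``.
    The relative threshold of 3.0 sits above the ~2.66 ratio that an
    optimal two-means split of a purely unimodal normal sample always
    attains; the absolute floor rejects splits driven by the
    breaths-per-window quantization of the rate estimate, which is far
    finer than the tens of breaths/min separating real high- and
    low-rate regimes.  A unimodal series instead gets the single state
    whose reference rate (``single_state_ref_bpm`` = (REM, NREM)) is
    nearer the overall mean.  Runs shorter than ``min_dwell_volumes``
    are merged into their neighbors to suppress flicker at transitions.
    """
    r = rates.rates_bpm
    n = r.size
    codes = np.empty(n, dtype=np.int8)

    def single_state() -> StateLabels:
        rem_ref, nrem_ref = single_state_ref_bpm
        mean = r.mean()
        codes[:] = (REM_CODE if abs(mean - rem_ref) <= abs(mean - nrem_ref)
                    else NREM_CODE)
        return StateLabels(codes, rates.tr_seconds)

    if n < 2 or np.ptp(r) == 0:
        return single_state()
    _, hi_mask, pooled_sd = _two_means_1d(r)
    if hi_mask.sum() == 0 or hi_mask.sum() == n:
        return single_state()
    gap = r[hi_mask].mean() - r[~hi_mask].mean()
    if gap <= min_gap_bpm:
        return single_state()
    if pooled_sd > 0 and gap <= separation_factor * pooled_sd:
        return single_state()
    codes[:] = np.where(hi_mask, REM_CODE, NREM_CODE)
    _merge_short_runs(codes, min_dwell_volumes)
    return StateLabels(codes, rates.tr_seconds)


def _merge_short_runs(codes: np.ndarray, min_len: int) -> None:
    """Iteratively absorb runs shorter than min_len into a neighbor.

    The shortest offending run (first on ties) flips to the longer
    adjacent run's state (first neighbor on ties); repeats until no run
    is short or a single run remains.
    """
    while True:
        runs = []
        start = 0
        for i in range(1, codes.size + 1):
            if i == codes.size or codes[i] != codes[start]:
                runs.append((start, i - start))
                start = i
        if len(runs) <= 1:
            return
        lengths = [ln for _, ln in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_len:
            return
        s, ln = runs[shortest]
        if shortest == 0:
            donor = runs[1]
        elif shortest == len(runs) - 1:
            donor = runs[shortest - 1]
        else:
            left, right = runs[shortest - 1], runs[shortest + 1]
            donor = left if left[1] >= right[1] else right
        codes[s:s + ln] = codes[donor[0]]


def apply_inclusion(labels: StateLabels,
                    min_volumes: int = MIN_VOLUMES_PER_STATE,
                    ) -> InclusionDecision:
    """State-resolved analysis inclusion rules.

    Included iff the subject shows at least one REM<->NREM transition and
    each state covers at least ``min_volumes`` volumes (>=, so exactly 90
    passes).  The reason string names the first failed rule.
    """
    v_rem = labels.count(State.REM_LIKE)
    v_nrem = labels.count(State.NREM_LIKE)
    n_trans = labels.n_transitions
    if n_trans < 1:
        return InclusionDecision(False, "no state transitions",
                                 v_rem, v_nrem, n_trans)
    for count, state in ((v_rem, "REM-like"), (v_nrem, "NREM-like")):
        if count < min_volumes:
            return InclusionDecision(
                False,
                f"{state} state has {count} volumes, fewer than the "
                f"required {min_volumes}",
                v_rem, v_nrem, n_trans)
    return InclusionDecision(True, "included", v_rem, v_nrem, n_trans)
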