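"""Synthetic rsfMRI cohorts with two alternating sleep-like states.

Under urethane anesthesia the rodent brain alternates between a REM-like
state (high breathing rate, strong thalamocortical coupling) and an
NREM-like state (low breathing rate, strong interhemispheric
corticocortical coupling).  This module simulates multi-subject cohorts
with that structure: per-volume latent states with configurable mean dwell
times, state-specific ROI correlation matrices, a quasi-periodic
respiration waveform whose instantaneous rate tracks the state, smooth
small-amplitude motion parameters, and an optional "lesion" group whose
REM-state correlations on selected edges are reduced by configured deltas.

Every downstream stage of the pipeline (state labeling, windowed partial
correlation, group statistics) is testable against the ground truth
carried by :class:`SyntheticSubject`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

from .core import (MotionParams, NREM_CODE, REM_CODE, RespirationTrace,
                   RoiTimeSeriesSet, State, StateLabels, state_to_code)

__all__ = [
    "SyntheticCohortConfig", "SyntheticSubject", "default_roi_labels",
    "default_state_correlations", "default_effect_edges",
    "generate_state_sequence", "generate_subject", "generate_voxel_subject",
    "generate_cohort", "apply_effect_edges", "check_correlation_matrix",
]

# 17-ROI atlas: 7 bilateral pairs plus 3 midline structures.
_BILATERAL = ["AC", "MC", "SC", "VC", "HC", "Str", "ThVL"]
_MIDLINE = ["mPFC", "CgC", "RC"]


def default_roi_labels() -> list[str]:
    """Bilateral AC/MC/SC/VC/HC/Str/ThVL plus midline mPFC/CgC/RC (17)."""
    labels = []
    for name in _BILATERAL:
        labels += [f"{name}_L", f"{name}_R"]
    return labels + list(_MIDLINE)


def _roi_class(label: str) -> tuple[str, str]:
    """(region, side) where side is 'L', 'R' or 'M' (midline)."""
    if label in _MIDLINE:
        return label, "M"
    region, side = label.rsplit("_", 1)
    return region, side


_CORTICAL = {"AC", "MC", "SC", "VC", "mPFC", "CgC", "RC"}


# Latent-factor loadings per state.  Sigma = B B^T + diag(1 - rowsums),
# which is positive definite by construction as long as every row of B has
# squared norm < 1.  Factors: one shared "cortical" factor, one factor per
# hemisphere, and one homotopic factor per bilateral region.  The numbers
# are chosen so that the thalamocortical and striato/hippocampo-cortical
# couplings are elevated in the REM-like state while interhemispheric
# corticocortical couplings (homotopic and heterotopic) are elevated in
# the NREM-like state.
_FACTOR_LOADINGS = {
    # state: (cortical-factor loading by structure, hemisphere loading,
    #         homotopic loading by region)
    State.REM_LIKE: (
        {"cortex": 0.47, "ThVL": 0.74, "Str": 0.74, "HC": 0.64},
        0.32,
        {"AC": 0.48, "MC": 0.48, "SC": 0.48, "VC": 0.48,
         "HC": 0.20, "Str": 0.0, "ThVL": 0.0},
    ),
    State.NREM_LIKE: (
        {"cortex": 0.55, "ThVL": 0.40, "Str": 0.46, "HC": 0.37},
        0.22,
        {"AC": 0.55, "MC": 0.55, "SC": 0.55, "VC": 0.55,
         "HC": 0.60, "Str": 0.54, "ThVL": 0.58},
    ),
}


def _factor_sigma(state: State) -> np.ndarray:
    labels = default_roi_labels()
    cort_load, hem_load, homo_load = _FACTOR_LOADINGS[state]
    factors = ["cortical", "left", "right"] + [f"homo_{r}"
                                               for r in _BILATERAL]
    b = np.zeros((len(labels), len(factors)))
    col = {f: k for k, f in enumerate(factors)}
    for i, lab in enumerate(labels):
        region, side = _roi_class(lab)
        key = region if region in cort_load else "cortex"
        b[i, col["cortical"]] = cort_load[key]
        if side == "L":
            b[i, col["left"]] = hem_load
        elif side == "R":
            b[i, col["right"]] = hem_load
        if region in homo_load:
            b[i, col[f"homo_{region}"]] = homo_load[region]
    sigma = b @ b.T
    resid = 1.0 - np.diag(sigma)
    if resid.min() <= 0:
        raise ValueError("factor loadings exceed unit variance")
    sigma = sigma + np.diag(resid)
    return (sigma + sigma.T) / 2.0


def default_state_correlations() -> tuple[np.ndarray, np.ndarray]:
    """Default (sigma_rem, sigma_nrem) for the 17-ROI atlas.

    REM-like: elevated thalamocortical (~0.45 same-side) and
    striato/hippocampo-cortical coupling.  NREM-like: elevated
    interhemispheric corticocortical coupling (homotopic ~0.60 vs ~0.45
    in REM).  Built from a latent-factor model so both are valid
    correlation matrices (unit diagonal, positive definite).
    """
    sigma_rem = _factor_sigma(State.REM_LIKE)
    sigma_nrem = _factor_sigma(State.NREM_LIKE)
    check_correlation_matrix(sigma_rem, "sigma_rem")
    check_correlation_matrix(sigma_nrem, "sigma_nrem")
    return sigma_rem, sigma_nrem


def default_effect_edges() -> list[tuple[str, str, float]]:
    """REM-state correlation decreases planted in the lesion group.

    Five corticocortical, striatocortical and corticohippocampal edges
    with deltas between 0.30 and 0.41 (subtracted from the control
    REM-state correlation).
    """
    return [
        ("MC_L", "MC_R", 0.41),
        ("Str_R", "MC_R", 0.38),
        ("HC_R", "CgC", 0.35),
        ("Str_L", "SC_L", 0.33),
        ("AC_L", "AC_R", 0.30),
    ]


def check_correlation_matrix(m: np.ndarray, name: str = "matrix") -> None:
    """Assert symmetry, unit diagonal and positive definiteness."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValueError(f"{name} does not have a unit diagonal")
    w = np.linalg.eigvalsh(m)
    if w.min() <= 1e-10:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {w.min():.3g})")


def apply_effect_edges(sigma: np.ndarray,
                       effect_edges: list[tuple[str, str, float]],
                       roi_labels: list[str],
                       max_projection_change: float = 0.01) -> np.ndarray:
    """Subtract deltas from correlation entries; keep the matrix valid.

    If the modified matrix loses positive definiteness it is projected to
    the nearest correlation matrix; a projection that moves any entry by
    more than ``max_projection_change`` aborts so that planted effects
    stay interpretable.
    """
    out = np.array(sigma, dtype=float, copy=True)
    index = {lab: i for i, lab in enumerate(roi_labels)}
    for a, b, delta in effect_edges:
        for lab in (a, b):
            if lab not in index:
                raise ValueError(f"effect edge names unknown ROI {lab!r}")
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"effect edge ({a}, {b}) is a diagonal entry")
        out[i, j] -= delta
        out[j, i] -= delta
        if abs(out[i, j]) >= 1.0:
            raise ValueError(
                f"effect delta {delta} on edge ({a}, {b}) leaves "
                f"correlation {out[i, j]:.3f} outside (-1, 1)")
    w = np.linalg.eigvalsh(out)
    if w.min() <= 1e-10:
        projected = corr_nearest(out, threshold=1e-8)
        change = np.max(np.abs(projected - out))
        if change > max_projection_change:
            worst = np.unravel_index(np.argmax(np.abs(projected - out)),
                                     out.shape)
            raise ValueError(
                "effect deltas break positive definiteness; nearest "
                f"correlation projection moves entry "
                f"({roi_labels[worst[0]]}, {roi_labels[worst[1]]}) by "
                f"{change:.4f} > {max_projection_change}")
        out = (projected + projected.T) / 2.0
        np.fill_diagonal(out, 1.0)
    check_correlation_matrix(out, "lesion REM correlation matrix")
    return out


@dataclass
class SyntheticCohortConfig:
    """Full generative specification of a synthetic cohort.

    Defaults mirror the acquisition and physiology the pipeline targets:
    TR 2 s, 1200 volumes (40 min), 17 ROIs, mean dwell times 99 s
    (REM-like) and 78.6 s (NREM-like), breathing ~128 vs ~100 breaths/min
    in the high- vs low-rate state, and five REM-only lesion effects with
    deltas 0.30-0.41.
    """

    n_control: int = 8
    n_lesion: int = 8
    n_volumes: int = 1200
    tr_seconds: float = 2.0
    n_rois: int = 17
    roi_labels: list[str] = field(default_factory=default_roi_labels)
    rem_mean_dwell_s: float = 99.0
    nrem_mean_dwell_s: float = 78.6
    min_dwell_volumes: int = 30        # dwell-time law truncated below here
    sigma_rem: np.ndarray | None = None
    sigma_nrem: np.ndarray | None = None
    effect_edges: list[tuple[str, str, float]] = field(
        default_factory=default_effect_edges)
    rem_breath_rate_bpm: float = 128.0
    nrem_breath_rate_bpm: float = 100.0
    breath_rate_jitter_bpm: float = 4.0   # per-subject offset SD
    breath_rate_wander_bpm: float = 2.0   # slow within-scan drift SD
    resp_sampling_hz: float = 50.0
    ar_coef: float = 0.3                  # AR(1) temporal smoothing
    bold_baseline: float = 100.0
    bold_amplitude: float = 1.0
    noise_sd: float = 0.5                 # voxel-level noise (voxel fixtures)
    motion_sd: float = 0.05               # SD of each motion regressor
    single_state_fraction: float = 0.0    # P(subject never transitions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rem is None or self.sigma_nrem is None:
            if self.n_rois != 17 or self.roi_labels != default_roi_labels():
                raise ValueError(
                    "sigma_rem/sigma_nrem must be supplied for a non-default "
                    "ROI set")
            self.sigma_rem, self.sigma_nrem = default_state_correlations()
        self.sigma_rem = np.asarray(self.sigma_rem, dtype=float)
        self.sigma_nrem = np.asarray(self.sigma_nrem, dtype=float)
        if len(self.roi_labels) != self.n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        if self.sigma_rem.shape != (self.n_rois, self.n_rois):
            raise ValueError("sigma_rem shape must be (n_rois, n_rois)")
        if self.sigma_nrem.shape != (self.n_rois, self.n_rois):
            raise ValueError("sigma_nrem shape must be (n_rois, n_rois)")
        check_correlation_matrix(self.sigma_rem, "sigma_rem")
        check_correlation_matrix(self.sigma_nrem, "sigma_nrem")
        min_dwell_s = self.min_dwell_volumes * self.tr_seconds
        for name, mean in (("rem_mean_dwell_s", self.rem_mean_dwell_s),
                           ("nrem_mean_dwell_s", self.nrem_mean_dwell_s)):
            if mean <= 0:
                raise ValueError(f"{name} must be positive")
            if mean <= min_dwell_s:
                raise ValueError(
                    f"{name}={mean} must exceed the minimum dwell "
                    f"{min_dwell_s} s ({self.min_dwell_volumes} volumes)")
        if self.rem_breath_rate_bpm <= self.nrem_breath_rate_bpm:
            raise ValueError(
                "REM-like breathing rate must exceed the NREM-like rate "
                "(high rate <-> REM-like)")
        if not 0.0 <= self.single_state_fraction <= 1.0:
            raise ValueError("single_state_fraction must lie in [0, 1]")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        # fail loudly at configuration time if the lesion matrix is invalid
        self.lesion_sigma_rem()

    def lesion_sigma_rem(self) -> np.ndarray:
        """REM correlation matrix of the lesion group (effects applied)."""
        if not self.effect_edges:
            return self.sigma_rem
        return apply_effect_edges(self.sigma_rem, self.effect_edges,
                                  self.roi_labels)

    def state_sigma(self, state: State, group: str) -> np.ndarray:
        if State(state) is State.REM_LIKE:
            return (self.lesion_sigma_rem() if group == "lesion"
                    else self.sigma_rem)
        return self.sigma_nrem


@dataclass
class SyntheticSubject:
    """Generated subject plus the ground truth that produced it."""

    subject_id: str
    group: str
    roi_ts: RoiTimeSeriesSet
    motion: MotionParams
    respiration: RespirationTrace
    true_states: StateLabels
    true_sigma_by_state: dict[State, np.ndarray]


def _subject_rng(cfg: SyntheticCohortConfig, subject_seed: int,
                 stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, int(subject_seed), stream])


def sample_dwell_times(cfg: SyntheticCohortConfig, state: State,
                       rng: np.random.Generator, size: int) -> np.ndarray:
    """Shifted-exponential dwell times (seconds), minimum one window.

    The exponential is the maximum-entropy law for a positive duration
    with a given mean; shifting it by one analysis window (30 volumes)
    guarantees every run contains at least one window.
    """
    shift = cfg.min_dwell_volumes * cfg.tr_seconds
    mean = (cfg.rem_mean_dwell_s if State(state) is State.REM_LIKE
            else cfg.nrem_mean_dwell_s)
    return shift + rng.exponential(mean - shift, size=size)


def generate_state_sequence(cfg: SyntheticCohortConfig,
                            subject_seed: int) -> StateLabels:
    """Alternating REM-like/NREM-like label sequence for one subject.

    With probability ``single_state_fraction`` the subject never
    transitions and the whole scan carries one state.
    """
    rng = _subject_rng(cfg, subject_seed, 0)
    codes = np.empty(cfg.n_volumes, dtype=np.int8)
    start_rem = bool(rng.random() < 0.5)
    if rng.random() < cfg.single_state_fraction:
        codes[:] = REM_CODE if start_rem else NREM_CODE
        return StateLabels(codes, cfg.tr_seconds)
    pos = 0
    state = State.REM_LIKE if start_rem else State.NREM_LIKE
    while pos < cfg.n_volumes:
        dwell_s = float(sample_dwell_times(cfg, state, rng, 1)[0])
        n = max(cfg.min_dwell_volumes, int(dwell_s / cfg.tr_seconds))
        end = min(pos + n, cfg.n_volumes)
        codes[pos:end] = state_to_code(state)
        pos = end
        state = (State.NREM_LIKE if state is State.REM_LIKE
                 else State.REM_LIKE)
    return StateLabels(codes, cfg.tr_seconds)


def _latent_roi_series(cfg: SyntheticCohortConfig, group: str,
                       states: StateLabels,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean latent ROI series with state-switching correlation.

    Innovations are multivariate normal with the active state's
    correlation; an AR(1) filter with innovation variance scaled by
    (1 - phi^2) adds temporal smoothness while preserving the stationary
    correlation within a state.
    """
    t, r = cfg.n_volumes, cfg.n_rois
    chol = {
        REM_CODE: np.linalg.cholesky(cfg.state_sigma(State.REM_LIKE, group)),
        NREM_CODE: np.linalg.cholesky(cfg.state_sigma(State.NREM_LIKE,
                                                      group)),
    }
    white = rng.standard_normal((t, r))
    innov = np.empty_like(white)
    for code, l_mat in chol.items():
        mask = states.codes == code
        innov[mask] = white[mask] @ l_mat.T
    phi = cfg.ar_coef
    if phi == 0.0:
        return innov
    from scipy.signal import lfilter
    scale = np.sqrt(1.0 - phi * phi)
    # x[t] = phi x[t-1] + scale*innov[t], with x[0] = innov[0] so the
    # process is stationary from the first sample
    driven = innov.copy()
    driven[0] /= scale
    return lfilter([scale], [1.0, -phi], driven, axis=0)


def _synthesize_respiration(cfg: SyntheticCohortConfig, states: StateLabels,
                            rng: np.random.Generator) -> RespirationTrace:
    """Sinusoid whose instantaneous rate tracks the state sequence."""
    fs = cfg.resp_sampling_hz
    duration = cfg.n_volumes * cfg.tr_seconds
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    offset = rng.normal(0.0, cfg.breath_rate_jitter_bpm)
    vol_idx = np.minimum((t / cfg.tr_seconds).astype(int), cfg.n_volumes - 1)
    bpm = np.where(states.codes[vol_idx] == REM_CODE,
                   cfg.rem_breath_rate_bpm, cfg.nrem_breath_rate_bpm) + offset
    # slow physiological wander
    from scipy.ndimage import gaussian_filter1d
    wander = gaussian_filter1d(rng.standard_normal(n), sigma=5 * fs)
    sd = wander.std()
    if sd > 0 and cfg.breath_rate_wander_bpm > 0:
        bpm = bpm + cfg.breath_rate_wander_bpm * wander / sd
    phase = 2.0 * np.pi * np.cumsum(bpm / 60.0) / fs
    amp = 1.0 + 0.1 * gaussian_filter1d(rng.standard_normal(n), sigma=fs)
    signal = amp * np.sin(phase) + 0.05 * rng.standard_normal(n)
    return RespirationTrace(t, signal, fs)


def _synthesize_motion(cfg: SyntheticCohortConfig,
                       rng: np.random.Generator) -> MotionParams:
    """Six smooth small-amplitude random walks (nuisance regressors)."""
    from scipy.ndimage import gaussian_filter1d
    walk = np.cumsum(rng.standard_normal((cfg.n_volumes, 6)), axis=0)
    walk = gaussian_filter1d(walk, sigma=3.0, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return MotionParams(walk / sd * cfg.motion_sd)


def generate_subject(cfg: SyntheticCohortConfig, group: str,
                     subject_seed: int,
                     subject_id: str | None = None) -> SyntheticSubject:
    """One subject: ROI series, motion, respiration and true states.

    All randomness derives from ``(cfg.seed, subject_seed)``; repeated
    calls are bit-identical.
    """
    if group not in ("control", "lesion"):
        raise ValueError(f"group must be 'control' or 'lesion', got {group!r}")
    states = generate_state_sequence(cfg, subject_seed)
    latent = _latent_roi_series(cfg, group, states,
                                _subject_rng(cfg, subject_seed, 1))
    values = cfg.bold_baseline + cfg.bold_amplitude * latent
    roi_ts = RoiTimeSeriesSet(values, cfg.tr_seconds, list(cfg.roi_labels))
    motion = _synthesize_motion(cfg, _subject_rng(cfg, subject_seed, 2))
    resp = _synthesize_respiration(cfg, states,
                                   _subject_rng(cfg, subject_seed, 3))
    if subject_id is None:
        subject_id = f"{group}{subject_seed:03d}"
    return SyntheticSubject(
        subject_id=subject_id, group=group, roi_ts=roi_ts, motion=motion,
        respiration=resp, true_states=states,
        true_sigma_by_state={
            State.REM_LIKE: cfg.state_sigma(State.REM_LIKE, group),
            State.NREM_LIKE: cfg.state_sigma(State.NREM_LIKE, group),
        })


def generate_voxel_subject(cfg: SyntheticCohortConfig, group: str,
                           grid_shape: tuple[int, int, int],
                           roi_label_map: np.ndarray, subject_seed: int,
                           voxel_noise_sd: float | None = None,
                           ) -> tuple[np.ndarray, SyntheticSubject]:
    """Small 4D volume whose voxels carry their ROI's latent series.

    ``roi_label_map`` assigns integer codes (0 = outside any ROI,
    k = cfg.roi_labels[k-1]).  Voxels inside an ROI get that ROI's latent
    series plus independent Gaussian noise; code-0 voxels are pure noise.
    """
    roi_label_map = np.asarray(roi_label_map)
    if roi_label_map.shape != tuple(grid_shape):
        raise ValueError("label map shape must equal grid_shape")
    max_code = int(roi_label_map.max(initial=0))
    if max_code > cfg.n_rois:
        raise ValueError(
            f"label map contains code {max_code} but config defines only "
            f"{cfg.n_rois} ROIs")
    if voxel_noise_sd is None:
        voxel_noise_sd = cfg.noise_sd
    subject = generate_subject(cfg, group, subject_seed)
    latent = (subject.roi_ts.values - cfg.bold_baseline) / cfg.bold_amplitude
    rng = _subject_rng(cfg, subject_seed, 4)
    t = cfg.n_volumes
    vol = np.empty(tuple(grid_shape) + (t,), dtype=np.float32)
    flat_map = roi_label_map.reshape(-1)
    flat = vol.reshape(-1, t)
    for code in np.unique(flat_map):
        idx = np.flatnonzero(flat_map == code)
        if code == 0:
            flat[idx] = rng.standard_normal((idx.size, t))
        else:
            noise = (voxel_noise_sd * rng.standard_normal((idx.size, t))
                     if voxel_noise_sd > 0 else 0.0)
            flat[idx] = latent[:, code - 1][None, :] + noise
    return vol, subject


def generate_cohort(cfg: SyntheticCohortConfig) -> list[SyntheticSubject]:
    """Deterministic cohort of n_control + n_lesion subjects."""
    if cfg.n_control < 1 or cfg.n_lesion < 1:
        raise ValueError("need at least one subject per group")
    subjects = []
    for i in range(cfg.n_control):
        subjects.append(generate_subject(
            cfg, "control", subject_seed=i, subject_id=f"ctrl{i:03d}"))
    for i in range(cfg.n_lesion):
        subjects.append(generate_subject(
            cfg, "lesion", subject_seed=cfg.n_control + i,
            subject_id=f"les{i:03d}"))
    return subjects
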