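"""Partial correlation, windowing and Fisher-z subject summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sleepfc import (MotionParams, RoiTimeSeriesSet, State, StateLabels,
                     SyntheticCohortConfig, fisher_z, generate_subject,
                     partial_corr, partition_windows, seed_map,
                     state_connectivity, whole_scan_connectivity)
from sleepfc.connectivity import R_CLIP, Window, WindowSet
from sleepfc.core import NREM_CODE, REM_CODE, code_to_state


def _normal_equations_oracle(x, y, z):
    """Independent residual-correlation implementation."""
    t = len(x)
    d = np.column_stack([np.ones(t), z])
    proj = d @ np.linalg.inv(d.T @ d) @ d.T
    rx, ry = x - proj @ x, y - proj @ y
    return rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))


class TestPartialCorr:
    def test_empty_nuisance_is_pearson(self, rng):
        x, y = rng.standard_normal((2, 100))
        assert partial_corr(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_shared_nuisance_column_removed(self, rng):
        t = 3000
        z = rng.standard_normal((t, 3))
        y = z[:, 0] + 0.3 * rng.standard_normal(t)
        x = rng.standard_normal(t)
        assert abs(partial_corr(x, y, z)) < 0.05

    def test_matches_oracle_to_1e10(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 50))
            z = rng.standard_normal((50, 6))
            assert partial_corr(x, y, z) == pytest.approx(
                _normal_equations_oracle(x, y, z), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        x, y = rng.standard_normal((2, 80))
        z = rng.standard_normal((80, 4))
        df = pd.DataFrame({"x": x, "y": y,
                           **{f"z{i}": z[:, i] for i in range(4)}})
        expected = pg.partial_corr(
            df, x="x", y="y", covar=[f"z{i}" for i in range(4)])["r"].iloc[0]
        assert partial_corr(x, y, z) == pytest.approx(expected, abs=1e-10)

    def test_symmetry_and_affine_invariance(self, rng):
        x, y = rng.standard_normal((2, 60))
        z = rng.standard_normal((60, 2))
        r = partial_corr(x, y, z)
        assert partial_corr(y, x, z) == pytest.approx(r, abs=1e-12)
        assert partial_corr(3.0 * x + 5.0, -0.5 * y + 1.0, z) \
            == pytest.approx(-r, abs=1e-12)

    def test_invariance_to_nuisance_recombination(self, rng):
        x, y = rng.standard_normal((2, 60))
        z = rng.standard_normal((60, 3))
        mix = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        assert partial_corr(x, y, z @ mix) == pytest.approx(
            partial_corr(x, y, z), abs=1e-10)

    def test_zero_variance_residual_is_nan(self, rng):
        z = rng.standard_normal((50, 2))
        x = 2.0 * z[:, 0] - z[:, 1] + 4.0    # exactly in the design span
        y = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert np.isnan(partial_corr(x, y, z))

    def test_too_few_samples_rejected(self, rng):
        z = rng.standard_normal((8, 6))
        with pytest.raises(ValueError, match="T > p"):
            partial_corr(rng.standard_normal(8), rng.standard_normal(8), z)


class TestPartitionWindows:
    def _labels(self, codes):
        return StateLabels(np.asarray(codes, dtype=np.int8), 2.0)

    def test_90_volume_run_yields_exactly_3_windows(self):
        ws = partition_windows(self._labels([REM_CODE] * 90), width=30)
        assert len(ws) == 3
        assert [w.start for w in ws.windows] == [0, 30, 60]
        assert all(w.length == 30 for w in ws.windows)

    def test_29_volume_run_yields_no_window(self):
        assert len(partition_windows(self._labels([REM_CODE] * 29))) == 0

    def test_floor_rule_discards_remainders(self):
        codes = [REM_CODE] * 65 + [NREM_CODE] * 35
        ws = partition_windows(self._labels(codes), width=30)
        assert len(ws.of_state(State.REM_LIKE)) == 2
        assert len(ws.of_state(State.NREM_LIKE)) == 1

    def test_windows_stay_within_one_run(self):
        codes = [REM_CODE] * 45 + [NREM_CODE] * 45 + [REM_CODE] * 45
        ws = partition_windows(self._labels(codes), width=30)
        for w in ws.windows:
            run_codes = codes[w.start:w.start + w.length]
            assert len(set(run_codes)) == 1


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)

    @given(st.floats(0.0, 0.999))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            z = fisher_z(1.0)
        assert z == pytest.approx(np.arctanh(R_CLIP))


def _toy_subject(rng, t=120, r=4):
    values = rng.standard_normal((t, r))
    ts = RoiTimeSeriesSet(values, 2.0, [f"roi{k}" for k in range(r)])
    motion = MotionParams(0.05 * rng.standard_normal((t, 6)))
    return ts, motion


class TestStateConnectivity:
    def test_identical_windows_average_to_single_window(self, rng):
        ts, motion = _toy_subject(rng, t=60)
        ts.values[30:] = ts.values[:30]
        motion.values[30:] = motion.values[:30]
        labels = StateLabels(np.full(60, REM_CODE, dtype=np.int8), 2.0)
        ws = partition_windows(labels, width=30)
        both = state_connectivity(ts, motion, ws, State.REM_LIKE)
        one = state_connectivity(
            ts, motion, WindowSet([ws.windows[0]], 30), State.REM_LIKE)
        assert both.n_windows_used == 2
        np.testing.assert_allclose(both.z, one.z, atol=1e-10)

    def test_window_order_invariance(self, rng):
        ts, motion = _toy_subject(rng, t=120)
        labels = StateLabels(np.full(120, NREM_CODE, dtype=np.int8), 2.0)
        ws = partition_windows(labels, width=30)
        fwd = state_connectivity(ts, motion, ws, State.NREM_LIKE)
        rev = state_connectivity(
            ts, motion, WindowSet(ws.windows[::-1], 30), State.NREM_LIKE)
        np.testing.assert_allclose(fwd.z, rev.z, atol=1e-12)

    def test_matches_pairwise_partial_corr(self, rng):
        """The joint-residualization fast path equals edge-by-edge
        partial correlation."""
        ts, motion = _toy_subject(rng, t=30, r=5)
        ws = WindowSet([Window(0, 30, State.REM_LIKE)], 30)
        conn = state_connectivity(ts, motion, ws, State.REM_LIKE)
        for i in range(5):
            for j in range(i + 1, 5):
                r = partial_corr(ts.values[:, i], ts.values[:, j],
                                 motion.values)
                assert conn.z[i, j] == pytest.approx(np.arctanh(r),
                                                     abs=1e-10)

    def test_whole_scan_agrees_with_state_matrix_as_window_grows(self):
        cfg = SyntheticCohortConfig(seed=14, n_volumes=3000,
                                    single_state_fraction=1.0)
        subject = generate_subject(cfg, "control", 1)
        state = code_to_state(subject.true_states.codes[0])
        whole = whole_scan_connectivity(subject.roi_ts, subject.motion)
        big_window = state_connectivity(
            subject.roi_ts, subject.motion,
            WindowSet([Window(0, 3000, state)], 3000), state)
        np.testing.assert_allclose(whole.z, big_window.z, atol=1e-12,
                                   equal_nan=True)

    def test_subject_mean_z_near_truth(self):
        """Mean z over many windows sits near atanh(true r); the motion
        nuisance is independent of the signal so it only costs dof."""
        cfg = SyntheticCohortConfig(seed=15, n_volumes=6000,
                                    single_state_fraction=1.0, ar_coef=0.0)
        subject = generate_subject(cfg, "control", 0)
        state = code_to_state(subject.true_states.codes[0])
        labels = subject.true_states
        ws = partition_windows(labels, width=30)
        conn = state_connectivity(subject.roi_ts, subject.motion, ws,
                                  state)
        sigma = subject.true_sigma_by_state[state]
        iu = np.triu_indices(17, k=1)
        # per-window SE of z ~ 1/sqrt(W-3-p); mean over 200 windows
        se = 1.0 / np.sqrt(30 - 3 - 6) / np.sqrt(conn.n_windows_used)
        dev = conn.z[iu] - np.arctanh(sigma[iu])
        assert np.mean(np.abs(dev) < 4 * se) > 0.9

    def test_no_windows_of_requested_state_raises(self, rng):
        ts, motion = _toy_subject(rng, t=60)
        labels = StateLabels(np.full(60, REM_CODE, dtype=np.int8), 2.0)
        ws = partition_windows(labels, width=30)
        with pytest.raises(ValueError, match="NREM"):
            state_connectivity(ts, motion, ws, State.NREM_LIKE)


class TestSeedMap:
    def _fixture(self, rng, noise=0.0):
        t = 90
        latent = rng.standard_normal(t)
        vol = np.zeros((4, 3, 1, t))
        vol[0, 0, 0] = latent
        vol[1, :, 0] = latent + noise * rng.standard_normal((3, t))
        vol[2:, :, 0] = rng.standard_normal((2, 3, t))
        labels = StateLabels(np.full(t, REM_CODE, dtype=np.int8), 2.0)
        ws = partition_windows(labels, width=30)
        mask = np.ones((4, 3, 1), dtype=bool)
        return latent, vol, ws, mask

    def test_seed_voxel_hits_clipped_maximum(self, rng):
        latent, vol, ws, mask = self._fixture(rng)
        with pytest.warns(RuntimeWarning, match="clip"):
            zmap = seed_map(latent, vol, None, ws, State.REM_LIKE, mask)
        assert zmap[0, 0, 0] == pytest.approx(np.arctanh(R_CLIP))

    def test_independent_noise_voxels_near_zero(self, rng):
        latent, vol, ws, mask = self._fixture(rng, noise=0.5)
        zmap = seed_map(latent, vol, None, ws, State.REM_LIKE, mask)
        noise_z = zmap[2:, :, 0]
        # 3 windows of 30: SE of mean z ~ 1/sqrt(27)/sqrt(3) ~ 0.11
        assert np.abs(np.mean(noise_z)) < 0.25

    def test_masked_out_voxels_are_nan(self, rng):
        latent, vol, ws, mask = self._fixture(rng, noise=0.5)
        mask[3, :, :] = False
        zmap = seed_map(latent, vol, None, ws, State.REM_LIKE, mask)
        assert np.isnan(zmap[3]).all()
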