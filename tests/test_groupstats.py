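"""Edgewise/voxelwise group inference, FDR, edge graph, ratio utility."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sleepfc import (ConnectivityMatrix, State, build_edge_graph,
                     edgewise_compare, fdr_bh, group_map_vs_zero,
                     lesion_ratio, voxelwise_compare)


def _bh_brute(p):
    """Step-up definition: q_i = min_{j: p_(j) >= p_i} m p_(j) / rank."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestFdrBh:
    def test_hand_computed_step_up(self):
        q, reject = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
        assert reject.tolist() == [True, True, True, False]

    def test_identical_pvalues_share_q(self):
        q, _ = fdr_bh(np.full(7, 0.03))
        np.testing.assert_allclose(q, 0.03, atol=1e-12)

    def test_single_p_is_its_own_q(self):
        q, _ = fdr_bh(np.array([0.2]))
        assert q[0] == pytest.approx(0.2, abs=1e-15)

    def test_empty_input(self):
        q, reject = fdr_bh(np.array([]))
        assert q.size == 0 and reject.size == 0

    def test_nan_entries_excluded_from_family(self):
        q, reject = fdr_bh(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1]) and not reject[1]
        np.testing.assert_allclose(q[[0, 2]],
                                   _bh_brute([0.01, 0.04]), atol=1e-12)

    @given(st.integers(1, 20), st.integers(0, 10000))
    def test_matches_brute_force_step_up(self, m, seed):
        p = np.random.default_rng(seed).random(m)
        q, reject = fdr_bh(p, alpha=0.05)
        expected = _bh_brute(p)
        np.testing.assert_allclose(q, expected, atol=1e-12)
        assert (reject == (expected <= 0.05)).all()


def _matrices(z_stack, state=State.REM_LIKE):
    r = z_stack.shape[1]
    labels = [f"roi{k}" for k in range(r)]
    out = []
    for k, z in enumerate(z_stack):
        m = (z + z.T) / 2.0
        np.fill_diagonal(m, np.nan)
        out.append(ConnectivityMatrix(m, labels, state,
                                      subject_id=f"s{k}"))
    return out


class TestEdgewiseCompare:
    def test_identical_groups_show_nothing(self, rng):
        group = _matrices(rng.standard_normal((4, 5, 5)))
        result = edgewise_compare(group, list(group))
        assert np.allclose(result.table["t"], 0.0)
        assert np.allclose(result.table["p"], 1.0)
        assert result.n_significant == 0

    def test_group_swap_antisymmetry(self, rng):
        a = _matrices(rng.standard_normal((5, 4, 4)))
        b = _matrices(rng.standard_normal((6, 4, 4)) + 0.3)
        ab = edgewise_compare(a, b)
        ba = edgewise_compare(b, a)
        np.testing.assert_allclose(ab.table["t"], -ba.table["t"],
                                   atol=1e-10)
        np.testing.assert_allclose(ab.table["p"], ba.table["p"],
                                   atol=1e-12)
        np.testing.assert_allclose(ab.table["diff"], -ba.table["diff"],
                                   atol=1e-12)

    def test_diff_is_mean_a_minus_mean_b(self, rng):
        a = _matrices(rng.standard_normal((3, 4, 4)))
        b = _matrices(rng.standard_normal((3, 4, 4)))
        result = edgewise_compare(a, b)
        np.testing.assert_allclose(
            result.table["diff"],
            result.table["mean_z_a"] - result.table["mean_z_b"],
            atol=0.0)

    def test_strong_effect_detected(self, rng):
        a = _matrices(0.05 * rng.standard_normal((8, 4, 4)))
        zb = 0.05 * rng.standard_normal((8, 4, 4))
        zb[:, 0, 1] += 1.0
        zb[:, 1, 0] += 1.0
        b = _matrices(zb)
        result = edgewise_compare(a, b)
        sig = result.significant_edges()
        assert {("roi0", "roi1")} == set(zip(sig.roi_i, sig.roi_j))

    def test_zero_variance_edge_flagged_and_excluded(self, rng):
        za = rng.standard_normal((3, 3, 3))
        zb = rng.standard_normal((3, 3, 3))
        za[:, 0, 1] = za[:, 1, 0] = 0.7      # no variance in either group
        zb[:, 0, 1] = zb[:, 1, 0] = 0.7
        with pytest.warns(RuntimeWarning, match="excluded"):
            result = edgewise_compare(_matrices(za), _matrices(zb))
        row = result.table.set_index(["roi_i", "roi_j"]).loc[
            ("roi0", "roi1")]
        assert np.isnan(row["p"]) and np.isnan(row["q"])
        assert not row["significant"]

    def test_mismatched_rois_rejected(self, rng):
        a = _matrices(rng.standard_normal((2, 3, 3)))
        b = _matrices(rng.standard_normal((2, 4, 4)))
        with pytest.raises(ValueError, match="ROI"):
            edgewise_compare(a, b)

    def test_null_fdr_rate_controlled(self, rng):
        """Across independent null comparisons, FDR-significant edges are
        rare and uncorrected rejections sit near the nominal rate."""
        n_sig = 0
        rejections = []
        for _ in range(60):
            a = _matrices(rng.standard_normal((8, 6, 6)))
            b = _matrices(rng.standard_normal((8, 6, 6)))
            result = edgewise_compare(a, b)
            n_sig += result.n_significant
            rejections.append((result.table["p"] < 0.05).mean())
        assert n_sig / 60 <= 0.05 * 15 + 0.1
        assert np.mean(rejections) == pytest.approx(0.05, abs=0.02)


class TestVoxelMaps:
    shape = (6, 5, 2)

    def test_all_zero_maps_nothing_significant(self):
        maps = [np.zeros(self.shape) for _ in range(5)]
        out = group_map_vs_zero(maps, np.ones(self.shape, bool))
        assert np.isnan(out).all()

    def test_strong_block_survives_noise_does_not(self, rng):
        maps = []
        for _ in range(8):
            m = 0.05 * rng.standard_normal(self.shape)
            m[:3, :3, :] += 0.5
            maps.append(m)
        out = group_map_vs_zero(maps, np.ones(self.shape, bool))
        block = out[:3, :3, :]
        rest = out[3:, :, :]
        assert np.isfinite(block).all()
        assert np.isnan(rest).mean() > 0.9
        assert np.nanmean(block) == pytest.approx(0.5, abs=0.1)

    def test_empty_mask_is_empty_result(self, rng):
        maps = [rng.standard_normal(self.shape) for _ in range(4)]
        out = group_map_vs_zero(maps, np.zeros(self.shape, bool))
        assert np.isnan(out).all()

    def test_identical_groups_empty_difference(self, rng):
        maps = [rng.standard_normal(self.shape) for _ in range(4)]
        out = voxelwise_compare(maps, [m.copy() for m in maps],
                                np.ones(self.shape, bool))
        assert np.isnan(out).all()

    def test_alpha_one_reports_every_masked_voxel(self, rng):
        a = [rng.standard_normal(self.shape) for _ in range(4)]
        b = [rng.standard_normal(self.shape) for _ in range(4)]
        mask = np.zeros(self.shape, bool)
        mask[0] = True
        out = voxelwise_compare(a, b, mask, alpha=1.0)
        assert np.isfinite(out[mask]).all()
        assert np.isnan(out[~mask]).all()


class TestEdgeGraph:
    def _result(self, rng, deltas):
        za = 0.02 * rng.standard_normal((8, 17, 17))
        zb = 0.02 * rng.standard_normal((8, 17, 17))
        for (i, j), d in deltas.items():
            za[:, i, j] += d
            za[:, j, i] += d
        return edgewise_compare(_matrices(za), _matrices(zb))

    def test_width_increases_with_difference(self, rng):
        result = self._result(rng, {(0, 1): 0.12, (2, 3): 0.41})
        graph = build_edge_graph(result)
        small = graph.edges["roi0", "roi1"]["width"]
        large = graph.edges["roi2", "roi3"]["width"]
        assert large > small

    def test_strong_p_band_colored_red(self, rng):
        result = self._result(rng, {(0, 1): 0.8})
        graph = build_edge_graph(result)
        edge = graph.edges["roi0", "roi1"]
        assert edge["p"] < 0.01
        assert edge["p_band"] == "p<0.01"
        assert edge["color"] == "red"

    def test_empty_significance_gives_nodes_only(self, rng):
        result = self._result(rng, {})
        graph = build_edge_graph(result)
        assert graph.number_of_nodes() == 17
        assert graph.number_of_edges() == 0

    def test_edges_subset_of_significant(self, rng):
        result = self._result(rng, {(0, 1): 0.5, (4, 5): 0.45})
        graph = build_edge_graph(result)
        sig = set(map(tuple, result.significant_edges()[
            ["roi_i", "roi_j"]].to_numpy()))
        assert set(graph.edges) <= sig | {(b, a) for a, b in sig}


class TestLesionRatio:
    def test_identity(self):
        ratio, change = lesion_ratio(67.9, 67.9)
        assert ratio == 1.0 and change == 0.0

    def test_dopamine_depletion_rounds_to_51_percent(self):
        _, change = lesion_ratio(33.2, 67.9)
        assert round(change) == 51

    def test_increase_reports_negative_change(self):
        ratio, change = lesion_ratio(23.1, 22.5)
        assert ratio > 1.0 and change < 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lesion_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            lesion_ratio(1.0, -2.0)
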