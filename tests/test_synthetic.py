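"""Synthetic-data generators: known moments, stability, determinism."""

import numpy as np
import pytest

from dtfconn import (
    GroundTruthNetwork,
    attenuate_electrodes,
    control_network,
    fit,
    random_stable_network,
    simulate_fmri_blocks,
    simulate_mvar,
    spectral_radius,
)
from dtfconn.errors import ConfigurationError, StabilityError
from dtfconn.montage import POSTERIOR_ELECTRODES


class TestGroundTruthNetwork:
    def test_unstable_coefficients_raise_with_radius(self):
        with pytest.raises(StabilityError) as err:
            GroundTruthNetwork(coupling=np.array([[[1.1]]]), noise_sd=1.0)
        assert err.value.radius == pytest.approx(1.1)
        assert "1.1" in str(err.value)

    def test_edge_set_matches_nonzero_offdiagonals(self):
        A = np.zeros((2, 3, 3))
        A[0, 1, 0] = 0.4  # 0 -> 1 at lag 1
        A[1, 2, 1] = 0.3  # 1 -> 2 at lag 2
        A[0] += np.eye(3) * 0.2  # self terms are not edges
        net = GroundTruthNetwork(coupling=A, noise_sd=1.0)
        assert set(net.edge_set) == {(0, 1), (1, 2)}

    def test_random_stable_network_hits_target_radius(self):
        for order in (1, 3, 5):
            net = random_stable_network(5, order, seed=order)
            assert spectral_radius(net.coupling) == pytest.approx(0.9, abs=1e-8)


class TestSimulateMVAR:
    def test_lag_one_cross_covariance_matches_yule_walker(self, bivariate_net):
        # x1 is white with var 1; cov(x2(t), x1(t-1)) = 0.5 * var(x1)
        rec = simulate_mvar(bivariate_net, 100_000, seed=11)
        x1, x2 = rec.data
        lag1 = np.cov(x2[1:], x1[:-1])[0, 1]
        assert lag1 == pytest.approx(0.5 * np.var(x1), abs=0.02)

    def test_zero_coupling_gives_uncorrelated_channels(self):
        net = GroundTruthNetwork(coupling=np.zeros((1, 3, 3)), noise_sd=1.0)
        rec = simulate_mvar(net, 20_000, seed=2)
        for lag in (0, 1, 2):
            a = rec.data[:, lag:]
            b = rec.data[:, : a.shape[1]]
            c = np.corrcoef(np.vstack([a[0], b[1], b[2]]))
            off = np.abs(c[~np.eye(3, dtype=bool)])
            assert off.max() < 0.05

    def test_same_seed_is_bit_identical(self, bivariate_net):
        a = simulate_mvar(bivariate_net, 500, seed=9)
        b = simulate_mvar(bivariate_net, 500, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_stationarity_split_half_variance(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 20_000, seed=3)
        half = rec.n_samples // 2
        v1 = rec.data[:, :half].var(axis=1)
        v2 = rec.data[:, half:].var(axis=1)
        assert np.all(0.5 < v1 / v2) and np.all(v1 / v2 < 2.0)

    def test_refit_error_decreases_with_sample_size(self):
        net = random_stable_network(3, 2, density=0.5, strength=0.9, seed=5)

        def rmse(n):
            rec = simulate_mvar(net, n, seed=8)
            m = fit(rec, 2)
            return np.sqrt(np.mean((m.coeffs - net.coupling) ** 2))

        assert rmse(40_000) < rmse(4_000)


class TestControlAndPatientNetworks:
    def test_control_network_is_stable_and_spatial(self):
        net = control_network()
        assert net.radius < 1
        assert net.n_channels == 32
        assert len(net.edge_set) > 0

    def test_attenuation_scales_only_requested_couplings(self):
        net = control_network()
        pat = attenuate_electrodes(net, factor=0.5, direction="inflow")
        idx = [net.labels.index(e) for e in POSTERIOR_ELECTRODES]
        rest = [i for i in range(32) if i not in idx]
        off = ~np.eye(32, dtype=bool)
        # attenuated rows halve, untouched rows identical
        r = np.ones((32, 32))
        r[idx, :] = 0.5
        expected = net.coupling[0].copy()
        expected[off] *= r[off]
        np.testing.assert_allclose(pat.coupling[0], expected)
        np.testing.assert_allclose(
            pat.coupling[0][np.ix_(rest, rest)], net.coupling[0][np.ix_(rest, rest)]
        )

    def test_attenuation_direction_validated(self):
        with pytest.raises(ConfigurationError):
            attenuate_electrodes(control_network(), direction="sideways")


class TestSimulateFMRIBlocks:
    def test_realised_within_and_between_correlations(self):
        vol = simulate_fmri_blocks(
            (6, 6, 4), 1000, n_communities=2, within_r=0.6, between_r=0.1, seed=4
        )
        ts = vol.in_mask_timeseries()
        r = np.corrcoef(ts)
        lab = vol.community_labels
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert r[same & off].mean() == pytest.approx(0.6, abs=0.05)
        assert r[~same].mean() == pytest.approx(0.1, abs=0.05)

    def test_zero_correlation_case(self):
        vol = simulate_fmri_blocks(
            (4, 4, 2), 800, n_communities=2, within_r=0.0, between_r=0.0, seed=5
        )
        r = np.corrcoef(vol.in_mask_timeseries())
        off = ~np.eye(r.shape[0], dtype=bool)
        assert np.abs(r[off].mean()) < 0.02

    def test_single_high_correlation_community_is_one_dimensional(self):
        vol = simulate_fmri_blocks(
            (4, 4, 2), 2000, n_communities=1, within_r=0.99, between_r=0.0, seed=6
        )
        ts = vol.in_mask_timeseries()
        ts = ts - ts.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(ts, compute_uv=False)
        explained = sv[0] ** 2 / (sv**2).sum()
        # equicorrelation at r: top eigenvalue share -> (1 + (k-1) r) / k
        assert explained >= 0.95

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_fmri_blocks((0, 4, 4), 100, 2, 0.6, 0.1, seed=0)

    def test_invalid_correlation_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_fmri_blocks((4, 4, 2), 100, 2, within_r=0.1, between_r=0.6, seed=0)

    def test_labels_cover_in_mask_voxels_only(self):
        mask = np.zeros((5, 5, 3), dtype=bool)
        mask[1:4, 1:4, :] = True
        vol = simulate_fmri_blocks(
            (5, 5, 3), 100, 3, 0.5, 0.1, seed=7, mask=mask
        )
        assert len(vol.community_labels) == mask.sum()
        assert set(vol.community_labels) == {0, 1, 2}
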