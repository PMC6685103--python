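"""MVAR estimation: parameter recovery, order selection, pooling, serialisation."""

import numpy as np
import pytest

from dtfconn import (
    MultichannelRecording,
    MVARModel,
    fit,
    fit_epochs,
    random_stable_network,
    select_order,
    simulate_mvar,
)
from dtfconn.errors import ConditioningError, ConfigurationError


class TestFit:
    def test_bivariate_coefficient_recovery(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 50_000, seed=1)
        m = fit(rec, 1)
        assert m.coeffs[0, 1, 0] == pytest.approx(0.5, abs=0.02)
        other = m.coeffs[0][np.array([[True, True], [False, True]])]
        assert np.abs(other).max() < 0.02

    def test_zero_noise_recovery_is_exact(self):
        net = random_stable_network(3, 2, density=0.5, strength=0.9, seed=3)
        rng = np.random.default_rng(0)
        p = 2
        x = np.zeros((62, 3))
        x[:p] = rng.standard_normal((p, 3))
        for t in range(60):
            x[t + p] = sum(net.coupling[k] @ x[t + p - 1 - k] for k in range(p))
        rec = MultichannelRecording(x[p:].T, fs=100.0)
        m = fit(rec, p)
        np.testing.assert_allclose(m.coeffs, net.coupling, atol=1e-9)

    def test_white_noise_residual_covariance_is_identity(self, white_noise_rec):
        m = fit(white_noise_rec, 1)
        np.testing.assert_allclose(m.noise_cov, np.eye(4), atol=0.1)

    def test_matches_statsmodels_var_exactly(self):
        # independent implementation of the same OLS problem
        from statsmodels.tsa.api import VAR

        net = random_stable_network(3, 2, density=0.5, strength=0.9, seed=7)
        rec = simulate_mvar(net, 3000, seed=7)
        mine = fit(rec, 2)
        sm = VAR(rec.data.T).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(mine.coeffs, sm.coefs, atol=1e-8)

    def test_consistency_rmse_shrinks_with_n(self):
        net = random_stable_network(4, 2, density=0.4, strength=0.9, seed=9)

        def rmse(n):
            m = fit(simulate_mvar(net, n, seed=10), 2)
            return np.sqrt(np.mean((m.coeffs - net.coupling) ** 2))

        assert rmse(40_000) < rmse(4_000)

    def test_duplicate_channel_named_in_conditioning_error(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        rec = MultichannelRecording(
            np.vstack([x, x]), fs=100.0, labels=["F3", "F4"]
        )
        with pytest.raises(ConditioningError, match="F3~F4"):
            fit(rec, 1)

    def test_too_few_samples_rejected(self):
        rec = MultichannelRecording(
            np.random.default_rng(0).standard_normal((4, 10)), fs=100.0
        )
        with pytest.raises(ConfigurationError):
            fit(rec, 3)


class TestEpochPooling:
    def test_single_epoch_pooled_equals_continuous(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 2000, seed=5)
        continuous = fit(rec, 1)
        one_epoch = fit(rec.epoch(rec.duration), 1)
        np.testing.assert_allclose(continuous.coeffs, one_epoch.coeffs, atol=1e-12)

    def test_pooled_fit_excludes_cross_epoch_windows(self, bivariate_net):
        # concatenating two independent simulations as epochs must not use
        # the discontinuity; the pooled fit equals the row-stacked OLS of
        # the two segments
        a = simulate_mvar(bivariate_net, 1000, seed=1)
        b = simulate_mvar(bivariate_net, 1000, seed=2)
        both = MultichannelRecording(
            np.hstack([a.data, b.data]), fs=a.fs, labels=a.labels
        ).epoch(1000 / a.fs)
        m = fit(both, 1)
        # manual pooled normal equations excluding the seam
        Xs, Ys = [], []
        for seg in (a.data, b.data):
            Xs.append(seg[:, :-1].T)
            Ys.append(seg[:, 1:].T)
        X, Y = np.vstack(Xs), np.vstack(Ys)
        coef = np.linalg.lstsq(X, Y, rcond=None)[0].T
        np.testing.assert_allclose(m.coeffs[0], coef, atol=1e-10)

    def test_fit_epochs_returns_one_model_per_epoch(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 3000, seed=6).epoch(4.0)
        models = fit_epochs(rec, 1)
        assert len(models) == rec.n_epochs
        assert all(m.order == 1 for m in models)


class TestSelectOrder:
    def test_recovers_true_order_three(self):
        net = random_stable_network(3, 3, density=0.6, strength=0.9, seed=300)
        rec = simulate_mvar(net, 20_000, seed=0)
        sel = select_order(rec, 1, 6)
        assert sel.selected == 3

    def test_white_noise_selects_p_min(self, white_noise_rec):
        sel = select_order(white_noise_rec, 1, 8)
        assert sel.selected == 1
        # SBC penalty grows with order when no structure exists
        assert sel.sbc[0] == min(sel.sbc)

    def test_bivariate_order_one_recovered(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 20_000, seed=4)
        assert select_order(rec, 1, 6).selected == 1

    def test_criterion_curves_returned_for_audit(self, white_noise_rec):
        sel = select_order(white_noise_rec, 1, 5)
        assert sel.orders == [1, 2, 3, 4, 5]
        assert len(sel.sbc) == len(sel.fpe) == 5

    def test_fpe_criterion_usable(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 20_000, seed=4)
        assert select_order(rec, 1, 6, criterion="FPE").selected == 1

    def test_invalid_range_rejected(self, white_noise_rec):
        with pytest.raises(ConfigurationError):
            select_order(white_noise_rec, 5, 2)

    def test_identifiability_guard(self):
        rec = MultichannelRecording(
            np.random.default_rng(1).standard_normal((8, 400)), fs=100.0
        )
        with pytest.raises(ConfigurationError, match="guard"):
            select_order(rec, 1, 20)


class TestModelContainer:
    def test_json_round_trip(self, bivariate_net):
        rec = simulate_mvar(bivariate_net, 5000, seed=2)
        m = fit(rec, 1)
        m2 = MVARModel.from_json(m.to_json())
        np.testing.assert_allclose(m.coeffs, m2.coeffs)
        np.testing.assert_allclose(m.noise_cov, m2.noise_cov)
        assert m2.order == 1 and m2.labels == m.labels

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ConfigurationError):
            MVARModel(
                order=1,
                coeffs=np.zeros((1, 2, 2)),
                noise_cov=np.array([[1.0, 0.5], [0.0, 1.0]]),
                n_samples_used=10,
            )
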