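"""Least-squares fitting, artifact weighting, reconstruction."""

import numpy as np
import pytest

from tfdeconv.basis import make_basis
from tfdeconv.design import (
    ColumnInfo,
    DesignMatrix,
    EventRegressorSpec,
    assemble_design,
    build_event_regressors,
)
from tfdeconv.glm import (
    ARTIFACT_WEIGHT,
    artifact_weights,
    band_average,
    fit_ols,
    fit_wls,
    reconstruct,
)
from tfdeconv.signal import ContinuousSignal

FS = 20.0


def _random_design(t, n, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((t, n))
    cols = [ColumnInfo(kind="event", event_type="e", basis_index=j) for j in range(n)]
    return DesignMatrix(values=values, columns=cols)


class TestOLS:
    def test_identity_design_returns_data(self):
        Y = np.random.default_rng(0).standard_normal((5, 3))
        X = DesignMatrix(
            values=np.eye(5),
            columns=[ColumnInfo(kind="drift", drift_index=i) for i in range(5)],
        )
        fit = fit_ols(Y, X)
        np.testing.assert_allclose(fit.beta, Y, atol=1e-10)
        assert fit.dof == 0

    def test_orthonormal_design_collapses_normal_equations(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.standard_normal((50, 4)))
        X = DesignMatrix(
            values=Q, columns=[ColumnInfo(kind="drift", drift_index=i) for i in range(4)]
        )
        Y = rng.standard_normal((50, 2))
        fit = fit_ols(Y, X)
        np.testing.assert_allclose(fit.beta, Q.T @ Y, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = _random_design(50, 6, seed=2)
        Y = rng.standard_normal((50, 3))
        fit = fit_ols(Y, X)
        Xv = X.values
        oracle = np.linalg.solve(Xv.T @ Xv, Xv.T @ Y)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-8)
        assert fit.dof == 50 - 6
        assert (fit.rss >= 0).all()

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X = _random_design(200, 8, seed=3)
        Y = rng.standard_normal((200, 4))
        fit = fit_ols(Y, X)
        resid = Y - X.values @ fit.beta
        scale = np.abs(X.values.T @ Y).max()
        assert np.abs(X.values.T @ resid).max() <= 1e-6 * scale

    def test_all_zero_design_rejected(self):
        X = DesignMatrix(values=np.zeros((10, 2)), columns=[ColumnInfo("drift")] * 2)
        with pytest.raises(ValueError):
            fit_ols(np.ones((10, 1)), X)

    def test_rank_deficiency_flagged_not_fatal(self, caplog):
        X = _random_design(30, 3, seed=4)
        X.values[:, 2] = X.values[:, 0] + X.values[:, 1]
        with caplog.at_level("WARNING"):
            fit = fit_ols(np.random.default_rng(4).standard_normal((30, 1)), X)
        assert fit.rank == 2
        assert "rank" in caplog.text


class TestArtifactWeights:
    def test_clean_signal_all_ones(self):
        sig = ContinuousSignal(0.1 * np.ones(2000), 200.0)
        times = np.arange(0.2, 9.8, 0.05)
        assert (artifact_weights(sig, 2.0, 0.4, times) == 1.0).all()

    def test_single_spike_kills_nine_bins(self):
        values = np.zeros(2000)
        spike_t = 5.0
        values[int(spike_t * 200)] = 100.0
        times = np.arange(0.2, 9.61, 0.05)
        w = artifact_weights(ContinuousSignal(values, 200.0), 2.0, 0.4, times)
        bad = np.flatnonzero(w < 1)
        assert bad.size == 9
        np.testing.assert_allclose(w[bad], ARTIFACT_WEIGHT)
        assert (np.abs(times[bad] - spike_t) <= 0.2 + 1e-9).all()

    def test_hundred_large_spikes_all_detected(self, short_sim):
        from tfdeconv.simulate import add_spikes

        spiked, idx = add_spikes(short_sim.signal, 100, 100.0, 1234)
        detected = np.flatnonzero(np.abs(spiked.values) > 2.0)
        assert np.isin(idx, detected).all()


class TestWLS:
    def test_unit_weights_equal_ols(self):
        X = _random_design(60, 5, seed=5)
        Y = np.random.default_rng(5).standard_normal((60, 2))
        a = fit_ols(Y, X)
        b = fit_wls(Y, X, np.ones(60))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-12)
        assert a.dof == b.dof

    def test_binary_weights_equal_row_deletion(self):
        rng = np.random.default_rng(6)
        X = _random_design(80, 4, seed=6)
        Y = rng.standard_normal((80, 3))
        keep = rng.random(80) > 0.3
        w = keep.astype(float)
        wls = fit_wls(Y, X, w)
        sub = DesignMatrix(values=X.values[keep], columns=X.columns)
        deleted = fit_ols(Y[keep], sub)
        np.testing.assert_allclose(wls.beta, deleted.beta, atol=1e-8)
        assert wls.dof == deleted.dof

    def test_artifact_weight_equivalent_to_deletion(self):
        rng = np.random.default_rng(7)
        X = _random_design(80, 4, seed=7)
        Y = rng.standard_normal((80, 2))
        w = np.ones(80)
        w[:20] = ARTIFACT_WEIGHT
        wls = fit_wls(Y, X, w)
        sub = DesignMatrix(values=X.values[20:], columns=X.columns)
        deleted = fit_ols(Y[20:], sub)
        np.testing.assert_allclose(wls.beta, deleted.beta, atol=1e-8)
        assert wls.dof == deleted.dof

    def test_all_zero_weights_rejected(self):
        X = _random_design(10, 2)
        with pytest.raises(ValueError):
            fit_wls(np.ones((10, 1)), X, np.zeros(10))


class TestReconstruct:
    def _isolated_fir_setup(self):
        times = np.arange(0.2, 120.0, 1 / FS)
        basis = make_basis("fir", 81, (-2, 2), FS)
        onsets = np.arange(10.0, 110.0, 10.0)
        block = build_event_regressors(onsets, EventRegressorSpec("e"), basis, times)
        X = assemble_design(event_blocks={"e": block}, basis=basis)
        return times, basis, onsets, X

    def test_zero_beta_zero_image(self):
        _, basis, _, X = self._isolated_fir_setup()
        fit = fit_ols(np.zeros((X.values.shape[0], 2)), X)
        r = reconstruct(fit, "e")
        assert not r.values.any()

    def test_fir_reconstruction_equals_epoch_average(self):
        """OLS with an FIR basis on isolated events is selective averaging."""
        times, basis, onsets, X = self._isolated_fir_setup()
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((times.size, 2))
        Y -= Y.mean(axis=0)
        fit = fit_ols(Y, X)
        r = reconstruct(fit, "e")
        for j in range(2):
            epochs = []
            for onset in onsets:
                c = int(round((onset - times[0]) * FS))
                epochs.append(Y[c - 40 : c + 41, j])
            np.testing.assert_allclose(r.values[:, j], np.mean(epochs, axis=0), atol=1e-8)

    def test_unknown_event_type_rejected(self):
        _, _, _, X = self._isolated_fir_setup()
        fit = fit_ols(np.zeros((X.values.shape[0], 1)), X)
        with pytest.raises(KeyError):
            reconstruct(fit, "nope")

    def test_orthogonal_drift_leaves_reconstruction_unchanged(self):
        times, basis, onsets, X = self._isolated_fir_setup()
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((times.size, 1))
        r_plain = reconstruct(fit_ols(Y, X), "e")
        # residualise a drift column against the event block -> exactly orthogonal
        drift = rng.standard_normal(times.size)
        E = X.values
        drift -= E @ np.linalg.lstsq(E, drift, rcond=None)[0]
        X2 = DesignMatrix(
            values=np.column_stack([E, drift]),
            columns=X.columns + [ColumnInfo(kind="drift", drift_index=0)],
            basis=basis,
        )
        r_aug = reconstruct(fit_ols(Y, X2), "e")
        np.testing.assert_allclose(r_plain.values, r_aug.values, atol=1e-8)

    def test_serial_correlation_does_not_bias_estimates(self):
        """Mean reconstruction over AR-noise realisations converges on truth."""
        times, basis, onsets, X = self._isolated_fir_setup()
        rng = np.random.default_rng(10)
        beta_true = rng.standard_normal((X.values.shape[1], 1))
        clean = X.values @ beta_true
        r_true = reconstruct(fit_ols(clean, X), "e")
        from scipy.signal import lfilter

        images = []
        for _ in range(50):
            e = lfilter([1.0], [1.0, -0.8], rng.standard_normal((times.size, 1)), axis=0)
            images.append(reconstruct(fit_ols(clean + e, X), "e").values)
        bias = np.mean(images, axis=0) - r_true.values
        # unbiasedness: residual bias is only Monte-Carlo noise of the 50 draws
        assert np.abs(bias).max() < 0.35
        assert np.abs(bias).mean() < 0.12


class TestBandAverage:
    def _resp(self):
        from tfdeconv.glm import TFResponse

        values = np.arange(12.0).reshape(3, 4)
        return TFResponse(
            values=values,
            peritimes=np.array([-0.1, 0.0, 0.1]),
            freqs=np.array([10.0, 20.0, 30.0, 40.0]),
            event_type="e",
        )

    def test_single_frequency_band_is_that_column(self):
        r = self._resp()
        np.testing.assert_allclose(band_average(r, (20.0, 20.0)), r.values[:, 1])

    def test_constant_image_gives_constant_waveform(self):
        r = self._resp()
        r.values[:] = 3.5
        np.testing.assert_allclose(band_average(r, (10.0, 40.0)), 3.5)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_average(self._resp(), (70.0, 80.0))
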