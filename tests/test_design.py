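"""Basis sets, convolution regressors, drift block, high-pass filtering."""

import numpy as np
import pytest

from tfdeconv.basis import make_basis
from tfdeconv.design import (
    EventRegressorSpec,
    assemble_design,
    build_event_regressors,
    dct_drift_regressors,
    highpass_design_and_data,
)

FS = 20.0
TIMES = np.arange(0.2, 100.0, 1 / FS)


class TestMakeBasis:
    @pytest.mark.parametrize("order,n_cols", [(11, 22), (1, 2)])
    def test_fourier_column_count(self, order, n_cols):
        b = make_basis("fourier", order, (-2, 2), FS)
        assert b.values.shape == (81, n_cols)

    def test_fir_partition_of_unity(self):
        b = make_basis("fir", 8, (-2, 2), FS)
        assert b.values.shape[1] == 8
        np.testing.assert_allclose(b.values.sum(axis=1), 1.0)

    def test_fourier_columns_nearly_orthogonal(self):
        b = make_basis("fourier", 5, (-2, 2), FS)
        g = b.values.T @ b.values
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 0.05 * np.diag(g).min()

    def test_hanning_tapers_edges(self):
        b = make_basis("fourier_hanning", 3, (-2, 2), FS)
        assert np.abs(b.values[0]).max() < 1e-12
        assert np.abs(b.values[-1]).max() < 1e-12

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_basis("gamma", 3, (-2, 2), FS)


class TestEventRegressors:
    def test_single_delta_places_shifted_basis(self):
        basis = make_basis("fir", 8, (-2, 2), FS)
        onset = 10.0
        block = build_event_regressors([onset], EventRegressorSpec("e"), basis, TIMES)
        b0 = int(round((onset - TIMES[0]) * FS))
        lo = b0 + round(basis.window[0] * FS)
        np.testing.assert_allclose(block[lo : lo + basis.n_bins, :], basis.values)
        mask = np.ones(len(TIMES), bool)
        mask[lo : lo + basis.n_bins] = False
        assert not block[mask].any()

    def test_superposition_of_isolated_events(self):
        basis = make_basis("fourier", 4, (-2, 2), FS)
        spec = EventRegressorSpec("e")
        one = build_event_regressors([10.0], spec, basis, TIMES)
        two = build_event_regressors([30.0], spec, basis, TIMES)
        both = build_event_regressors([10.0, 30.0], spec, basis, TIMES)
        np.testing.assert_allclose(both, one + two, atol=1e-12)

    def test_modulator_linearity(self):
        basis = make_basis("fourier", 3, (-2, 2), FS)
        onsets = [10.0, 30.0, 50.0]
        singles = [
            build_event_regressors([o], EventRegressorSpec("e"), basis, TIMES)
            for o in onsets
        ]
        spec = EventRegressorSpec("e", modulator_values=[2.0, 0.0, 1.0], center_modulator=False)
        block = build_event_regressors(onsets, spec, basis, TIMES)
        np.testing.assert_allclose(block, 2 * singles[0] + 0 * singles[1] + 1 * singles[2], atol=1e-12)

    def test_out_of_range_event_dropped(self, caplog):
        basis = make_basis("fourier", 2, (-2, 2), FS)
        with caplog.at_level("WARNING"):
            block = build_event_regressors(
                [500.0], EventRegressorSpec("e"), basis, TIMES
            )
        assert not block.any()
        assert "dropped" in caplog.text

    def test_boxcar_covers_duration(self):
        basis = make_basis("fir", 80, (-2, 2), FS)
        spec = EventRegressorSpec("e", input_kind="boxcar")
        block = build_event_regressors(
            [10.0], spec, basis, TIMES, durations=np.array([1.0])
        )
        # boxcar of 1 s convolved with the tiling gives 20x the single-delta mass
        single = build_event_regressors([10.0], EventRegressorSpec("e"), basis, TIMES)
        assert block.sum() == pytest.approx(20 * single.sum())


class TestDriftBlock:
    def test_cutoff_zero_constant_only(self):
        d = dct_drift_regressors(500, FS, 0.0)
        assert d.shape == (500, 1)
        assert np.ptp(d[:, 0]) == 0

    def test_column_count_formula(self):
        # 450 s of power at 20 Hz (approximate bin count 9000)
        d = dct_drift_regressors(9000, FS, 0.1)
        assert d.shape[1] == 90 + 1

    def test_orthogonality(self):
        d = dct_drift_regressors(400, FS, 0.5)
        g = d.T @ d
        np.testing.assert_allclose(g, np.eye(d.shape[1]), atol=1e-10)


class TestAssemble:
    def test_widths_add(self):
        basis = make_basis("fourier", 3, (-2, 2), FS)
        spec = EventRegressorSpec("a")
        b1 = build_event_regressors([10.0], spec, basis, TIMES)
        b2 = build_event_regressors([30.0], spec, basis, TIMES)
        X = assemble_design(event_blocks={"a": b1, "b": b2}, basis=basis)
        assert X.n_columns == b1.shape[1] + b2.shape[1]
        assert len(X.columns) == X.n_columns
        assert X.event_types == ["a", "b"]

    def test_identical_event_lists_flagged(self):
        basis = make_basis("fourier", 3, (-2, 2), FS)
        block = build_event_regressors([10.0, 30.0], EventRegressorSpec("a"), basis, TIMES)
        X = assemble_design(event_blocks={"a": block, "b": block.copy()}, basis=basis)
        assert X.efficiency["max_inter_event_corr"] == pytest.approx(1.0)

    def test_default_simulation_design_not_degenerate(self, short_sim, short_power):
        from tfdeconv.experiments import events_frame
        from tfdeconv.model import InducedResponseModel

        model = InducedResponseModel(short_power, events_frame(short_sim))
        assert model.design.efficiency["max_inter_event_corr"] < 1.0


class TestHighpass:
    def test_cutoff_zero_removes_mean(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((300, 2)) + 5.0
        X = rng.standard_normal((300, 3))
        Yf, Xf = highpass_design_and_data(Y, X, 0.0, FS)
        np.testing.assert_allclose(Yf.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xf.mean(axis=0), 0.0, atol=1e-10)

    def test_constant_column_zeroed_and_flagged(self, caplog):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(300), rng.standard_normal(300)])
        with caplog.at_level("WARNING"):
            _, Xf = highpass_design_and_data(rng.standard_normal((300, 1)), X, 0.25, FS)
        assert np.abs(Xf[:, 0]).max() < 1e-10
        assert "remove" in caplog.text

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((300, 2))
        X = rng.standard_normal((300, 3))
        Y1, X1 = highpass_design_and_data(Y, X, 0.25, FS)
        Y2, X2 = highpass_design_and_data(Y1, X1, 0.25, FS)
        np.testing.assert_allclose(Y1, Y2, atol=1e-10)
        np.testing.assert_allclose(X1, X2, atol=1e-10)
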