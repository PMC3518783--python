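"""Statsmodels-style front end: InducedResponseModel / InducedResponseResults.

`InducedResponseModel` binds a continuous time-frequency power matrix to an
event table and a convolution design (peristimulus basis set plus
discrete-cosine drift block); `fit()` estimates the GLM by ordinary or
weighted least squares and returns an `InducedResponseResults` holding the
coefficients, residual diagnostics and reconstruction methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averaging import average_baseline, epoch
from .basis import BasisSet, make_basis
from .design import (
    DesignMatrix,
    EventRegressorSpec,
    assemble_design,
    build_event_regressors,
    dct_drift_regressors,
)
from .glm import GLMFit, TFResponse, artifact_weights, band_average, fit_ols, fit_wls, reconstruct
from .signal import ContinuousSignal
from .spectral import SpectralConfig, TFPower, apply_transform, mtm_spectrogram

__all__ = ["InducedResponseModel", "InducedResponseResults"]


class InducedResponseModel:
    """Convolution GLM for induced time-frequency responses.

    Parameters
    ----------
    power : TFPower
        Continuous power matrix Y (time x frequency), already transformed
        if desired.
    events : pandas.DataFrame
        Columns ``onset_s`` and ``event_type``; optional ``value`` holds a
        parametric modulator (used for event types listed in
        ``modulated_types``).
    basis : str or BasisSet, default "fourier"
        Peristimulus basis family; built at ``order`` over ``window`` when
        given as a string.
    order : int, default 11
        Basis order (a Fourier set of order q has 2q functions).
    window : (float, float), default (-2, 2)
        Peristimulus window in seconds.
    drift_cutoff_hz : float, default 0.1
        Upper frequency of the discrete-cosine drift block (0 keeps only
        the constant).
    modulated_types : sequence of str, optional
        Event types that additionally get a parametric-modulator block
        scaled by mean-centred ``value``.
    """

    def __init__(
        self,
        power: TFPower,
        events: pd.DataFrame,
        basis: str | BasisSet = "fourier",
        order: int = 11,
        window: tuple[float, float] = (-2.0, 2.0),
        drift_cutoff_hz: float = 0.1,
        modulated_types: tuple[str, ...] = (),
    ) -> None:
        self.power = power
        self.events = events.sort_values("onset_s").reset_index(drop=True)
        if isinstance(basis, BasisSet):
            self.basis = basis
        else:
            self.basis = make_basis(basis, order, window, power.fs_power)
        self.drift_cutoff_hz = drift_cutoff_hz
        self.modulated_types = tuple(modulated_types)
        self.design = self._build_design()

    @classmethod
    def from_signal(
        cls,
        signal: ContinuousSignal,
        events: pd.DataFrame,
        spectral: SpectralConfig | None = None,
        transform: str = "sqrt",
        **kwargs,
    ) -> "InducedResponseModel":
        """Convenience constructor running the spectral stage internally."""
        spectral = spectral or SpectralConfig()
        power = mtm_spectrogram(signal, spectral)
        if transform != "none":
            power = apply_transform(power, transform)
        return cls(power, events, **kwargs)

    def _build_design(self) -> DesignMatrix:
        times = self.power.times
        event_blocks: dict[str, np.ndarray] = {}
        modulator_blocks: dict[str, np.ndarray] = {}
        for ev_type, grp in self.events.groupby("event_type", sort=False):
            onsets = grp["onset_s"].to_numpy(dtype=float)
            spec = EventRegressorSpec(event_type=str(ev_type))
            event_blocks[str(ev_type)] = build_event_regressors(
                onsets, spec, self.basis, times
            )
            if str(ev_type) in self.modulated_types:
                if "value" not in grp:
                    raise ValueError(f"no modulator values for event type {ev_type!r}")
                mspec = EventRegressorSpec(
                    event_type=str(ev_type),
                    modulator_values=grp["value"].to_numpy(dtype=float),
                )
                modulator_blocks[str(ev_type)] = build_event_regressors(
                    onsets, mspec, self.basis, times
                )
        drift = dct_drift_regressors(times.size, self.power.fs_power, self.drift_cutoff_hz)
        return assemble_design(
            event_blocks=event_blocks,
            basis=self.basis,
            drift=drift,
            modulator_blocks=modulator_blocks,
        )

    def fit(
        self,
        method: str = "ols",
        weights: np.ndarray | None = None,
        artifact_signal: ContinuousSignal | None = None,
        artifact_threshold: float = 2.0,
        win_s: float = 0.4,
    ) -> "InducedResponseResults":
        """Estimate the GLM.

        method : {"ols", "wls"}
            ``wls`` requires either explicit per-bin ``weights`` or an
            ``artifact_signal`` from which weights are derived by amplitude
            thresholding.
        """
        if method == "ols":
            fit = fit_ols(self.power, self.design)
        elif method == "wls":
            if weights is None:
                if artifact_signal is None:
                    raise ValueError("wls needs weights or an artifact_signal")
                weights = artifact_weights(
                    artifact_signal, artifact_threshold, win_s, self.power.times
                )
            fit = fit_wls(self.power, self.design, weights)
        else:
            raise ValueError(f"unknown method {method!r}")
        return InducedResponseResults(model=self, glm=fit)


@dataclass
class InducedResponseResults:
    """Fitted convolution model: coefficients, diagnostics, reconstructions."""

    model: InducedResponseModel
    glm: GLMFit

    @property
    def params(self) -> np.ndarray:
        """n x f coefficient matrix."""
        return self.glm.beta

    @property
    def df_resid(self) -> int:
        return self.glm.dof

    @property
    def rss(self) -> np.ndarray:
        return self.glm.rss

    def response(self, event_type: str, modulator: bool = False) -> TFResponse:
        """Deconvolved impulse-response image R = B beta for one event type."""
        return reconstruct(self.glm, event_type, modulator=modulator)

    def band_waveform(
        self, event_type: str, band: tuple[float, float], modulator: bool = False
    ) -> np.ndarray:
        """Band-averaged peristimulus waveform of the reconstructed image."""
        return band_average(self.response(event_type, modulator=modulator), band)

    def comparator_average(
        self,
        event_type: str,
        window: tuple[float, float] | None = None,
        baseline_window: tuple[float, float] = (-2.0, -1.5),
    ) -> TFResponse:
        """Post-hoc epoch average for the same event type (the comparator)."""
        window = window or self.model.basis.window
        onsets = self.model.events.query("event_type == @event_type")["onset_s"].to_numpy()
        epochs = epoch(self.model.power, onsets, window, event_type=event_type)
        return average_baseline(epochs, baseline_window)

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        m = self.model
        lines = [
            "Induced-response convolution model",
            "==================================",
            f"time bins:            {m.power.n_times}",
            f"frequencies:          {m.power.freqs.size} "
            f"({m.power.freqs[0]:g}-{m.power.freqs[-1]:g} Hz)",
            f"power transform:      {m.power.transform}",
            f"basis:                {m.basis.kind} order {m.basis.order} "
            f"({m.basis.n_funcs} functions over [{m.basis.window[0]:g}, {m.basis.window[1]:g}] s)",
            f"design columns:       {m.design.n_columns} (rank {self.glm.rank})",
            f"residual dof:         {self.df_resid}",
            f"estimator:            {'WLS' if self.glm.weights is not None else 'OLS'}",
            f"max inter-event corr: {m.design.efficiency.get('max_inter_event_corr', float('nan')):.3f}",
            "",
            "event type        peak |R|   at time (s)   at freq (Hz)",
        ]
        for ev in m.design.event_types:
            r = self.response(ev)
            i, j = np.unravel_index(np.abs(r.values).argmax(), r.values.shape)
            lines.append(
                f"{ev:<16}  {r.values[i, j]:+8.4f}   {r.peritimes[i]:+10.2f}   {r.freqs[j]:10.1f}"
            )
        return "\n".join(lines)

    def plot_response(self, event_type: str, ax=None, **kw):
        return self.response(event_type).plot(ax=ax, **kw)
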