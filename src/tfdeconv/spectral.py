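"""Multitaper sliding-window time-frequency power estimation.

Power is estimated on a sliding 0.4 s window stepped every 0.05 s, at
frequencies 2.5:2.5:90 Hz by default. The frequency smoothing (half
bandwidth) follows a piecewise rule — 2.5 Hz up to 25 Hz, 0.1·f between 25
and 50 Hz, constant 5 Hz above — and the number of Slepian (DPSS) tapers per
frequency follows the standard 2TW−1 rule with that smoothing, giving 1
taper for 2.5–30 Hz, 2 for 32.5–42.5 Hz and 3 from 45 Hz upward under the
default window. Power is averaged over tapers so the taper count does not
change the expected power level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import dpss

from .signal import ContinuousSignal

__all__ = [
    "SpectralConfig",
    "TFPower",
    "freq_resolution",
    "taper_count",
    "mtm_spectrogram",
    "apply_transform",
]


def _default_freqs() -> np.ndarray:
    return np.arange(2.5, 90.0 + 1e-9, 2.5)


@dataclass
class SpectralConfig:
    """Sliding-window multitaper settings."""

    win_s: float = 0.4
    step_s: float = 0.05
    freqs: np.ndarray = field(default_factory=_default_freqs)
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.win_s <= 0 or self.step_s <= 0:
            raise ValueError("win_s and step_s must be positive")
        self.freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        if self.transform not in ("none", "sqrt", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class TFPower:
    """Time x frequency power matrix with axis metadata.

    ``values[i, j]`` is the power in window centred at ``times[i]`` at
    frequency ``freqs[j]``; ``fs_power = 1/step_s`` is the sampling rate of
    the power time axis.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    transform: str = "none"
    fs_power: float = 20.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values shape does not match axes")

    @property
    def n_times(self) -> int:
        return self.times.size


def freq_resolution(f: float) -> float:
    """Frequency smoothing (half bandwidth, Hz) at analysis frequency ``f``.

    2.5 Hz (the inverse of the 0.4 s window) up to 25 Hz, one tenth of the
    frequency between 25 and 50 Hz, then a constant 5 Hz. Continuous in
    ``f``, so the resulting images have no discontinuities in frequency.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f <= 25.0:
        return 2.5
    if f <= 50.0:
        return 0.1 * f
    return 5.0


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def taper_count(f: float, win_s: float) -> int:
    """Number of DPSS tapers at frequency ``f`` for window length ``win_s``.

    K = max(1, round(2 * win_s * freq_resolution(f)) - 1), rounding half
    away from zero. With the default 0.4 s window this yields a single taper
    for 2.5-30 Hz, two for 32.5-42.5 Hz and three from 45 Hz upward.
    """
    if win_s <= 0:
        raise ValueError("win_s must be positive")
    return max(1, _round_half_away(2.0 * win_s * freq_resolution(f)) - 1)


@lru_cache(maxsize=256)
def _dpss_cached(win_len: int, nw: float, k: int) -> np.ndarray:
    tapers = dpss(win_len, nw, Kmax=k, norm=2)
    return np.atleast_2d(tapers)


def mtm_spectrogram(signal: ContinuousSignal, cfg: SpectralConfig) -> TFPower:
    """Multitaper spectrogram of a continuous signal.

    Windows are interior-only (no padding): the time axis starts at
    ``win_s/2`` and the power series is shorter than the raw signal by one
    window length. Each frequency uses its own taper family with
    time-bandwidth product ``win_s * freq_resolution(f)``; per-frequency
    power is the average over tapers of the squared demodulated projection,
    scaled as a one-sided density (2/fs).
    """
    fs = signal.fs
    win_len = round(cfg.win_s * fs)
    step = round(cfg.step_s * fs)
    x = signal.values
    if x.size < win_len:
        raise ValueError("signal shorter than the analysis window")
    if np.any(cfg.freqs >= fs / 2):
        raise ValueError("analysis frequencies must lie below Nyquist")

    windows = sliding_window_view(x, win_len)[::step]  # (n_wins, win_len)
    n_wins = windows.shape[0]
    times = cfg.win_s / 2 + np.arange(n_wins) * cfg.step_s

    tt = np.arange(win_len) / fs
    power = np.empty((n_wins, cfg.freqs.size))
    for j, f in enumerate(cfg.freqs):
        bw = freq_resolution(f)
        k = taper_count(f, cfg.win_s)
        tapers = _dpss_cached(win_len, cfg.win_s * bw, k)
        carrier = np.exp(-2j * np.pi * f * tt)
        # (win_len, k) complex projection vectors
        proj = (tapers * carrier).T.conj()
        coef = windows @ proj
        power[:, j] = (np.abs(coef) ** 2).mean(axis=1) * (2.0 / fs)

    out = TFPower(
        values=power,
        times=times,
        freqs=cfg.freqs.copy(),
        transform="none",
        fs_power=1.0 / cfg.step_s,
    )
    if cfg.transform != "none":
        out = apply_transform(out, cfg.transform)
    return out


def apply_transform(p: TFPower, kind: str, log_eps: float | None = None) -> TFPower:
    """Elementwise power transform: none, sqrt, or log.

    ``log`` uses log(x + eps) with eps defaulting to 1e-12 times the median
    power, to keep exact zeros finite without distorting in-range values.
    """
    if kind == "none":
        return replace(p, values=p.values.copy())
    if np.any(p.values < 0):
        raise ValueError("power must be non-negative before transforming")
    if kind == "sqrt":
        values = np.sqrt(p.values)
    elif kind == "log":
        if log_eps is None:
            med = float(np.median(p.values))
            log_eps = 1e-12 * med if med > 0 else np.finfo(float).tiny
        values = np.log(p.values + log_eps)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return replace(p, values=values, transform=kind)
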