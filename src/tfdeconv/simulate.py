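"""Synthetic induced-response signals.

Generates continuous band-limited-noise carriers whose amplitude is modulated
by Gaussian bumps: event-related synchronisation (ERS, an amplitude increase)
on a regular grid of onsets, and event-related desynchronisation (ERD, an
amplitude decrease) in a random subset of trials at a variable latency after
the ERS. Components can be mixed at the "source" level (one carrier carries
both modulations) or at the "sensor" level (two independently modulated
carriers summed), optionally with additive white noise. Noise-free
single-component ground-truth traces are emitted alongside the mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal import ContinuousSignal

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimOutput",
    "bandlimited_noise",
    "bump_modulation",
    "simulate",
    "add_spikes",
]


@dataclass
class SimConfig:
    """Parameters of the simulated induced-response recording.

    Defaults reproduce the reference scenario: a 450 s beta-band (15–35 Hz)
    carrier of unit standard deviation, ERS events every 5 s with a +100%
    amplitude bump (sigma 125 ms), ERD with a −90% bump (sigma 250 ms) in a
    random half of the trials, at a normally distributed latency after the
    ERS.
    """

    duration_s: float = 450.0
    fs: float = 200.0
    carrier_band: tuple[float, float] = (15.0, 35.0)
    carrier_sd: float = 1.0
    ers_interval_s: float = 5.0
    ers_sigma_s: float = 0.125
    ers_gain: float = 1.0
    erd_sigma_s: float = 0.250
    erd_gain: float = 0.9
    erd_probability: float = 0.5
    latency_mean_s: float = 0.0
    latency_sd_s: float = 0.0
    mixing: str = "source"
    noise_sd: float = 0.0
    seed: int = 0
    # First ERS onset sits at 2x this so a full peristimulus epoch fits.
    epoch_halfwidth_s: float = 2.0

    def __post_init__(self) -> None:
        low, high = self.carrier_band
        if not (0 < low < high < self.fs / 2):
            raise ValueError(f"carrier band {self.carrier_band} outside (0, fs/2)")
        if not 0 <= self.erd_gain <= 1:
            raise ValueError("erd_gain must lie in [0, 1]")
        if not 0 <= self.erd_probability <= 1:
            raise ValueError("erd_probability must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mixing not in ("source", "sensor"):
            raise ValueError(f"unknown mixing {self.mixing!r}")


@dataclass
class SimOutput:
    """Simulated recording plus event lists and noise-free ground truth."""

    signal: ContinuousSignal
    ers_onsets: np.ndarray
    erd_onsets: np.ndarray
    truth_ers: ContinuousSignal
    truth_erd: ContinuousSignal
    config: SimConfig = field(repr=False, default=None)


def bandlimited_noise(
    duration_s: float,
    fs: float,
    band: tuple[float, float],
    sd: float,
    seed: int | np.random.Generator,
) -> ContinuousSignal:
    """Band-pass-filtered Gaussian white noise rescaled to a target sd.

    A 4th-order Butterworth band-pass is applied forward and backward
    (zero phase); the result is rescaled so its sample standard deviation
    equals ``sd`` exactly. ``sd = 0`` yields an all-zero trace.
    """
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} outside (0, fs/2)")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = round(duration_s * fs)
    if sd == 0:
        return ContinuousSignal(np.zeros(n), fs)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x *= sd / x.std()
    return ContinuousSignal(x, fs)


def bump_modulation(
    onsets: np.ndarray,
    sigma_s: float,
    gain: float,
    sign: float,
    duration_s: float,
    fs: float,
) -> np.ndarray:
    """Sum of Gaussian amplitude bumps, one per onset.

    Each bump is ``sign * gain * exp(-(t - onset)^2 / (2 sigma^2))`` and
    peaks at exactly ``sign * gain`` at its onset. Onsets outside the
    recording simply contribute their tails.
    """
    n = round(duration_s * fs)
    wave = np.zeros(n)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        return wave
    half = 6.0 * sigma_s  # beyond 6 sigma a bump is numerically negligible
    t = np.arange(n) / fs
    for onset in onsets:
        lo = max(0, int(np.floor((onset - half) * fs)))
        hi = min(n, int(np.ceil((onset + half) * fs)) + 1)
        if hi <= lo:
            continue
        seg = t[lo:hi] - onset
        wave[lo:hi] += sign * gain * np.exp(-(seg**2) / (2 * sigma_s**2))
    return wave


def _ers_onset_grid(cfg: SimConfig) -> np.ndarray:
    start = 2.0 * cfg.epoch_halfwidth_s
    return np.arange(start, cfg.duration_s + 1e-9, cfg.ers_interval_s)


def simulate(cfg: SimConfig) -> SimOutput:
    """Generate a simulated recording according to ``cfg``.

    ERS onsets lie on a regular grid; ERD onsets are a random
    ``erd_probability`` subset of the ERS onsets shifted by
    ``Normal(latency_mean_s, latency_sd_s)`` draws. With source mixing a
    single carrier is multiplied by ``1 + ERS bumps - ERD bumps`` (floored
    at 0); with sensor mixing two independent carriers are modulated
    separately and summed. The noise-free single-component traces
    ``truth_ers`` / ``truth_erd`` reuse the same carriers and onsets.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_c1, rng_c2, rng_sel, rng_lat, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    ers_onsets = _ers_onset_grid(cfg)
    n_ers = ers_onsets.size
    with_erd = rng_sel.random(n_ers) < cfg.erd_probability
    latencies = rng_lat.normal(cfg.latency_mean_s, cfg.latency_sd_s, size=int(with_erd.sum()))
    erd_onsets = ers_onsets[with_erd] + latencies

    carrier1 = bandlimited_noise(cfg.duration_s, cfg.fs, cfg.carrier_band, cfg.carrier_sd, rng_c1)
    ers_bumps = bump_modulation(
        ers_onsets, cfg.ers_sigma_s, cfg.ers_gain, +1.0, cfg.duration_s, cfg.fs
    )
    erd_bumps = bump_modulation(
        erd_onsets, cfg.erd_sigma_s, cfg.erd_gain, +1.0, cfg.duration_s, cfg.fs
    )

    if cfg.mixing == "source":
        mod = 1.0 + ers_bumps - erd_bumps
        n_clipped = int((mod < 0).sum())
        if n_clipped:
            logger.warning(
                "source-mixing amplitude modulation clipped at 0 in %d samples", n_clipped
            )
            mod = np.clip(mod, 0.0, None)
        values = carrier1.values * mod
    else:  # sensor
        carrier2 = bandlimited_noise(
            cfg.duration_s, cfg.fs, cfg.carrier_band, cfg.carrier_sd, rng_c2
        )
        values = carrier1.values * (1.0 + ers_bumps) + carrier2.values * (1.0 - erd_bumps)

    if cfg.noise_sd > 0:
        values = values + rng_noise.normal(0.0, cfg.noise_sd, size=values.size)

    # Single-component, noise-free ground truth on the same carriers/onsets.
    if cfg.mixing == "source":
        truth_ers = ContinuousSignal(carrier1.values * (1.0 + ers_bumps), cfg.fs)
        truth_erd = ContinuousSignal(carrier1.values * (1.0 - erd_bumps), cfg.fs)
    else:
        carrier2 = bandlimited_noise(
            cfg.duration_s, cfg.fs, cfg.carrier_band, cfg.carrier_sd, rng_c2
        )
        truth_ers = ContinuousSignal(carrier1.values * (1.0 + ers_bumps), cfg.fs)
        truth_erd = ContinuousSignal(carrier2.values * (1.0 - erd_bumps), cfg.fs)

    return SimOutput(
        signal=ContinuousSignal(values, cfg.fs),
        ers_onsets=ers_onsets,
        erd_onsets=erd_onsets,
        truth_ers=truth_ers,
        truth_erd=truth_erd,
        config=cfg,
    )


def add_spikes(
    signal: ContinuousSignal,
    n_spikes: int,
    amplitude: float,
    seed: int | np.random.Generator,
) -> tuple[ContinuousSignal, np.ndarray]:
    """Add ``amplitude`` to ``n_spikes`` distinct random samples.

    Returns the contaminated signal and the (sorted) spike sample indices.
    """
    if n_spikes > signal.n_samples:
        raise ValueError("more spikes than samples")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(signal.n_samples, size=n_spikes, replace=False))
    values = signal.values.copy()
    values[idx] += amplitude
    return ContinuousSignal(values, signal.fs), idx
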