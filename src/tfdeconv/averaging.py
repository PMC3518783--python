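"""Conventional post-hoc epoching, averaging and baseline correction.

The comparator method: continuous power is epoched around event onsets,
averaged over trials and baseline-corrected per frequency. It works well for
isolated events with fixed timing but mixes overlapping response components
with variable relative latencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .glm import TFResponse
from .spectral import TFPower

logger = logging.getLogger(__name__)

__all__ = ["EpochSet", "epoch", "average_baseline"]


@dataclass
class EpochSet:
    """trial x peristimulus-time x frequency array of power epochs."""

    epochs: np.ndarray
    peritimes: np.ndarray
    freqs: np.ndarray
    event_type: str = ""

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


def epoch(
    power: TFPower,
    onsets: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    event_type: str = "",
) -> EpochSet:
    """Extract peristimulus epochs around each onset (nearest-bin aligned).

    Events whose window would extend past the power series are dropped with
    a log entry; an empty result is an error.
    """
    t_min, t_max = window
    if not t_max > t_min:
        raise ValueError("degenerate window")
    fs = power.fs_power
    n_before = round(-t_min * fs)
    n_after = round(t_max * fs)
    peritimes = np.arange(-n_before, n_after + 1) / fs
    t = power.n_times
    out = []
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    for onset in onsets:
        c = int(round((onset - power.times[0]) * fs))
        lo, hi = c - n_before, c + n_after + 1
        if lo < 0 or hi > t:
            logger.info("epoch at %.3f s exceeds the recording; dropped", onset)
            continue
        out.append(power.values[lo:hi, :])
    if not out:
        raise ValueError("no valid epochs inside the power series")
    return EpochSet(
        epochs=np.stack(out), peritimes=peritimes, freqs=power.freqs, event_type=event_type
    )


def average_baseline(
    e: EpochSet, baseline_window: tuple[float, float] = (-2.0, -1.5)
) -> TFResponse:
    """Trial mean followed by per-frequency baseline subtraction.

    The baseline is the mean over peristimulus bins inside
    ``baseline_window``, subtracted from every time bin of that frequency.
    """
    b_lo, b_hi = baseline_window
    mask = (e.peritimes >= b_lo - 1e-9) & (e.peritimes <= b_hi + 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {baseline_window} outside the epoch")
    mean = e.epochs.mean(axis=0)
    baseline = mean[mask, :].mean(axis=0)
    return TFResponse(
        values=mean - baseline,
        peritimes=e.peritimes,
        freqs=e.freqs,
        event_type=e.event_type,
        method="averaging",
    )
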