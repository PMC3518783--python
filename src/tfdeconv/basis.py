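"""Peristimulus impulse-response basis sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BasisSet", "make_basis"]


@dataclass
class BasisSet:
    """p x m matrix of basis functions of peristimulus time.

    ``values[:, j]`` samples basis function j on ``peritimes`` (seconds,
    spanning ``window``); a Fourier set of order q has m = 2q columns
    (q sines followed by q cosines, no constant term — the mean belongs to
    the drift block), an FIR set of order q has q unit boxes tiling the
    window.
    """

    values: np.ndarray
    window: tuple[float, float]
    kind: str
    order: int
    peritimes: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_funcs(self) -> int:
        return self.values.shape[1]


def make_basis(
    kind: str, order: int, window: tuple[float, float], fs_power: float
) -> BasisSet:
    """Construct a basis set over a peristimulus window.

    kind : {"fourier", "fourier_hanning", "fir"}
        ``fourier`` — sines and cosines of 1..order cycles over the window;
        ``fourier_hanning`` — the same multiplied by a Hann taper, for
        responses concentrated in the window centre; ``fir`` — ``order``
        contiguous unit boxes tiling the window.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    t_min, t_max = window
    if not t_max > t_min:
        raise ValueError("degenerate window")
    p = round((t_max - t_min) * fs_power) + 1
    peritimes = t_min + np.arange(p) / fs_power
    u = (peritimes - t_min) / (t_max - t_min)  # normalised position in [0, 1]

    if kind in ("fourier", "fourier_hanning"):
        cols = [np.sin(2 * np.pi * k * u) for k in range(1, order + 1)]
        cols += [np.cos(2 * np.pi * k * u) for k in range(1, order + 1)]
        values = np.column_stack(cols)
        if kind == "fourier_hanning":
            values = values * np.hanning(p)[:, None]
    elif kind == "fir":
        edges = np.floor(np.linspace(0, p, order + 1)).astype(int)
        values = np.zeros((p, order))
        for j in range(order):
            values[edges[j] : edges[j + 1], j] = 1.0
    else:
        raise ValueError(f"unknown basis kind {kind!r}")

    return BasisSet(values=values, window=(t_min, t_max), kind=kind, order=order, peritimes=peritimes)
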