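"""Continuous single-channel signal container and disk round-trips."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np


@dataclass
class ContinuousSignal:
    """A continuous, uniformly sampled single-channel time-domain trace.

    Parameters
    ----------
    values : ndarray, shape (n,)
        Signal samples in arbitrary units.
    fs : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("signal", data=self.values)
            dset.attrs["fs"] = self.fs

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ContinuousSignal":
        with h5py.File(path, "r") as f:
            dset = f["signal"]
            return cls(values=dset[...], fs=float(dset.attrs["fs"]))

    def to_text(self, path: str | Path) -> None:
        """Single-column delimited text; the sampling rate travels separately."""
        np.savetxt(path, self.values, fmt="%.10g")

    @classmethod
    def from_text(cls, path: str | Path, fs: float) -> "ContinuousSignal":
        return cls(values=np.loadtxt(path), fs=fs)
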