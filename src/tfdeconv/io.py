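"""File formats and run configuration.

Event lists travel as 3-column TSV (onset_s, event_type, value; header row
required); arrays (continuous power, reconstructed images) live in HDF5
with their axes, with long-format TSV as a text fallback. The run
configuration is YAML, validated before any computation, and every run
writes its resolved configuration next to the outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .glm import TFResponse
from .spectral import SpectralConfig, TFPower

__all__ = [
    "read_events",
    "write_events",
    "write_tfpower",
    "read_tfpower",
    "write_tfresponse",
    "read_tfresponse",
    "tfpower_to_tsv",
    "RunConfig",
]

_EVENT_COLUMNS = ["onset_s", "event_type", "value"]


def read_events(path: str | Path) -> pd.DataFrame:
    """Parse an event TSV, validating onsets and sorting by onset.

    Errors name the offending line (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be "
                         f"{_EVENT_COLUMNS}")
    onsets = pd.to_numeric(df["onset_s"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(onsets.to_numpy()))
    if bad.size:
        raise ValueError(f"{path}: non-numeric onset_s on line {bad[0] + 2}")
    neg = np.flatnonzero(onsets.to_numpy() < 0)
    if neg.size:
        raise ValueError(f"{path}: negative onset_s on line {neg[0] + 2}")
    df["onset_s"] = onsets
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return df.sort_values("onset_s", kind="stable", ignore_index=True)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, _EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_tfpower(p: TFPower, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=p.values)
        f.create_dataset("times", data=p.times)
        f.create_dataset("freqs", data=p.freqs)
        f.attrs["transform"] = p.transform
        f.attrs["fs_power"] = p.fs_power


def read_tfpower(path: str | Path) -> TFPower:
    with h5py.File(path, "r") as f:
        return TFPower(
            values=f["power"][...],
            times=f["times"][...],
            freqs=f["freqs"][...],
            transform=str(f.attrs["transform"]),
            fs_power=float(f.attrs["fs_power"]),
        )


def write_tfresponse(r: TFResponse, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("response", data=r.values)
        f.create_dataset("peritimes", data=r.peritimes)
        f.create_dataset("freqs", data=r.freqs)
        f.attrs["event_type"] = r.event_type
        f.attrs["transform"] = r.transform
        f.attrs["method"] = r.method


def read_tfresponse(path: str | Path) -> TFResponse:
    with h5py.File(path, "r") as f:
        return TFResponse(
            values=f["response"][...],
            peritimes=f["peritimes"][...],
            freqs=f["freqs"][...],
            event_type=str(f.attrs["event_type"]),
            transform=str(f.attrs["transform"]),
            method=str(f.attrs["method"]),
        )


def tfpower_to_tsv(p: TFPower, path: str | Path) -> None:
    """Long-format text export: one (time, freq, power) row per cell."""
    t, f = np.meshgrid(p.times, p.freqs, indexing="ij")
    pd.DataFrame(
        {"time_s": t.ravel(), "freq_hz": f.ravel(), "power": p.values.ravel()}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Resolved analysis configuration for one pipeline run."""

    win_s: float = 0.4
    step_s: float = 0.05
    freq_lo: float = 2.5
    freq_hi: float = 90.0
    freq_step: float = 2.5
    transform: str = "sqrt"
    basis_kind: str = "fourier"
    basis_order: int = 11
    window: tuple[float, float] = (-2.0, 2.0)
    drift_cutoff_hz: float = 0.1
    artifact_threshold: float | None = None
    modulated_types: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transform not in ("none", "sqrt", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.basis_kind not in ("fourier", "fourier_hanning", "fir"):
            raise ValueError(f"unknown basis kind {self.basis_kind!r}")
        if self.basis_order < 1:
            raise ValueError("basis_order must be >= 1")
        if not self.window[1] > self.window[0]:
            raise ValueError("degenerate peristimulus window")
        if self.drift_cutoff_hz < 0:
            raise ValueError("drift_cutoff_hz must be >= 0")
        if self.artifact_threshold is not None and self.artifact_threshold <= 0:
            raise ValueError("artifact_threshold must be positive")

    def spectral(self) -> SpectralConfig:
        freqs = np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)
        return SpectralConfig(win_s=self.win_s, step_s=self.step_s, freqs=freqs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["window"] = list(self.window)
        d["modulated_types"] = list(self.modulated_types)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "window" in d:
            d["window"] = tuple(d["window"])
        if "modulated_types" in d:
            d["modulated_types"] = tuple(d["modulated_types"])
        return cls(**d)
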