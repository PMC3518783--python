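"""Convolution design matrices.

Regressors are built by convolving input (stimulus) functions — delta trains
at event onsets, boxcars, or continuous covariates, optionally scaled
trial-wise by a parametric modulator — with a peristimulus basis set, and
are complemented by a discrete-cosine drift block that plays the role of
baseline correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet

logger = logging.getLogger(__name__)

__all__ = [
    "EventRegressorSpec",
    "ColumnInfo",
    "DesignMatrix",
    "build_event_regressors",
    "dct_drift_regressors",
    "assemble_design",
    "highpass_design_and_data",
]


@dataclass
class EventRegressorSpec:
    """How one event type enters the design.

    ``input_kind`` selects the stimulus function: "delta" places a unit
    impulse at the nearest power bin to each onset, "boxcar" a unit box over
    [onset, onset + duration], "continuous" uses a user-supplied series on
    the power time axis. ``modulator_values`` (one scalar per event) scale
    the impulses trial-wise; mean-centred by default so the unmodulated
    block keeps the average-response interpretation.
    """

    event_type: str
    input_kind: str = "delta"
    modulator_values: np.ndarray | None = None
    center_modulator: bool = True

    def __post_init__(self) -> None:
        if self.input_kind not in ("delta", "boxcar", "continuous"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")


@dataclass
class ColumnInfo:
    """Provenance of one design-matrix column."""

    kind: str  # "event" or "drift"
    event_type: str | None = None
    basis_index: int | None = None
    modulator: bool = False
    drift_index: int | None = None


@dataclass
class DesignMatrix:
    """t x n regressor matrix with per-column provenance.

    ``efficiency`` holds the maximum absolute correlation between event
    columns belonging to different event types — a design-efficiency
    diagnostic: correlated regressors make responses hard to attribute
    uniquely.
    """

    values: np.ndarray
    columns: list[ColumnInfo]
    basis: BasisSet | None = None
    efficiency: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def event_column_indices(self, event_type: str, modulator: bool = False) -> np.ndarray:
        idx = [
            i
            for i, c in enumerate(self.columns)
            if c.kind == "event" and c.event_type == event_type and c.modulator == modulator
        ]
        if not idx:
            raise KeyError(f"no columns for event type {event_type!r} (modulator={modulator})")
        return np.asarray(idx)

    @property
    def event_types(self) -> list[str]:
        seen: list[str] = []
        for c in self.columns:
            if c.kind == "event" and c.event_type not in seen:
                seen.append(c.event_type)
        return seen


def _input_function(
    onsets: np.ndarray,
    spec: EventRegressorSpec,
    times: np.ndarray,
    fs_power: float,
    durations: np.ndarray | None,
    continuous: np.ndarray | None,
) -> np.ndarray:
    t = times.size
    if spec.input_kind == "continuous":
        if continuous is None or len(continuous) != t:
            raise ValueError("continuous input requires a series on the power time axis")
        return np.asarray(continuous, dtype=float)

    scales = np.ones(onsets.size)
    if spec.modulator_values is not None:
        mod = np.asarray(spec.modulator_values, dtype=float)
        if mod.size != onsets.size:
            raise ValueError("one modulator value per event required")
        scales = mod - mod.mean() if spec.center_modulator else mod

    u = np.zeros(t)
    t0, t1 = times[0], times[-1]
    for i, onset in enumerate(onsets):
        if onset < t0 - 0.5 / fs_power or onset > t1 + 0.5 / fs_power:
            logger.warning("event at %.3f s outside power time axis; dropped", onset)
            continue
        b = int(round((onset - t0) * fs_power))
        b = min(max(b, 0), t - 1)
        if spec.input_kind == "delta":
            u[b] += scales[i]
        else:  # boxcar
            dur = 0.0 if durations is None else float(durations[i])
            b_end = min(t, b + max(1, int(round(dur * fs_power))))
            u[b:b_end] += scales[i]
    return u


def build_event_regressors(
    onsets: np.ndarray,
    spec: EventRegressorSpec,
    basis: BasisSet,
    times: np.ndarray,
    durations: np.ndarray | None = None,
    continuous: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve an event input function with each basis column.

    The basis window maps to lag relative to onset, so negative window
    starts produce acausal (pre-onset) lags; the result is truncated to the
    power time axis.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    fs_power = 1.0 / (times[1] - times[0])
    u = _input_function(onsets, spec, times, fs_power, durations, continuous)
    t = times.size
    t_min_bin = round(basis.window[0] * fs_power)  # negative for acausal windows
    block = np.empty((t, basis.n_funcs))
    pad = abs(t_min_bin)
    for j in range(basis.n_funcs):
        conv = np.convolve(u, basis.values[:, j])
        full = np.zeros(conv.size + 2 * pad)
        full[pad : pad + conv.size] = conv
        start = pad - t_min_bin
        block[:, j] = full[start : start + t]
    return block


def dct_drift_regressors(t: int, fs_power: float, cutoff_hz: float) -> np.ndarray:
    """Constant column plus discrete-cosine drifts up to ``cutoff_hz``.

    K = floor(2 * t * cutoff_hz / fs_power) cosine columns
    cos(pi k (2i + 1) / (2t)); together with the constant they form a
    mutually orthogonal DCT-II family absorbing slow power drifts.
    """
    if cutoff_hz < 0:
        raise ValueError("cutoff_hz must be >= 0")
    k_max = int(np.floor(2.0 * t * cutoff_hz / fs_power))
    i = np.arange(t)
    cols = [np.ones(t) / np.sqrt(t)]
    for k in range(1, k_max + 1):
        cols.append(np.sqrt(2.0 / t) * np.cos(np.pi * k * (2 * i + 1) / (2 * t)))
    return np.column_stack(cols)


def assemble_design(
    event_blocks: dict[str, np.ndarray] | None = None,
    basis: BasisSet | None = None,
    drift: np.ndarray | None = None,
    modulator_blocks: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """Concatenate event, modulator and drift blocks with provenance.

    Also computes the design-efficiency diagnostic: pairwise correlations
    between columns of different event blocks (high values flag events
    whose responses cannot be attributed uniquely).
    """
    blocks: list[np.ndarray] = []
    columns: list[ColumnInfo] = []
    event_blocks = event_blocks or {}
    modulator_blocks = modulator_blocks or {}

    t = None
    for name, block in list(event_blocks.items()) + list(modulator_blocks.items()):
        if t is None:
            t = block.shape[0]
        elif block.shape[0] != t:
            raise ValueError("event blocks have mismatched time lengths")
    if drift is not None:
        if t is None:
            t = drift.shape[0]
        elif drift.shape[0] != t:
            raise ValueError("drift block time length mismatch")

    for name, block in event_blocks.items():
        blocks.append(block)
        columns += [
            ColumnInfo(kind="event", event_type=name, basis_index=j)
            for j in range(block.shape[1])
        ]
    for name, block in modulator_blocks.items():
        blocks.append(block)
        columns += [
            ColumnInfo(kind="event", event_type=name, basis_index=j, modulator=True)
            for j in range(block.shape[1])
        ]
    if drift is not None:
        blocks.append(drift)
        columns += [ColumnInfo(kind="drift", drift_index=k) for k in range(drift.shape[1])]

    if not blocks:
        raise ValueError("no blocks to assemble")
    values = np.column_stack(blocks)

    efficiency: dict = {}
    names = list(event_blocks) + [f"{n} (modulator)" for n in modulator_blocks]
    all_event = list(event_blocks.values()) + list(modulator_blocks.values())
    max_corr = 0.0
    pair = None
    for a in range(len(all_event)):
        for b in range(a + 1, len(all_event)):
            ca = _safe_corr(all_event[a], all_event[b])
            m = float(np.nanmax(np.abs(ca))) if ca.size else 0.0
            if m > max_corr:
                max_corr, pair = m, (names[a], names[b])
    efficiency["max_inter_event_corr"] = max_corr
    efficiency["worst_pair"] = pair
    if max_corr > 1 - 1e-10 and pair is not None:
        logger.warning(
            "event regressors for %s and %s are perfectly correlated; "
            "responses cannot be attributed uniquely",
            *pair,
        )
    return DesignMatrix(values=values, columns=columns, basis=basis, efficiency=efficiency)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = ac.std(axis=0)
    sb = bc.std(axis=0)
    sa[sa == 0] = np.inf
    sb[sb == 0] = np.inf
    return (ac.T @ bc) / a.shape[0] / np.outer(sa, sb)


def highpass_design_and_data(
    Y: np.ndarray, X: np.ndarray, cutoff_hz: float, fs_power: float
) -> tuple[np.ndarray, np.ndarray]:
    """Residualise every column of Y and X against a DCT set up to cutoff.

    The identical projection is applied to data and design, so the fitted
    model is unchanged on the retained subspace. Cutoff 0 removes the mean
    only. Columns of X that become (near) zero — e.g. a constant column —
    are flagged in the log for removal.
    """
    t = Y.shape[0]
    if X.shape[0] != t:
        raise ValueError("Y and X must share the time axis")
    D = dct_drift_regressors(t, fs_power, cutoff_hz)  # orthonormal columns
    def proj(M: np.ndarray) -> np.ndarray:
        return M - D @ (D.T @ M)
    Yf, Xf = proj(Y), proj(X)
    scale = np.abs(X).max(axis=0)
    dead = np.flatnonzero(np.abs(Xf).max(axis=0) <= 1e-10 * np.maximum(scale, 1e-300))
    if dead.size:
        logger.warning("high-pass filtering zeroed design columns %s; remove them", dead.tolist())
    return Yf, Xf
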