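"""GLM estimation and reconstruction of induced time-frequency responses.

The continuous power matrix Y (time x frequency) is modelled as
Y = X beta + eps; beta is estimated per frequency by ordinary or weighted
least squares, and the event-specific impulse-response image is rebuilt as
R_i = B beta_i, a peristimulus-time x frequency image interpretable as the
deconvolved response the event would evoke in isolation. Weighted least
squares with near-zero weights on artefact-affected bins suppresses their
influence while keeping the series continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import DesignMatrix
from .signal import ContinuousSignal
from .spectral import TFPower

logger = logging.getLogger(__name__)

__all__ = [
    "GLMFit",
    "TFResponse",
    "fit_ols",
    "fit_wls",
    "artifact_weights",
    "reconstruct",
    "band_average",
    "ARTIFACT_WEIGHT",
]

#: weight assigned to power bins whose analysis window overlaps an artefact
ARTIFACT_WEIGHT = 2.0**-256

# weights at or below this count as zero when tallying effective time bins
_ZERO_WEIGHT_TOL = 2.0**-128


@dataclass
class GLMFit:
    """Least-squares fit of the convolution model.

    beta : (n, f) coefficients; rss : per-frequency residual sum of squares;
    dof : effective time bins (non-zero weight) minus design rank.
    """

    beta: np.ndarray
    dof: int
    rss: np.ndarray
    design: DesignMatrix
    rank: int
    weights: np.ndarray | None = None
    transform: str = "none"
    freqs: np.ndarray | None = None


@dataclass
class TFResponse:
    """Reconstructed peristimulus-time x frequency impulse-response image."""

    values: np.ndarray  # (p, f)
    peritimes: np.ndarray
    freqs: np.ndarray
    event_type: str
    transform: str = "none"
    method: str = "glm"

    def plot(self, ax=None, **imshow_kw):
        """Display the image (peristimulus time on x, frequency on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        extent = [self.peritimes[0], self.peritimes[-1], self.freqs[0], self.freqs[-1]]
        im = ax.imshow(
            self.values.T, origin="lower", aspect="auto", extent=extent, **imshow_kw
        )
        ax.set_xlabel("peristimulus time (s)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(f"{self.event_type} ({self.method})")
        return im


def fit_ols(Y: TFPower | np.ndarray, X: DesignMatrix) -> GLMFit:
    """Ordinary least squares fit, per frequency column.

    Rank-deficient designs are solved with the pseudoinverse and flagged
    with a warning rather than rejected (correlated regressors are a design
    problem, not an estimation failure).
    """
    values, transform, freqs = _as_matrix(Y)
    return _solve(values, X, weights=None, transform=transform, freqs=freqs)


def fit_wls(Y: TFPower | np.ndarray, X: DesignMatrix, weights: np.ndarray) -> GLMFit:
    """Weighted least squares: rows scaled by sqrt(weight), then OLS.

    Equivalent to a diagonal-covariance GLS (pre-whitening data and design
    by the inverse square-root of the noise covariance). Weights of
    ``ARTIFACT_WEIGHT`` are numerically indistinguishable from deleting the
    corresponding rows while keeping matrix shapes fixed.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")
    values, transform, freqs = _as_matrix(Y)
    if weights.size != values.shape[0]:
        raise ValueError("one weight per time bin required")
    return _solve(values, X, weights=weights, transform=transform, freqs=freqs)


def _as_matrix(Y: TFPower | np.ndarray) -> tuple[np.ndarray, str, np.ndarray | None]:
    if isinstance(Y, TFPower):
        return Y.values, Y.transform, Y.freqs
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, "none", None


def _solve(
    Y: np.ndarray,
    X: DesignMatrix,
    weights: np.ndarray | None,
    transform: str,
    freqs: np.ndarray | None = None,
) -> GLMFit:
    Xv = X.values
    if Y.shape[0] != Xv.shape[0]:
        raise ValueError("Y and X must share the time axis")
    if not np.any(Xv):
        raise ValueError("design matrix is all zero")
    if weights is not None:
        sw = np.sqrt(weights)[:, None]
        Yw, Xw = Y * sw, Xv * sw
        t_eff = int((weights > _ZERO_WEIGHT_TOL).sum())
    else:
        Yw, Xw = Y, Xv
        t_eff = Y.shape[0]
    beta, _, rank, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    if rank < Xv.shape[1]:
        logger.warning(
            "design rank %d < %d columns (max inter-event correlation %.3f); "
            "pseudoinverse solution returned",
            rank,
            Xv.shape[1],
            X.efficiency.get("max_inter_event_corr", np.nan),
        )
    resid = Yw - Xw @ beta
    rss = (resid**2).sum(axis=0)
    return GLMFit(
        beta=beta,
        dof=t_eff - rank,
        rss=np.atleast_1d(rss),
        design=X,
        rank=int(rank),
        weights=weights,
        transform=transform,
        freqs=freqs,
    )


def artifact_weights(
    signal: ContinuousSignal,
    threshold: float,
    win_s: float,
    power_times: np.ndarray,
) -> np.ndarray:
    """Down-weight power bins whose analysis window overlaps an artefact.

    Samples with |signal| > threshold are flagged; every power bin whose
    window (centre +/- win_s/2) contains a flagged sample receives weight
    ``ARTIFACT_WEIGHT`` (effectively zero), all others weight 1.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.flatnonzero(np.abs(signal.values) > threshold)
    weights = np.ones(len(power_times))
    if bad.size == 0:
        return weights
    bad_t = np.sort(bad / signal.fs)
    half = win_s / 2 + 1e-9  # inclusive boundary despite float accumulation
    centres = np.asarray(power_times)
    # a bin is affected iff some bad_t lies in [centre - half, centre + half]
    lo = np.searchsorted(bad_t, centres - half, side="left")
    hi = np.searchsorted(bad_t, centres + half, side="right")
    weights[hi > lo] = ARTIFACT_WEIGHT
    return weights


def reconstruct(fit: GLMFit, event_type: str, modulator: bool = False) -> TFResponse:
    """Rebuild the time-frequency image R = B beta for one event type.

    Column provenance (never positional indexing) selects the rows of beta;
    for a modulator block the image reads as the modulation of the induced
    response per unit (centred) modulator value.
    """
    X = fit.design
    if X.basis is None:
        raise ValueError("design has no basis set attached")
    rows = X.event_column_indices(event_type, modulator=modulator)
    beta_i = fit.beta[rows, :]
    values = X.basis.values @ beta_i
    freqs = fit.freqs if fit.freqs is not None else np.arange(values.shape[1], dtype=float)
    return TFResponse(
        values=values,
        peritimes=X.basis.peritimes,
        freqs=np.asarray(freqs, dtype=float),
        event_type=event_type,
        transform=fit.transform,
        method="glm",
    )


def band_average(resp: TFResponse, band: tuple[float, float]) -> np.ndarray:
    """Mean of the image over frequency bins inside [band_low, band_high]."""
    mask = (resp.freqs >= band[0]) & (resp.freqs <= band[1])
    if not mask.any():
        raise ValueError(f"no frequencies inside band {band}")
    return resp.values[:, mask].mean(axis=1)
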