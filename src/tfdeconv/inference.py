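"""Second-level pixelwise statistics on time-frequency images.

Reconstructed impulse-response images from repeated runs (or subjects) are
compared pixel by pixel with pooled-variance two-sample t-tests — the
summary-statistic approach: first-level serial correlation affects only
efficiency, not the validity of these second-level tests. Gaussian image
smoothing (FWHM-parameterised, the neuroimaging convention) is provided for
display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .glm import TFResponse

__all__ = ["StatMap", "two_sample_t_map", "smooth_tf"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StatMap:
    """Pixelwise t and p maps over peristimulus time x frequency."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: int
    peritimes: np.ndarray
    freqs: np.ndarray
    correction: str = "none"

    def rejection_fraction(self, alpha: float = 0.05) -> float:
        return float((self.p_values < alpha).mean())


def two_sample_t_map(
    group1: Sequence[TFResponse],
    group2: Sequence[TFResponse],
    correction: str = "none",
) -> StatMap:
    """Pooled-variance two-sample t-test per pixel, two-sided p-values.

    ``correction="bonferroni"`` multiplies p by the pixel count (clipped at
    1); otherwise the map is uncorrected.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need at least two images per group")
    ref = group1[0]
    for r in list(group1) + list(group2):
        if r.values.shape != ref.values.shape or not np.allclose(r.peritimes, ref.peritimes):
            raise ValueError("images have mismatched axes")
    a = np.stack([r.values for r in group1])
    b = np.stack([r.values for r in group2])
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    var_pooled = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(var_pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    if correction == "bonferroni":
        p = np.minimum(p * t.size, 1.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return StatMap(
        t_values=t,
        p_values=p,
        df=df,
        peritimes=ref.peritimes,
        freqs=ref.freqs,
        correction=correction,
    )


def smooth_tf(
    image: np.ndarray,
    fwhm_time: float,
    fwhm_freq: float,
    dt_s: float,
    df_hz: float,
) -> np.ndarray:
    """Separable Gaussian smoothing of a (time x frequency) image.

    Kernel sizes are full widths at half maximum in seconds / Hz; the
    kernel is normalised (mean-preserving) and boundaries are reflective.
    """
    if fwhm_time <= 0 or fwhm_freq <= 0:
        raise ValueError("kernel sizes must be positive")
    sigma = (fwhm_time / dt_s * _FWHM_TO_SIGMA, fwhm_freq / df_hz * _FWHM_TO_SIGMA)
    return ndimage.gaussian_filter(np.asarray(image, dtype=float), sigma=sigma, mode="reflect")
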