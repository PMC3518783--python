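"""Basis-set optimisation: nested F-tests and a simple evidence criterion.

The order of a basis set is chosen by the extra-sum-of-squares principle:
starting from a single component, additional basis functions are retained
while they explain significant extra variance. Non-nested families (e.g.
Fourier vs Fourier-Hanning) are ranked with an approximate log model
evidence; here a BIC computed from the residual sum of squares and design
rank, a deliberately simple stand-in for a full hierarchical (free-energy)
comparison, with the same interface so a richer backend can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basis import make_basis
from .design import DesignMatrix, build_event_regressors, dct_drift_regressors

logger = logging.getLogger(__name__)

__all__ = ["SelectionTrace", "extra_ss_ftest", "stepup_order", "evidence_compare"]


@dataclass
class SelectionTrace:
    """Per-order F statistics and thresholds from the step-up procedure.

    ``decision`` is the largest order whose F exceeds its critical value
    (0 when even the first basis function is not significant).
    """

    orders: np.ndarray
    f_stats: np.ndarray
    thresholds: np.ndarray
    p_values: np.ndarray
    decision: int
    frequency: float | None = None


def _rank(M: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(M)) if M.size else 0


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    if X.size == 0:
        return float(y @ y)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def extra_ss_ftest(
    y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray
) -> tuple[float, int, int, float]:
    """Extra-sum-of-squares F test of nested designs on one data column.

    Returns (F, df1, df2, p) with df1 the rank gained by the full design
    and df2 its residual degrees of freedom. A full design that gains no
    rank yields F = 0 with p = 1 (flagged in the log). Perfect fits yield
    F = inf, p = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_reduced = np.atleast_2d(X_reduced) if X_reduced.size else X_reduced
    # nesting check: reduced columns must lie in the span of the full design
    if X_reduced.size:
        proj = X_full @ np.linalg.lstsq(X_full, X_reduced, rcond=None)[0]
        scale = max(float(np.abs(X_reduced).max()), 1e-300)
        if np.abs(proj - X_reduced).max() > 1e-6 * scale:
            raise ValueError("designs are not nested")
    r_red, r_full = _rank(X_reduced), _rank(X_full)
    df1 = r_full - r_red
    df2 = y.size - r_full
    if df1 <= 0:
        logger.warning("full design gains no rank; F set to 0")
        return 0.0, 0, df2, 1.0
    rss_r = _rss(y, X_reduced)
    rss_f = _rss(y, X_full)
    if rss_f <= np.finfo(float).eps * y.size * max(rss_r, 1.0):
        return np.inf, df1, df2, 0.0
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def _order_design(
    onsets: np.ndarray,
    times: np.ndarray,
    basis_kind: str,
    order: int,
    window: tuple[float, float],
    drift: np.ndarray,
) -> np.ndarray:
    fs_power = 1.0 / (times[1] - times[0])
    basis = make_basis(basis_kind, order, window, fs_power)
    from .design import EventRegressorSpec

    block = build_event_regressors(onsets, EventRegressorSpec("ev"), basis, times)
    return np.column_stack([block, drift])


def stepup_order(
    y: np.ndarray,
    basis_kind: str,
    max_order: int,
    onsets: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] = (-2.0, 2.0),
    alpha: float = 0.05,
    drift_cutoff_hz: float = 0.0,
    frequency: float | None = None,
) -> SelectionTrace:
    """Step-up selection of the basis order on one frequency column.

    The design is rebuilt at every order; order k is tested against order
    k-1 (order 0 = drift/constant block only). The critical F at ``alpha``
    rises with the order because residual degrees of freedom shrink.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    fs_power = 1.0 / (times[1] - times[0])
    drift = dct_drift_regressors(y.size, fs_power, drift_cutoff_hz)

    orders, fs_, thr, ps = [], [], [], []
    X_prev = drift
    for k in range(1, max_order + 1):
        X_k = _order_design(onsets, times, basis_kind, k, window, drift)
        if _rank(X_k) <= _rank(X_prev):
            logger.warning("design rank-deficient at order %d; truncating step-up", k)
            break
        F, df1, df2, p = extra_ss_ftest(y, X_prev, X_k)
        orders.append(k)
        fs_.append(F)
        ps.append(p)
        thr.append(float(stats.f.isf(alpha, df1, df2)) if df1 > 0 else np.inf)
        X_prev = X_k
    orders = np.asarray(orders)
    fs_ = np.asarray(fs_)
    thr = np.asarray(thr)
    above = orders[fs_ > thr]
    decision = int(above.max()) if above.size else 0
    return SelectionTrace(
        orders=orders,
        f_stats=fs_,
        thresholds=thr,
        p_values=np.asarray(ps),
        decision=decision,
        frequency=frequency,
    )


def evidence_compare(
    y: np.ndarray, designs: list[np.ndarray | DesignMatrix]
) -> np.ndarray:
    """Approximate log model evidence for each (possibly non-nested) design.

    Uses -BIC/2 = -(t ln(RSS/t) + r ln t)/2 with r the design rank: the
    fit term rewards explained variance, the complexity term penalises
    additional regressors. Higher is better; only differences between
    candidates on the same data are meaningful.
    """
    if len(designs) < 2:
        raise ValueError("need at least two candidate designs")
    y = np.asarray(y, dtype=float).ravel()
    t = y.size
    scores = []
    for d in designs:
        X = d.values if isinstance(d, DesignMatrix) else np.asarray(d, dtype=float)
        rss = _rss(y, X)
        r = _rank(X)
        rss = max(rss, np.finfo(float).tiny)
        bic = t * np.log(rss / t) + r * np.log(t)
        scores.append(-bic / 2.0)
    return np.asarray(scores)
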