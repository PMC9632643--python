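"""Left-eye / right-eye coupling indices.

Four bivariate measures of how synchronized the two eyes' horizontal traces
are, computed on band-filtered channel pairs: Pearson correlation, the
nonlinear correlation ratio h^2 (binned piecewise-linear regression),
band-averaged magnitude-squared coherence, and a time-domain Granger
causality index (log residual-variance ratio of restricted vs. full
autoregressions, order chosen by BIC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats


@dataclass(frozen=True)
class ConnectivityResult:
    correlation: float
    h2: float
    coherence: float
    granger: float
    granger_xy: float  # x -> y
    granger_yx: float  # y -> x
    band: tuple | None = None


def linear_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant channel: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def _h2_directed(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """h^2 of y given x: variance explained by a binned piecewise-linear
    regression of y on x (equal-width bins over the x range, least-squares
    line within each bin)."""
    var_y = y.var()
    if var_y == 0:
        raise ValueError("var(y) = 0: h^2 undefined")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    edges[0] -= 1e-12
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                    n_bins - 1)
    resid_ss = 0.0
    for b in range(n_bins):
        mask = which == b
        n_b = int(mask.sum())
        if n_b == 0:
            continue
        if n_b < 3:  # too few points to fit: a constant prediction
            resid_ss += float(((y[mask] - y[mask].mean()) ** 2).sum())
            continue
        design = np.column_stack([np.ones(n_b), x[mask]])
        coef, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
        resid_ss += float(((y[mask] - design @ coef) ** 2).sum())
    return float(np.clip(1.0 - (resid_ss / len(x)) / var_y, 0.0, 1.0))


def nonlinear_correlation_h2(x: np.ndarray, y: np.ndarray,
                             n_bins: int = 10) -> float:
    """Symmetrized nonlinear correlation ratio h^2 in [0, 1].

    Captures any (possibly non-monotone) functional dependence between the
    channels; returns max(h^2(y|x), h^2(x|y)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("channels must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return max(_h2_directed(x, y, n_bins), _h2_directed(y, x, n_bins))


def band_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                   band: tuple, segment_s: float = 4.0) -> float:
    """Mean magnitude-squared coherence over the band.

    Welch-style averaged overlapping segments (default 4 s, 50% overlap,
    Hann taper).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("band must lie inside (0, fs/2)")
    nperseg = int(round(segment_s * fs))
    if len(x) < 4 * nperseg:
        raise ValueError("need at least 4 segments of data")
    f, cxy = signal.coherence(x, y, fs=fs, nperseg=nperseg)
    sel = (f >= f_lo) & (f <= f_hi)
    if not sel.any():
        raise ValueError("no frequency bins inside the band")
    return float(cxy[sel].mean())


def _ar_residual_var(targets: np.ndarray, design: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    resid = targets - design @ coef
    return float(resid.var())


def _granger_directed(x: np.ndarray, y: np.ndarray, order: int) -> float:
    """ln(var restricted / var full) for x -> y at a fixed AR order."""
    n = len(y)
    rows = n - order
    lags_y = np.column_stack([y[order - k - 1: n - k - 1] for k in range(order)])
    lags_x = np.column_stack([x[order - k - 1: n - k - 1] for k in range(order)])
    ones = np.ones((rows, 1))
    target = y[order:]
    var_r = _ar_residual_var(target, np.hstack([ones, lags_y]))
    var_f = _ar_residual_var(target, np.hstack([ones, lags_y, lags_x]))
    if var_f <= 0 or var_r <= 0:
        raise ValueError("singular autoregression")
    return float(np.log(var_r / var_f))


def _bic_order(x: np.ndarray, max_order: int) -> int:
    """AR order of x by Bayesian information criterion."""
    n = len(x)
    best, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        rows = n - p
        design = np.column_stack(
            [np.ones(rows)] + [x[p - k - 1: n - k - 1] for k in range(p)])
        var = _ar_residual_var(x[p:], design)
        if var <= 0:
            continue
        bic = rows * np.log(var) + (p + 1) * np.log(rows)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def granger_index(x: np.ndarray, y: np.ndarray, max_order: int = 20
                  ) -> tuple[float, float, float]:
    """Symmetrized Granger causality index.

    Returns ``(mean, x->y, y->x)`` where each directed index is the log
    ratio of restricted to full AR residual variances; >= 0 up to
    estimation noise.  Note the index measures *incremental* predictability:
    identical channels score ~0 because the restricted model already carries
    the shared past.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 10 * max_order:
        raise ValueError("need equal lengths >= 10 * max_order")
    order = max(_bic_order(x, max_order), _bic_order(y, max_order))
    gxy = _granger_directed(x, y, order)
    gyx = _granger_directed(y, x, order)
    return (gxy + gyx) / 2.0, gxy, gyx


def connectivity_features(x: np.ndarray, y: np.ndarray, fs: float,
                          band: tuple, n_bins: int = 10,
                          max_order: int = 20) -> ConnectivityResult:
    """All four coupling indices for one band-filtered channel pair."""
    g, gxy, gyx = granger_index(x, y, max_order=max_order)
    return ConnectivityResult(
        correlation=linear_correlation(x, y),
        h2=nonlinear_correlation_h2(x, y, n_bins=n_bins),
        coherence=band_coherence(x, y, fs, band),
        granger=g, granger_xy=gxy, granger_yx=gyx, band=band)
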