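"""Preprocessing of horizontal gaze traces.

Pipeline order per subject: range normalization to [-0.5, +0.5], linear-phase
FIR band-pass filtering into the analysis bands (default 0.08-5 Hz and
5-25 Hz), and median-filter-based blink removal.  A blink is an excursion
that rises and returns to its pre-event level; over- and undershoots of the
eye (which do not return) are deliberately left untouched, since they carry
the dysmetria signal.

Note on the low band edge: at fs = 240 Hz an order-200 FIR filter cannot
realize a sharp 0.08 Hz cut; the filter is applied as specified and the
order is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR specification (windowed-sinc design)."""

    band: tuple  # (f_lo, f_hi) Hz
    fs: float
    order: int = 200
    window_kind: str = "hamming"

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (0 <= f_lo < f_hi < self.fs / 2):
            raise ValueError("band must satisfy 0 <= f_lo < f_hi < fs/2")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def taps(self) -> np.ndarray:
        return signal.firwin(self.order + 1, list(self.band),
                             pass_zero=False, window=self.window_kind,
                             fs=self.fs)


@dataclass(frozen=True)
class Spectrum:
    """Relative power spectral density (sums to 1 over 0..fs/2)."""

    frequencies: np.ndarray
    relative_power: np.ndarray


#: default analysis bands (Hz)
BAND_LOW = (0.08, 5.0)
BAND_HIGH = (5.0, 25.0)
BAND_WIDE = (0.08, 25.0)


def normalize_range(x: np.ndarray) -> np.ndarray:
    """Affine map of x onto [-0.5, +0.5] (order-preserving)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant input: range normalization undefined")
    return (x - lo) / (hi - lo) - 0.5


def bandpass_fir(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply a linear-phase band-pass FIR with group-delay compensation.

    The input is reflect-padded by one filter length at each end, convolved
    with the symmetric taps in 'same' mode (which centers the kernel and
    cancels the group delay), and unpadded, so the output is time-aligned
    with the input and of equal length.
    """
    x = np.asarray(x, dtype=float)
    taps = spec.taps()
    L = len(taps)
    if len(x) <= spec.order:
        raise ValueError("input must be longer than the filter order")
    xp = np.pad(x, L, mode="reflect")
    y = signal.fftconvolve(xp, taps, mode="same")
    return y[L:-L]


def remove_blinks(x: np.ndarray, fs: float, median_order: int = 200,
                  mad_mult: float = 5.0, max_blink_s: float = 0.5,
                  return_tol_frac: float = 0.1,
                  min_event_samples: int = 3) -> np.ndarray:
    """Excise blink artifacts using a running-median reference.

    Samples deviating from the order-``median_order`` running median by more
    than ``mad_mult`` x MAD are grouped into events.  An event is a blink iff
    the signal level after it returns to within tolerance of the level before
    it (medians of 50 ms flanks, tolerance ``return_tol_frac`` x a robust
    signal span) AND the event lasts at most ``max_blink_s``.  Blink samples
    are replaced by the running median; non-returning excursions (saccade
    steps, over/undershoots) are preserved.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if median_order >= n:
        raise ValueError("median_order must be smaller than the input length")
    m = median_filter(x, size=median_order + 1, mode="reflect")
    resid = x - m
    mad = np.median(np.abs(resid - np.median(resid)))
    thr = mad_mult * mad + 1e-12
    flagged = np.abs(resid) > thr
    if not flagged.any():
        return x.copy()

    # group flagged samples into events, merging gaps < 10 samples
    idx = np.flatnonzero(flagged)
    splits = np.flatnonzero(np.diff(idx) >= 10) + 1
    events = np.split(idx, splits)

    span = np.quantile(x, 0.95) - np.quantile(x, 0.05)
    tol = return_tol_frac * span
    flank = max(int(round(0.05 * fs)), 1)
    max_len = int(round(max_blink_s * fs))

    y = x.copy()
    for ev in events:
        i0, i1 = ev[0], ev[-1] + 1
        if i1 - i0 < min_event_samples or i1 - i0 > max_len:
            continue
        pre = np.median(x[max(i0 - flank, 0):i0]) if i0 > 0 else x[0]
        post = np.median(x[i1:i1 + flank]) if i1 < n else x[-1]
        if abs(post - pre) <= tol:
            y[i0:i1] = m[i0:i1]
    return y


def relative_psd(x: np.ndarray, fs: float, nperseg: int | None = None) -> Spectrum:
    """Averaged-periodogram (Welch) PSD normalized to sum to 1."""
    x = np.asarray(x, dtype=float)
    if len(x) < 256:
        raise ValueError("need at least 256 samples for a PSD estimate")
    if nperseg is None:
        nperseg = min(len(x), 4096)
    f, p = signal.welch(x, fs=fs, nperseg=nperseg)
    total = p.sum()
    if total == 0:
        rel = np.full_like(p, 1.0 / len(p))
    else:
        rel = p / total
    return Spectrum(frequencies=f, relative_power=rel)


def preprocess_channel(x: np.ndarray, fs: float, band: tuple,
                       fir_order: int = 200, median_order: int = 200,
                       renormalize: bool = True) -> np.ndarray:
    """normalize -> band-pass -> blink removal (-> renormalize).

    The trailing renormalization rescales the band-passed, blink-free trace
    back onto [-0.5, +0.5] so amplitude-threshold statistics see the stated
    range.
    """
    y = normalize_range(x)
    y = bandpass_fir(y, FilterSpec(band=band, fs=fs, order=fir_order))
    y = remove_blinks(y, fs, median_order=median_order)
    if renormalize:
        y = normalize_range(y)
    return y
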