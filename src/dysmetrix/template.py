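"""Matched-filter template similarity and threshold-based surface area.

Two whole-recording saccade-quality statistics:

* ``matched_filter_score`` — normalized cross-correlation of the gaze trace
  with an ideal center->target->center saccade pulse; clean saccades
  correlate highly, dysmetric ones (overshoot spikes, staircase undershoots)
  less.  The score averages the first four positive peaks and the first four
  absolute negative troughs of the correlation trace, matching the task's
  guarantee of at least four saccades to each side.
* ``threshold_surface`` — area between the normalized trace and fixed
  amplitude thresholds (default +/-0.35 on the [-0.5, +0.5] scale); sharp
  hypermetric peaks spend little time beyond the threshold, giving a small
  area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class SaccadeTemplate:
    samples: np.ndarray
    fs: float
    rise_s: float
    hold_s: float


@dataclass(frozen=True)
class TemplateScore:
    score: float
    peak_times: np.ndarray  # seconds, selected extrema of the NCC trace
    n_peaks: int
    n_troughs: int
    incomplete: bool  # fewer than 4 peaks or troughs available


def ideal_template(fs: float = 240.0, hold_s: float = 1.5,
                   rise_s: float = 0.05) -> SaccadeTemplate:
    """Ideal saccade pulse: 0, smooth rise to +0.5, hold, smooth return to 0.

    Default hold of 1.5 s is the midpoint of the task's 1.3-2.0 s target
    dwell; the rise uses a raised-cosine ramp.
    """
    if fs <= 0 or hold_s < 0 or rise_s < 0:
        raise ValueError("fs must be positive; hold_s, rise_s non-negative")
    n_rise = max(int(round(rise_s * fs)), 1)
    n_hold = int(round(hold_s * fs))
    ramp = 0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, n_rise + 1)))
    samples = 0.5 * np.concatenate([ramp, np.ones(n_hold), ramp[::-1]])
    return SaccadeTemplate(samples=samples, fs=fs, rise_s=rise_s, hold_s=hold_s)


def _ncc(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of x with the template.

    Both the template and each local window of x are mean-subtracted and
    energy-normalized, so the output lies in [-1, 1] and is invariant to
    offset and scale of the signal.
    """
    t = template - template.mean()
    t_norm = np.sqrt((t ** 2).sum())
    if t_norm == 0:
        raise ValueError("degenerate (constant) template")
    t = t / t_norm
    L = len(t)
    num = signal.fftconvolve(x, t[::-1], mode="valid")
    # running local mean / energy of x over the template window
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x ** 2)))
    s = csum[L:] - csum[:-L]
    s2 = csum2[L:] - csum2[:-L]
    local_var = np.maximum(s2 - s ** 2 / L, 0.0)
    denom = np.sqrt(local_var)
    out = np.zeros_like(num)
    ok = denom > 1e-12
    # mean subtraction of the window is implicit: t has zero mean, so
    # sum(t * (x - mean)) = sum(t * x)
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def matched_filter_score(x: np.ndarray, template: SaccadeTemplate,
                         fs: float, min_separation_s: float = 1.3,
                         selection: str = "largest") -> TemplateScore:
    """Score a trace by its similarity to the ideal saccade template.

    The NCC trace is searched for positive peaks (leftward/rightward pulses
    appear as +/- template matches) and negative troughs with a minimum
    separation of the shortest target dwell.  The score is the mean of the
    four largest peak values and the four largest absolute trough values
    (``selection='temporal'`` takes the first four of each in time order
    instead); the largest extrema correspond to the actual saccade events,
    whereas low local maxima between saccades carry no saccade information.
    If fewer than four are available on either side, all available are used
    and the result is flagged incomplete.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= len(template.samples):
        raise ValueError("input must be longer than the template")
    c = _ncc(x, template.samples)
    dist = max(int(round(min_separation_s * fs)), 1)
    pk_idx, pk_props = signal.find_peaks(c, height=0.0, distance=dist)
    tr_idx, tr_props = signal.find_peaks(-c, height=0.0, distance=dist)

    def select(idx, heights):
        if selection == "largest":
            order = np.argsort(heights)[::-1][:4]
            chosen = np.sort(idx[order])
        else:
            chosen = idx[:4]
        return chosen

    pk_sel = select(pk_idx, pk_props["peak_heights"])
    tr_sel = select(tr_idx, tr_props["peak_heights"])
    vals = np.concatenate([c[pk_sel], np.abs(c[tr_sel])])
    if vals.size == 0:
        raise ValueError("no correlation extrema found")
    score = float(vals.mean())
    times = np.sort(np.concatenate([pk_sel, tr_sel])) / fs
    return TemplateScore(score=score, peak_times=times,
                         n_peaks=len(pk_sel), n_troughs=len(tr_sel),
                         incomplete=(len(pk_sel) < 4 or len(tr_sel) < 4))


def threshold_surface(x: np.ndarray, thr_pos: float = 0.35,
                      thr_neg: float = -0.35, fs: float = 240.0) -> float:
    """Area above +threshold plus area below -threshold (amplitude*seconds).

    area = integral of max(x - thr_pos, 0) dt + integral of max(thr_neg - x, 0) dt,
    trapezoidal rule.  Expects x normalized to [-0.5, +0.5].
    """
    x = np.asarray(x, dtype=float)
    if not (-0.5 <= thr_neg < 0 < thr_pos <= 0.5):
        raise ValueError("thresholds must satisfy -0.5 <= thr_neg < 0 < thr_pos <= 0.5")
    dt = 1.0 / fs
    above = np.maximum(x - thr_pos, 0.0)
    below = np.maximum(thr_neg - x, 0.0)
    return float(np.trapezoid(above + below, dx=dt))
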