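"""Multiscale complexity profiles via coarse-graining.

Coarse-graining at scale tau replaces the series by non-overlapping window
means of length tau — effectively a low-pass filter with cutoff ~fs/(2*tau) —
and the base entropy is recomputed at each scale 1..tau_max.  Profiles:

* MDE  — multiscale dispersion entropy
* MFE  — multiscale (local) fuzzy entropy
* MFDE — multiscale fluctuation dispersion entropy

For the dispersion-based profiles the normal-CDF mapping parameters (mean,
SD) are fitted once on the scale-1 series and reused at every scale, so the
class boundaries stay comparable across scales (refitting per scale is
available via ``refit_ncdf=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .irregularity import (EntropyParams, dispersion_entropy,
                           fluctuation_dispersion_entropy,
                           local_fuzzy_entropy)

MEASURES = ("MDE", "MFE", "MFDE")


@dataclass(frozen=True)
class MultiscaleProfile:
    measure: str
    scales: np.ndarray
    values: np.ndarray
    band: tuple | None = None


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means: y_j = mean(x[(j-1)tau .. j tau))."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > len(x):
        raise ValueError("tau exceeds series length")
    n = (len(x) // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def multiscale_profile(x: np.ndarray, measure: str = "MDE",
                       params: EntropyParams | None = None,
                       tau_max: int = 10, band: tuple | None = None,
                       refit_ncdf: bool = False) -> MultiscaleProfile:
    """Entropy of the coarse-grained series at scales 1..tau_max."""
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    p = params or EntropyParams()
    x = np.asarray(x, dtype=float)
    mu, sigma = x.mean(), x.std()
    values = np.empty(tau_max)
    for tau in range(1, tau_max + 1):
        y = coarse_grain(x, tau)
        if measure == "MDE":
            kw = {} if refit_ncdf else {"mu": mu, "sigma": sigma}
            values[tau - 1] = dispersion_entropy(y, m=p.m, c=p.c, d=p.d, **kw)
        elif measure == "MFDE":
            kw = {} if refit_ncdf else {"mu": mu, "sigma": sigma}
            values[tau - 1] = fluctuation_dispersion_entropy(
                y, m=p.m, c=p.c, d=p.d, **kw)
        else:  # MFE
            values[tau - 1] = local_fuzzy_entropy(
                y, m=p.m, r=p.r, fuzzy_power=p.fuzzy_power)
    return MultiscaleProfile(measure=measure,
                             scales=np.arange(1, tau_max + 1),
                             values=values, band=band)
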