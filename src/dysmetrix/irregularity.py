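"""Single-scale irregularity and uncertainty measures.

Implements the measures used to quantify how irregular a band-limited gaze
trace is: sample entropy, local fuzzy entropy, dispersion entropy,
fluctuation dispersion entropy, Higuchi's fractal dimension, and normalized
Lempel-Ziv (LZ76) complexity.  All are implemented from their definitions;
sample entropy uses a KD-tree pair count so full-length recordings (~10^4
samples) remain fast.

Defaults (m = 2, d = 1, c = 6, r = 0.2 * SD, fuzzy_power = 2, kmax = 10) are
the standard choices of the originating method literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm


@dataclass(frozen=True)
class EntropyParams:
    """Shared parameter bundle for the entropy measures."""

    m: int = 2            # embedding dimension
    r: float = 0.2        # tolerance, fraction of signal SD
    c: int = 6            # number of classes (dispersion methods)
    d: int = 1            # embedding delay
    fuzzy_power: float = 2.0

    def __post_init__(self):
        if self.m < 1 or self.c < 2 or self.d < 1:
            raise ValueError("require m >= 1, c >= 2, d >= 1")
        if self.r <= 0 or self.fuzzy_power <= 0:
            raise ValueError("r and fuzzy_power must be positive")


def _embed(x: np.ndarray, m: int, d: int = 1) -> np.ndarray:
    """Delay-embedding matrix of shape (n - (m-1)*d, m)."""
    n = len(x) - (m - 1) * d
    if n < 1:
        raise ValueError("series too short for this embedding")
    idx = np.arange(n)[:, None] + d * np.arange(m)[None, :]
    return x[idx]


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn: -ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r`` is a fraction of the signal SD.  Returns NaN (with a warning) when
    no template matches exist at either length.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError("series too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    # SampEn convention: both template lengths use the same number of
    # vectors, n - m; count_neighbors counts ordered pairs incl. self-pairs
    n_vec = len(x) - m
    emb_m = _embed(x, m)[:n_vec]
    tree_m = cKDTree(emb_m)
    b = (tree_m.count_neighbors(tree_m, tol, p=np.inf) - n_vec) // 2
    emb_m1 = _embed(x, m + 1)
    tree_m1 = cKDTree(emb_m1)
    a = (tree_m1.count_neighbors(tree_m1, tol, p=np.inf) - len(emb_m1)) // 2
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no template matches)")
        return float("nan")
    return float(-np.log(a / b))


def local_fuzzy_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                        fuzzy_power: float = 2.0) -> float:
    """Fuzzy entropy with locally centered templates.

    Embedding vectors are centered by their own mean; similarity between two
    templates is exp(-(d/r)^p) with Chebyshev distance d.  Returns
    -ln(phi_{m+1} / phi_m) where phi is the mean pairwise similarity.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * m:
        raise ValueError("series too short for fuzzy entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(mm: int) -> float:
        emb = _embed(x, mm)[: len(x) - m]
        emb = emb - emb.mean(axis=1, keepdims=True)
        n = len(emb)
        # blockwise pairwise Chebyshev distances to bound memory
        total = 0.0
        count = 0
        block = 256  # bounds the (block x n x m) distance intermediate
        for i0 in range(0, n, block):
            a = emb[i0:i0 + block]
            d = np.abs(a[:, None, :] - emb[None, :, :]).max(axis=2)
            sim = np.exp(-((d / tol) ** fuzzy_power))
            total += sim.sum() - np.trace(sim[:, i0:i0 + len(a)])
            count += len(a) * (n - 1)
        return total / count

    p_m = phi(m)
    p_m1 = phi(m + 1)
    if p_m == 0 or p_m1 == 0:
        warnings.warn("fuzzy entropy undefined (zero similarity)")
        return float("nan")
    return float(-np.log(p_m1 / p_m))


def _dispersion_classes(x: np.ndarray, c: int,
                        mu: float | None = None,
                        sigma: float | None = None) -> np.ndarray:
    """Map x through the normal CDF (fitted mean/SD) to classes 1..c."""
    x = np.asarray(x, dtype=float)
    mu = x.mean() if mu is None else mu
    sigma = x.std() if sigma is None else sigma
    if sigma == 0:
        raise ValueError("degenerate series (zero SD) for dispersion mapping")
    y = norm.cdf(x, loc=mu, scale=sigma)
    # round c*y + 0.5 half-up onto 1..c (equal-probability classes for a
    # Gaussian input)
    z = np.floor(c * y + 1.0).astype(int)
    return np.clip(z, 1, c)


def _pattern_entropy(patterns: np.ndarray) -> float:
    """Shannon entropy (nats) of the empirical pattern distribution."""
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def dispersion_entropy(x: np.ndarray, m: int = 2, c: int = 6, d: int = 1,
                       mu: float | None = None,
                       sigma: float | None = None) -> float:
    """DispEn: Shannon entropy of dispersion-pattern frequencies.

    ``mu``/``sigma`` override the normal-CDF fit (used by the multiscale
    variant, which fixes the mapping at scale 1).
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= (m - 1) * d + 1:
        raise ValueError("series too short for dispersion entropy")
    z = _dispersion_classes(x, c, mu=mu, sigma=sigma)
    return _pattern_entropy(_embed(z, m, d))


def fluctuation_dispersion_entropy(x: np.ndarray, m: int = 2, c: int = 6,
                                   d: int = 1, mu: float | None = None,
                                   sigma: float | None = None) -> float:
    """FDispEn: DispEn on successive class differences.

    Patterns are the (m-1) differences of the class vectors, with values in
    {-(c-1), ..., c-1}.
    """
    if m < 2:
        raise ValueError("fluctuation patterns require m >= 2")
    x = np.asarray(x, dtype=float)
    if len(x) <= (m - 1) * d + 1:
        raise ValueError("series too short for fluctuation dispersion entropy")
    z = _dispersion_classes(x, c, mu=mu, sigma=sigma)
    emb = _embed(z, m, d)
    return _pattern_entropy(np.diff(emb, axis=1))


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi's fractal dimension via curve lengths L(k), k = 1..kmax.

    FD is the negative slope of the least-squares fit of ln L(k) on ln k;
    values lie in [1, 2] for typical signals (1 = smooth curve, ~2 = noise).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * kmax:
        raise ValueError("series too short for this kmax")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm_f = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm_f / k)
        lk[k - 1] = np.mean(lengths)
    logs = np.log(np.arange(1, kmax + 1))
    slope = np.polyfit(logs, np.log(lk), 1)[0]
    return float(-slope)


def lz76_phrases(bits: np.ndarray) -> int:
    """LZ76 exhaustive-parsing phrase count of a binary sequence.

    A new phrase ends as soon as the current word is not a substring of the
    text preceding it (Lempel-Ziv 1976 complexity).
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        return 0
    count = 0
    i = 0
    while i < n:
        j = i + 1
        # extend the phrase while s[i:j] occurs in s[:j-1]
        while j <= n and s[i:j] in s[: j - 1]:
            j += 1
        count += 1
        i = j
    return count


def lempel_ziv(x: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized signal.

    Returns C(n) * log2(n) / n, which tends to 1 for i.i.d. random binary
    sequences and to ~0 for highly regular ones.
    """
    x = np.asarray(x, dtype=float)
    bits = x > np.median(x)
    n = len(bits)
    if n < 2:
        raise ValueError("series too short")
    c = lz76_phrases(bits)
    return float(c * np.log2(n) / n)
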