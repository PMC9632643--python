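"""Independent brute-force reference implementations used only by the tests.

Every function here is written directly from the defining formula as plain
double loops / exhaustive enumeration, deliberately sharing no code with the
package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm


def sampen_bruteforce(x, m, r_frac):
    """SampEn by explicit double loop over template pairs."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r_frac * x.std()

    def count(mm):
        vecs = [x[i:i + mm] for i in range(n - m)]  # n-m vectors, both lengths
        c = 0
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                if np.max(np.abs(vecs[i] - vecs[j])) <= tol:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def locfuzen_bruteforce(x, m, r_frac, p):
    """Local fuzzy entropy by explicit double loop."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r_frac * x.std()

    def phi(mm):
        vecs = []
        for i in range(n - m):
            v = x[i:i + mm]
            vecs.append(v - v.mean())
        tot, cnt = 0.0, 0
        for i in range(len(vecs)):
            for j in range(len(vecs)):
                if i == j:
                    continue
                d = np.max(np.abs(vecs[i] - vecs[j]))
                tot += math.exp(-((d / tol) ** p))
                cnt += 1
        return tot / cnt

    return -math.log(phi(m + 1) / phi(m))


def _classes(x, c):
    x = np.asarray(x, dtype=float)
    y = norm.cdf(x, loc=x.mean(), scale=x.std())
    # class = round-half-up of (c*y + 0.5), clamped to 1..c
    return [min(max(int(math.floor(c * v + 0.5 + 0.5)), 1), c) for v in y]


def dispen_bruteforce(x, m, c, d):
    """DispEn by explicit pattern histogram."""
    z = _classes(x, c)
    n = len(z) - (m - 1) * d
    counts = {}
    for i in range(n):
        pat = tuple(z[i + k * d] for k in range(m))
        counts[pat] = counts.get(pat, 0) + 1
    total = sum(counts.values())
    return -sum((v / total) * math.log(v / total) for v in counts.values())


def fdispen_bruteforce(x, m, c, d):
    """FDispEn by explicit difference-pattern histogram."""
    z = _classes(x, c)
    n = len(z) - (m - 1) * d
    counts = {}
    for i in range(n):
        pat = tuple(z[i + (k + 1) * d] - z[i + k * d] for k in range(m - 1))
        counts[pat] = counts.get(pat, 0) + 1
    total = sum(counts.values())
    return -sum((v / total) * math.log(v / total) for v in counts.values())


def lz76_bruteforce(s: str) -> int:
    """LZ76 phrase count by step-by-step parsing with explicit search."""
    phrases = 0
    i = 0
    n = len(s)
    while i < n:
        length = 1
        while i + length <= n:
            word = s[i:i + length]
            prefix = s[:i + length - 1]
            if word not in prefix:
                break
            length += 1
        length = min(length, n - i)
        phrases += 1
        i += length
    return phrases


def mwu_exact_bruteforce(a, b):
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    a = list(map(float, a))
    b = list(map(float, b))
    n1, n2 = len(a), len(b)
    pooled = a + b

    def u_of(sample_a, sample_b):
        return sum(1.0 if x > y else (0.5 if x == y else 0.0)
                   for x in sample_a for y in sample_b)

    u_obs = u_of(a, b)
    mean_u = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mean_u)
    total = 0
    as_extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(n1 + n2) if i not in combo]
        if abs(u_of(ga, gb) - mean_u) >= dev_obs - 1e-12:
            as_extreme += 1
        total += 1
    return u_obs, as_extreme / total


def hedges_g_bruteforce(a, b):
    """Hedges' g straight from the formula."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    s1 = sum((v - a.mean()) ** 2 for v in a) / (n1 - 1)
    s2 = sum((v - b.mean()) ** 2 for v in b) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    j = 1 - 3 / (4 * (n1 + n2) - 9)
    return j * (a.mean() - b.mean()) / sp
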