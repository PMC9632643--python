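"""Group comparison and test-retest reliability statistics.

Two-sided Mann-Whitney U (exact enumeration for small tie-free samples,
normal approximation with tie and continuity corrections otherwise),
Hedges' g standardized mean difference with small-sample bias correction,
and Pearson correlation for session-to-session reliability.

No multiple-testing correction is applied anywhere: per-feature p-values are
reported as-is and should be read accordingly when many features are
screened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    u_statistic: float
    p_value: float
    hedges_g: float
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float


def mann_whitney_u(a, b, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Uses exact enumeration when the pooled sample size is at most
    ``exact_max_n`` and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hedges_g(a, b) -> float:
    """Bias-corrected standardized mean difference (a minus b).

    g = J * (mean(a) - mean(b)) / s_pooled with
    s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2) and
    J = 1 - 3 / (4(n1+n2) - 9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(s2))


def test_retest_pcc(session1, session2) -> float:
    """Pearson correlation between paired per-subject feature values."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if len(s1) != len(s2):
        raise ValueError("sessions must be paired (equal lengths)")
    if len(s1) < 3:
        raise ValueError("need at least 3 paired subjects")
    return float(sps.pearsonr(s1, s2).statistic)


def compare_groups(a, b, feature: str = "") -> GroupComparison:
    """Full two-group comparison (U, p, Hedges' g, descriptives)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u, p = mann_whitney_u(a, b)
    return GroupComparison(
        feature=feature, u_statistic=u, p_value=p, hedges_g=hedges_g(a, b),
        n1=len(a), n2=len(b),
        mean1=float(a.mean()), sd1=float(a.std(ddof=1)),
        mean2=float(b.mean()), sd2=float(b.std(ddof=1)))
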