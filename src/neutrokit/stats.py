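"""Small statistical primitives shared across modules.

Benjamini-Hochberg is implemented here directly because its exact step-up
behavior is part of the package's contract (permutation and chi-square
enrichment results are thresholded on the adjusted values).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( p_(j) * n / j ), clipped to 1, returned in the
    input order.  Monotone non-decreasing in the sorted order by
    construction.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def chi_square_2x2(a: float, b: float, c: float, d: float):
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]].

    Returns ``(statistic, p, min_expected)``.  Uses the closed form
    (ad - bc)^2 N / ((a+b)(c+d)(a+c)(b+d)) with one degree of freedom; a
    table with a zero margin has undefined expectation and returns
    ``(0.0, 1.0, 0.0)``.
    """
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0, 1.0, 0.0
    stat = (a * d - b * c) ** 2 * n / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, df=1))
    min_expected = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    return float(stat), p, float(min_expected)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p on [[a, b], [c, d]]."""
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def enrichment_2x2(a: float, b: float, c: float, d: float,
                   min_expected: float = 5.0):
    """Chi-square with Fisher fallback when any expected cell is small.

    Returns ``(statistic, p, method)`` where method is ``"chisq"`` or
    ``"fisher"`` (statistic is NaN for the Fisher branch).
    """
    stat, p, expected = chi_square_2x2(a, b, c, d)
    if expected < min_expected:
        return float("nan"), fisher_2x2(int(a), int(b), int(c), int(d)), "fisher"
    return stat, p, "chisq"
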