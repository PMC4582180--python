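"""Independent oracles used by the test suite.

Each oracle is deliberately naive (enumeration, brute-force sums, closed
forms) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def affine_alignment_score_enumerated(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.1
) -> float:
    """Max global alignment score by exhaustive enumeration of alignments.

    Affine gap scoring follows the convention that the first position of a
    gap costs ``gap_open`` and each subsequent position ``gap_extend``.
    No memoization: every monotone alignment path is visited.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i]][b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if last == "A" else gap_open
            best = max(best, -cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if last == "B" else gap_open
            best = max(best, -cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def anova_f_bruteforce(groups) -> tuple[float, int, int]:
    """F statistic from explicit sum-of-squares accumulation."""
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        ssb += len(g) * (g.mean() - grand) ** 2
        for v in g:
            ssw += (v - g.mean()) ** 2
    k = len(groups)
    dfb, dfw = k - 1, len(allv) - k
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def step_bleach_strip_mean(t: float, w: float, d: float, n: int = 2001) -> float:
    """Mean concentration in a width-w strip after a step bleach (erf form)."""
    from scipy.special import erf

    x = np.linspace(-w / 2, w / 2, n)
    s = np.sqrt(4.0 * d * t)
    c = 1.0 - 0.5 * (erf((w / 2 - x) / s) + erf((w / 2 + x) / s))
    return float(np.trapezoid(c, x) / w)
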