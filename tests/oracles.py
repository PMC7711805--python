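"""Independent brute-force oracles used to validate the optimized estimators.

Everything here is written as a literal transcription of the defining
formulas — explicit Python double loops, no vectorization — and must stay
independent of the implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def _cheb(x, i, j, k) -> float:
    return max(abs(x[i + t] - x[j + t]) for t in range(k))


def naive_sample_entropy(x, m: int, r_abs: float) -> float:
    """-ln(A/B) over unordered template pairs, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nm = n - m
    b = a = 0
    for i in range(nm):
        for j in range(i + 1, nm):
            if _cheb(x, i, j, m) <= r_abs:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def naive_approximate_entropy(x, m: int, r_abs: float) -> float:
    """Phi^m - Phi^(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(k: int) -> float:
        nk = n - k + 1
        total = 0.0
        for i in range(nk):
            c = sum(1 for j in range(nk) if _cheb(x, i, j, k) <= r_abs)
            total += math.log(c / nk)
        return total / nk

    return phi(m) - phi(m + 1)


def brute_force_u(a, b) -> float:
    """Mann-Whitney U of sample ``a``: pairwise wins + half-ties."""
    u = 0.0
    for ai in a:
        for bj in b:
            if ai > bj:
                u += 1.0
            elif ai == bj:
                u += 0.5
    return u
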