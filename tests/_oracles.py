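"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own numerics: exact integer
arithmetic for the hypergeometric enumeration and a literal step-up
loop for Benjamini-Hochberg.
"""

from math import comb

import numpy as np

# integer form of the 1e-7 relative tie tolerance: include a table iff
# num_k * 10^9 <= num_obs * (10^9 + 100)
TIE_NUM = 10**9 + 100
TIE_DEN = 10**9


def fisher_margin_pvalues(total: int, row1: int, col1: int) -> dict[int, float]:
    """Exact two-sided p for every table with the given margins.

    Returns {a: p} for each feasible top-left cell a; point
    probabilities are compared as exact integers.
    """
    kmin = max(0, col1 - (total - row1))
    kmax = min(row1, col1)
    nums = {k: comb(row1, k) * comb(total - row1, col1 - k)
            for k in range(kmin, kmax + 1)}
    denom = comb(total, col1)
    out = {}
    for a, na in nums.items():
        acc = sum(x for x in nums.values() if x * TIE_DEN <= na * TIE_NUM)
        out[a] = min(1.0, acc / denom)
    return out


def fisher_exact_enum(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for one table, by full enumeration."""
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 in (0, total) or col1 in (0, total):
        return 1.0
    return fisher_margin_pvalues(total, row1, col1)[a]


def bh_stepup(p_values) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up procedure."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted
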