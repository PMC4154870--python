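"""Independent brute-force oracles for the RSA statistic.

These enumerate every equally likely placement of a gene's k siRNAs among N
ranks and count events directly — no hypergeometric formula — so they are
independent of the implementation they check.
"""

from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def _tail_counts(n_total: int, k: int):
    """counts[j][r] = number of k-subsets of {1..N} whose j-th smallest <= r."""
    counts = [[0] * (n_total + 1) for _ in range(k + 1)]
    for subset in combinations(range(1, n_total + 1), k):
        for j in range(1, k + 1):
            counts[j][subset[j - 1]] += 1  # j-th smallest equals subset[j-1]
    for j in range(1, k + 1):
        for r in range(1, n_total + 1):
            counts[j][r] += counts[j][r - 1]  # cumulate: j-th smallest <= r
    return counts


def enumerated_tail(j: int, r: int, n_total: int, k: int) -> float:
    """P(at least j of k uniformly placed siRNAs land in the top r ranks)."""
    counts = _tail_counts(n_total, k)
    total = counts[1][n_total] if k >= 1 else 1  # == C(N, k)
    return counts[j][r] / total


def enumerated_p_min(ranks, n_total: int) -> float:
    """Exhaustive-enumeration version of the RSA minimal tail probability."""
    rs = sorted(ranks)
    k = len(rs)
    return min(enumerated_tail(j, rs[j - 1], n_total, k) for j in range(1, k + 1))
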