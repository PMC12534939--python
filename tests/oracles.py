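"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — exhaustive recursion, per-edge
recounts, the textbook O(nm) edit-distance table — and shares no code with
the implementation under test.
"""

from __future__ import annotations

import math
from functools import lru_cache


def brute_force_alignment_score(S, n: int, m: int, g_open: float, g_extend: float) -> float:
    """Best affine-gap global alignment score by exhaustive enumeration.

    ``S[i][j]`` is the substitution score for aligning a_i with b_j.  The
    recursion walks every alignment; a gap column costs g_open when it starts
    a run in its sequence (including right after a gap run in the other
    sequence) and g_extend when it extends one.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: int) -> float:
        if i == n and j == m:
            return 0.0
        cands = []
        if i < n and j < m:
            cands.append(S[i][j] + best(i + 1, j + 1, 0))
        if i < n:
            cands.append(-(g_extend if last == 1 else g_open) + best(i + 1, j, 1))
        if j < m:
            cands.append(-(g_extend if last == 2 else g_open) + best(i, j + 1, 2))
        return max(cands)

    return best(0, 0, 0)


def survival_raw_scores(diffs, n_bins: int = 30, width: float = 0.1) -> list[float]:
    """Per-bin log2 survival fractions by direct recount.

    A bin whose tail is empty gets a single pseudo-observation.  The small
    tolerance on the edge comparison mirrors decimal bin edges that are not
    exactly representable in binary floating point.
    """
    n = len(diffs)
    out = []
    for k in range(n_bins):
        edge = width * k
        count = sum(1 for d in diffs if d >= edge - 1e-9)
        out.append(math.log2(count / n) if count > 0 else math.log2(1.0 / n))
    return out


def levenshtein_dp(s1: str, s2: str) -> int:
    """Classical edit-distance dynamic program."""
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, 1):
        cur = [i]
        for j, b in enumerate(s2, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[len(s2)]
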