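"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive recursion
or naive scans) so they stay independent of the implementation paths they
check.
"""

from functools import lru_cache

import numpy as np

NEG = float("-inf")


def brute_force_affine_score(a: str, b: str, match: float, mismatch: float,
                             gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score by exhaustive recursion over edit
    paths.  A gap of length k costs gap_open + (k - 1) * gap_extend."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        """Best score aligning a[:i] with b[:j], last column of type
        ``last`` ('S' start, 'M' match/mismatch, 'GA' gap in a, 'GB' gap
        in b)."""
        if last == "S":
            return 0.0 if (i == 0 and j == 0) else NEG
        if last == "M":
            if i == 0 or j == 0:
                return NEG
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            return s + max(best(i - 1, j - 1, p) for p in ("S", "M", "GA", "GB"))
        if last == "GB":  # column consumes a residue of a over a gap in b
            if i == 0:
                return NEG
            return max(best(i - 1, j, "GB") + gap_extend,
                       max(best(i - 1, j, p) for p in ("S", "M", "GA"))
                       + gap_open)
        if j == 0:  # last == "GA"
            return NEG
        return max(best(i, j - 1, "GA") + gap_extend,
                   max(best(i, j - 1, p) for p in ("S", "M", "GB"))
                   + gap_open)

    return max(best(len(a), len(b), s) for s in ("M", "GA", "GB", "S"))


def brute_force_cut(states: list) -> tuple:
    """Minimal-discordance cut by scanning every cut point."""
    n = len(states)
    best_cut, best_disc = 0, None
    for cut in range(n + 1):
        disc = sum(1 for s in states[:cut] if s == "4") \
            + sum(1 for s in states[cut:] if s == "18")
        if best_disc is None or disc < best_disc:
            best_cut, best_disc = cut, disc
    return best_cut, best_disc


def naive_sse_cut(y: np.ndarray, min_side: int) -> tuple:
    """Best two-segment SSE cut by recomputing each split from scratch."""
    n = len(y)
    best = None
    for cut in range(min_side, n - min_side + 1):
        left, right = y[:cut], y[cut:]
        sse = float(((left - left.mean()) ** 2).sum()
                    + ((right - right.mean()) ** 2).sum())
        if best is None or sse < best[1]:
            best = (cut, sse)
    return best


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
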