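"""Independent reference implementations used only as test oracles.

Each oracle is written as a direct transcription of the defining
recurrence or an exhaustive enumeration, deliberately sharing no code
with the package implementation it checks.
"""

from __future__ import annotations

import sys
from functools import lru_cache


# --------------------------------------------------------------------------
# Loop decomposition over a pair table (recursive descent)

def _match_pairs(db: str) -> dict[int, int]:
    stack, pairs = [], {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    assert not stack
    return pairs


def decompose_structure(db: str) -> dict[str, int]:
    """Classify every region of a dot-bracket string by recursive
    descent over its pair table.

    Walks each region left to right; on meeting a pair it follows the
    helix inward (counting its pairs and recording interruptions) and
    recurses into the enclosed region.  Categories follow the same
    grammar the package documents; only the traversal differs.
    """
    pairs = _match_pairs(db)
    out = dict(
        n_hairpins=0, n_bulges_left=0, n_bulges_right=0,
        n_loops_left=0, n_loops_right=0,
        n_unbranched_stacks=0, n_branched_stacks=0,
        n_unpaired=0, nt_in_hairpins=0, nt_in_bulges=0, nt_in_loops=0,
        n_paired=len(pairs),
    )

    def region(lo: int, hi: int, in_loop_of: str | None) -> list[tuple[int, int]]:
        """Scan [lo, hi); returns top-level pairs; tallies unpaired NT
        into the category named by ``in_loop_of``."""
        found, k, run_unpaired = [], lo, 0
        while k < hi:
            if k in pairs:
                found.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                run_unpaired += 1
                k += 1
        if in_loop_of is not None:
            out[in_loop_of] += run_unpaired
        return found

    def helix(i: int, j: int) -> None:
        # follow the perfectly stacked run inward
        a, b = i, j
        while a + 1 < b - 1 and a + 1 in pairs and pairs[a + 1] == b - 1:
            a, b = a + 1, b - 1
        interior = region(a + 1, b, None)
        n_unpaired_inside = (b - a - 1) - sum(q - p + 1 for p, q in interior)
        if not interior:
            out["n_hairpins"] += 1
            out["nt_in_hairpins"] += n_unpaired_inside
            out["n_unbranched_stacks"] += 1
        elif len(interior) == 1:
            (p, q), = interior
            for side, gap in (("left", p - a - 1), ("right", b - q - 1)):
                if gap == 1:
                    out[f"n_bulges_{side}"] += 1
                    out["nt_in_bulges"] += 1
                elif gap >= 2:
                    out[f"n_loops_{side}"] += 1
                    out["nt_in_loops"] += gap
            out["n_unbranched_stacks"] += 1
        else:
            out["n_branched_stacks"] += 1
            out["n_unpaired"] += n_unpaired_inside
        for p, q in interior:
            helix(p, q)

    sys.setrecursionlimit(10000)
    for p, q in region(0, len(db), "n_unpaired"):
        helix(p, q)
    return out


# --------------------------------------------------------------------------
# Exhaustive enumeration of balanced dot-bracket strings

def all_structures(n: int):
    """Every balanced string over '(', ')', '.' of length exactly n."""

    def rec(prefix: str, open_count: int, remaining: int):
        if remaining == 0:
            if open_count == 0:
                yield prefix
            return
        yield from rec(prefix + ".", open_count, remaining - 1)
        if remaining > open_count:  # room to close what we open
            yield from rec(prefix + "(", open_count + 1, remaining - 1)
        if open_count > 0:
            yield from rec(prefix + ")", open_count - 1, remaining - 1)

    yield from rec("", 0, n)


# --------------------------------------------------------------------------
# Levenshtein distance: memoized transcription of the defining recursion

def lev_recursive(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def lev(x: str, y: str) -> int:
        if not y:
            return len(x)
        if not x:
            return len(y)
        if x[0] == y[0]:
            return lev(x[1:], y[1:])
        return 1 + min(lev(x[1:], y), lev(x, y[1:]), lev(x[1:], y[1:]))

    return lev(a, b)


# --------------------------------------------------------------------------
# Maximum non-crossing pairing by exhaustive recursion (tiny n)

_WOBBLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def max_pairs_exhaustive(seq: str, min_hairpin: int = 3) -> int:
    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < min_hairpin + 1:
            return 0
        m = best(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            if (seq[i], seq[k]) in _WOBBLE:
                m = max(m, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return m

    return best(0, len(seq) - 1)


# --------------------------------------------------------------------------
# Two-sample KS statistic by direct CDF comparison

def ks_statistic_bruteforce(a, b) -> float:
    values = sorted(set(a) | set(b))
    best = 0.0
    for v in values:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best
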