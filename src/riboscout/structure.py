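"""Secondary structure prediction and dot-bracket grammar parsing.

Every downstream feature consumes only a ``(dotbracket, mfe)`` pair, so
folding is a pluggable backend:

``maxpair`` (default)
    A deterministic maximum-base-pairing dynamic program (Watson–Crick
    plus GU wobble, minimum hairpin loop of 3 unpaired NT) with an
    energy proxy of −1 kcal/mol per pair.  No external dependency;
    bit-reproducible everywhere.

``vienna``
    ViennaRNA's thermodynamic MFE fold, used when the RNAlib python
    bindings are importable.

Precomputed structures can bypass folding entirely (see
:func:`fold_records` ``cache``).

The grammar applied to a dot-bracket string: a *stack* is a maximal run
of consecutively nested base pairs uninterrupted by unpaired NT on
either strand.  A *hairpin* is an unpaired run closed by a single pair.
Between two stacks along a helix, an unpaired run of exactly one NT is
a *bulge* and of two or more NT an *internal loop*, labeled left when
on the opening (5'→3') strand and right when on the closing strand;
the two sides of an internal loop count independently.  A stack is
*branched* when the loop it closes contains two or more child helices.
Unpaired NT in multiloops and external regions count as unpaired;
hairpin/bulge/loop NT do not.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "FoldResult",
    "StructuralCounts",
    "StructureParseError",
    "pair_table",
    "fold",
    "fold_records",
    "parse_structure",
    "get_backend",
]


class StructureParseError(ValueError):
    """Malformed dot-bracket input (bad character or unbalanced)."""


@dataclass(frozen=True)
class FoldResult:
    """Predicted secondary structure of one sequence."""

    dotbracket: str
    mfe: float
    backend: str = "maxpair"


@dataclass(frozen=True)
class StructuralCounts:
    """Category counts extracted from one dot-bracket string."""

    n_hairpins: int = 0
    n_bulges_left: int = 0
    n_bulges_right: int = 0
    n_loops_left: int = 0
    n_loops_right: int = 0
    n_unbranched_stacks: int = 0
    n_branched_stacks: int = 0
    n_unpaired: int = 0
    nt_in_hairpins: int = 0
    nt_in_bulges: int = 0
    nt_in_loops: int = 0
    n_paired: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def pair_table(dotbracket: str) -> np.ndarray:
    """Map each position to its partner index, −1 when unpaired.

    Standard nested matching via a stack.  Characters outside
    ``(``, ``)``, ``.`` and unbalanced brackets raise
    :class:`StructureParseError` with the offending position.
    """
    pt = np.full(len(dotbracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unmatched ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif ch != ".":
            raise StructureParseError(f"invalid character {ch!r} at position {i}")
    if stack:
        raise StructureParseError(f"unmatched '(' at position {stack[-1]}")
    return pt


# ---------------------------------------------------------------------------
# Folding backends

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# complementarity matrix: AU, UA, CG, GC, GU, UG
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[_a, _b] = True

MIN_HAIRPIN = 3  # minimum unpaired NT enclosed by any pair


@njit(cache=True)
def _nussinov_tables(code: np.ndarray, can_pair: np.ndarray, min_hairpin: int):
    n = code.shape[0]
    N = np.zeros((n, n), dtype=np.int64)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            for k in range(i + min_hairpin + 1, j + 1):
                if can_pair[code[i], code[k]]:
                    left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = N[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


@njit(cache=True)
def _nussinov_traceback(N: np.ndarray, code: np.ndarray, can_pair: np.ndarray, min_hairpin: int):
    n = code.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    # explicit stack of (i, j) intervals
    stack_i = np.empty(n + 1, dtype=np.int64)
    stack_j = np.empty(n + 1, dtype=np.int64)
    top = 0
    if n > 0:
        stack_i[top] = 0
        stack_j[top] = n - 1
        top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i >= j:
            continue
        if N[i, j] == N[i + 1, j]:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
            continue
        for k in range(i + min_hairpin + 1, j + 1):
            if can_pair[code[i], code[k]]:
                left = N[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = N[k + 1, j] if k + 1 <= j else 0
                if N[i, j] == 1 + left + right:
                    partner[i] = k
                    partner[k] = i
                    stack_i[top] = i + 1
                    stack_j[top] = k - 1
                    top += 1
                    stack_i[top] = k + 1
                    stack_j[top] = j
                    top += 1
                    break
    return partner


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unsanitized base {exc.args[0]!r} in sequence") from None


def fold_maxpair(sequence: str) -> FoldResult:
    """Deterministic maximum base-pairing fold; energy proxy −1/pair.

    Ties in the dynamic program resolve toward leaving the 5'-most
    position unpaired, then toward the 5'-most admissible partner, so
    the structure is a pure function of the sequence.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    code = _encode(sequence)
    if n <= MIN_HAIRPIN + 1:
        return FoldResult("." * n, 0.0, "maxpair")
    N = _nussinov_tables(code, _CAN_PAIR, MIN_HAIRPIN)
    partner = _nussinov_traceback(N, code, _CAN_PAIR, MIN_HAIRPIN)
    db = np.full(n, ".", dtype="U1")
    db[partner > np.arange(n)] = "("
    db[(partner >= 0) & (partner < np.arange(n))] = ")"
    n_pairs = int((partner >= 0).sum()) // 2
    return FoldResult("".join(db), -float(n_pairs), "maxpair")


def fold_vienna(sequence: str) -> FoldResult:
    """Thermodynamic MFE fold through the ViennaRNA python bindings."""
    import RNA  # deferred: optional backend

    db, mfe = RNA.fold(sequence)
    return FoldResult(db, float(mfe), "vienna")


_BACKENDS: dict[str, Callable[[str], FoldResult]] = {
    "maxpair": fold_maxpair,
    "vienna": fold_vienna,
}


def get_backend(backend: str | Callable[[str], FoldResult]) -> Callable[[str], FoldResult]:
    if callable(backend):
        return backend
    try:
        return _BACKENDS[backend]
    except KeyError:
        raise ValueError(
            f"unknown folding backend {backend!r}; choose from {sorted(_BACKENDS)}"
        ) from None


def fold(sequence: str, backend: str | Callable[[str], FoldResult] = "maxpair") -> FoldResult:
    """Fold one sanitized ACGU sequence with the chosen backend."""
    return get_backend(backend)(sequence)


def fold_records(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    backend: str | Callable[[str], FoldResult] = "maxpair",
    cache: Mapping[str, FoldResult] | None = None,
) -> dict[str, FoldResult]:
    """Fold many ``id → sequence`` entries, honoring a structure cache.

    Backend failures are re-raised naming the offending record id.
    """
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    out: dict[str, FoldResult] = {}
    fn = get_backend(backend)
    for rid, seq in items:
        if cache is not None and rid in cache:
            out[rid] = cache[rid]
            continue
        try:
            out[rid] = fn(seq)
        except Exception as exc:
            raise RuntimeError(f"folding backend failed on record {rid!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Structural grammar

def _helices(pt: np.ndarray) -> list[list[tuple[int, int]]]:
    """Group pairs into stacks: maximal runs of consecutively nested pairs."""
    n = len(pt)
    helices: list[list[tuple[int, int]]] = []
    seen = np.zeros(n, dtype=bool)
    for i in range(n):
        j = pt[i]
        if j <= i or seen[i]:
            continue
        run = [(i, int(j))]
        seen[i] = seen[j] = True
        a, b = i, int(j)
        while a + 1 < b - 1 and pt[a + 1] == b - 1:
            a, b = a + 1, b - 1
            run.append((a, b))
            seen[a] = seen[b] = True
        helices.append(run)
    return helices


def _children(pt: np.ndarray, lo: int, hi: int) -> tuple[list[tuple[int, int]], int]:
    """Top-level child pairs and unpaired count strictly inside (lo, hi)."""
    kids: list[tuple[int, int]] = []
    unpaired = 0
    k = lo + 1
    while k < hi:
        if pt[k] == -1:
            unpaired += 1
            k += 1
        else:
            kids.append((k, int(pt[k])))
            k = int(pt[k]) + 1
    return kids, unpaired


def parse_structure(dotbracket: str) -> StructuralCounts:
    """Decompose a dot-bracket string into the structural grammar counts.

    Conservation holds for every parse::

        n_paired + nt_in_hairpins + nt_in_bulges + nt_in_loops + n_unpaired
            == len(dotbracket)
    """
    pt = pair_table(dotbracket)
    n = len(pt)

    counts = dict(
        n_hairpins=0,
        n_bulges_left=0,
        n_bulges_right=0,
        n_loops_left=0,
        n_loops_right=0,
        n_unbranched_stacks=0,
        n_branched_stacks=0,
        n_unpaired=0,
        nt_in_hairpins=0,
        nt_in_bulges=0,
        nt_in_loops=0,
        n_paired=int((pt >= 0).sum()),
    )

    # external (top-level) unpaired NT
    _, ext_unpaired = _children(pt, -1, n)
    counts["n_unpaired"] += ext_unpaired

    for helix in _helices(pt):
        a, b = helix[-1]  # innermost pair closes this stack's loop
        kids, unpaired = _children(pt, a, b)
        if len(kids) == 0:
            counts["n_hairpins"] += 1
            counts["nt_in_hairpins"] += unpaired
            counts["n_unbranched_stacks"] += 1
        elif len(kids) == 1:
            (c, d), = kids
            left, right = c - a - 1, b - d - 1
            if left == 1:
                counts["n_bulges_left"] += 1
                counts["nt_in_bulges"] += 1
            elif left >= 2:
                counts["n_loops_left"] += 1
                counts["nt_in_loops"] += left
            if right == 1:
                counts["n_bulges_right"] += 1
                counts["nt_in_bulges"] += 1
            elif right >= 2:
                counts["n_loops_right"] += 1
                counts["nt_in_loops"] += right
            counts["n_unbranched_stacks"] += 1
        else:
            # multiloop: this stack branches; its unpaired NT stay "unpaired"
            counts["n_branched_stacks"] += 1
            counts["n_unpaired"] += unpaired
    return StructuralCounts(**counts)
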