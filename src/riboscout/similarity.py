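"""Candidate-to-riboswitch similarity ranking.

A candidate UTR window is compared to every positive-corpus riboswitch
through three distances:

* D_L   — absolute sequence-length difference (NT);
* D_struct — squared difference of the normalized structural feature
  block (vector slots S66..S74), summed;
* D_Lev — unit-cost Levenshtein edit distance between the two
  dot-bracket strings.

Each distance is normalized by a stated maximum and the three are
combined into a similarity in [0, 1]:

    J_Sim = 1 − (1/3) (D_L/max D_L + D_Lev/max D_Lev + D_struct/max D_struct)

where max D_L = L_max − L_min over the corpora (reference: 476 − 25 =
451), max D_Lev = max((L_max − L_min) − L_UTR, L_UTR), and
max D_struct is the candidate's maximum structural distance over the
whole positive set.  The length-based edit-distance maximum is a bound
rather than a true maximum, so each normalized term is clipped to ≤ 1
before combining.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .features import STRUCTURAL_SLICE
from .reference import MAX_RS_LENGTH, MIN_SEQ_LENGTH

__all__ = [
    "SimilarityMatch",
    "SimilarityNormalizers",
    "length_distance",
    "struct_distance",
    "lev_distance",
    "j_sim",
    "rank_matches",
]


@dataclass(frozen=True)
class SimilarityMatch:
    """One candidate-to-positive comparison."""

    utr_id: str
    rs_id: str
    d_length: float
    d_struct: float
    d_lev: float
    j_sim: float
    rs_ligand: str | None = None


@dataclass(frozen=True)
class SimilarityNormalizers:
    """Corpus length extremes feeding the J_Sim normalizers."""

    max_len: int = MAX_RS_LENGTH
    min_len: int = MIN_SEQ_LENGTH

    @property
    def d_length_max(self) -> float:
        return float(self.max_len - self.min_len)

    def d_lev_max(self, utr_len: int) -> float:
        return float(max(self.d_length_max - utr_len, utr_len))

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "SimilarityNormalizers":
        """Recompute the extremes from an actual corpus."""
        if not len(lengths):
            raise ValueError("no lengths to derive normalizers from")
        return cls(max_len=int(max(lengths)), min_len=int(min(lengths)))


def length_distance(l_utr: int, l_rs: int) -> float:
    """|L_UTR − L_RS|."""
    return float(abs(l_utr - l_rs))


def struct_distance(fv_utr: np.ndarray, fv_rs: np.ndarray) -> float:
    """Summed squared difference over the structural block S66..S74."""
    fv_utr, fv_rs = np.asarray(fv_utr), np.asarray(fv_rs)
    if fv_utr.shape != fv_rs.shape:
        raise ValueError("feature vectors assembled under different contexts")
    d = fv_utr[STRUCTURAL_SLICE] - fv_rs[STRUCTURAL_SLICE]
    return float(d @ d)


def lev_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein (edit) distance between two strings."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _clip01(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def j_sim(
    d_length: float,
    d_lev: float,
    d_struct: float,
    utr_len: int,
    d_struct_max: float,
    normalizers: SimilarityNormalizers | None = None,
) -> float:
    """Combine the three normalized distances into a similarity in [0, 1].

    Each normalized term is clipped to ≤ 1; a zero normalizer means the
    corresponding distance is identically zero and contributes nothing.
    """
    norm = normalizers or SimilarityNormalizers()

    def term(d: float, m: float) -> float:
        return _clip01(d / m) if m > 0 else 0.0

    penalty = (
        term(d_length, norm.d_length_max)
        + term(d_lev, norm.d_lev_max(utr_len))
        + term(d_struct, d_struct_max)
    ) / 3.0
    return _clip01(1.0 - penalty)


def rank_matches(
    utr_id: str,
    utr_seq_len: int,
    utr_features: np.ndarray,
    utr_dotbracket: str,
    positives: Sequence[tuple[str, int, np.ndarray, str, str | None]],
    normalizers: SimilarityNormalizers | None = None,
    top_n: int = 3,
    ligand_tally_n: int = 20,
) -> tuple[list[SimilarityMatch], Counter]:
    """Rank a candidate against the positive set by J_Sim.

    ``positives`` is a sequence of ``(rs_id, length, feature_vector,
    dotbracket, ligand)`` tuples.  Returns the ``top_n`` matches (stable
    descending J_Sim, ties broken by rs_id) and the ligand tally over
    the top ``ligand_tally_n`` matches.  Ranking is invariant to the
    input order of the positive set.
    """
    if not positives:
        raise ValueError("empty positive set: no structural-distance normalizer")
    norm = normalizers or SimilarityNormalizers()

    d_structs = np.array(
        [struct_distance(utr_features, fv) for _, _, fv, _, _ in positives]
    )
    d_struct_max = float(d_structs.max())
    matches = []
    for (rs_id, rs_len, _, rs_db, ligand), ds in zip(positives, d_structs):
        dl = length_distance(utr_seq_len, rs_len)
        dv = lev_distance(utr_dotbracket, rs_db)
        matches.append(
            SimilarityMatch(
                utr_id=utr_id,
                rs_id=rs_id,
                d_length=dl,
                d_struct=float(ds),
                d_lev=float(dv),
                j_sim=j_sim(dl, dv, float(ds), utr_seq_len, d_struct_max, norm),
                rs_ligand=ligand,
            )
        )
    matches.sort(key=lambda m: (-m.j_sim, m.rs_id))
    tally = Counter(
        m.rs_ligand for m in matches[:ligand_tally_n] if m.rs_ligand is not None
    )
    return matches[:top_n], tally
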