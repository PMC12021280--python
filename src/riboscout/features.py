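"""Assembly of the 74-element normalized feature vector.

Layout (fixed, documented, serialization-stable):

* S1..S64 — 3-mer frequencies in lexicographic A<C<G<U order, each the
  3-mer count divided by the number of 3-mers in the sequence (L − 2);
  the block sums to 1 for any sequence of length ≥ 3.
* S65 — GC content, (N_G + N_C) / L.
* S66 — minimum free energy, min-normalized across the dataset:
  mfe / min(all mfe), so the most negative MFE maps to 1 and an
  unstructured sequence to 0.
* S67..S73 — structural counts (unbranched stacks, branched stacks,
  internal loops left/right, hairpins, bulges left/right), each
  max-normalized by the dataset-wide maximum of that count.
* S74 — fraction of unpaired NT (multiloop + external), already in
  [0, 1].

Structural normalization is fit once on the combined positive +
unlabeled corpus and persisted; new sequences (e.g. truncated
sub-sequences) are scored under the stored maxima without refitting,
with out-of-range values clipped into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .structure import FoldResult, StructuralCounts, parse_structure

__all__ = [
    "KMERS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "STRUCTURAL_SLICE",
    "NormalizationContext",
    "kmer_freqs",
    "gc_content",
    "structural_raw",
    "fit_normalization",
    "assemble",
    "feature_table",
    "ks_distances",
    "MIN_SEQ_LENGTH",
]

#: Minimum ingest length: guarantees valid 3-mer statistics and matches
#: the smallest sequence length in the reference corpora.
MIN_SEQ_LENGTH = 25

KMERS: tuple[str, ...] = tuple("".join(p) for p in product("ACGU", repeat=3))
_KMER_INDEX = {k: i for i, k in enumerate(KMERS)}

#: Raw structural slots, in vector order S66..S74.
STRUCTURAL_COUNT_NAMES: tuple[str, ...] = (
    "unbranched_stacks",
    "branched_stacks",
    "loops_left",
    "loops_right",
    "hairpins",
    "bulges_left",
    "bulges_right",
)

FEATURE_NAMES: tuple[str, ...] = (
    KMERS + ("gc_content", "mfe_norm") + STRUCTURAL_COUNT_NAMES + ("unpaired_frac",)
)
N_FEATURES = len(FEATURE_NAMES)  # 74
STRUCTURAL_SLICE = slice(65, 74)  # S66..S74 (0-based 65..73)

_COUNT_ATTRS = (
    "n_unbranched_stacks",
    "n_branched_stacks",
    "n_loops_left",
    "n_loops_right",
    "n_hairpins",
    "n_bulges_left",
    "n_bulges_right",
)


def kmer_freqs(sequence: str, k: int = 3) -> np.ndarray:
    """Length-normalized k-mer frequency vector (lexicographic ACGU order)."""
    n_kmers = len(sequence) - k + 1
    if n_kmers < 1:
        raise ValueError(f"sequence shorter than k={k}: {len(sequence)} NT")
    v = np.zeros(4**k)
    if k == 3:
        for i in range(n_kmers):
            v[_KMER_INDEX[sequence[i : i + 3]]] += 1
    else:  # generic path, same normalization
        idx = {"".join(p): i for i, p in enumerate(product("ACGU", repeat=k))}
        for i in range(n_kmers):
            v[idx[sequence[i : i + k]]] += 1
    return v / n_kmers


def gc_content(sequence: str) -> float:
    """(N_G + N_C) / L."""
    if not sequence:
        raise ValueError("empty sequence has no GC content")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def structural_raw(counts: StructuralCounts, mfe: float, length: int) -> np.ndarray:
    """Raw 9-slot structural vector: [mfe, 7 counts, unpaired fraction]."""
    return np.array(
        [mfe]
        + [float(getattr(counts, a)) for a in _COUNT_ATTRS]
        + [counts.n_unpaired / length],
        dtype=float,
    )


@dataclass
class NormalizationContext:
    """Dataset-level scaling for the structural block.

    ``count_max`` holds per-count maxima over the combined fitting
    corpus (1 where a count was never observed, avoiding 0/0);
    ``mfe_min`` is the corpus-minimum (most negative) MFE, or 0 when
    every record is unstructured.
    """

    count_max: np.ndarray  # shape (7,)
    mfe_min: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "count_max": dict(zip(STRUCTURAL_COUNT_NAMES, self.count_max.tolist())),
                    "mfe_min": self.mfe_min,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationContext":
        d = json.loads(Path(path).read_text())
        return cls(
            count_max=np.array([d["count_max"][n] for n in STRUCTURAL_COUNT_NAMES]),
            mfe_min=float(d["mfe_min"]),
        )


def fit_normalization(raw_vectors: Iterable[np.ndarray]) -> NormalizationContext:
    """Fit per-count maxima and the global minimum MFE on raw 9-vectors."""
    raws = np.asarray(list(raw_vectors), dtype=float)
    if raws.size == 0:
        raise ValueError("cannot fit normalization on an empty dataset")
    count_max = raws[:, 1:8].max(axis=0)
    count_max[count_max <= 0] = 1.0
    return NormalizationContext(count_max=count_max, mfe_min=float(raws[:, 0].min()))


def assemble(
    sequence: str,
    fold: FoldResult,
    context: NormalizationContext,
    counts: StructuralCounts | None = None,
) -> np.ndarray:
    """Assemble one 74-element feature vector, every value in [0, 1]."""
    if context is None:
        raise ValueError("a fitted NormalizationContext is required")
    if counts is None:
        counts = parse_structure(fold.dotbracket)
    raw = structural_raw(counts, fold.mfe, len(sequence))
    v = np.empty(N_FEATURES)
    v[:64] = kmer_freqs(sequence)
    v[64] = gc_content(sequence)
    v[65] = 0.0 if context.mfe_min >= 0 else raw[0] / context.mfe_min
    v[66:73] = raw[1:8] / context.count_max
    v[73] = raw[8]
    return np.clip(v, 0.0, 1.0)


def feature_table(
    sequences: Mapping[str, str],
    folds: Mapping[str, FoldResult],
    context: NormalizationContext,
    min_len: int = MIN_SEQ_LENGTH,
) -> pd.DataFrame:
    """Featurize many records into a DataFrame (id index, 74 named columns).

    Records shorter than ``min_len`` are excluded (too short for stable
    k-mer statistics and below the corpus length floor).
    """
    rows, ids = [], []
    for rid, seq in sequences.items():
        if len(seq) < min_len:
            continue
        rows.append(assemble(seq, folds[rid], context))
        ids.append(rid)
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=FEATURE_NAMES)


def raw_structural_table(
    sequences: Mapping[str, str], folds: Mapping[str, FoldResult]
) -> list[np.ndarray]:
    """Raw 9-vectors for every record, for normalization fitting."""
    return [
        structural_raw(parse_structure(folds[rid].dotbracket), folds[rid].mfe, len(seq))
        for rid, seq in sequences.items()
    ]


def ks_distances(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Per-feature two-sample Kolmogorov–Smirnov statistics in [0, 1]."""
    if a.empty or b.empty:
        raise ValueError("KS distance needs two non-empty feature tables")
    return pd.Series(
        {col: ks_2samp(a[col].to_numpy(), b[col].to_numpy()).statistic for col in a.columns}
    )
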