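"""5'-truncation scan of candidate windows under a trained ensemble.

A long UTR can bury a compact riboswitch-like element near the start
codon, so each candidate window is re-scored as a series of 5'-
truncated suffixes: n start offsets evenly spaced from ``first_offset``
down to the position that still preserves the reserved 3' region (the
start codon plus downstream nucleotides), so every sub-sequence keeps
the translation-initiation context.

Each suffix is folded, featurized under the *stored* training
normalization context (no refit) and ensemble-scored.  The resulting
profile is classified:

* ``robust``   — full window detected and at least half the suffixes
  detected;
* ``fragile``  — full window detected but fewer than half the suffixes;
* ``emergent`` — full window not detected yet ≥ ``emergent_bins``
  suffixes detected (an element revealed only by truncation);
* ``negative`` — everything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import MIN_SEQ_LENGTH, NormalizationContext, assemble
from .pu import DEFAULT_THRESHOLD, PUModel, ensemble_score
from .structure import FoldResult, get_backend

__all__ = ["ScanEntry", "ScanProfile", "make_subsequences", "scan"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanEntry:
    start_offset: int
    fraction_of_full_length: float
    j_ensemble: float  # NaN when folding/featurization failed
    n_agree: int
    per_model: tuple[float, ...] = ()  # raw adjusted output per classifier


@dataclass
class ScanProfile:
    utr_id: str
    full_j_ensemble: float
    entries: list[ScanEntry] = field(default_factory=list)
    robustness: str = "negative"  # robust | fragile | emergent | negative


def make_subsequences(
    window: str,
    n: int = 20,
    first_offset: int = 30,
    reserved_3prime: int = 25,
) -> list[tuple[int, str]]:
    """Evenly spaced 5'-truncated suffixes of a candidate window.

    Offsets are ``n`` evenly spaced integers (rounded, duplicates
    collapsed) from ``first_offset`` to ``len(window) − reserved_3prime
    − 1``; each suffix therefore retains the final ``reserved_3prime``
    nucleotides.  Windows too short for the full schedule yield fewer
    suffixes (down to one); a window not even covering the reserved 3'
    region is an error.
    """
    L = len(window)
    if L <= reserved_3prime:
        raise ValueError(
            f"window of {L} NT cannot preserve a {reserved_3prime} NT 3' region"
        )
    last = L - reserved_3prime - 1
    if last < first_offset:
        logger.info(
            "window of %d NT shorter than offset schedule; producing fewer suffixes", L
        )
        offsets = [last]
    else:
        offsets = sorted(
            {int(round(x)) for x in np.linspace(first_offset, last, n)}
        )
    return [(off, window[off:]) for off in offsets]


def scan(
    models: Sequence[PUModel],
    window: str,
    context: NormalizationContext,
    utr_id: str = "",
    backend: str | Callable[[str], FoldResult] = "maxpair",
    threshold: float = DEFAULT_THRESHOLD,
    n: int = 20,
    first_offset: int = 30,
    reserved_3prime: int = 25,
    emergent_bins: int = 5,
) -> ScanProfile:
    """Score every truncated suffix of a window under the ensemble.

    Per-suffix folding or featurization failures are recorded as NaN
    scores without aborting the scan.  Detection per bin (and for the
    full window) means J_Ensemble ≥ ``threshold``.
    """
    fold_fn = get_backend(backend)
    feature_names = models[0].feature_names

    def score_one(seq: str) -> tuple[float, int, tuple[float, ...]]:
        fr = fold_fn(seq)
        fv = assemble(seq, fr, context)
        row = ensemble_score(
            models,
            pd.DataFrame([fv], columns=list(feature_names)),
            threshold=threshold,
        ).iloc[0]
        raw = tuple(float(row[f"pu_{m.split_name}"]) for m in models)
        return float(row["J_ensemble"]), int(row["n_agree"]), raw

    full_j, _, _ = score_one(window)
    profile = ScanProfile(utr_id=utr_id, full_j_ensemble=full_j)
    for off, sub in make_subsequences(window, n, first_offset, reserved_3prime):
        try:
            if len(sub) < MIN_SEQ_LENGTH:
                raise ValueError("suffix below minimum featurizable length")
            j, agree, raw = score_one(sub)
        except Exception as exc:  # per-item failure: keep scanning
            logger.warning("scan of %s offset %d failed: %s", utr_id, off, exc)
            j, agree, raw = float("nan"), 0, ()
        profile.entries.append(
            ScanEntry(
                start_offset=off,
                fraction_of_full_length=len(sub) / len(window),
                j_ensemble=j,
                n_agree=agree,
                per_model=raw,
            )
        )

    js = np.array([e.j_ensemble for e in profile.entries])
    detected = np.nan_to_num(js, nan=-1.0) >= threshold
    full_detected = full_j >= threshold
    if full_detected and detected.sum() >= len(detected) / 2:
        profile.robustness = "robust"
    elif full_detected:
        profile.robustness = "fragile"
    elif detected.sum() >= emergent_bins:
        profile.robustness = "emergent"
    else:
        profile.robustness = "negative"
    return profile
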