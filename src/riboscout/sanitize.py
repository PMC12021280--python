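"""Sequence ingest and sanitation.

Raw nucleotide sequences arrive with mixed case, T/U usage and IUPAC
ambiguity codes.  Every downstream stage (folding, k-mer counting,
similarity) assumes a clean ACGU alphabet, so ambiguity codes are
resolved deterministically: each code becomes the first of its possible
bases in the fixed order A, C, G, T/U.  Ligand annotations on positive
examples are free text and are canonicalized through an editable alias
table (e.g. "mn", "manganese" and "Mn2+" all denote the manganese ion).

5'UTR records are converted into a fixed search window before scoring:
the UTR is appended with the start codon plus 22 downstream coding
nucleotides and then trimmed, 5'→3', to its last 300 nucleotides — so a
regulatory structure near the ribosome-initiation site is always inside
the window.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "SequenceRecord",
    "LigandMap",
    "SanitationError",
    "sanitize_sequence",
    "canonicalize_ligand",
    "dedupe",
    "preprocess_utr",
    "preprocess_records",
    "DEFAULT_LIGAND_ALIASES",
]

#: Ambiguity-code resolution: each IUPAC code maps to the first of its
#: possible bases in the order A, C, G, T/U.  T and U both become U.
IUPAC_SUBSTITUTION: Mapping[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "U",
    "U": "U",
    "R": "A",  # A/G
    "Y": "C",  # C/T
    "S": "G",  # G/C
    "W": "A",  # A/T
    "K": "G",  # G/T
    "M": "A",  # A/C
    "B": "C",  # C/G/T
    "D": "A",  # A/G/T
    "H": "A",  # A/C/T
    "V": "A",  # A/C/G (first-match rule)
    "N": "A",  # any
}


class SanitationError(ValueError):
    """Raised when a sequence contains a non-IUPAC character."""


class Source(str, Enum):
    """Provenance class of a sequence record."""

    POSITIVE = "positive"
    UNLABELED = "unlabeled"
    NEGATIVE_RANDOM = "negative_random"
    NEGATIVE_EXON = "negative_exon"


@dataclass
class SequenceRecord:
    """One RNA entry after sanitation.

    ``sequence`` is the clean ACGU string used everywhere downstream;
    ``raw_sequence`` preserves the input.  Positive records carry a
    canonical ``ligand`` label; unlabeled and negative records do not.
    """

    id: str
    raw_sequence: str
    sequence: str
    source: Source
    ligand: str | None = None
    cds: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.source, str):
            self.source = Source(self.source)

    @classmethod
    def from_raw(
        cls,
        id: str,
        raw_sequence: str,
        source: Source | str,
        ligand: str | None = None,
        cds: str | None = None,
    ) -> "SequenceRecord":
        return cls(
            id=id,
            raw_sequence=raw_sequence,
            sequence=sanitize_sequence(raw_sequence),
            source=Source(source),
            ligand=ligand,
            cds=sanitize_sequence(cds) if cds else None,
        )


def sanitize_sequence(raw: str) -> str:
    """Resolve IUPAC ambiguity codes to a clean uppercase ACGU string.

    Length is preserved.  A character outside the IUPAC nucleotide
    alphabet raises :class:`SanitationError` naming its position.
    """
    out = []
    for pos, ch in enumerate(raw.upper()):
        try:
            out.append(IUPAC_SUBSTITUTION[ch])
        except KeyError:
            raise SanitationError(
                f"non-IUPAC character {ch!r} at position {pos}"
            ) from None
    return "".join(out)


# ---------------------------------------------------------------------------
# Ligand canonicalization

#: Default alias table.  Cobalamin subtypes collapse to "cobalamin",
#: manganese spellings to "Mn2+", protein-specific and tRNA ligands to
#: umbrella labels, and speculative/synthetic classes to "unknown".
DEFAULT_LIGAND_ALIASES: Mapping[str, str] = {
    "mn": "Mn2+",
    "manganese": "Mn2+",
    "mn2+": "Mn2+",
    "cobalamin": "cobalamin",
    "adenosylcobalamin": "cobalamin",
    "methylcobalamin": "cobalamin",
    "hydroxocobalamin": "cobalamin",
    "aquacobalamin": "cobalamin",
    "b12": "cobalamin",
    "tpp": "TPP",
    "thiamine pyrophosphate": "TPP",
    "thi-box": "TPP",
    "sam": "SAM",
    "s-adenosyl methionine": "SAM",
    "s-adenosylmethionine": "SAM",
    "trna": "tRNA",
    "protein": "protein",
    "fmn": "FMN",
    "zmp-ztp": "zmp-ztp",
    "guanidine": "guanidine",
    "glycine": "glycine",
    "purine": "purine",
    "lysine": "lysine",
    "fluoride": "fluoride",
    # speculative or synthetic classes
    "nha-i motif": "unknown",
    "duf1646": "unknown",
    "raia": "unknown",
    "synthetic": "unknown",
    "sul1": "unknown",
    "blank": "unknown",
    "": "unknown",
    "unknown": "unknown",
}


@dataclass
class LigandMap:
    """Alias → canonical ligand mapping, editable and serializable."""

    aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LIGAND_ALIASES)
    )

    def __post_init__(self) -> None:
        self.aliases = {k.lower(): v for k, v in self.aliases.items()}

    @classmethod
    def from_json(cls, path: str | Path) -> "LigandMap":
        return cls(aliases=json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.aliases, indent=1, sort_keys=True))


def canonicalize_ligand(raw_ligand: str | None, ligand_map: LigandMap | None = None) -> str:
    """Map a free-text ligand annotation to its canonical label.

    Unrecognized non-empty labels pass through lowercased (with a
    warning) so that rare classes survive; empty or speculative labels
    become ``"unknown"``.
    """
    ligand_map = ligand_map or LigandMap()
    key = (raw_ligand or "").strip().lower()
    if key in ligand_map.aliases:
        return ligand_map.aliases[key]
    logger.warning("unrecognized ligand label %r passed through lowercased", raw_ligand)
    return key


# ---------------------------------------------------------------------------
# Deduplication

def dedupe(records: Sequence[SequenceRecord]) -> tuple[list[SequenceRecord], int]:
    """Drop records whose sanitized sequence was already seen.

    The first occurrence (input order) keeps its id and metadata.
    Returns ``(kept_records, removed_count)``.
    """
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    for rec in records:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        kept.append(rec)
    removed = len(records) - len(kept)
    if removed:
        logger.info("dedupe removed %d duplicate sequence(s)", removed)
    return kept, removed


# ---------------------------------------------------------------------------
# 5'UTR search-window construction

def preprocess_utr(
    utr: str,
    cds: str,
    downstream_nt: int = 22,
    max_len: int = 300,
    on_bad_start: str = "warn",
) -> str:
    """Build the riboswitch search window for one 5'UTR.

    The UTR is appended with the start codon plus ``downstream_nt``
    coding nucleotides, then trimmed to its last ``max_len`` characters
    (5'→3'), so the start codon and downstream region always survive at
    the 3' end.  Output length is ``min(max_len, len(utr) + 3 +
    downstream_nt)``.

    Raises ``ValueError`` when the CDS is absent or shorter than
    ``3 + downstream_nt``.  A CDS not beginning with AUG either warns or
    raises, per ``on_bad_start`` ("warn" or "drop").
    """
    take = 3 + downstream_nt
    if not cds or len(cds) < take:
        raise ValueError(
            f"CDS absent or shorter than {take} NT; record must be dropped"
        )
    if not cds.startswith("AUG"):
        msg = f"CDS does not begin with AUG (starts {cds[:3]!r})"
        if on_bad_start == "drop":
            raise ValueError(msg)
        logger.warning(msg)
    window = utr + cds[:take]
    return window[-max_len:]


def preprocess_records(
    records: Iterable[SequenceRecord],
    downstream_nt: int = 22,
    max_len: int = 300,
    on_bad_start: str = "warn",
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Window every UTR record; drop those with unusable CDS.

    Returns the windowed records plus a ``{id: reason}`` map of drops.
    """
    kept: list[SequenceRecord] = []
    dropped: dict[str, str] = {}
    for rec in records:
        try:
            window = preprocess_utr(
                rec.sequence,
                rec.cds or "",
                downstream_nt=downstream_nt,
                max_len=max_len,
                on_bad_start=on_bad_start,
            )
        except ValueError as exc:
            dropped[rec.id] = str(exc)
            logger.info("dropping %s: %s", rec.id, exc)
            continue
        kept.append(replace(rec, sequence=window))
    return kept, dropped


# ---------------------------------------------------------------------------
# Manifest writer

def write_manifest(
    path: str | Path,
    records: Sequence[SequenceRecord],
    dropped: Mapping[str, str] | None = None,
) -> None:
    """Write a CSV manifest: id, source, ligand, length, dropped_reason."""
    dropped = dropped or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "source", "ligand", "length", "dropped_reason"])
        for rec in records:
            writer.writerow(
                [rec.id, rec.source.value, rec.ligand or "", len(rec.sequence), ""]
            )
        for rid, reason in dropped.items():
            writer.writerow([rid, "", "", "", reason])
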