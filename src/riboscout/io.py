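"""Readers and writers for the pipeline's on-disk formats.

Sequences travel as multi-record FASTA (wrapped lines, Biopython);
per-record metadata (source class, ligand) as a CSV or JSON sidecar
keyed by id; CDS sequences as a second FASTA keyed by id; structures
as a CSV cache ``id, dotbracket, mfe, backend``; feature tables as CSV
with named columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .sanitize import SequenceRecord, Source
from .structure import FoldResult

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_records",
    "write_records",
    "read_structure_cache",
    "write_structure_cache",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """id → raw sequence string from a (possibly wrapped) FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    SeqIO.write(
        (BioSeqRecord(Seq(s), id=rid, description="") for rid, s in sequences.items()),
        str(path),
        "fasta",
    )


def read_records(
    fasta_path: str | Path,
    meta_path: str | Path | None = None,
    cds_path: str | Path | None = None,
    default_source: Source = Source.UNLABELED,
) -> list[SequenceRecord]:
    """Assemble sanitized records from FASTA + optional metadata sidecar.

    The sidecar (CSV with columns ``id, source, ligand`` or a JSON
    object keyed by id) supplies provenance; the optional CDS FASTA is
    joined by id.
    """
    raw = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    if meta_path is not None:
        p = Path(meta_path)
        if p.suffix.lower() == ".json":
            meta = json.loads(p.read_text())
        else:
            df = pd.read_csv(p, dtype=str).fillna("")
            meta = {row["id"]: dict(row) for _, row in df.iterrows()}
    cds = read_fasta(cds_path) if cds_path else {}
    records = []
    for rid, seq in raw.items():
        m = meta.get(rid, {})
        records.append(
            SequenceRecord.from_raw(
                id=rid,
                raw_sequence=seq,
                source=m.get("source") or default_source,
                ligand=m.get("ligand") or None,
                cds=cds.get(rid),
            )
        )
    return records


def write_records(
    out_dir: str | Path, name: str, records: Sequence[SequenceRecord]
) -> tuple[Path, Path]:
    """Write a sanitized dataset as FASTA + CSV metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{name}.fasta"
    meta = out_dir / f"{name}.meta.csv"
    write_fasta(fasta, {r.id: r.sequence for r in records})
    pd.DataFrame(
        [
            {"id": r.id, "source": r.source.value, "ligand": r.ligand or "",
             "length": len(r.sequence)}
            for r in records
        ]
    ).to_csv(meta, index=False)
    return fasta, meta


def write_structure_cache(path: str | Path, folds: Mapping[str, FoldResult]) -> None:
    pd.DataFrame(
        [
            {"id": rid, "dotbracket": fr.dotbracket, "mfe": fr.mfe, "backend": fr.backend}
            for rid, fr in folds.items()
        ]
    ).to_csv(path, index=False)


def read_structure_cache(path: str | Path) -> dict[str, FoldResult]:
    df = pd.read_csv(path)
    return {
        row["id"]: FoldResult(row["dotbracket"], float(row["mfe"]), str(row["backend"]))
        for _, row in df.iterrows()
    }
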