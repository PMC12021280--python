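"""Synthetic corpora with known ground truth for every pipeline stage.

The generator emulates the data classes the analysis assumes:

* **positives** — riboswitch-like records partitioned into ligand
  classes.  Each record is a structure-poor backbone with class-
  specific numbers of planted stem-loops: a GC-rich stem, a short
  loop, and the stem's reverse complement, optionally interrupted by a
  bulge or a small internal loop.  Planting guarantees that the
  default folding backend recovers structures whose feature
  distributions differ between classes and from background.
* **unlabeled background** — structure-poor random sequences (the
  backbone alphabet is skewed toward A and C, whose pairing partners
  are scarce) with a controllable fraction of hidden positives spiked
  in; a manifest records which ids are spiked.
* **random negatives** — uniform ACGU sequences, lengths resampled
  from the positive set.
* **exon-like negatives** — moderately structured non-positives (one
  planted stem-loop), between background and positives in structure.
* **CDS stubs** — AUG-led coding fragments for UTR windowing.

The class ``separation`` knob scales the planted signal: at 1 the
classes carry their full structural signature, at 0 positives are
drawn from the background distribution (a negative control for the
whole pipeline).  Every draw is seeded; identical configs reproduce
byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sanitize import SequenceRecord, Source

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "default_config",
    "gen_positives",
    "gen_unlabeled",
    "gen_random_negatives",
    "gen_exon_negatives",
    "gen_cds_stubs",
    "generate_corpus",
]

BASES = np.array(list("ACGU"))
#: Structure-poor backbone: A and C dominate, so Watson–Crick/GU
#: partners are scarce and opportunistic pairing stays low.
BACKBONE_P = np.array([0.55, 0.35, 0.05, 0.05])
#: GC-rich stem alphabet: strong, foldable planted helices.
STEM_P = np.array([0.05, 0.45, 0.45, 0.05])
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class ClassSpec:
    """Structural signature of one synthetic ligand class."""

    ligand: str
    count: int
    stem_len: tuple[int, int] = (6, 9)
    n_hairpins: tuple[int, int] = (2, 3)
    p_bulge: float = 0.3
    p_loop: float = 0.2


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded study conditions for one synthetic corpus."""

    seed: int = 0
    classes: tuple[ClassSpec, ...] = ()
    n_unlabeled: int = 2000
    spike_fraction: float = 0.05
    n_random_negatives: int = 0
    n_exon_negatives: int = 0
    length_range: tuple[int, int] = (100, 180)
    cds_stub_length: int = 60
    separation: float = 1.0

    @property
    def n_positives(self) -> int:
        return sum(c.count for c in self.classes)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions: three ligand classes (~2000
    positives), each three planted stem-loops per record, differing in
    stem length and in bulge-versus-internal-loop character along a
    graded continuum (so a withheld class lies within the span of the
    others, as related riboswitch classes do); 2000 unlabeled with a
    5% positive spike."""
    cfg = GeneratorConfig(
        seed=seed,
        classes=(
            ClassSpec("ligand_a", 700, stem_len=(8, 11), n_hairpins=(3, 3), p_bulge=0.7, p_loop=0.1),
            ClassSpec("ligand_b", 700, stem_len=(8, 11), n_hairpins=(3, 3), p_bulge=0.4, p_loop=0.4),
            ClassSpec("ligand_c", 600, stem_len=(9, 12), n_hairpins=(3, 3), p_bulge=0.1, p_loop=0.7),
        ),
        n_unlabeled=2000,
        spike_fraction=0.05,
        length_range=(115, 170),
    )
    return replace(cfg, **overrides) if overrides else cfg


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), stage])


def _draw(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    return "".join(rng.choice(BASES, size=n, p=p))


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def _plant_hairpin(
    rng: np.random.Generator, spec: ClassSpec
) -> tuple[str, str]:
    """One stem-loop (sequence, planned dot-bracket)."""
    s = int(rng.integers(spec.stem_len[0], spec.stem_len[1] + 1))
    stem5 = _draw(rng, s, STEM_P)
    loop = _draw(rng, int(rng.integers(4, 8)), BACKBONE_P)
    seq5, db5 = stem5, "(" * s
    if rng.random() < spec.p_bulge and s >= 4:
        cut = int(rng.integers(2, s - 1))
        seq5 = stem5[:cut] + _draw(rng, 1, BACKBONE_P) + stem5[cut:]
        db5 = "(" * cut + "." + "(" * (s - cut)
    elif rng.random() < spec.p_loop and s >= 4:
        cut = int(rng.integers(2, s - 1))
        ins = int(rng.integers(2, 4))
        seq5 = stem5[:cut] + _draw(rng, ins, BACKBONE_P) + stem5[cut:]
        db5 = "(" * cut + "." * ins + "(" * (s - cut)
    return (
        seq5 + loop + _revcomp(stem5),
        db5 + "." * len(loop) + ")" * s,
    )


def _positive_record(
    rng: np.random.Generator, spec: ClassSpec, length: int, separation: float
) -> tuple[str, str]:
    """One planted positive: (sequence, planned structure)."""
    n_h_full = int(rng.integers(spec.n_hairpins[0], spec.n_hairpins[1] + 1))
    n_h = int(round(n_h_full * separation))
    parts = [_plant_hairpin(rng, spec) for _ in range(n_h)]
    planted = sum(len(seq) for seq, _ in parts)
    if planted > length - 2 * (n_h + 1):
        raise ValueError(
            f"class {spec.ligand!r}: planted structure ({planted} NT) does not "
            f"fit a {length} NT sequence"
        )
    spacer_total = length - planted
    cuts = np.sort(rng.integers(0, spacer_total + 1, size=n_h))
    spans = np.diff(np.concatenate([[0], cuts, [spacer_total]]))
    seq, db = [], []
    for i, span in enumerate(spans):
        seq.append(_draw(rng, int(span), BACKBONE_P))
        db.append("." * int(span))
        if i < len(parts):
            s, d = parts[i]
            seq.append(s)
            db.append(d)
    return "".join(seq), "".join(db)


def gen_positives(
    config: GeneratorConfig,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Labeled positive records plus their planned ground-truth structures."""
    if not config.classes:
        raise ValueError("at least one ligand class is required")
    rng = _rng(config, 1)
    records, plans = [], {}
    for spec in config.classes:
        for i in range(spec.count):
            length = int(rng.integers(*config.length_range))
            seq, plan = _positive_record(rng, spec, length, config.separation)
            rid = f"rs_{spec.ligand}_{i:05d}"
            records.append(
                SequenceRecord(rid, seq, seq, Source.POSITIVE, ligand=spec.ligand)
            )
            plans[rid] = plan
    return records, plans


def gen_unlabeled(
    config: GeneratorConfig,
) -> tuple[list[SequenceRecord], dict[str, list[str]]]:
    """Background records with hidden positives spiked in.

    Returns the records (all ``source=unlabeled``, no ligand) and a
    manifest ``{"spiked_ids": [...]}`` naming the hidden positives.
    """
    rng = _rng(config, 2)
    n_spike = int(round(config.n_unlabeled * config.spike_fraction))
    records: list[SequenceRecord] = []
    spiked: list[str] = []
    classes = config.classes
    for i in range(config.n_unlabeled):
        rid = f"unl_{i:05d}"
        length = int(rng.integers(*config.length_range))
        if i < n_spike and classes:
            spec = classes[i % len(classes)]
            seq, _ = _positive_record(rng, spec, length, config.separation)
            spiked.append(rid)
        else:
            seq = _draw(rng, length, BACKBONE_P)
        records.append(SequenceRecord(rid, seq, seq, Source.UNLABELED))
    return records, {"spiked_ids": spiked}


def gen_random_negatives(
    config: GeneratorConfig,
    positive_lengths: Sequence[int] | None = None,
) -> list[SequenceRecord]:
    """Uniform ACGU sequences, length-matched to the positive set.

    When ``positive_lengths`` is given, lengths are resampled from it
    with replacement (seeded); otherwise drawn from the config range.
    """
    rng = _rng(config, 3)
    uniform = np.full(4, 0.25)
    records = []
    for i in range(config.n_random_negatives):
        if positive_lengths is not None and len(positive_lengths):
            length = int(rng.choice(np.asarray(positive_lengths)))
        else:
            length = int(rng.integers(*config.length_range))
        seq = _draw(rng, length, uniform)
        records.append(
            SequenceRecord(f"neg_{i:05d}", seq, seq, Source.NEGATIVE_RANDOM)
        )
    return records


def gen_exon_negatives(config: GeneratorConfig) -> list[SequenceRecord]:
    """Moderately structured negatives: one planted stem-loop each."""
    rng = _rng(config, 4)
    spec = ClassSpec("exon_like", 0, stem_len=(4, 6), n_hairpins=(1, 1))
    records = []
    for i in range(config.n_exon_negatives):
        length = int(rng.integers(*config.length_range))
        seq, _ = _positive_record(rng, spec, length, 1.0)
        records.append(
            SequenceRecord(f"exon_{i:05d}", seq, seq, Source.NEGATIVE_EXON)
        )
    return records


def gen_cds_stubs(
    records: Sequence[SequenceRecord], config: GeneratorConfig
) -> dict[str, str]:
    """AUG-led coding stubs (length ``cds_stub_length``) per record id."""
    rng = _rng(config, 5)
    return {
        rec.id: "AUG" + _draw(rng, config.cds_stub_length - 3, BACKBONE_P)
        for rec in records
    }


@dataclass
class SyntheticCorpus:
    """Everything one synthetic study needs, with full ground truth."""

    config: GeneratorConfig
    positives: list[SequenceRecord]
    unlabeled: list[SequenceRecord]
    negatives: list[SequenceRecord]
    exon_negatives: list[SequenceRecord]
    structure_plans: dict[str, str]
    spiked_ids: list[str] = field(default_factory=list)

    def sequences(self, records: Sequence[SequenceRecord]) -> dict[str, str]:
        return {r.id: r.sequence for r in records}


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate all data classes for one seeded study."""
    positives, plans = gen_positives(config)
    unlabeled, manifest = gen_unlabeled(config)
    negatives = gen_random_negatives(
        config, positive_lengths=[len(r.sequence) for r in positives]
    )
    exons = gen_exon_negatives(config)
    return SyntheticCorpus(
        config=config,
        positives=positives,
        unlabeled=unlabeled,
        negatives=negatives,
        exon_negatives=exons,
        structure_plans=plans,
        spiked_ids=manifest["spiked_ids"],
    )
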