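"""Reference configuration of the published riboswitch ensemble design.

These constants describe the RNAcentral-derived riboswitch training
corpus that the ensemble design was built around: the per-ligand class
census (67,683 sequences across canonicalized ligand classes), the ten
major ligand classes (each ≥ 2% of the corpus), the nine leave-out
pairs, and the corpus length extremes used to normalize similarity
scores.  They are defaults — every consumer accepts alternatives so the
same machinery runs on synthetic corpora.
"""

from __future__ import annotations

__all__ = [
    "RIBOSWITCH_LIGAND_CENSUS",
    "MAJOR_LIGAND_THRESHOLD",
    "MAJOR_LIGANDS",
    "HOLDOUT_PAIRS",
    "MAX_RS_LENGTH",
    "MIN_SEQ_LENGTH",
]

#: Canonicalized ligand → sequence count in the riboswitch corpus.
#: (Duplicate printed labels merge under canonicalization; counts sum
#: to 67,683.)
RIBOSWITCH_LIGAND_CENSUS: dict[str, int] = {
    "cobalamin": 15718,
    "TPP": 12459,
    "SAM": 8686,
    "glycine": 4836,
    "FMN": 4255,
    "purine": 2648,
    "lysine": 2318,
    "fluoride": 1975,
    "zmp-ztp": 1841,
    "guanidine": 1640,
    "Mg2+": 1308,
    "methionine": 1175,
    "molybdenum": 1163,
    "unknown": 1130,
    "glucosamine": 1007,
    "glutamine": 846,
    "Mn2+": 819,
    "homocysteine": 811,
    "tetrahydrofolate": 631,
    "Pre-Q1": 605,
    "Ni/Co": 569,
    "GMP": 565,
    "cyclic-di-GMP": 526,
    "glucosamine-6-phosphate": 52,
    "2'-dG-II": 30,
    "aminoglycoside": 21,
    "guanine": 20,
    "cyclic-di-AMP": 5,
    "adenine": 4,
    "tRNA": 3,
    "leucine": 2,
    "tryptophan": 2,
    "tyrosine": 2,
    "proline": 2,
    "threonine": 2,
    "valine": 1,
    "histidine": 1,
    "protein": 1,
    "tetracycline": 1,
    "(p)ppGpp": 1,
    "alanine": 1,
    "serine": 1,
}

#: A ligand class is "major" when it holds at least this fraction of
#: the positive corpus.
MAJOR_LIGAND_THRESHOLD: float = 0.02

#: The ten major classes (each ≥ 2% of the corpus), by representation.
MAJOR_LIGANDS: tuple[str, ...] = (
    "cobalamin",
    "TPP",
    "SAM",
    "glycine",
    "FMN",
    "purine",
    "lysine",
    "fluoride",
    "zmp-ztp",
    "guanidine",
)

#: The nine two-class holdouts used alongside the ten single-class
#: holdouts and the pooled rare-class ("other") holdout: 20 splits.
HOLDOUT_PAIRS: tuple[tuple[str, str], ...] = (
    ("FMN", "glycine"),
    ("FMN", "SAM"),
    ("FMN", "TPP"),
    ("FMN", "cobalamin"),
    ("TPP", "cobalamin"),
    ("TPP", "glycine"),
    ("TPP", "SAM"),
    ("cobalamin", "SAM"),
    ("cobalamin", "TPP"),
)

#: Length of the largest riboswitch in the corpus; UTR windows are
#: trimmed to ≤ 300 NT, so this is also the global length maximum.
MAX_RS_LENGTH: int = 476

#: Smallest sequence length across the riboswitch and UTR corpora;
#: also the minimum ingest length enforced at featurization.
MIN_SEQ_LENGTH: int = 25
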