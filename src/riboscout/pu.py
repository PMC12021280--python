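"""Positive-unlabeled ensemble: ligand-holdout splits, Elkan–Noto
classifiers, ensemble scoring, hit selection, permutation importance.

The Elkan–Noto construction: a probabilistic binary classifier g is
trained to separate labeled positives (s = 1) from unlabeled records
(s = 0), so g estimates p(s=1 | x).  Under the selected-completely-at-
random assumption, p(y=1 | x) = g(x) / c with c = p(s=1 | y=1), and c
is estimated as the mean of g over a held-out fraction of the labeled
positives.  The adjusted score g(x)/c is clipped into [0, 1].  Because
the adjustment is a fixed positive rescaling, ranking by adjusted
score is identical to ranking by the base output.

Extrapolation to unseen riboswitch classes is measured by ligand
holdout: entire ligand classes are withheld from training and their
detection rate is the validation accuracy.  The reference design uses
20 splits (ten single major classes, nine pairs, one pooled
rare-class holdout); the same rules apply to any labeled corpus.

The ensemble score of a record is the mean of the per-classifier
outputs, each normalized by that classifier's maximum output over the
full positive corpus:

    J_Ensemble(x) = (1/m) Σ_i  PU_i(x) / max_RS PU_i(RS)

Hit selection instead thresholds the non-normalized adjusted output
(default 0.95) per classifier, counting how many classifiers agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.svm import SVC

__all__ = [
    "HoldoutSplit",
    "PUModel",
    "build_splits",
    "default_base_classifier",
    "fit_pu",
    "validate",
    "train_accuracy",
    "ensemble_score",
    "select_hits",
    "permutation_importance",
    "fit_ensemble",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.95


@dataclass(frozen=True)
class HoldoutSplit:
    """One ligand-withheld train/validation partition."""

    name: str
    withheld_ligands: frozenset[str]
    train_positive_ids: tuple[str, ...]
    validation_positive_ids: tuple[str, ...]
    unlabeled_ids: tuple[str, ...]


def build_splits(
    positive_ligands: Mapping[str, str],
    unlabeled_ids: Sequence[str],
    major_threshold: float = 0.02,
    pairs: Sequence[tuple[str, str]] | None = None,
    pooled_rare: bool = True,
) -> list[HoldoutSplit]:
    """Enumerate ligand-holdout splits from a labeled positive corpus.

    ``positive_ligands`` maps record id → canonical ligand.  One split
    is produced per *major* class (representation ≥ ``major_threshold``),
    one per configured pair, plus one pooled holdout of every rare
    class (when ``pooled_rare`` and rare classes exist).  A pair naming
    a class absent from the corpus is an error, as is any split whose
    training positives would be empty.
    """
    if not positive_ligands:
        raise ValueError("no labeled positives to split")
    ligands = pd.Series(positive_ligands)
    census = ligands.value_counts()
    frac = census / census.sum()
    majors = [l for l in census.index if frac[l] >= major_threshold]

    by_class: dict[str, list[str]] = {
        lig: sorted(ligands.index[ligands == lig]) for lig in census.index
    }
    unlabeled = tuple(unlabeled_ids)

    def make(name: str, withheld: Iterable[str]) -> HoldoutSplit:
        withheld = frozenset(withheld)
        val = tuple(rid for lig in sorted(withheld) for rid in by_class[lig])
        train = tuple(rid for rid in ligands.index if ligands[rid] not in withheld)
        if not train:
            raise ValueError(f"split {name!r} leaves no training positives")
        if not val:
            raise ValueError(f"split {name!r} has an empty validation set")
        return HoldoutSplit(name, withheld, train, val, unlabeled)

    splits = [make(f"holdout_{lig}", {lig}) for lig in majors]
    for a, b in pairs or ():
        for lig in (a, b):
            if lig not in by_class:
                raise ValueError(f"pair names absent ligand class {lig!r}")
        splits.append(make(f"holdout_{a}+{b}", {a, b}))
    rare = [l for l in census.index if frac[l] < major_threshold]
    if pooled_rare and rare:
        splits.append(make("holdout_other", rare))
    return splits


def default_base_classifier(seed: int | None = None) -> SVC:
    """The reference base classifier: RBF-kernel SVC with probability
    outputs (C=10, gamma=0.4), unweighted."""
    return SVC(C=10, kernel="rbf", gamma=0.4, probability=True, random_state=seed)


@dataclass
class PUModel:
    """One fitted Elkan–Noto classifier for one holdout split."""

    split_name: str
    base: BaseEstimator
    c_hat: float
    rs_max: float = float("nan")
    seed: int = 0
    feature_names: tuple[str, ...] = field(default_factory=tuple)

    def base_output(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        proba = self.base.predict_proba(np.asarray(X, dtype=float))
        return proba[:, list(self.base.classes_).index(1)]

    def score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Adjusted positive-class probability, clipped into [0, 1]."""
        return np.clip(self.base_output(X) / self.c_hat, 0.0, 1.0)


def fit_pu(
    split: HoldoutSplit,
    features: pd.DataFrame,
    holdout_ratio: float = 0.1,
    seed: int = 0,
    base: BaseEstimator | None = None,
    min_train: int = 10,
) -> PUModel:
    """Fit one Elkan–Noto classifier on a holdout split.

    A seeded ``holdout_ratio`` fraction of the training positives is
    withheld from the base fit and used only to estimate
    c = p(s=1 | y=1) as the mean base output over that held-out set.
    """
    train_pos = list(split.train_positive_ids)
    unlabeled = list(split.unlabeled_ids)
    if len(train_pos) < min_train or len(unlabeled) < min_train:
        raise ValueError(
            f"split {split.name!r} too small: {len(train_pos)} positives, "
            f"{len(unlabeled)} unlabeled (need ≥ {min_train} each)"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(train_pos))
    n_hold = max(1, int(round(holdout_ratio * len(train_pos))))
    hold_ids = [train_pos[i] for i in perm[:n_hold]]
    fit_ids = [train_pos[i] for i in perm[n_hold:]]

    X = np.vstack(
        [features.loc[fit_ids].to_numpy(float), features.loc[unlabeled].to_numpy(float)]
    )
    y = np.concatenate([np.ones(len(fit_ids)), np.zeros(len(unlabeled))])
    model = clone(base) if base is not None else default_base_classifier(seed)
    model.fit(X, y)

    probe = PUModel(
        split_name=split.name,
        base=model,
        c_hat=1.0,
        seed=seed,
        feature_names=tuple(features.columns),
    )
    c_hat = float(probe.base_output(features.loc[hold_ids]).mean())
    if not np.isfinite(c_hat) or c_hat <= 0:
        raise ValueError(
            f"degenerate label-frequency estimate c={c_hat!r}; "
            "increase holdout_ratio or check feature separation"
        )
    probe.c_hat = c_hat
    all_pos = list(split.train_positive_ids) + list(split.validation_positive_ids)
    probe.rs_max = float(probe.score(features.loc[all_pos]).max())
    return probe


def validate(
    model: PUModel,
    split: HoldoutSplit,
    features: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Fraction of withheld-class positives scoring ≥ threshold."""
    ids = list(split.validation_positive_ids)
    if not ids:
        raise ValueError(f"split {split.name!r} has no validation positives")
    return float((model.score(features.loc[ids]) >= threshold).mean())


def train_accuracy(
    model: PUModel,
    split: HoldoutSplit,
    features: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Fraction of training positives scoring ≥ threshold."""
    ids = list(split.train_positive_ids)
    return float((model.score(features.loc[ids]) >= threshold).mean())


def ensemble_score(
    models: Sequence[PUModel],
    features: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score records under the full ensemble.

    Returns a DataFrame indexed like ``features`` with one raw-output
    column per classifier, the normalized mean ``J_ensemble`` and the
    agreement count ``n_agree`` (classifiers whose non-normalized
    output reaches ``threshold``).
    """
    if not models:
        raise ValueError("empty ensemble")
    out = pd.DataFrame(index=features.index)
    normed = np.zeros(len(features))
    agree = np.zeros(len(features), dtype=int)
    for m in models:
        if not np.isfinite(m.rs_max) or m.rs_max <= 0:
            raise ValueError(f"model {m.split_name!r} lacks a positive rs_max")
        s = m.score(features)
        out[f"pu_{m.split_name}"] = s
        normed += np.minimum(s / m.rs_max, 1.0)
        agree += s >= threshold
    out["J_ensemble"] = normed / len(models)
    out["n_agree"] = agree
    return out


def select_hits(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_agree: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Select and rank hits from an ensemble score table.

    ``min_agree`` defaults to *all* classifiers.  Hits are sorted by
    ``J_ensemble`` descending with ties broken by id.  Also returns the
    histogram of ``n_agree`` over 1..n_models.
    """
    n_models = int(scores.columns.str.startswith("pu_").sum())
    if min_agree is None:
        min_agree = n_models
    hist = (
        scores["n_agree"]
        .value_counts()
        .reindex(range(1, n_models + 1), fill_value=0)
        .rename("count")
    )
    hits = scores[scores["n_agree"] >= min_agree]
    # descending J_ensemble, ties broken by ascending id
    order = np.lexsort((hits.index.to_numpy(), -hits["J_ensemble"].to_numpy()))
    return hits.iloc[order], hist


def permutation_importance(
    models: Sequence[PUModel],
    features: pd.DataFrame,
    labels: np.ndarray,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.Series:
    """Per-feature mean accuracy loss from column scrambling.

    ``labels`` are the assumed classes of the probe sample (1 for
    positives, 0 for background).  For every feature, the column is
    shuffled (seeded) ``repeats`` times, records are re-scored by each
    classifier, and the drop in thresholded accuracy relative to the
    unshuffled baseline is recorded; the returned Series averages the
    loss over repeats and classifiers.
    """
    rng = np.random.default_rng(seed)
    X = features.to_numpy(float)
    labels = np.asarray(labels)
    baselines = [
        float(((m.score(X) >= threshold).astype(int) == labels).mean()) for m in models
    ]
    losses = pd.Series(0.0, index=features.columns)
    for j, col in enumerate(features.columns):
        total = 0.0
        for _ in range(repeats):
            perm = rng.permutation(len(X))
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            for m, base_acc in zip(models, baselines):
                acc = float(((m.score(Xp) >= threshold).astype(int) == labels).mean())
                total += base_acc - acc
        losses[col] = total / (repeats * len(models))
    return losses


def fit_ensemble(
    splits: Sequence[HoldoutSplit],
    features: pd.DataFrame,
    holdout_ratio: float = 0.1,
    seed: int = 0,
    base: BaseEstimator | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[PUModel], pd.DataFrame]:
    """Fit one classifier per split; return models and a metrics table.

    The metrics table carries, per split, the training accuracy on
    positives, the withheld-class validation accuracy, and the number
    of training/validation records.
    """
    models, rows = [], []
    for i, split in enumerate(splits):
        m = fit_pu(split, features, holdout_ratio=holdout_ratio, seed=seed + i, base=base)
        rows.append(
            {
                "split": split.name,
                "withheld": "+".join(sorted(split.withheld_ligands)),
                "n_train_pos": len(split.train_positive_ids),
                "n_validation": len(split.validation_positive_ids),
                "c_hat": m.c_hat,
                "train_accuracy": train_accuracy(m, split, features, threshold),
                "validation_accuracy": validate(m, split, features, threshold),
            }
        )
        models.append(m)
        logger.info("fitted %s: val acc %.3f", split.name, rows[-1]["validation_accuracy"])
    return models, pd.DataFrame(rows).set_index("split")
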