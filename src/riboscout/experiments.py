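"""Seeded end-to-end synthetic studies.

One :func:`run_study` call executes the whole discovery pipeline on a
generated corpus with known ground truth — fold, featurize, build
ligand-holdout splits, fit the Elkan–Noto ensemble, score, select hits
— and measures what the ground truth makes measurable:

* withheld-class validation accuracy per split (extrapolation to
  unseen ligand classes);
* recall of the positives spiked into the unlabeled pool, among hits
  selected by all classifiers;
* background positive-rate (un-spiked unlabeled records selected);
* optionally, the retrained negative control: the ensemble is refit
  with uniform-random negatives included in the 0-labeled pool and the
  false-positive rate is measured on those negatives — the procedure
  the published negative control used.

Repeating over seeds gives distributional summaries; every stage's
randomness derives from the single study seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import features, pu, synth
from .structure import fold_records
from .synth import GeneratorConfig, SyntheticCorpus, default_config

__all__ = ["StudyResult", "run_study", "summarize_studies"]


@dataclass
class StudyResult:
    """Everything measured in one seeded synthetic study."""

    seed: int
    config: GeneratorConfig
    split_metrics: pd.DataFrame
    validation_accuracies: dict[str, float]
    spiked_recall: float
    background_hit_rate: float
    n_hits: int
    agree_histogram: pd.Series
    control_fpr: float | None = None
    control_recall: float | None = None
    corpus: SyntheticCorpus | None = None
    models: list = field(default_factory=list)
    feature_table: pd.DataFrame | None = None
    context: features.NormalizationContext | None = None

    @property
    def median_validation_accuracy(self) -> float:
        return float(np.median(list(self.validation_accuracies.values())))


def run_study(
    seed: int,
    config: GeneratorConfig | None = None,
    backend: str = "maxpair",
    threshold: float = pu.DEFAULT_THRESHOLD,
    negative_control: bool = False,
    n_control_train_negatives: int | None = None,
    keep_artifacts: bool = False,
) -> StudyResult:
    """Run one seeded synthetic study end to end.

    When ``negative_control`` is set, the corpus's random negatives are
    folded and featurized, the ensemble is retrained with them added to
    the 0-labeled pool (all of them, or a seeded subsample of
    ``n_control_train_negatives``), and the false-positive rate at
    ``threshold`` (all classifiers agreeing) is measured on the full
    negative set, together with the retrained ensemble's spiked recall.
    """
    config = replace(config or default_config(), seed=seed)
    corpus = synth.generate_corpus(config)

    pos = corpus.sequences(corpus.positives)
    unl = corpus.sequences(corpus.unlabeled)
    train_seqs = {**pos, **unl}
    folds = fold_records(train_seqs, backend=backend)

    # normalization is fit once on the combined positive + unlabeled corpus
    context = features.fit_normalization(features.raw_structural_table(train_seqs, folds))
    table = features.feature_table(train_seqs, folds, context)

    ligands = {r.id: r.ligand for r in corpus.positives}
    unl_ids = [r.id for r in corpus.unlabeled if r.id in table.index]
    splits = pu.build_splits(ligands, unl_ids)
    models, metrics = pu.fit_ensemble(splits, table, seed=seed, threshold=threshold)

    scores = pu.ensemble_score(models, table.loc[unl_ids], threshold=threshold)
    hits, hist = pu.select_hits(scores, threshold=threshold)
    spiked = [i for i in corpus.spiked_ids if i in table.index]
    background = [i for i in unl_ids if i not in set(spiked)]
    spiked_recall = (
        float(len(set(hits.index) & set(spiked)) / len(spiked)) if spiked else float("nan")
    )
    background_rate = float(
        len(set(hits.index) & set(background)) / len(background)
    )

    result = StudyResult(
        seed=seed,
        config=config,
        split_metrics=metrics,
        validation_accuracies=dict(metrics["validation_accuracy"]),
        spiked_recall=spiked_recall,
        background_hit_rate=background_rate,
        n_hits=len(hits),
        agree_histogram=hist,
    )

    if negative_control:
        if not corpus.negatives:
            raise ValueError("negative_control requires n_random_negatives > 0")
        neg = corpus.sequences(corpus.negatives)
        neg_folds = fold_records(neg, backend=backend)
        neg_table = features.feature_table(neg, neg_folds, context)
        full = pd.concat([table, neg_table])
        neg_ids = list(neg_table.index)
        if n_control_train_negatives is not None and n_control_train_negatives < len(neg_ids):
            rng = np.random.default_rng([seed % (2**31), 97])
            train_neg = list(rng.choice(neg_ids, n_control_train_negatives, replace=False))
        else:
            train_neg = neg_ids
        ctrl_splits = pu.build_splits(ligands, unl_ids + train_neg)
        ctrl_models, _ = pu.fit_ensemble(ctrl_splits, full, seed=seed, threshold=threshold)
        neg_scores = pu.ensemble_score(ctrl_models, full.loc[neg_ids], threshold=threshold)
        result.control_fpr = float((neg_scores["n_agree"] == len(ctrl_models)).mean())
        ctrl_unl = pu.ensemble_score(ctrl_models, full.loc[unl_ids], threshold=threshold)
        ctrl_hits, _ = pu.select_hits(ctrl_unl, threshold=threshold)
        result.control_recall = (
            float(len(set(ctrl_hits.index) & set(spiked)) / len(spiked))
            if spiked
            else float("nan")
        )

    if keep_artifacts:
        result.corpus = corpus
        result.models = models
        result.feature_table = table
        result.context = context
    return result


def summarize_studies(results: Sequence[StudyResult]) -> dict[str, float]:
    """Median summaries across seeds."""
    all_val = [v for r in results for v in r.validation_accuracies.values()]
    out = {
        "median_validation_accuracy": float(np.median(all_val)),
        "median_spiked_recall": float(np.median([r.spiked_recall for r in results])),
        "median_background_hit_rate": float(
            np.median([r.background_hit_rate for r in results])
        ),
    }
    fprs = [r.control_fpr for r in results if r.control_fpr is not None]
    if fprs:
        out["median_control_fpr"] = float(np.median(fprs))
        out["median_control_recall"] = float(
            np.median([r.control_recall for r in results if r.control_recall is not None])
        )
    return out
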