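"""Ligand-holdout split design and the Elkan–Noto ensemble."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from riboscout import pu
from riboscout.reference import (
    HOLDOUT_PAIRS,
    MAJOR_LIGANDS,
    RIBOSWITCH_LIGAND_CENSUS,
)


def census_positive_ligands(scale: int = 100) -> dict[str, str]:
    """Toy labeled positives whose ligand proportions follow the
    reference riboswitch census (at least one record per class)."""
    ligands = {}
    i = 0
    for ligand, count in RIBOSWITCH_LIGAND_CENSUS.items():
        for _ in range(max(1, round(count / scale))):
            ligands[f"rs_{i:05d}"] = ligand
            i += 1
    return ligands


class TestBuildSplits:
    def test_reference_configuration_yields_twenty_splits(self):
        ligands = census_positive_ligands()
        splits = pu.build_splits(ligands, ["u1", "u2"], pairs=HOLDOUT_PAIRS)
        assert len(splits) == 20
        singles = [s for s in splits if len(s.withheld_ligands) == 1
                   and s.name != "holdout_other"]
        assert {next(iter(s.withheld_ligands)) for s in singles} == set(MAJOR_LIGANDS)
        other = [s for s in splits if s.name == "holdout_other"]
        assert len(other) == 1
        assert all(l not in MAJOR_LIGANDS for l in other[0].withheld_ligands)

    def test_three_equal_classes_no_pairs(self):
        ligands = {f"r{i}": ["a", "b", "c"][i % 3] for i in range(30)}
        splits = pu.build_splits(ligands, ["u1"])
        assert len(splits) == 3
        for s in splits:
            assert set(s.train_positive_ids).isdisjoint(s.validation_positive_ids)
            assert len(s.validation_positive_ids) == 10

    def test_validation_set_is_exactly_the_withheld_class(self):
        ligands = {f"r{i}": ("a" if i < 20 else "b") for i in range(30)}
        splits = pu.build_splits(ligands, ["u1"])
        for s in splits:
            expected = {r for r, l in ligands.items() if l in s.withheld_ligands}
            assert set(s.validation_positive_ids) == expected

    def test_single_class_corpus_raises(self):
        with pytest.raises(ValueError, match="training positives"):
            pu.build_splits({f"r{i}": "TPP" for i in range(5)}, ["u1"])

    def test_pair_naming_absent_class_raises(self):
        ligands = {f"r{i}": ["a", "b"][i % 2] for i in range(10)}
        with pytest.raises(ValueError, match="absent"):
            pu.build_splits(ligands, ["u1"], pairs=[("a", "zzz")])

    def test_deterministic_names_and_order(self):
        ligands = census_positive_ligands()
        s1 = pu.build_splits(ligands, ["u1"], pairs=HOLDOUT_PAIRS)
        s2 = pu.build_splits(ligands, ["u1"], pairs=HOLDOUT_PAIRS)
        assert [a.name for a in s1] == [a.name for a in s2]


class _ConstantClassifier:
    """Probabilistic stub: p(1|x) = g for every x."""

    classes_ = np.array([0, 1])

    def __init__(self, g):
        self.g = g

    def get_params(self, deep=True):
        return {"g": self.g}

    def set_params(self, **p):
        self.g = p.get("g", self.g)
        return self

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        out = np.full((len(X), 2), 1 - self.g)
        out[:, 1] = self.g
        return out


def _toy_split(n_pos=40, n_unl=40):
    ligands = {f"p{i}": ["a", "b"][i % 2] for i in range(n_pos)}
    unl = [f"u{i}" for i in range(n_unl)]
    features = pd.DataFrame(
        np.random.default_rng(0).random((n_pos + n_unl, 3)),
        index=list(ligands) + unl,
    )
    return pu.build_splits(ligands, unl)[0], features


class TestElkanNoto:
    def test_c_hat_equals_constant_base_output(self):
        split, feats = _toy_split()
        model = pu.fit_pu(split, feats, seed=0, base=_ConstantClassifier(0.6))
        assert model.c_hat == pytest.approx(0.6)

    def test_score_is_base_over_c_clipped(self):
        split, feats = _toy_split()
        model = pu.fit_pu(split, feats, seed=0, base=_ConstantClassifier(0.6))
        # base(x) = c_hat for every x here, so adjusted score is exactly 1
        assert model.score(feats) == pytest.approx(1.0)

    def test_adjustment_preserves_ranking(self, small_study):
        model = small_study.models[0]
        X = small_study.feature_table.sample(80, random_state=0)
        base = model.base_output(X)
        adj = model.score(X)
        # strictly increasing transform up to clipping
        order = np.argsort(base)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_too_few_records_raises(self):
        split, feats = _toy_split(n_pos=8, n_unl=40)
        with pytest.raises(ValueError, match="too small"):
            pu.fit_pu(split, feats, seed=0)

    def test_determinism(self, small_study):
        split = pu.build_splits(
            {r.id: r.ligand for r in small_study.corpus.positives},
            [r.id for r in small_study.corpus.unlabeled],
        )[0]
        m1 = pu.fit_pu(split, small_study.feature_table, seed=5)
        m2 = pu.fit_pu(split, small_study.feature_table, seed=5)
        assert m1.c_hat == m2.c_hat
        X = small_study.feature_table.iloc[:50]
        assert np.array_equal(m1.score(X), m2.score(X))

    def test_c_hat_recovers_spiked_label_frequency(self):
        """On cleanly separated features with known hidden positives,
        the estimated labeling frequency c matches the constructed
        labeled-fraction within ±0.1 (mean over 10 seeds)."""
        estimates, truths = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n_pos, n_spike, n_bg = 100, 40, 160
            pos = r.normal(0.8, 0.05, (n_pos, 2))
            spike = r.normal(0.8, 0.05, (n_spike, 2))
            bg = r.normal(0.2, 0.05, (n_bg, 2))
            ids = (
                [f"p{i}" for i in range(n_pos)]
                + [f"s{i}" for i in range(n_spike)]
                + [f"b{i}" for i in range(n_bg)]
            )
            feats = pd.DataFrame(np.vstack([pos, spike, bg]), index=ids)
            ligands = {f"p{i}": ["a", "b"][i % 2] for i in range(n_pos)}
            split = pu.build_splits(ligands, ids[n_pos:])[0]
            model = pu.fit_pu(
                split, feats, seed=seed, holdout_ratio=0.2,
                base=LogisticRegression(C=1e6, max_iter=2000),
            )
            # labeled fraction among the true positives the base fit saw:
            # the split's training positives minus the c-estimation holdout,
            # against the spiked (hidden) positives in the 0-labeled pool
            n_fit = len(split.train_positive_ids) - max(
                1, round(0.2 * len(split.train_positive_ids))
            )
            truths.append(n_fit / (n_fit + n_spike))
            estimates.append(model.c_hat)
        assert abs(np.mean(estimates) - np.mean(truths)) < 0.1


class TestEnsembleScoring:
    def _models(self, outputs):
        ms = []
        for i, (g, rs_max) in enumerate(outputs):
            m = pu.PUModel(f"s{i}", _ConstantClassifier(g), c_hat=1.0, rs_max=rs_max)
            ms.append(m)
        return ms

    def test_outputs_at_rs_max_give_one(self):
        models = self._models([(0.8, 0.8), (0.5, 0.5)])
        scores = pu.ensemble_score(models, pd.DataFrame(np.zeros((3, 2))))
        assert scores["J_ensemble"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_outputs_give_zero(self):
        models = self._models([(0.0, 0.9), (0.0, 0.9)])
        scores = pu.ensemble_score(models, pd.DataFrame(np.zeros((2, 2))))
        assert (scores["J_ensemble"] == 0).all()

    def test_arithmetic_mean_of_normalized_outputs(self):
        models = self._models([(0.4, 0.8), (0.8, 0.8)])  # 0.5 and 1.0
        scores = pu.ensemble_score(models, pd.DataFrame(np.zeros((1, 2))))
        assert scores["J_ensemble"].iloc[0] == pytest.approx(0.75)

    def test_missing_rs_max_raises(self):
        m = pu.PUModel("s", _ConstantClassifier(0.5), c_hat=1.0)
        with pytest.raises(ValueError, match="rs_max"):
            pu.ensemble_score([m], pd.DataFrame(np.zeros((1, 2))))

    def test_validate_extremes(self):
        split, feats = _toy_split()
        high = pu.fit_pu(split, feats, seed=0, base=_ConstantClassifier(0.99))
        assert pu.validate(high, split, feats) == 1.0  # scores clip to 1
        low = pu.fit_pu(split, feats, seed=0, base=_ConstantClassifier(0.5))
        low.c_hat = 1.0  # base 0.5 / 1.0 = 0.5 < threshold
        assert pu.validate(low, split, feats) == 0.0


class TestHitSelection:
    def _scores(self):
        idx = [f"u{i}" for i in range(6)]
        return pd.DataFrame(
            {
                "pu_a": [1.0, 1.0, 0.96, 0.2, 0.0, 1.0],
                "pu_b": [1.0, 0.5, 0.97, 0.1, 0.0, 1.0],
                "J_ensemble": [1.0, 0.75, 0.965, 0.15, 0.0, 1.0],
                "n_agree": [2, 1, 2, 0, 0, 2],
            },
            index=idx,
        )

    def test_all_zero_scores_select_nothing(self):
        scores = self._scores()
        scores[["pu_a", "pu_b", "J_ensemble"]] = 0.0
        scores["n_agree"] = 0
        hits, _ = pu.select_hits(scores)
        assert hits.empty

    def test_min_agree_one_is_superset_of_all(self):
        scores = self._scores()
        loose, _ = pu.select_hits(scores, min_agree=1)
        strict, _ = pu.select_hits(scores, min_agree=None)
        assert set(strict.index) <= set(loose.index)

    def test_sorted_desc_with_id_tiebreak_and_histogram(self):
        hits, hist = pu.select_hits(self._scores())
        assert hits.index.tolist() == ["u0", "u5", "u2"]  # 1.0 tie → id order
        assert hist.loc[1] == 1 and hist.loc[2] == 3

    def test_threshold_monotonicity(self, small_study):
        table = small_study.feature_table
        unl = [r.id for r in small_study.corpus.unlabeled if r.id in table.index]
        counts = []
        for thr in (0.5, 0.95):
            scores = pu.ensemble_score(small_study.models, table.loc[unl], threshold=thr)
            hits, _ = pu.select_hits(scores, threshold=thr)
            counts.append(len(hits))
        assert counts[1] <= counts[0]


class TestPermutationImportance:
    def test_constant_column_has_zero_loss(self, small_study):
        table = small_study.feature_table.iloc[:120].copy()
        table["gc_content"] = 0.5
        labels = np.array([1 if i.startswith("rs_") else 0 for i in table.index])
        losses = pu.permutation_importance(
            small_study.models[:1], table, labels, repeats=3, seed=0
        )
        assert losses["gc_content"] == 0.0

    def test_losses_bounded_below(self, small_study):
        table = small_study.feature_table.iloc[:120]
        labels = np.array([1 if i.startswith("rs_") else 0 for i in table.index])
        losses = pu.permutation_importance(
            small_study.models[:1], table, labels, repeats=2, seed=0
        )
        assert np.isfinite(losses).all() and (losses >= -1).all()
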