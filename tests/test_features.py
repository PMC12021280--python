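"""The 74-element feature vector: k-mers, GC, structural block,
dataset normalization and KS diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riboscout import features as F
from riboscout.structure import FoldResult, fold, parse_structure

from .oracles import ks_statistic_bruteforce

acgu = st.text(alphabet="ACGU", min_size=3, max_size=120)


class TestSequenceFeatures:
    def test_repeated_trimer(self):
        v = F.kmer_freqs("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0

    def test_two_distinct_trimers(self):
        v = F.kmer_freqs("ACGU")
        named = dict(zip(F.KMERS, v))
        assert named["ACG"] == 0.5 and named["CGU"] == 0.5

    @given(acgu)
    def test_kmer_block_sums_to_one(self, seq):
        assert F.kmer_freqs(seq).sum() == pytest.approx(1.0)

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            F.kmer_freqs("AC")

    @pytest.mark.parametrize("seq, gc", [("GGCC", 1.0), ("AAUU", 0.0), ("ACGU", 0.5)])
    def test_gc_content(self, seq, gc):
        assert F.gc_content(seq) == gc

    def test_gc_empty_raises(self):
        with pytest.raises(ValueError):
            F.gc_content("")


class TestStructuralRaw:
    def test_fully_unpaired(self):
        counts = parse_structure("." * 30)
        raw = F.structural_raw(counts, 0.0, 30)
        assert raw.tolist() == [0, 0, 0, 0, 0, 0, 0, 0, 1.0]

    def test_branching_example_slots(self):
        counts = parse_structure("((...((...))...((...))...))")
        raw = F.structural_raw(counts, -6.0, 27)
        assert raw[1] == 2 and raw[2] == 1  # unbranched, branched

    def test_unpaired_fraction_slot(self):
        db = "...(((....)))...(((....)))..."
        raw = F.structural_raw(parse_structure(db), -6.0, len(db))
        # 9 multiloop/external unpaired NT over the structure's length
        assert raw[8] == pytest.approx(9 / len(db))


def _fold_result(db, mfe):
    return FoldResult(db, mfe, "test")


class TestNormalization:
    def test_single_record_maxima(self):
        db = "..((...))."
        counts = parse_structure(db)
        raw = F.structural_raw(counts, -2.0, len(db))
        ctx = F.fit_normalization([raw])
        v = F.assemble("GGAAAUUUCC", _fold_result(db, -2.0), ctx)
        # the max-normalized count slots are 1 where nonzero, 0 elsewhere
        assert set(np.round(v[66:73], 12)) <= {0.0, 1.0}

    def test_min_mfe_record_gets_one(self):
        raws = [np.array([-8.0] + [1] * 7 + [0.5]), np.array([-2.0] + [1] * 7 + [0.5])]
        ctx = F.fit_normalization(raws)
        assert ctx.mfe_min == -8.0

    def test_all_unstructured_dataset_guard(self):
        raw = np.array([0.0] * 8 + [1.0])
        ctx = F.fit_normalization([raw, raw])
        v = F.assemble("ACGUACGUACGU", _fold_result("." * 12, 0.0), ctx)
        assert v[65] == 0.0  # normalized MFE
        assert (ctx.count_max == 1.0).all()

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            F.fit_normalization([])

    def test_roundtrip_json(self, tmp_path):
        ctx = F.fit_normalization([np.array([-3.0, 1, 2, 0, 1, 4, 0, 2, 0.3])])
        ctx.to_json(tmp_path / "ctx.json")
        back = F.NormalizationContext.from_json(tmp_path / "ctx.json")
        assert back.mfe_min == ctx.mfe_min
        assert (back.count_max == ctx.count_max).all()


class TestAssembledVector:
    @given(st.integers(0, 5000))
    def test_dimensions_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), int(rng.integers(25, 100))))
        fr = fold(seq)
        raw = F.structural_raw(parse_structure(fr.dotbracket), fr.mfe, len(seq))
        ctx = F.fit_normalization([raw, np.array([-30.0, 5, 3, 4, 4, 6, 4, 4, 1.0])])
        v = F.assemble(seq, fr, ctx)
        assert v.shape == (74,)
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert v[:64].sum() == pytest.approx(1.0)

    def test_applying_context_twice_is_identical(self):
        seq = "GGGGAAAACCCCAAAGGGGAAAACCCC"
        fr = fold(seq)
        raw = F.structural_raw(parse_structure(fr.dotbracket), fr.mfe, len(seq))
        ctx = F.fit_normalization([raw])
        v1 = F.assemble(seq, fr, ctx)
        v2 = F.assemble(seq, fr, ctx)
        assert (v1 == v2).all()

    def test_feature_table_serialization_roundtrip(self, tmp_path):
        seqs = {f"r{i}": "GGGGAAAACCCC" + "ACGU" * (4 + i) for i in range(4)}
        folds = {rid: fold(s) for rid, s in seqs.items()}
        ctx = F.fit_normalization(F.raw_structural_table(seqs, folds))
        tab = F.feature_table(seqs, folds, ctx)
        assert list(tab.columns) == list(F.FEATURE_NAMES)
        path = tmp_path / "feat.csv"
        tab.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(back.to_numpy(), tab.to_numpy())

    def test_max_normalization_tightness_on_fitting_corpus(self):
        rng = np.random.default_rng(7)
        seqs = {
            f"r{i}": "".join(rng.choice(list("ACGU"), 60)) + "GGGGGAAAACCCCC"
            for i in range(30)
        }
        folds = {rid: fold(s) for rid, s in seqs.items()}
        ctx = F.fit_normalization(F.raw_structural_table(seqs, folds))
        tab = F.feature_table(seqs, folds, ctx)
        observed = tab.loc[:, list(F.STRUCTURAL_COUNT_NAMES)]
        raw_max = np.array(
            [
                max(
                    getattr(parse_structure(folds[r].dotbracket), a)
                    for r in seqs
                )
                for a in (
                    "n_unbranched_stacks", "n_branched_stacks", "n_loops_left",
                    "n_loops_right", "n_hairpins", "n_bulges_left", "n_bulges_right",
                )
            ]
        )
        # every structural column with a nonzero observation attains 1.0
        for col, mx in zip(F.STRUCTURAL_COUNT_NAMES, raw_max):
            if mx > 0:
                assert observed[col].max() == pytest.approx(1.0)


class TestKSDistances:
    def _table(self, rng, shift=0.0, n=40):
        data = rng.random((n, 74)) * 0.5 + shift
        return pd.DataFrame(np.clip(data, 0, 1), columns=F.FEATURE_NAMES)

    def test_identical_datasets_are_zero(self, rng):
        a = self._table(rng)
        assert (F.ks_distances(a, a) == 0).all()

    def test_disjoint_support_is_one(self, rng):
        a = self._table(rng, 0.0)
        b = self._table(rng, 0.51)
        assert F.ks_distances(a, b).min() == pytest.approx(1.0)

    def test_matches_bruteforce_cdf_comparison(self, rng):
        a = self._table(rng)
        b = self._table(rng, 0.1)
        stats = F.ks_distances(a, b)
        for col in list(F.FEATURE_NAMES)[:5] + ["mfe_norm", "unpaired_frac"]:
            assert stats[col] == pytest.approx(
                ks_statistic_bruteforce(a[col].tolist(), b[col].tolist())
            )

    def test_empty_raises(self, rng):
        with pytest.raises(ValueError):
            F.ks_distances(self._table(rng), self._table(rng).iloc[:0])
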