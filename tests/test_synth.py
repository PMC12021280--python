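"""The synthetic corpus generator: determinism, ground truth, and the
structural signal it promises."""

import numpy as np
import pytest

from riboscout import synth
from riboscout.sanitize import Source, preprocess_utr
from riboscout.structure import fold, parse_structure

from .conftest import small_config


class TestPositives:
    def test_count_conservation_and_labels(self):
        cfg = small_config(seed=1)
        records, plans = synth.gen_positives(cfg)
        assert len(records) == cfg.n_positives == 210
        assert {r.ligand for r in records} == {"ligand_a", "ligand_b", "ligand_c"}
        assert set(plans) == {r.id for r in records}
        for r in records[:20]:
            assert set(r.sequence) <= set("ACGU")
            assert len(plans[r.id]) == len(r.sequence)

    def test_planted_hairpins_are_recovered_by_folding(self):
        """Records of a 3-hairpin class fold into ≥ 3 hairpins in at
        least 90% of cases under the default backend."""
        cfg = small_config(seed=2)
        records, _ = synth.gen_positives(cfg)
        by_class = [r for r in records if r.ligand == "ligand_a"][:50]
        frac = np.mean(
            [parse_structure(fold(r.sequence).dotbracket).n_hairpins >= 3
             for r in by_class]
        )
        assert frac >= 0.9

    def test_same_seed_reproduces_byte_identical_output(self):
        a, _ = synth.gen_positives(small_config(seed=3))
        b, _ = synth.gen_positives(small_config(seed=3))
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_different_seed_changes_sequences(self):
        a, _ = synth.gen_positives(small_config(seed=3))
        b, _ = synth.gen_positives(small_config(seed=4))
        assert [r.sequence for r in a] != [r.sequence for r in b]

    def test_infeasible_stem_parameters_raise(self):
        cfg = small_config(
            seed=1,
            classes=(synth.ClassSpec("x", 5, stem_len=(40, 45), n_hairpins=(3, 3)),),
            length_range=(100, 120),
        )
        with pytest.raises(ValueError, match="does not fit"):
            synth.gen_positives(cfg)

    def test_no_classes_raises(self):
        with pytest.raises(ValueError):
            synth.gen_positives(small_config(seed=1, classes=()))


class TestUnlabeled:
    def test_spike_arithmetic_and_manifest(self):
        cfg = small_config(seed=5, n_unlabeled=1000, spike_fraction=0.05)
        records, manifest = synth.gen_unlabeled(cfg)
        assert len(records) == 1000
        assert len(manifest["spiked_ids"]) == 50
        assert all(r.ligand is None for r in records)
        assert all(r.source is Source.UNLABELED for r in records)

    def test_zero_spike_fraction_empty_manifest(self):
        cfg = small_config(seed=5, spike_fraction=0.0)
        _, manifest = synth.gen_unlabeled(cfg)
        assert manifest["spiked_ids"] == []


class TestRandomNegatives:
    def test_lengths_resampled_from_positives(self):
        cfg = small_config(seed=6, n_random_negatives=200)
        lengths = [130, 150, 164]
        negs = synth.gen_random_negatives(cfg, positive_lengths=lengths)
        assert len(negs) == 200
        assert {len(r.sequence) for r in negs} <= set(lengths)

    def test_base_composition_is_uniform(self):
        cfg = small_config(seed=7, n_random_negatives=400, length_range=(100, 101))
        negs = synth.gen_random_negatives(cfg)
        pooled = "".join(r.sequence for r in negs)
        for base in "ACGU":
            assert pooled.count(base) / len(pooled) == pytest.approx(0.25, abs=0.02)

    def test_seeded_determinism(self):
        cfg = small_config(seed=8, n_random_negatives=50)
        a = synth.gen_random_negatives(cfg)
        b = synth.gen_random_negatives(cfg)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestCdsStubs:
    def test_stubs_start_with_aug_and_have_configured_length(self):
        cfg = small_config(seed=9)
        records, _ = synth.gen_positives(cfg)
        stubs = synth.gen_cds_stubs(records[:30], cfg)
        for rid, stub in stubs.items():
            assert stub.startswith("AUG")
            assert len(stub) == cfg.cds_stub_length

    def test_windowing_succeeds_on_every_stub(self):
        cfg = small_config(seed=9)
        records, _ = synth.gen_positives(cfg)
        stubs = synth.gen_cds_stubs(records[:30], cfg)
        for r in records[:30]:
            window = preprocess_utr(r.sequence, stubs[r.id])
            assert window.endswith(stubs[r.id][:25])


class TestSeparationKnob:
    def test_zero_separation_matches_background_statistics(self):
        cfg = small_config(seed=10, separation=0.0)
        pos, plans = synth.gen_positives(cfg)
        assert all(set(p) == {"."} or p == "" for p in plans.values())
        # no planted pairs: structural intensity indistinguishable from background
        unl, _ = synth.gen_unlabeled(small_config(seed=10, spike_fraction=0.0))
        pos_pairs = np.mean(
            [fold(r.sequence).mfe / len(r.sequence) for r in pos[:40]]
        )
        bg_pairs = np.mean(
            [fold(r.sequence).mfe / len(r.sequence) for r in unl[:40]]
        )
        assert abs(pos_pairs - bg_pairs) < 0.02


class TestCorpus:
    def test_generate_corpus_is_complete_and_consistent(self):
        cfg = small_config(seed=11, n_random_negatives=30, n_exon_negatives=10)
        corpus = synth.generate_corpus(cfg)
        assert len(corpus.positives) == cfg.n_positives
        assert len(corpus.negatives) == 30
        assert len(corpus.exon_negatives) == 10
        assert set(corpus.spiked_ids) <= {r.id for r in corpus.unlabeled}
        all_ids = [r.id for r in corpus.positives + corpus.unlabeled
                   + corpus.negatives + corpus.exon_negatives]
        assert len(all_ids) == len(set(all_ids))
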