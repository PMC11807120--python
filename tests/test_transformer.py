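import numpy as np
import pytest

from rxntree.chem import canonical_smiles
from rxntree.data import make_training_pair
from rxntree.gcn import TemplateRanking
from rxntree.grammar import apply_template
from rxntree.tokenizer import TokenSequence, Vocabulary, condition_token, tokenize_smiles
from rxntree.transformer import Seq2SeqTransformer, TransformerConfig


@pytest.fixture(scope="module")
def tiny_model():
    """An untrained model over a small vocabulary, for mechanical checks."""
    vocab = Vocabulary.build(
        [list("CONc1()=Br"), ["Br", "Cl"]], n_templates=4
    )
    cfg = TransformerConfig(d_model=32, n_encoder_layers=1, n_decoder_layers=1,
                            d_ff=32, n_heads=2, dropout=0.0)
    return Seq2SeqTransformer(vocab, cfg, conditioned=True, seed=0)


def pairs_for(model, records, conditioned=True):
    return [make_training_pair(r, conditioned, model.vocab) for r in records]


class TestConfig:
    def test_head_count_must_divide_dimension(self):
        with pytest.raises(ValueError):
            TransformerConfig(d_model=50, n_heads=4)

    def test_full_scale_preset_matches_original_architecture(self):
        c = TransformerConfig.full_scale()
        assert (c.d_model, c.n_encoder_layers, c.d_ff, c.n_heads, c.dropout, c.batch_size) == (
            512, 6, 2048, 8, 0.1, 128)


class TestAccuracyMetrics:
    def test_partial_accuracy_matches_manual_recount(self, tiny_model):
        """Teacher-forced token accuracy equals an independent position count."""
        model = tiny_model
        from rxntree.data import ReactionRecord
        recs = [ReactionRecord("CCO", "CCBr", 1), ReactionRecord("CC(=O)O", "CC(=O)N", 2)]
        pairs = pairs_for(model, recs)
        got = model.partial_accuracy(pairs)
        correct = total = 0
        for src, tgt in pairs:
            s = model._pad([model.source_ids(src)])
            t = model._pad([model.target_ids(tgt)])
            pred = model.logits(s, t[:, :-1]).data.argmax(-1)[0]
            gold = t[0, 1:]
            for p, g in zip(pred, gold):
                if g != model.vocab.pad_id:
                    total += 1
                    correct += int(p == g)
        assert got == pytest.approx(correct / total)

    def test_perfect_at_most_partial_and_memorizer_is_exact(self, search_system):
        model = search_system.transformer
        pairs = pairs_for(model, search_system.records[:60])
        partial = model.partial_accuracy(pairs)
        perfect = model.perfect_accuracy(pairs)
        assert perfect <= partial + 1e-12
        assert perfect >= 0.95  # trained to reproduce its corpus

    def test_empty_pairs_raise(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.perfect_accuracy([])

    def test_out_of_vocabulary_token_rejected_before_training(self, tiny_model):
        bad = [(TokenSequence(("Z",)), TokenSequence(("C",)))]
        with pytest.raises(KeyError):
            tiny_model.fit(bad)


class TestDecoding:
    def test_beam_width_one_equals_greedy(self, search_system):
        model = search_system.transformer
        rec = search_system.records[0]
        src, _ = make_training_pair(rec, True, model.vocab)
        greedy = model.greedy_decode(src)
        beam = model.beam_decode(src, 1)
        assert beam.smiles()[0] == greedy

    def test_wider_beam_never_worse(self, search_system):
        model = search_system.transformer
        for rec in search_system.records[:5]:
            src, _ = make_training_pair(rec, True, model.vocab)
            best5 = model.beam_decode(src, 5).products[0][1]
            best20 = model.beam_decode(src, 20).products[0][1]
            assert best20 >= best5 - 1e-9

    def test_beam_results_valid_canonical_deduplicated(self, search_system):
        model = search_system.transformer
        src, _ = make_training_pair(search_system.records[3], True, model.vocab)
        out = model.beam_decode(src, 10)
        smis = out.smiles()
        assert len(set(smis)) == len(smis)
        assert all(s == canonical_smiles(s) for s in smis)
        scores = [sc for _, sc in out.products]
        assert scores == sorted(scores, reverse=True)

    def test_decoding_deterministic(self, search_system):
        model = search_system.transformer
        src, _ = make_training_pair(search_system.records[7], True, model.vocab)
        model._beam_cache.clear()
        a = model.beam_decode(src, 5)
        model._beam_cache.clear()
        b = model.beam_decode(src, 5)
        assert a == b

    def test_invalid_width(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.beam_decode(TokenSequence(("C",)), 0)

    def test_converged_conditional_rank1_matches_grammar_oracle(self, search_system):
        """The top beam product under a template condition is the oracle product."""
        model = search_system.transformer
        hits = 0
        for rec in search_system.records[:20]:
            src, _ = make_training_pair(rec, True, model.vocab)
            top = model.beam_decode(src, 5).smiles()[0]
            oracle = apply_template(rec.reactant, search_system.templates[rec.template_index])
            hits += top == oracle
        assert hits >= 19


class TestTopN:
    def test_nesting(self, search_system):
        model = search_system.transformer
        pairs = pairs_for(model, search_system.records[:30])
        t1 = model.top_n_accuracy(pairs, 1, 10)
        t5 = model.top_n_accuracy(pairs, 5, 10)
        t10 = model.top_n_accuracy(pairs, 10, 10)
        assert t1 <= t5 <= t10
        assert t1 >= 0.9  # memorizer

    def test_n_cannot_exceed_width(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.top_n_accuracy([], 11, 10)


class TestEnumerateProducts:
    def test_no_templates_empty(self, search_system):
        out = search_system.transformer.enumerate_products("CCO", TemplateRanking(()), 5)
        assert out == []

    def test_single_product_template_contributes_one(self, search_system):
        model = search_system.transformer
        smi = "COc1ccc(C)cc1"  # aryl methyl ether: demethylation (single product)
        t_demethyl = next(t for t in search_system.templates if t.name == "o_demethylation")
        ranking = TemplateRanking(((t_demethyl.index, 1.0),))
        out = model.enumerate_products(smi, ranking, width=5,
                                       single_product={t_demethyl.index})
        assert len(out) == 1
        prod, t_idx, rank = out[0]
        assert rank == 0 and t_idx == t_demethyl.index
        assert prod == apply_template(smi, t_demethyl)

    def test_bounded_by_templates_times_width(self, search_system):
        model = search_system.transformer
        smi = search_system.start
        ranking = search_system.gcn.predict_templates(smi, 10)
        from rxntree.gcn import filter_matching_templates
        ranking = filter_matching_templates(smi, ranking, search_system.template_patterns())
        out = model.enumerate_products(smi, ranking, width=2,
                                       single_product={t.index for t in search_system.templates if t.single_product})
        assert len(out) <= len(ranking) * 2
        smis = [p for p, _, _ in out]
        assert len(set(smis)) == len(smis)  # deduplicated across templates


class TestPersistence:
    def test_save_load_roundtrip(self, search_system, tmp_path):
        model = search_system.transformer
        model.save(tmp_path / "m")
        clone = Seq2SeqTransformer.load(tmp_path / "m")
        src, _ = make_training_pair(search_system.records[0], True, model.vocab)
        assert clone.greedy_decode(src) == model.greedy_decode(src)
        assert clone.config == model.config
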