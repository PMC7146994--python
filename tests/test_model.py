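import numpy as np
import pytest

from smilesgen import nn
from smilesgen.corpus import build_vocabulary, encode_windows
from smilesgen.model import (
    ArchitectureSpec,
    build_network,
    generate_smiles,
    train,
)


def lstm_params(input_size, hidden):
    return 4 * ((input_size + hidden) * hidden + hidden)


def gru_params(input_size, hidden):
    return 3 * ((input_size + hidden) * hidden + hidden)


def dense_params(input_size, output):
    return input_size * output + output


def expected_params(spec: ArchitectureSpec, V: int) -> int:
    """Closed-form parameter count, independent of the layer code."""
    unit = lstm_params if spec.unit == "LSTM" else gru_params
    if spec.family == "A":
        bi_embed = bi_enc = False
    elif spec.family == "B":
        bi_embed = bi_enc = True
    else:
        bi_embed = spec.bidirectional_embedding
        bi_enc = spec.bidirectional_encoding
    embed_mult = 2 if bi_embed else 1
    enc_mult = 2 if bi_enc else 1
    embed_out = spec.embedding_size * embed_mult
    enc_out = spec.encoding_size * enc_mult
    k = spec.branch_count
    embed = embed_mult * unit(V, spec.embedding_size)
    enc = enc_mult * unit(embed_out, spec.encoding_size)
    if spec.family in ("A", "B"):
        total = embed + enc
        merged = enc_out
    elif spec.family == "C":
        total = embed + k * enc
        merged = k * enc_out if spec.merge_mode == "concatenate" else enc_out
    else:
        total = k * (embed + enc)
        merged = k * enc_out if spec.merge_mode == "concatenate" else enc_out
    if k > 1 and spec.merge_mode == "learnable_average":
        total += k
    return total + dense_params(merged, V)


TABLE_CONFIGS = [
    # two-layer variants at both reference sizes, LSTM and GRU
    ArchitectureSpec("A", "LSTM", 256, 256, 1, "concatenate"),
    ArchitectureSpec("A", "GRU", 256, 256, 1, "concatenate"),
    ArchitectureSpec("B", "LSTM", 256, 256, 1, "concatenate"),
    ArchitectureSpec("B", "GRU", 256, 256, 1, "concatenate"),
    ArchitectureSpec("A", "LSTM", 64, 64, 1, "concatenate"),
    ArchitectureSpec("B", "LSTM", 64, 64, 1, "concatenate"),
    # parallel-encoder family at every evaluated branch count
    *[
        ArchitectureSpec("C", "LSTM", 64, 64, k, "concatenate")
        for k in [1, 2, 3, 4, 5, 6, 7, 8, 16]
    ],
    ArchitectureSpec("C", "LSTM", 64, 64, 4, "average"),
    ArchitectureSpec("C", "LSTM", 64, 64, 4, "learnable_average"),
    ArchitectureSpec("D", "LSTM", 64, 64, 4, "concatenate"),
    ArchitectureSpec("D", "LSTM", 64, 64, 4, "average"),
    ArchitectureSpec("D", "LSTM", 64, 64, 4, "learnable_average"),
    ArchitectureSpec("C", "LSTM", 128, 64, 4, "concatenate"),
]


class TestParameterCounts:
    @pytest.mark.parametrize(
        "spec", TABLE_CONFIGS, ids=lambda s: f"{s.family}-{s.unit}-"
        f"{s.embedding_size}/{s.encoding_size}-k{s.branch_count}-{s.merge_mode}"
    )
    def test_matches_closed_form(self, spec):
        V = 33
        model = build_network(spec, V, window_length=10)
        assert model.param_count() == expected_params(spec, V)

    def test_a_and_c_k1_identical_count(self):
        a = build_network(
            ArchitectureSpec("A", "LSTM", 32, 32, 1, "concatenate"), 20, 8
        )
        c = build_network(
            ArchitectureSpec(
                "C",
                "LSTM",
                32,
                32,
                1,
                "concatenate",
                bidirectional_embedding=False,
                bidirectional_encoding=False,
            ),
            20,
            8,
        )
        assert a.param_count() == c.param_count()


class TestForward:
    def test_softmax_sums_to_one(self):
        spec = ArchitectureSpec("C", "LSTM", 8, 8, 2, "concatenate")
        model = build_network(spec, 12, 6, seed=0)
        rng = np.random.default_rng(0)
        x = nn.one_hot(rng.integers(0, 12, size=(16, 6)), 12)
        probs = model.forward(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_output_shape(self):
        spec = ArchitectureSpec("B", "LSTM", 8, 8, 1, "concatenate")
        model = build_network(spec, 15, 5)
        x = nn.one_hot(np.zeros((3, 5), dtype=int), 15)
        assert model.forward(x).shape == (3, 15)

    def test_c_k1_forward_equals_b_with_same_weights(self):
        b = build_network(
            ArchitectureSpec("B", "LSTM", 8, 8, 1, "concatenate"), 10, 6,
            seed=4,
        )
        c = build_network(
            ArchitectureSpec("C", "LSTM", 8, 8, 1, "concatenate"), 10, 6,
            seed=5,
        )
        c.set_weights(b.get_weights())
        rng = np.random.default_rng(1)
        x = nn.one_hot(rng.integers(0, 10, size=(4, 6)), 10)
        np.testing.assert_allclose(b.forward(x), c.forward(x), atol=1e-6)

    def test_bidirectional_width_arithmetic(self):
        spec = ArchitectureSpec("C", "LSTM", 64, 64, 4, "concatenate")
        model = build_network(spec, 30, 8)
        assert model.output_width == 4 * 128
        spec_avg = ArchitectureSpec("C", "LSTM", 64, 64, 4, "average")
        assert build_network(spec_avg, 30, 8).output_width == 128

    def test_b_has_two_bidirectional_layers(self):
        model = build_network(
            ArchitectureSpec("B", "LSTM", 16, 16, 1, "concatenate"), 10, 6
        )
        recurrent = model.embed_layers + model.enc_layers
        assert len(recurrent) == 2
        assert all(isinstance(l, nn.Bidirectional) for l in recurrent)

    def test_mixed_units_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("B", "LSTMGRU", 8, 8, 1, "concatenate")


class TestLearnableAverage:
    def test_equal_logits_is_plain_average(self):
        merge = nn.LearnableAverageMerge(3)
        xs = [np.full((2, 4), float(i), dtype=np.float32) for i in range(3)]
        out = merge.forward_branches(xs)
        np.testing.assert_allclose(out, np.mean(xs, axis=0), atol=1e-7)

    def test_extreme_logit_selects_branch(self):
        merge = nn.LearnableAverageMerge(3)
        merge.params["logits"][1] = 50.0
        xs = [np.full((2, 4), float(i), dtype=np.float32) for i in range(3)]
        out = merge.forward_branches(xs)
        np.testing.assert_allclose(out, xs[1], atol=1e-7)

    def test_weights_sum_to_one_through_training(self):
        merge = nn.LearnableAverageMerge(4)
        rng = np.random.default_rng(0)
        for _ in range(25):
            xs = [
                rng.random((3, 5)).astype(np.float32) for _ in range(4)
            ]
            merge.forward_branches(xs)
            merge.backward(rng.random((3, 5)).astype(np.float32))
            merge.params["logits"] -= 0.1 * merge.grads["logits"]
            assert merge.weights.sum() == pytest.approx(1.0, abs=1e-6)
            assert (merge.weights >= 0).all()

    def test_k1_warns(self):
        with pytest.warns(UserWarning):
            nn.LearnableAverageMerge(1)

    def test_unequal_widths_rejected(self):
        merge = nn.AverageMerge()
        with pytest.raises(ValueError):
            merge.forward_branches(
                [np.zeros((2, 4)), np.zeros((2, 5))]
            )


class _StubModel:
    """Deterministic or uniform distribution emitter for sampler tests."""

    def __init__(self, vocab_size, window_length, script=None):
        self.vocab_size = vocab_size
        self.window_length = window_length
        self.script = script
        self._step = 0

    def forward(self, x, train=False):
        n = x.shape[0]
        out = np.full(
            (n, self.vocab_size), 1.0 / self.vocab_size, dtype=np.float32
        )
        if self.script is not None:
            idx = self.script[self._step % len(self.script)]
            out[:] = 1e-9
            out[:, idx] = 1.0
            self._step += 1
        return out


def _simple_vocab():
    return build_vocabulary(["CO"])  # chars: \n, C, O


class TestGeneration:
    def test_n_zero_empty_batch(self):
        vocab = _simple_vocab()
        stub = _StubModel(vocab.size, 4)
        batch = generate_smiles(stub, vocab, 0, seed=0)
        assert len(batch) == 0

    def test_scripted_stub_emits_cco(self):
        vocab = _simple_vocab()
        c = vocab.char_to_index["C"]
        o = vocab.char_to_index["O"]
        t = vocab.terminator_index
        stub = _StubModel(vocab.size, 4, script=[c, c, o, t])
        batch = generate_smiles(stub, vocab, 5, greedy=True, max_length=10)
        assert batch.strings == ["CCO"] * 5
        assert batch.truncated == [False] * 5

    def test_fixed_seed_reproducible(self):
        vocab = _simple_vocab()
        stub = _StubModel(vocab.size, 4)
        a = generate_smiles(stub, vocab, 20, seed=7, max_length=15)
        b = generate_smiles(stub, vocab, 20, seed=7, max_length=15)
        assert a.strings == b.strings

    def test_truncation_flagged(self):
        vocab = _simple_vocab()
        c = vocab.char_to_index["C"]
        stub = _StubModel(vocab.size, 4, script=[c])  # never terminates
        batch = generate_smiles(stub, vocab, 3, greedy=True, max_length=6)
        assert batch.truncated == [True] * 3
        assert batch.strings == ["CCCCCC"] * 3

    def test_uniform_stub_character_frequencies(self):
        # sampling correctness: uniform model => uniform char draws
        from collections import Counter

        vocab = _simple_vocab()
        V = vocab.size
        stub = _StubModel(V, 4)
        batch = generate_smiles(stub, vocab, 600, seed=3, max_length=30)
        draws = [ch for s in batch.strings for ch in s]
        freq = Counter(draws)
        # each non-terminator char equally likely among emitted chars
        expected = len(draws) / (V - 1)
        sd = np.sqrt(len(draws) * (1 / (V - 1)) * (1 - 1 / (V - 1)))
        for c in [ch for ch in vocab.chars if ch != vocab.terminator]:
            assert abs(freq.get(c, 0) - expected) < 3 * sd

    def test_temperature_must_be_positive(self):
        vocab = _simple_vocab()
        stub = _StubModel(vocab.size, 4)
        with pytest.raises(ValueError):
            generate_smiles(stub, vocab, 1, temperature=0.0)

    def test_desubstitution_applied(self):
        vocab = build_vocabulary(["LR"])
        l = vocab.char_to_index["L"]
        r = vocab.char_to_index["R"]
        t = vocab.terminator_index
        stub = _StubModel(vocab.size, 4, script=[l, r, t])
        batch = generate_smiles(stub, vocab, 1, greedy=True, max_length=5)
        assert batch.strings == ["ClBr"]


@pytest.fixture(scope="module")
def tiny_corpus():
    texts = ["CCO", "CCN", "CCC", "CC(C)O", "OCCO"] * 8
    vocab = build_vocabulary(texts)
    return encode_windows(texts, vocab, window_length=5), vocab


class TestTraining:

    def test_examiner_stop_at_first_epoch(self, tiny_corpus):
        corpus, vocab = tiny_corpus
        spec = ArchitectureSpec("A", "LSTM", 8, 8, 1, "concatenate")
        model = build_network(spec, vocab.size, 5, seed=0)
        cks = train(
            model,
            corpus,
            examiner_callback=lambda e, m: (True, 12.5),
            max_epochs=10,
            seed=0,
        )
        assert len(cks) == 1
        assert cks[0].validity_percent == 12.5

    def test_loss_trajectory_deterministic(self, tiny_corpus):
        corpus, vocab = tiny_corpus
        spec = ArchitectureSpec("A", "LSTM", 8, 8, 1, "concatenate")
        losses = []
        for _ in range(2):
            model = build_network(spec, vocab.size, 5, seed=1)
            cks = train(model, corpus, max_epochs=3, seed=1)
            losses.append([c.loss for c in cks])
        assert losses[0] == losses[1]

    def test_loss_decreases(self, tiny_corpus):
        corpus, vocab = tiny_corpus
        spec = ArchitectureSpec("A", "LSTM", 12, 12, 1, "concatenate")
        model = build_network(spec, vocab.size, 5, seed=2)
        cks = train(model, corpus, max_epochs=5, seed=2)
        assert cks[-1].loss < cks[0].loss

    def test_checkpoint_per_epoch(self, tiny_corpus):
        corpus, vocab = tiny_corpus
        spec = ArchitectureSpec("A", "GRU", 6, 6, 1, "concatenate")
        model = build_network(spec, vocab.size, 5, seed=0)
        cks = train(model, corpus, max_epochs=4, seed=0)
        assert [c.epoch for c in cks] == [1, 2, 3, 4]

    def test_empty_corpus_rejected(self, tiny_corpus):
        _, vocab = tiny_corpus
        from smilesgen.corpus import EncodedCorpus

        empty = EncodedCorpus(
            contexts=np.zeros((0, 5), dtype=np.int16),
            labels=np.zeros(0, dtype=np.int16),
            window_length=5,
            vocabulary=vocab,
        )
        spec = ArchitectureSpec("A", "LSTM", 4, 4, 1, "concatenate")
        model = build_network(spec, vocab.size, 5)
        with pytest.raises(ValueError):
            train(model, empty, max_epochs=1)


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path, small_corpus):
        from smilesgen.model import load_checkpoint, save_checkpoint
        from smilesgen.model import TrainedCheckpoint

        _, texts, vocab = small_corpus
        spec = ArchitectureSpec("A", "LSTM", 6, 6, 1, "concatenate")
        model = build_network(spec, vocab.size, 6, seed=0)
        ckpt = TrainedCheckpoint(
            epoch=3, weights_ref=model.get_weights(), loss=1.5,
            validity_percent=42.0,
        )
        save_checkpoint(tmp_path, ckpt, spec)
        loaded = load_checkpoint(tmp_path, 3, vocab.size, 6)
        assert loaded.checksum() == model.checksum()
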