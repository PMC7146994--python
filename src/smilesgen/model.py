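"""Generator architectures: build, train and sample.

Four wiring families are supported. A and B are a two-layer recurrent
stack (unidirectional and bidirectional respectively); C keeps a single
embedding layer but fans out into parallel encoding layers whose
outputs are merged; D replicates the whole embedding+encoding stack in
parallel. "Embedding" here means the first recurrent layer reading the
one-hot character window, not a lookup table. The network maps a
(W, V) one-hot context to a length-V next-character distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import nn
from .corpus import EncodedCorpus, Vocabulary, desubstitute_tokens

Family = str  # "A" | "B" | "C" | "D"
MERGE_MODES = ("concatenate", "average", "learnable_average")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one generator variant."""

    family: str = "C"
    unit: str = "LSTM"
    embedding_size: int = 64
    encoding_size: int = 64
    branch_count: int = 4
    merge_mode: str = "concatenate"
    bidirectional_embedding: bool = True
    bidirectional_encoding: bool = True
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.family not in "ABCD":
            raise ValueError(f"unknown family {self.family!r}")
        if self.unit not in ("LSTM", "GRU"):
            raise ValueError("unit must be LSTM or GRU (not mixed)")
        if self.merge_mode not in MERGE_MODES:
            raise ValueError(f"unknown merge mode {self.merge_mode!r}")
        if self.family in "AB" and self.branch_count != 1:
            raise ValueError(f"family {self.family} requires branch_count=1")
        if self.branch_count < 1:
            raise ValueError("branch_count must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSpec":
        return cls(**data)


@dataclass
class TrainedCheckpoint:
    epoch: int  # 1-based
    weights_ref: dict[str, np.ndarray]
    loss: float
    validity_percent: Optional[float] = None


@dataclass
class GenerationBatch:
    """Raw sampler output: desubstituted SMILES candidates."""

    strings: list[str]
    truncated: list[bool]
    temperature: float
    max_length: int
    seed: int

    def __len__(self) -> int:
        return len(self.strings)


def _default_spec_ab(spec: ArchitectureSpec) -> tuple[bool, bool]:
    # family A is unidirectional, B bidirectional, regardless of the
    # embedding/encoding flags (which only matter for C and D)
    if spec.family == "A":
        return False, False
    if spec.family == "B":
        return True, True
    return spec.bidirectional_embedding, spec.bidirectional_encoding


class CharRNN:
    """A built generator network with manual forward/backward."""

    def __init__(
        self,
        spec: ArchitectureSpec,
        vocab_size: int,
        window_length: int,
        seed: int = 0,
    ) -> None:
        if vocab_size < 2:
            raise ValueError("vocab_size must be >= 2")
        if window_length < 1:
            raise ValueError("window_length must be >= 1")
        self.spec = spec
        self.vocab_size = vocab_size
        self.window_length = window_length
        rng = np.random.default_rng(seed)
        bi_embed, bi_enc = _default_spec_ab(spec)
        unit = nn.LSTM if spec.unit == "LSTM" else nn.GRU
        k = spec.branch_count

        def make_layer(in_size, size, bi, return_seq):
            if bi:
                return nn.Bidirectional(
                    unit(in_size, size, return_seq, rng),
                    unit(in_size, size, return_seq, rng),
                )
            return unit(in_size, size, return_seq, rng)

        embed_out = spec.embedding_size * (2 if bi_embed else 1)
        enc_out = spec.encoding_size * (2 if bi_enc else 1)
        self.embed_layers: list[nn.Layer] = []
        self.enc_layers: list[nn.Layer] = []
        if spec.family == "D":
            for _ in range(k):
                self.embed_layers.append(
                    make_layer(vocab_size, spec.embedding_size, bi_embed, True)
                )
                self.enc_layers.append(
                    make_layer(embed_out, spec.encoding_size, bi_enc, False)
                )
        else:
            self.embed_layers.append(
                make_layer(vocab_size, spec.embedding_size, bi_embed, True)
            )
            n_branches = k if spec.family == "C" else 1
            for _ in range(n_branches):
                self.enc_layers.append(
                    make_layer(embed_out, spec.encoding_size, bi_enc, False)
                )
        n_branches = len(self.enc_layers)
        self.merge: Optional[nn.Layer]
        if n_branches == 1:
            self.merge = None
            merged_width = enc_out
        elif spec.merge_mode == "concatenate":
            self.merge = nn.ConcatenateMerge()
            merged_width = n_branches * enc_out
        elif spec.merge_mode == "average":
            self.merge = nn.AverageMerge()
            merged_width = enc_out
        else:
            self.merge = nn.LearnableAverageMerge(n_branches)
            merged_width = enc_out
        self.dropout = nn.Dropout(spec.dropout_rate, np.random.default_rng(seed + 1))
        self.dense = nn.Dense(merged_width, vocab_size, rng)
        self.output_width = merged_width

    # -- parameter plumbing -------------------------------------------------
    def _layers(self) -> list[tuple[str, nn.Layer]]:
        out = [(f"embed{i}", l) for i, l in enumerate(self.embed_layers)]
        out += [(f"enc{i}", l) for i, l in enumerate(self.enc_layers)]
        if self.merge is not None and self.merge.params:
            out.append(("merge", self.merge))
        out.append(("dense", self.dense))
        return out

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, layer in self._layers()
            for k, v in layer.params.items()
        }

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, layer in self._layers()
            for k, v in layer.grads.items()
        }

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.params
        if set(weights) != set(params):
            raise ValueError("weight name mismatch")
        for k, v in weights.items():
            params[k][...] = v

    def checksum(self) -> str:
        return nn.weights_checksum(self.params)

    # -- forward / backward -------------------------------------------------
    def forward(self, x_onehot: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, W, V) one-hot -> (B, V) softmax probabilities."""
        if len(self.embed_layers) == 1:
            embedded = self.embed_layers[0].forward(x_onehot, train)
            branch_outputs = [
                enc.forward(embedded, train) for enc in self.enc_layers
            ]
        else:  # family D: independent stacks
            branch_outputs = [
                enc.forward(emb.forward(x_onehot, train), train)
                for emb, enc in zip(self.embed_layers, self.enc_layers)
            ]
        if self.merge is None:
            merged = branch_outputs[0]
        else:
            merged = self.merge.forward_branches(branch_outputs)
        logits = self.dense.forward(self.dropout.forward(merged, train), train)
        self._last_logits = logits
        return nn.softmax(logits, axis=-1)

    def backward(self, dlogits: np.ndarray) -> None:
        dmerged = self.dropout.backward(self.dense.backward(dlogits))
        if self.merge is None:
            dbranches = [dmerged]
        else:
            dbranches = self.merge.backward(dmerged)
        if len(self.embed_layers) == 1:
            dembedded = sum(
                enc.backward(db)
                for enc, db in zip(self.enc_layers, dbranches)
            )
            self.embed_layers[0].backward(dembedded)
        else:
            for emb, enc, db in zip(
                self.embed_layers, self.enc_layers, dbranches
            ):
                emb.backward(enc.backward(db))


def build_network(
    spec: ArchitectureSpec,
    vocab_size: int,
    window_length: int,
    seed: int = 0,
) -> CharRNN:
    """Construct an untrained generator network for the given variant."""
    return CharRNN(spec, vocab_size, window_length, seed=seed)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


#: examiner callback: (epoch, model) -> (stop, validity_percent or None)
ExaminerCallback = Callable[[int, CharRNN], tuple[bool, Optional[float]]]


def train(
    model: CharRNN,
    corpus: EncodedCorpus,
    examiner_callback: Optional[ExaminerCallback] = None,
    max_epochs: int = 100,
    seed: int = 0,
    batch_size: int = 128,
    learning_rate: float = 1e-3,
    checkpoint_dir: Optional[Path] = None,
    verbose: bool = False,
) -> list[TrainedCheckpoint]:
    """Train on next-character cross-entropy, checkpointing each epoch
    and consulting the examiner callback after every epoch.

    Windows are reshuffled every epoch with an epoch-derived seed, so
    runs are reproducible from (corpus, seed). Raises
    :class:`DivergenceError` if the loss goes non-finite.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    V = corpus.vocabulary.size
    opt = nn.Adam(model.params, lr=learning_rate)
    n = len(corpus)
    checkpoints: list[TrainedCheckpoint] = []
    for epoch in range(1, max_epochs + 1):
        rng = np.random.default_rng((seed, epoch))
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            x = nn.one_hot(corpus.contexts[idx], V)
            y = corpus.labels[idx].astype(np.int64)
            probs = model.forward(x, train=True)
            batch = len(idx)
            eps = 1e-12
            loss = -np.log(probs[np.arange(batch), y] + eps).sum()
            total_loss += float(loss)
            dlogits = probs.copy()
            dlogits[np.arange(batch), y] -= 1.0
            dlogits /= batch
            model.backward(dlogits.astype(nn.DTYPE))
            opt.step(model.params, model.grads)
        mean_loss = total_loss / n
        if not np.isfinite(mean_loss):
            raise DivergenceError(f"loss became {mean_loss} at epoch {epoch}")
        ckpt = TrainedCheckpoint(
            epoch=epoch, weights_ref=model.get_weights(), loss=mean_loss
        )
        stop = False
        if examiner_callback is not None:
            stop, validity = examiner_callback(epoch, model)
            ckpt.validity_percent = validity
        checkpoints.append(ckpt)
        if checkpoint_dir is not None:
            save_checkpoint(checkpoint_dir, ckpt, model.spec)
        if verbose:
            print(
                f"epoch {epoch}: loss {mean_loss:.4f}"
                + (
                    f" validity {ckpt.validity_percent:.1f}%"
                    if ckpt.validity_percent is not None
                    else ""
                )
            )
        if stop:
            break
    return checkpoints


def save_checkpoint(
    directory: Path, ckpt: TrainedCheckpoint, spec: ArchitectureSpec
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"epoch_{ckpt.epoch:03d}"
    np.savez(stem.with_suffix(".npz"), **ckpt.weights_ref)
    sidecar = {
        "epoch": ckpt.epoch,
        "loss": ckpt.loss,
        "validity_percent": ckpt.validity_percent,
        "spec": spec.to_dict(),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return stem.with_suffix(".npz")


def load_checkpoint(
    directory: Path, epoch: int, vocab_size: int, window_length: int
) -> CharRNN:
    directory = Path(directory)
    stem = directory / f"epoch_{epoch:03d}"
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    spec = ArchitectureSpec.from_dict(sidecar["spec"])
    model = CharRNN(spec, vocab_size, window_length)
    with np.load(stem.with_suffix(".npz")) as data:
        model.set_weights({k: data[k] for k in data.files})
    return model


def generate_smiles(
    model,
    vocab: Vocabulary,
    n: int,
    temperature: float = 1.0,
    max_length: int = 120,
    seed: int = 0,
    greedy: bool = False,
) -> GenerationBatch:
    """Sample n SMILES strings from the model.

    Each string starts from a context of W terminators; characters are
    drawn from the softmax (divided by ``temperature``) until the
    terminator appears or ``max_length`` is reached (such strings are
    flagged truncated but still returned — they count as candidates).
    Output strings are desubstituted back to standard SMILES. ``model``
    needs only ``forward``, ``window_length`` and ``vocab_size``; test
    stubs can stand in for a trained network.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return GenerationBatch([], [], temperature, max_length, seed)
    rng = np.random.default_rng(seed)
    W = model.window_length
    V = model.vocab_size
    term = vocab.terminator_index
    contexts = np.full((n, W), term, dtype=np.int64)
    done = np.zeros(n, dtype=bool)
    outputs: list[list[int]] = [[] for _ in range(n)]
    for _ in range(max_length):
        active = np.flatnonzero(~done)
        if len(active) == 0:
            break
        x = nn.one_hot(contexts[active], V)
        probs = model.forward(x, train=False)
        if greedy:
            choices = np.argmax(probs, axis=-1)
        else:
            if temperature != 1.0:
                logits = np.log(np.maximum(probs, 1e-12)) / temperature
                probs = nn.softmax(logits, axis=-1)
            cdf = np.cumsum(probs.astype(np.float64), axis=-1)
            cdf /= cdf[:, -1:]
            u = rng.random((len(active), 1))
            choices = (u > cdf).sum(axis=1)
        for row, choice in zip(active, choices):
            if choice == term:
                done[row] = True
            else:
                outputs[row].append(int(choice))
        contexts[active, :-1] = contexts[active, 1:]
        contexts[active, -1] = choices
    strings = [
        desubstitute_tokens(vocab.decode(chars)) for chars in outputs
    ]
    truncated = [not d for d in done]
    return GenerationBatch(
        strings=strings,
        truncated=truncated,
        temperature=temperature,
        max_length=max_length,
        seed=seed,
    )
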