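"""Pluggable note-text encoders and the hierarchical temporal module.

The default encoder is a lightweight trainable embedding bag (mean-pooled
token embeddings) — the adapter interface (``name``, ``dim``, ``max_length``,
``encode(tokens)``) lets a long-context transformer be swapped in where one
is available. Temporal modeling is a 2-layer Bi-LSTM over the time-ordered
note embeddings with additive attention pooling to a patient vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, const
from ._nn import AdditiveAttention, BiLSTM, Module, xavier
from ._autograd import param
from .corpus import Note, PatientRecord

log = logging.getLogger(__name__)

UNK = "<unk>"


class EncoderError(ValueError):
    pass


def build_vocab(records: list[PatientRecord], min_count: int = 1) -> dict[str, int]:
    """Token vocabulary from (training) records; index 0 is the OOV bucket."""
    from .preprocess import tokenize
    counts: dict[str, int] = {}
    for r in records:
        for n in r.notes:
            for t in (n.tokens if n.tokens is not None else tokenize(n.text)):
                counts[t] = counts.get(t, 0) + 1
    vocab = {UNK: 0}
    for t in sorted(counts):
        if counts[t] >= min_count:
            vocab[t] = len(vocab)
    return vocab


class EmbeddingBagEncoder(Module):
    """Trainable token-embedding table, mean-pooled per note."""

    name = "bag"

    def __init__(self, vocab: dict[str, int], dim: int = 32, seed: int = 0,
                 max_length: int = 4096):
        self.vocab = vocab
        self.dim = dim
        self.max_length = max_length
        rng = np.random.default_rng(seed)
        self.table = param(xavier(rng, len(vocab), dim))

    def token_ids(self, tokens: list[str]) -> np.ndarray:
        if len(tokens) > self.max_length:
            log.debug("encoder truncating note from %d to %d tokens",
                      len(tokens), self.max_length)
            tokens = tokens[: self.max_length]
        return np.array([self.vocab.get(t, 0) for t in tokens], dtype=np.intp)

    def encode(self, tokens: list[str]) -> Tensor:
        if not tokens:
            return const(np.zeros(self.dim))
        ids = self.token_ids(tokens)
        return self.table.take_rows(ids).mean(axis=0)


ENCODERS = {"bag": EmbeddingBagEncoder}


def get_encoder_factory(name: str):
    if name not in ENCODERS:
        raise EncoderError(
            f"unregistered encoder adapter {name!r}; known: {sorted(ENCODERS)}"
        )
    return ENCODERS[name]


@dataclass
class NoteEmbedding:
    """Mean-pooled dense representation of one note."""

    vector: Tensor
    source: str = "bag"

    @property
    def dim(self):
        return self.vector.data.shape[0]


def encode_note(note: Note, encoder) -> NoteEmbedding:
    from .preprocess import tokenize
    tokens = note.tokens if note.tokens is not None else tokenize(note.text)
    return NoteEmbedding(vector=encoder.encode(tokens), source=encoder.name)


def cache_note_embeddings(encoder, records: list[PatientRecord], path) -> None:
    """Persist eval-mode embeddings keyed by note_id (npz matrix file)."""
    keys, mats = [], []
    for r in records:
        for n in r.notes:
            keys.append(n.note_id)
            mats.append(encode_note(n, encoder).vector.data)
    np.savez(path, note_ids=np.array(keys), embeddings=np.stack(mats))


# ---------------------------------------------------------------------------
# temporal module


@dataclass
class TemporalEncoding:
    """Per-note recurrent states, attention weights, and the pooled vector."""

    u: list[Tensor]                 # one state per note, time order
    v: Tensor                       # attention-pooled patient vector
    alpha: np.ndarray               # attention weights, simplex-valued
    meta: dict = field(default_factory=dict)


class TemporalEncoder(Module):
    """Bi-LSTM over note embeddings + additive temporal attention."""

    def __init__(self, rng, d_in: int, d_hidden: int = 256, n_layers: int = 2,
                 d_attn: int | None = None):
        self.bilstm = BiLSTM(rng, d_in, d_hidden, n_layers=n_layers)
        self.attn = AdditiveAttention(rng, self.bilstm.d_out, d_attn or d_hidden)
        self.d_out = self.bilstm.d_out

    def __call__(self, embeddings: list[Tensor]) -> TemporalEncoding:
        if not embeddings:
            raise EncoderError("temporal_encode requires at least one note")
        u = self.bilstm(embeddings)
        v, alpha = self.attn(u)
        a = alpha.data.copy()
        assert abs(a.sum() - 1.0) < 1e-6 and np.all(a >= 0)
        return TemporalEncoding(u=u, v=v, alpha=a)


def temporal_encode(sequence: list[NoteEmbedding] | list[Tensor],
                    module: TemporalEncoder) -> TemporalEncoding:
    """Apply the temporal module to time-ordered note embeddings."""
    embs = [e.vector if isinstance(e, NoteEmbedding) else e for e in sequence]
    return module(embs)
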