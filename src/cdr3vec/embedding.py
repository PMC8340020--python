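"""Skip-gram n-gram embedding of CDR3 sequences.

The model is a word2vec-style shallow network trained with the skip-gram
objective and negative sampling on a corpus of tokenized CDR3 sequences.
Because CDR3s are short, the default context window (25 tokens) spans the
whole sentence, so every token in a sequence is context for every other.

A whole sequence is converted to a vector with the shift-average rule: for
gram size n, the n shifted variants of the sequence (dropping 0, 1, ..., n-1
leading residues) are each tokenized non-overlappingly, the vectors of all
resulting tokens are summed, and the sum is divided by the total token count
across all variants.  A sequence of exactly n residues therefore embeds to
exactly its single token's vector.  Any out-of-vocabulary token makes the
sequence non-embeddable (callers skip and log).

Training is deterministic given the seed (single worker, numpy RNG only).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .airr_io import TrimConfig
from .corpus import read_corpus, tokenize_nonoverlapping
from .errors import (
    CorruptModelError,
    NotEmbeddableError,
    OOVError,
    TooShortError,
    TrainingError,
)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyper-parameters of the skip-gram model.

    dim=100, window=25 and min_count=2 follow the recommended settings for
    CDR3 corpora; the window deliberately exceeds any tokenized CDR3 length so
    the whole sequence acts as context.
    """

    n: int = 3
    dim: int = 100
    window: int = 25
    min_count: int = 2
    algorithm: str = "skip-gram"
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.dim <= 1024):
            raise ValueError("dim must be in [2, 1024]")
        if self.window < 1 or self.min_count < 1:
            raise ValueError("window and min_count must be >= 1")
        if self.algorithm != "skip-gram":
            raise ValueError("only the skip-gram algorithm is supported")


class SequenceVector(NamedTuple):
    """Shift-averaged sequence embedding and the token count that normalized it."""

    vector: np.ndarray
    n_grams_used: int


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _build_pairs(sentences: Sequence[Sequence[str]], vocab: dict[str, int], window: int) -> np.ndarray:
    pairs: list[tuple[int, int]] = []
    for sent in sentences:
        idx = [vocab[t] for t in sent if t in vocab]
        for i, center in enumerate(idx):
            lo = max(0, i - window)
            hi = min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, idx[j]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(pairs, dtype=np.int64)


class CDR3Embedder(TransformerMixin, BaseEstimator):
    """Skip-gram embedding of CDR3 n-grams, scikit-learn transformer style.

    Parameters mirror :class:`EmbeddingConfig`.  ``fit`` expects an iterable
    of *already trimmed* amino-acid sequences (or pre-tokenized sentences);
    ``transform`` maps trimmed sequences to shift-averaged vectors.  The trim
    used at training time is stored on the model so that
    :meth:`embed_junction` can apply the identical trim at inference.

    Fitted attributes
    -----------------
    vocab_ : dict mapping token -> row index
    vectors_ : ndarray of shape (len(vocab_), dim), the input-layer vectors
    counts_ : dict mapping token -> corpus frequency
    """

    def __init__(
        self,
        n: int = 3,
        dim: int = 100,
        window: int = 25,
        min_count: int = 2,
        epochs: int = 5,
        negative: int = 5,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
        seed: int = 0,
        trim: TrimConfig = TrimConfig(),
        batch_size: int = 4096,
    ) -> None:
        self.n = n
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed
        self.trim = trim
        self.batch_size = batch_size

    # -- training ---------------------------------------------------------

    def _as_sentences(self, X: Iterable) -> list[list[str]]:
        sentences = []
        for item in X:
            if isinstance(item, str):
                tokens = tokenize_nonoverlapping(item, self.n)
            else:
                tokens = list(item)
            if tokens:
                sentences.append(tokens)
        return sentences

    def fit(self, X: Iterable, y=None) -> "CDR3Embedder":
        """Train on an iterable of trimmed sequences or token lists."""
        cfg = self.config  # validates hyper-parameters
        sentences = self._as_sentences(X)
        if not sentences:
            raise TrainingError("empty corpus: nothing to train on")
        counts = Counter(t for sent in sentences for t in sent)
        kept = sorted(t for t, c in counts.items() if c >= self.min_count)
        if not kept:
            raise TrainingError(
                f"vocabulary empty after min_count={self.min_count} filter"
            )
        vocab = {t: i for i, t in enumerate(kept)}
        pairs = _build_pairs(sentences, vocab, self.window)
        if len(pairs) == 0:
            raise TrainingError("no (center, context) pairs; sentences too short")

        V = len(vocab)
        rng = np.random.default_rng(self.seed)
        W = (rng.random((V, self.dim)) - 0.5) / self.dim  # input vectors
        C = np.zeros((V, self.dim))  # output (context) vectors

        # unigram^0.75 noise distribution, standard for negative sampling
        freq = np.array([counts[t] for t in kept], dtype=float) ** 0.75
        noise = freq / freq.sum()

        n_batches = self.epochs * max(1, -(-len(pairs) // self.batch_size))
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(pairs))
            for start in range(0, len(pairs), self.batch_size):
                batch = pairs[order[start : start + self.batch_size]]
                lr = self.alpha + (self.min_alpha - self.alpha) * step / max(1, n_batches - 1)
                step += 1
                centers = batch[:, 0]
                ctx = batch[:, 1]
                neg = rng.choice(V, size=(len(batch), self.negative), p=noise)
                targets = np.concatenate([ctx[:, None], neg], axis=1)  # B x K
                labels = np.zeros(targets.shape)
                labels[:, 0] = 1.0
                w = W[centers]  # B x d
                cv = C[targets]  # B x K x d
                scores = _sigmoid(np.einsum("bd,bkd->bk", w, cv))
                g = (labels - scores) * lr  # B x K
                dW = np.einsum("bk,bkd->bd", g, cv)
                dC = g[..., None] * w[:, None, :]
                np.add.at(W, centers, dW)
                np.add.at(C, targets.reshape(-1), dC.reshape(-1, self.dim))

        self.vocab_ = vocab
        self.vectors_ = W
        self.counts_ = dict(counts)
        return self

    @property
    def config(self) -> EmbeddingConfig:
        return EmbeddingConfig(
            n=self.n,
            dim=self.dim,
            window=self.window,
            min_count=self.min_count,
            epochs=self.epochs,
            negative=self.negative,
            alpha=self.alpha,
            min_alpha=self.min_alpha,
            seed=self.seed,
        )

    # -- inference --------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "vocab_"):
            raise TrainingError("model is not fitted")

    def embed_ngram(self, gram: str) -> np.ndarray:
        """Stored vector of an in-vocabulary token; :class:`OOVError` otherwise."""
        self._check_fitted()
        if len(gram) != self.n:
            raise ValueError(f"gram {gram!r} has length {len(gram)}, expected {self.n}")
        try:
            return self.vectors_[self.vocab_[gram]]
        except KeyError:
            raise OOVError(gram) from None

    def shifted_variants(self, seq: str) -> list[str]:
        """The n shifted variants: drop 0, 1, ..., n-1 leading residues."""
        return [seq[k:] for k in range(self.n)]

    def embed_sequence(self, seq: str) -> SequenceVector:
        """Shift-average embedding of a trimmed sequence.

        Sums the vectors of every token of every shifted variant and divides
        by the total token count; variants too short to yield a token
        contribute nothing to numerator or denominator.
        """
        self._check_fitted()
        if len(seq) < self.n:
            raise TooShortError(
                f"sequence of length {len(seq)} shorter than gram size {self.n}"
            )
        total = np.zeros(self.dim)
        used = 0
        for variant in self.shifted_variants(seq):
            for tok in tokenize_nonoverlapping(variant, self.n):
                row = self.vocab_.get(tok)
                if row is None:
                    raise NotEmbeddableError(
                        f"token {tok!r} of sequence {seq!r} not in vocabulary"
                    )
                total += self.vectors_[row]
                used += 1
        return SequenceVector(vector=total / used, n_grams_used=used)

    def embed_junction(self, cdr3_aa: str) -> SequenceVector:
        """Trim with the model's own :class:`TrimConfig`, then embed."""
        from .airr_io import trim_cdr3

        return self.embed_sequence(trim_cdr3(cdr3_aa, self.trim))

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Embed trimmed sequences; raises on any OOV sequence (use
        :func:`embed_sequences` for skip-and-report behaviour)."""
        return np.vstack([self.embed_sequence(s).vector for s in X])

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_model(self, path)


def embed_sequences(
    model: CDR3Embedder, seqs: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Embed many sequences, skipping the non-embeddable ones.

    Returns ``(matrix, kept_indices, skipped_indices)``; ``matrix`` has one
    row per kept sequence.
    """
    rows, kept, skipped = [], [], []
    for i, s in enumerate(seqs):
        try:
            rows.append(model.embed_sequence(s).vector)
            kept.append(i)
        except (OOVError, TooShortError):
            skipped.append(i)
    mat = np.vstack(rows) if rows else np.empty((0, model.dim))
    return mat, np.asarray(kept, dtype=int), skipped


# -- functional wrappers ---------------------------------------------------


def train_embedding(
    corpus: str | Path | Sequence[Sequence[str]],
    cfg: EmbeddingConfig = EmbeddingConfig(),
    trim: TrimConfig = TrimConfig(),
) -> CDR3Embedder:
    """Train from a corpus file (one space-delimited sentence per line) or
    in-memory sentences."""
    if isinstance(corpus, (str, Path)):
        sentences = read_corpus(corpus)
    else:
        sentences = [list(s) for s in corpus]
    model = CDR3Embedder(
        n=cfg.n,
        dim=cfg.dim,
        window=cfg.window,
        min_count=cfg.min_count,
        epochs=cfg.epochs,
        negative=cfg.negative,
        alpha=cfg.alpha,
        min_alpha=cfg.min_alpha,
        seed=cfg.seed,
        trim=trim,
    )
    return model.fit(sentences)


def save_model(model: CDR3Embedder, path: str | Path) -> None:
    """Persist as text word-vector format plus a JSON sidecar.

    The main file starts with a ``"<vocab_size> <dim>"`` header followed by
    one ``"<token> <v1> ... <vdim>"`` line per token; the sidecar
    ``<path>.json`` records the hyper-parameters and the trim used at
    training, so applying the model always trims the way training did.
    """
    model._check_fitted()
    path = Path(path)
    tokens = sorted(model.vocab_, key=model.vocab_.__getitem__)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {model.dim}\n")
        for tok in tokens:
            vec = " ".join(repr(float(v)) for v in model.vectors_[model.vocab_[tok]])
            fh.write(f"{tok} {vec}\n")
    meta = {
        "config": asdict(model.config),
        "trim": asdict(model.trim),
        "counts": model.counts_,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta), encoding="utf-8")


def load_model(path: str | Path) -> CDR3Embedder:
    """Inverse of :func:`save_model`; validates header/vector consistency."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise CorruptModelError(f"{path}: empty model file")
    try:
        vocab_size, dim = (int(x) for x in lines[0].split())
    except ValueError:
        raise CorruptModelError(f"{path}: malformed header {lines[0]!r}") from None
    body = [ln for ln in lines[1:] if ln.strip()]
    if vocab_size == 0 or len(body) != vocab_size:
        raise CorruptModelError(
            f"{path}: header promises {vocab_size} tokens, file has {len(body)}"
        )
    vocab: dict[str, int] = {}
    vectors = np.empty((vocab_size, dim))
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) != dim + 1:
            raise CorruptModelError(
                f"{path}: row {i} has {len(parts) - 1} values, expected {dim}"
            )
        vocab[parts[0]] = i
        vectors[i] = [float(x) for x in parts[1:]]

    meta_path = Path(str(path) + ".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        cfg = EmbeddingConfig(**meta["config"])
        trim = TrimConfig(**meta["trim"])
        counts = {str(k): int(v) for k, v in meta.get("counts", {}).items()}
    else:
        n = len(next(iter(vocab)))
        cfg = EmbeddingConfig(n=n, dim=dim)
        trim = TrimConfig()
        counts = {}
    if cfg.dim != dim:
        raise CorruptModelError(
            f"{path}: sidecar dim {cfg.dim} disagrees with header dim {dim}"
        )
    model = CDR3Embedder(
        n=cfg.n,
        dim=cfg.dim,
        window=cfg.window,
        min_count=cfg.min_count,
        epochs=cfg.epochs,
        negative=cfg.negative,
        alpha=cfg.alpha,
        min_alpha=cfg.min_alpha,
        seed=cfg.seed,
        trim=trim,
    )
    model.vocab_ = vocab
    model.vectors_ = vectors
    model.counts_ = counts
    return model
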