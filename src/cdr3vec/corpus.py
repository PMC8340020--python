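"""Tokenizing trimmed CDR3 sequences into non-overlapping n-grams.

A CDR3 amino-acid sequence plays the role of a sentence and each fixed-length
n-gram (default n=3) the role of a word.  Tokenization is non-overlapping and
starts at offset 0: a sequence of length L yields floor(L/n) tokens and the
trailing remainder is discarded.  The training corpus contains exactly one
tokenized line per sequence, in input order; shifted variants appear only at
embedding time (see :mod:`cdr3vec.embedding`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .airr_io import _AA20_SET, RearrangementRecord, TrimConfig
from .errors import AlphabetError


@dataclass(frozen=True)
class CorpusConfig:
    """Gram size and the trim applied upstream of tokenization."""

    n: int = 3
    trim: TrimConfig = field(default_factory=TrimConfig)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("gram size n must be >= 1")


@dataclass
class CorpusSummary:
    n_sentences: int = 0
    n_tokens: int = 0
    n_distinct: int = 0
    n_skipped: int = 0


def tokenize_nonoverlapping(seq: str, n: int) -> list[str]:
    """Split ``seq`` into consecutive non-overlapping n-grams from position 0.

    The trailing ``len(seq) mod n`` residues are discarded, so concatenating
    the returned tokens reproduces the first ``floor(len/n)*n`` characters.
    """
    if set(seq) - _AA20_SET:
        raise AlphabetError(
            f"sequence contains non-standard residues: {sorted(set(seq) - _AA20_SET)}"
        )
    return [seq[i : i + n] for i in range(0, len(seq) - n + 1, n)]


def _as_sequence(item: "str | RearrangementRecord") -> str:
    if isinstance(item, RearrangementRecord):
        if item.cdr3_aa is None:
            raise ValueError(f"record {item.sequence_id} has no cdr3_aa")
        return item.cdr3_aa
    return item


def build_corpus(
    records: Iterable["str | RearrangementRecord"],
    cfg: CorpusConfig,
    out: str | Path,
) -> CorpusSummary:
    """Write the tokenized corpus (one space-delimited sentence per line).

    ``records`` must already be trimmed per ``cfg.trim``; sequences yielding
    zero tokens (length < n) are skipped and counted in the summary.
    """
    out = Path(out)
    summary = CorpusSummary()
    distinct: set[str] = set()
    with out.open("w", encoding="utf-8") as fh:
        for item in records:
            tokens = tokenize_nonoverlapping(_as_sequence(item), cfg.n)
            if not tokens:
                summary.n_skipped += 1
                continue
            fh.write(" ".join(tokens) + "\n")
            summary.n_sentences += 1
            summary.n_tokens += len(tokens)
            distinct.update(tokens)
    summary.n_distinct = len(distinct)
    return summary


def read_corpus(path: str | Path) -> list[list[str]]:
    """Read a corpus file back as a list of token lists."""
    sentences = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                sentences.append(line.split(" "))
    return sentences


def tokenize_records(
    records: Sequence["str | RearrangementRecord"], cfg: CorpusConfig
) -> list[list[str]]:
    """In-memory variant of :func:`build_corpus`: token lists, empty ones dropped."""
    out = []
    for item in records:
        tokens = tokenize_nonoverlapping(_as_sequence(item), cfg.n)
        if tokens:
            out.append(tokens)
    return out
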