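"""Reading, cleaning, tokenizing and encoding clinical-note records.

A corpus is a sequence of records, each carrying a free-text note (for
example a discharge summary) and the set of diagnosis/procedure codes a
human coder assigned to the admission.  This module turns such records
into fixed-length integer sequences plus binary label vectors over the
``k`` most frequent codes, the form the classifier consumes.

Conventions
-----------
* PAD has index 0, UNK index 1; both are always present in a vocabulary.
* Tokens rarer than ``min_count`` in the training corpus encode as UNK.
* Notes longer than ``max_len`` keep their first ``max_len`` tokens
  (discharge summaries front-load diagnoses), shorter ones are padded on
  the right with PAD.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD_TOKEN = "<pad>"
UNK_TOKEN = "UNK"
PAD_INDEX = 0
UNK_INDEX = 1

#: Minimal English stop-word list used when the caller injects none.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from has he her his in is it its of on
    or she that the this to was were will with""".split()
)

# De-identification placeholders look like "[**2172-7-6**]" or
# "[**Last Name (NamePattern1) 47696**]"; the whole span is noise.
_DEID_RE = re.compile(r"\[\*\*.*?\*\*\]", flags=re.DOTALL)
_TOKEN_RE = re.compile(r"[a-z0-9]+")


class NoRetainedCodesError(ValueError):
    """Record has no code left in the selected code set (must be filtered out)."""


@dataclass(frozen=True)
class RawRecord:
    """One clinical-note record: identifier, free text, assigned code set."""

    record_id: str
    text: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))


@dataclass(frozen=True)
class Vocabulary:
    """Dense token -> index map with fixed PAD=0 / UNK=1 slots."""

    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        t2i = self.token_to_index
        if t2i.get(PAD_TOKEN) != PAD_INDEX or t2i.get(UNK_TOKEN) != UNK_INDEX:
            raise ValueError("vocabulary must map PAD to 0 and UNK to 1")
        if sorted(t2i.values()) != list(range(len(t2i))):
            raise ValueError("vocabulary indices must be dense in [0, v)")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tok, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        t2i: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                t2i[tok] = int(idx)
        return cls(t2i)


@dataclass(frozen=True)
class CodeSet:
    """Ordered list of selected codes with their training-corpus frequencies.

    Order is descending frequency with lexicographic tie-break; label-vector
    positions are fixed by this order for the lifetime of a model.
    """

    codes: tuple[str, ...]
    frequencies: tuple[int, ...]
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if len(self.codes) != len(self.frequencies):
            raise ValueError("codes and frequencies must align")
        order = sorted(zip(self.codes, self.frequencies), key=lambda cf: (-cf[1], cf[0]))
        if tuple(c for c, _ in order) != self.codes:
            raise ValueError("codes must be ordered by descending frequency, ties lexicographic")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.index_of

    @property
    def index_of(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codes)}

    def label_vector(self, codes: Iterable[str]) -> np.ndarray:
        y = np.zeros(len(self.codes), dtype=np.int8)
        lookup = self.index_of
        for c in codes:
            if c in lookup:
                y[lookup[c]] = 1
        return y

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for code, freq in zip(self.codes, self.frequencies):
                fh.write(f"{code}\t{freq}\n")

    @classmethod
    def load(cls, path: str | Path) -> "CodeSet":
        codes, freqs = [], []
        with open(path) as fh:
            for line in fh:
                c, f = line.rstrip("\n").split("\t")
                codes.append(c)
                freqs.append(int(f))
        return cls(tuple(codes), tuple(freqs))


@dataclass(frozen=True)
class EncodedRecord:
    """Padded/truncated token index sequence plus a binary label vector."""

    record_id: str
    token_indices: np.ndarray  # (max_len,) int32
    label_vector: np.ndarray  # (l_g,) int8
    n_tokens: int = field(default=0)  # real (pre-padding) token count, capped at max_len

    def __post_init__(self) -> None:
        if self.label_vector.sum() < 1:
            raise ValueError("encoded record must retain at least one label")


def tokenize(
    text: str,
    stopwords: frozenset[str] | set[str] | None = None,
    min_token_chars: int = 1,
) -> list[str]:
    """Clean and tokenize a clinical note.

    Strips de-identification placeholders (``[** ... **]`` spans) wholesale,
    lowercases, keeps alphanumeric runs only, then removes stop words.
    ``min_token_chars`` optionally drops very short tokens (default keeps all).
    An input that cleans down to nothing yields an empty list.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    cleaned = _DEID_RE.sub(" ", text).lower()
    toks = _TOKEN_RE.findall(cleaned)
    return [t for t in toks if t not in stopwords and len(t) >= min_token_chars]


def build_vocabulary(corpus: Sequence[Sequence[str]], min_count: int = 3) -> Vocabulary:
    """Build a vocabulary from tokenized notes.

    Tokens with corpus frequency below ``min_count`` are excluded and will
    encode as UNK.  Index assignment is deterministic: descending frequency,
    lexicographic tie-break, starting after the PAD/UNK slots.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(tok for doc in corpus for tok in doc)
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count and tok not in (PAD_TOKEN, UNK_TOKEN)),
        key=lambda tok: (-counts[tok], tok),
    )
    t2i = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for i, tok in enumerate(kept, start=2):
        t2i[tok] = i
    return Vocabulary(t2i)


def select_top_codes(records: Sequence[RawRecord], k: int) -> CodeSet:
    """Select the ``k`` most frequent codes; ties break lexicographically.

    ``coverage`` on the returned set is the fraction of records that retain
    at least one code after restriction — records outside it are discarded
    before encoding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(rec.codes)
    if len(counts) < k:
        warnings.warn(
            f"only {len(counts)} distinct codes present, fewer than requested k={k}",
            stacklevel=2,
        )
    ranked = sorted(counts.items(), key=lambda cf: (-cf[1], cf[0]))[:k]
    selected = {c for c, _ in ranked}
    covered = sum(1 for rec in records if rec.codes & selected)
    coverage = covered / len(records) if records else 0.0
    return CodeSet(
        tuple(c for c, _ in ranked), tuple(f for _, f in ranked), coverage=coverage
    )


def encode_record(
    record: RawRecord,
    vocab: Vocabulary,
    codes: CodeSet,
    max_len: int = 1800,
    stopwords: frozenset[str] | set[str] | None = None,
    min_token_chars: int = 1,
) -> EncodedRecord:
    """Encode one record to indices + label vector.

    Raises :class:`NoRetainedCodesError` when the record keeps no code from
    ``codes`` — such records are dropped from the experiment, which is a
    different condition from malformed input.
    """
    label = codes.label_vector(record.codes)
    if label.sum() == 0:
        raise NoRetainedCodesError(
            f"record {record.record_id!r} retains no code from the selected set"
        )
    toks = tokenize(record.text, stopwords=stopwords, min_token_chars=min_token_chars)
    idx = np.full(max_len, PAD_INDEX, dtype=np.int32)
    kept = toks[:max_len]
    idx[: len(kept)] = [vocab.index(t) for t in kept]
    return EncodedRecord(record.record_id, idx, label, n_tokens=len(kept))


def encode_corpus(
    records: Sequence[RawRecord],
    vocab: Vocabulary,
    codes: CodeSet,
    max_len: int = 1800,
    **tokenize_kwargs,
) -> list[EncodedRecord]:
    """Encode all records, silently dropping those with no retained code."""
    out = []
    for rec in records:
        try:
            out.append(encode_record(rec, vocab, codes, max_len, **tokenize_kwargs))
        except NoRetainedCodesError:
            continue
    return out


# ---------------------------------------------------------------------------
# Corpus file format: one record per line, tab-separated
#   record_id <TAB> text <TAB> code1;code2;...
# ---------------------------------------------------------------------------

def write_corpus(records: Iterable[RawRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            text = rec.text.replace("\t", " ").replace("\n", " ")
            fh.write(f"{rec.record_id}\t{text}\t{';'.join(sorted(rec.codes))}\n")


def read_corpus(path: str | Path) -> list[RawRecord]:
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                record_id, text, code_field = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"malformed corpus line {lineno}: {line!r}") from exc
            if record_id in seen:
                raise ValueError(f"duplicate record_id {record_id!r} at line {lineno}")
            seen.add(record_id)
            codes = frozenset(c for c in code_field.split(";") if c)
            records.append(RawRecord(record_id, text, codes))
    return records
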