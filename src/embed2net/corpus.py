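"""Corpus preprocessing: normalization and dictionary-based synonym substitution.

The preprocessing phase lowercases, strips punctuation, optionally removes
purely numeric tokens and lemmatizes, and then (optionally) replaces every
synonym of a biomedical entity by its preferred term so that all mentions of
a concept collapse onto a single vocabulary item before embedding training.
Multi-word preferred terms become single underscore-joined tokens
(e.g. "breast neoplasms" -> "breast_neoplasms").
"""

from __future__ import annotations

import csv
import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DecodeError, SynonymAmbiguityError, TableValidationError
from .lemmatize import lemmatize, lemmatize_phrase

ENTITY_TYPES = ("gene", "disease", "drug", "other")

_NON_WORD = re.compile(r"[^\w]+", re.UNICODE)
_NUMERIC = re.compile(r"^\d+$")


@dataclass(frozen=True)
class TextDocument:
    doc_id: str
    text: str


@dataclass(frozen=True)
class TokenSequence:
    doc_id: str
    tokens: tuple[str, ...]

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)


@dataclass(frozen=True)
class PreprocessConfig:
    lemmatize: bool = True
    substitute_synonyms: bool = True
    drop_numeric: bool = True
    min_token_length: int = 1

    def __post_init__(self):
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


def _tokenize(text: str, *, lemma: bool, drop_numeric: bool,
              min_len: int) -> tuple[str, ...]:
    text = _NON_WORD.sub(" ", text.lower())
    out = []
    for tok in text.split():
        if drop_numeric and _NUMERIC.match(tok):
            continue
        if lemma:
            tok = lemmatize(tok)
        if len(tok) >= min_len:
            out.append(tok)
    return tuple(out)


def normalize_text(doc: TextDocument, config: PreprocessConfig) -> TokenSequence:
    """Lowercase, strip punctuation, drop numeric tokens, lemmatize."""
    text = doc.text
    if isinstance(text, bytes):
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise DecodeError(f"document {doc.doc_id!r}: undecodable text") from exc
    return TokenSequence(doc.doc_id, _tokenize(
        text, lemma=config.lemmatize, drop_numeric=config.drop_numeric,
        min_len=config.min_token_length))


@dataclass
class SynonymTable:
    """Maps normalized synonym phrases to (preferred term, entity type).

    Phrases are stored as word tuples. Each phrase is keyed both on its
    surface form and on its lemmatized form; surface matches take priority.
    Preferred terms are stored space-separated and emitted underscore-joined.
    """

    surface: dict[tuple[str, ...], str] = field(default_factory=dict)
    lemma: dict[tuple[str, ...], str] = field(default_factory=dict)
    types: dict[str, str] = field(default_factory=dict)  # preferred token -> type
    max_len: int = 0

    @staticmethod
    def preferred_token(preferred: str) -> str:
        return "_".join(preferred.split())

    def add(self, preferred: str, synonym: str, entity_type: str) -> None:
        if entity_type not in ENTITY_TYPES:
            raise TableValidationError(
                f"unknown entity_type {entity_type!r} for synonym {synonym!r}")
        syn_words = tuple(synonym.split())
        if not syn_words or not preferred.split():
            raise TableValidationError(
                f"empty phrase in row ({preferred!r}, {synonym!r})")
        existing = self.surface.get(syn_words)
        if existing is not None and existing != preferred:
            raise SynonymAmbiguityError(
                f"synonym {synonym!r} maps to both {existing!r} and {preferred!r}")
        self.surface[syn_words] = preferred
        lemma_words = lemmatize_phrase(syn_words)
        self.lemma.setdefault(lemma_words, preferred)
        self.types[self.preferred_token(preferred)] = entity_type
        self.max_len = max(self.max_len, len(syn_words), len(lemma_words))

    def lookup(self, words: tuple[str, ...]) -> str | None:
        hit = self.surface.get(words)
        if hit is None:
            hit = self.lemma.get(words)
        return hit

    def type_of(self, preferred_token: str) -> str | None:
        return self.types.get(preferred_token)

    def __len__(self) -> int:
        return len(self.surface)


def load_synonym_table(path: str | Path) -> SynonymTable:
    """Read a TSV with columns preferred_term / synonym / entity_type.

    Phrases are normalized with the same rules as the corpus text (no
    lemmatization of the stored surface forms; a lemmatized key is added
    alongside). A synonym phrase mapping to two distinct preferred terms is
    an ambiguity error listing the offending rows.
    """
    table = SynonymTable()
    seen: dict[tuple[str, ...], tuple[int, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"preferred_term", "synonym", "entity_type"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableValidationError(
                f"synonym table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            preferred = " ".join(_tokenize(
                row["preferred_term"] or "", lemma=False, drop_numeric=False,
                min_len=1))
            synonym = " ".join(_tokenize(
                row["synonym"] or "", lemma=False, drop_numeric=False, min_len=1))
            etype = (row["entity_type"] or "").strip().lower()
            syn_words = tuple(synonym.split())
            prior = seen.get(syn_words)
            if prior is not None and prior[1] != preferred:
                raise SynonymAmbiguityError(
                    f"synonym {synonym!r} maps to {prior[1]!r} (line {prior[0]}) "
                    f"and {preferred!r} (line {lineno})")
            table.add(preferred, synonym, etype)
            seen[syn_words] = (lineno, preferred)
    return table


def substitute_synonyms(tokens: TokenSequence | Sequence[str],
                        table: SynonymTable) -> TokenSequence:
    """Replace maximal synonym-phrase matches by preferred terms.

    Greedy longest-match, left-to-right, non-overlapping. Multi-word matches
    collapse to a single underscore-joined preferred token, so the token
    count never increases.
    """
    doc_id = tokens.doc_id if isinstance(tokens, TokenSequence) else ""
    toks = tuple(tokens.tokens if isinstance(tokens, TokenSequence) else tokens)
    if not table.surface:
        return TokenSequence(doc_id, toks)
    out: list[str] = []
    i, n = 0, len(toks)
    max_len = max(table.max_len, 1)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            hit = table.lookup(toks[i:i + length])
            if hit is not None:
                out.append(SynonymTable.preferred_token(hit))
                i += length
                matched = True
                break
        if not matched:
            out.append(toks[i])
            i += 1
    return TokenSequence(doc_id, tuple(out))


def preprocess_corpus(documents: Iterable[TextDocument],
                      config: PreprocessConfig,
                      table: SynonymTable | None = None) -> list[TokenSequence]:
    """Normalize (and optionally synonym-substitute) every document, in order."""
    out = []
    for doc in documents:
        seq = normalize_text(doc, config)
        if config.substitute_synonyms and table is not None:
            seq = substitute_synonyms(seq, table)
        out.append(seq)
    return out


def read_corpus(path: str | Path) -> list[TextDocument]:
    """Read a plain-text corpus, one document per line; gzip by suffix."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    docs = []
    with opener(path, "rt", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if line:
                docs.append(TextDocument(doc_id=f"doc{i}", text=line))
    return docs


def write_token_sequences(path: str | Path, seqs: Iterable[TokenSequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(" ".join(seq.tokens) + "\n")
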