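"""Note data model, tokenization, vocabulary, splits and OOV analysis.

A note is one free-text clinical document carrying a multilabel set of
top-level disease codes (possibly derived by rolling up fine-grained subtype
annotations).  Cross-hospital transfer is analysed through the vocabulary:
the tagger's word embeddings exist only for tokens seen in its training
hospital, so the fraction of target-domain tokens missing from the source
vocabulary (the OOV rate) is the first-order measure of lexical shift.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ontology import CodeOntology, rollup

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[./-][a-z0-9]+)*")
_NUMERIC_RE = re.compile(r"^[0-9]+(?:[./,-][0-9]+)*$")


@dataclass
class Note:
    """One clinical document: id, text, token sequence, label vector."""

    id: str
    text: str
    tokens: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None  # binary vector over disease codes
    subtypes: set[str] | None = None
    domain: str = ""

    def label_set(self) -> frozenset[int]:
        if self.labels is None:
            return frozenset()
        return frozenset(np.flatnonzero(self.labels).tolist())


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus the shuffle seed.

    Default 0.9/0.05/0.05.
    """

    train: float = 0.9
    validation: float = 0.05
    test: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(f < 0 for f in fracs):
            raise ValueError(f"negative split fraction in {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {fracs} do not sum to 1")


class Vocabulary:
    """Token -> contiguous integer ids, with reserved padding and unknown ids.

    Built from the training split only; tokens below the frequency cutoff
    share the single unknown id.
    """

    def __init__(self, tokens: Sequence[str], min_freq: int = 1) -> None:
        self.min_freq = min_freq
        self._token_to_id: dict[str, int] = {PAD_TOKEN: 0, UNK_TOKEN: 1}
        for tok in tokens:
            if tok not in self._token_to_id:
                self._token_to_id[tok] = len(self._token_to_id)
        self._id_to_token = [None] * len(self._token_to_id)
        for t, i in self._token_to_id.items():
            self._id_to_token[i] = t

    pad_id = 0
    unk_id = 1

    def __len__(self) -> int:
        return len(self._token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id

    def id_of(self, token: str) -> int:
        return self._token_to_id.get(token, self.unk_id)

    def encode(self, tokens: Iterable[str]) -> np.ndarray:
        return np.array([self.id_of(t) for t in tokens], dtype=np.int64)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, t in enumerate(self._id_to_token):
                fh.write(f"{t}\t{i}\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        tokens = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                t, i = line.rstrip("\n").split("\t")
                if int(i) >= 2:
                    tokens.append(t)
        return cls(tokens, min_freq=1)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace/punctuation; punctuation is dropped.

    Internal separators of measurements and abbreviations (``1.5``, ``q8-12h``)
    are kept so numeric tokens stay recognizable as numeric.  Deterministic;
    the empty string yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def is_numeric_token(token: str) -> bool:
    """True for all-digit tokens, optionally with ./,- separators (e.g. 3, 1.5)."""
    return bool(_NUMERIC_RE.match(token))


def build_vocabulary(notes: Sequence[Note], min_freq: int = 1) -> Vocabulary:
    """Build a vocabulary from training notes; cutoff tokens map to unknown."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    counts: dict[str, int] = {}
    for note in notes:
        for tok in note.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    kept = [t for t in counts if counts[t] >= min_freq]
    return Vocabulary(sorted(kept), min_freq=min_freq)


def split_corpus(
    notes: Sequence[Note], spec: SplitSpec = SplitSpec()
) -> tuple[list[Note], list[Note], list[Note]]:
    """Deterministically partition notes into train/validation/test.

    A seeded shuffle is followed by cutting at sizes rounded to nearest from
    the fractions; any rounding remainder goes to the training split.  The
    three parts are disjoint and exhaustive.
    """
    if len(notes) < 3:
        raise ValueError("need at least 3 notes to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(notes))
    n = len(notes)
    n_val = int(round(spec.validation * n))
    n_test = int(round(spec.test * n))
    n_train = n - n_val - n_test
    idx = iter(order)
    train = [notes[i] for _, i in zip(range(n_train), idx)]
    val = [notes[i] for _, i in zip(range(n_val), idx)]
    test = [notes[i] for _, i in zip(range(n_test), idx)]
    return train, val, test


def oov_rate(
    target_notes: Sequence[Note],
    vocabulary: Vocabulary,
    drop_numeric: bool = True,
) -> dict[str, float]:
    """Fraction of target-domain tokens absent from a source vocabulary.

    Returns both the occurrence-level rate (fraction of token occurrences
    that are out of vocabulary) and the type-level rate (fraction of distinct
    tokens), since either reading is defensible for a reported OOV figure.
    Numeric tokens are removed first when ``drop_numeric`` is set, matching
    the convention of quoting OOV "after filtering out numbers".
    """
    occ_total = occ_oov = 0
    types: dict[str, bool] = {}
    for note in target_notes:
        for tok in note.tokens:
            if drop_numeric and is_numeric_token(tok):
                continue
            occ_total += 1
            missing = tok not in vocabulary
            occ_oov += missing
            types[tok] = missing
    if occ_total == 0:
        raise ValueError("no target tokens left after filtering")
    return {
        "occurrence": occ_oov / occ_total,
        "type": sum(types.values()) / len(types),
        "n_occurrences": occ_total,
        "n_types": len(types),
    }


# -- serialization ----------------------------------------------------------


def notes_to_jsonl(notes: Iterable[Note], path) -> None:
    """Write notes as JSON-lines: id, text, subtypes and/or labels, domain."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            obj = {"id": note.id, "text": note.text, "domain": note.domain}
            if note.subtypes is not None:
                obj["subtypes"] = sorted(note.subtypes)
            if note.labels is not None:
                obj["labels"] = [int(x) for x in note.labels]
            fh.write(json.dumps(obj) + "\n")


def notes_from_jsonl(
    path,
    ontology: CodeOntology | None = None,
    n_labels: int | None = None,
) -> list[Note]:
    """Read JSON-lines notes, tokenizing text and resolving labels.

    Labels come from an explicit ``labels`` list when present, otherwise by
    rolling up the ``subtypes`` list through ``ontology``.
    """
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            subtypes = set(obj["subtypes"]) if "subtypes" in obj else None
            if "labels" in obj:
                labels = np.asarray(obj["labels"], dtype=np.int8)
            elif subtypes is not None and ontology is not None:
                labels = rollup(subtypes, ontology)
            else:
                labels = None if n_labels is None else np.zeros(n_labels, dtype=np.int8)
            notes.append(
                Note(
                    id=str(obj["id"]),
                    text=obj["text"],
                    tokens=tokenize(obj["text"]),
                    labels=labels,
                    subtypes=subtypes,
                    domain=obj.get("domain", ""),
                )
            )
    return notes


def training_eligible(notes: Iterable[Note]) -> list[Note]:
    """Notes with at least one positive label (the training-set condition)."""
    return [n for n in notes if n.labels is not None and n.labels.any()]
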