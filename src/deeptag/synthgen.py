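"""Synthetic clinical-note corpora with planted multilabel structure.

Real training corpora of expert-coded veterinary notes are restricted, so
every other module is exercised on generated ones that reproduce the
statistical structure the method assumes:

* multilabel notes — each note carries >= 1 top-level code, about 8 on
  average, drawn from a long-tailed code-frequency distribution;
* subtype diversity — each code is realized textually through many keyword
  "subtypes", so codes with more subtypes spread their training signal
  thinner;
* meta-disease structure — codes in the same meta-disease share theme
  tokens, so the label hierarchy is learnable from text;
* a shifted second domain — shorter notes, consistent abbreviation
  substitutions and fresh out-of-vocabulary tokens, and subtypes unique to
  the new domain, emulating transfer from a university referral hospital to
  a private practice.

Documents are bags of keyword tokens interleaved with background tokens at
random positions: the encoder is order-sensitive, but the planted signal is
lexical, which is the simplest structure that supports every property the
package tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Note
from .ontology import CodeOntology, rollup


@dataclass
class GeneratorConfig:
    """Study conditions for the source-domain corpus.

    Defaults mirror the real setting: 42 disease codes in 18 meta-diseases,
    a mean of 8 labels per note (minimum 1), mean document length 325 words,
    and long-tailed code frequencies.
    """

    n_codes: int = 42
    n_metas: int = 18
    subtype_range: tuple[int, int] = (2, 10)   # distinct subtypes per code
    subtype_counts: tuple[int, ...] | None = None  # explicit per-code counts (overrides range)
    keywords_per_subtype: int = 3              # subtype-specific tokens
    code_tokens: int = 2                       # shared across a code's subtypes
    meta_theme_tokens: int = 2                 # shared across a meta's codes
    keyword_repeat: int = 2                    # occurrences per injected keyword
    background_vocab_size: int = 2000
    numeric_token_fraction: float = 0.05       # share of background slots that are numbers
    doc_length_mean: float = 325.0
    mean_labels_per_note: float = 8.0
    freq_exponent: float = 1.0                 # code weight ~ (rank+1)^-exponent
    label_flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_range[0] < 1:
            raise ValueError("every code needs at least one subtype")
        if self.subtype_counts is not None:
            if len(self.subtype_counts) != self.n_codes:
                raise ValueError("subtype_counts must list one count per code")
            if min(self.subtype_counts) < 1:
                raise ValueError("every code needs at least one subtype")
        if self.n_metas > self.n_codes:
            raise ValueError("cannot have more metas than codes")
        if self.mean_labels_per_note < 1:
            raise ValueError("notes carry at least one label on average")


@dataclass
class ShiftConfig:
    """Cross-hospital shift transform parameters.

    ``oov_prob`` is the per-occurrence probability that a token is replaced
    by one unseen in the source domain, so it equals the expected
    occurrence-level OOV rate (default 0.154, the observed cross-hospital
    value).  A replacement is a consistent per-type "abbreviation" with
    probability ``abbreviation_share`` and a fresh noise token otherwise.
    ``length_scale`` thins documents to the private-practice length ratio
    (191/325 by default).  ``subtype_replacement_rate`` swaps planted
    subtypes for novel same-code subtypes unique to the shifted domain.
    ``code_reweight_exponent`` optionally subsamples notes under a re-drawn
    code-frequency profile (off by default: it breaks the 1:1 note mapping).
    """

    oov_prob: float = 0.154
    abbreviation_share: float = 0.5
    length_scale: float = 191.0 / 325.0
    subtype_replacement_rate: float = 0.3
    code_reweight_exponent: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("oov_prob", "abbreviation_share", "subtype_replacement_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.length_scale <= 1.0:
            raise ValueError("length_scale must be in (0, 1]")


@dataclass
class SubtypeInventory:
    """Planted ground truth: keyword sets per subtype, subtypes per code."""

    keywords: dict[str, list[str]]             # subtype id -> full keyword set
    specific: dict[str, list[str]]             # subtype id -> subtype-only tokens
    code_subtypes: dict[int, list[str]]        # code index -> its subtype ids
    background: list[str] = field(default_factory=list)

    def subtype_counts(self, n_codes: int) -> np.ndarray:
        return np.array([len(self.code_subtypes.get(d, ())) for d in range(n_codes)])


def generate_ontology(
    config: GeneratorConfig,
) -> tuple[CodeOntology, SubtypeInventory]:
    """Build a synthetic code hierarchy plus its keyword inventory.

    Codes are partitioned over the metas (every meta gets at least one);
    each code owns a seeded number of subtypes in ``subtype_range``; a
    subtype's keyword set is its own specific tokens plus tokens shared at
    the code and meta level, so same-meta codes are textually related.  The
    last code index is the non-disease bucket.  Deterministic in the seed.
    """
    rng = np.random.default_rng(config.seed)
    D, G = config.n_codes, config.n_metas
    meta_of = np.empty(D, dtype=int)
    meta_of[:G] = np.arange(G)                 # every meta nonempty
    meta_of[G:] = rng.integers(0, G, size=D - G)
    meta_of = meta_of[rng.permutation(D)]

    keywords: dict[str, list[str]] = {}
    specific: dict[str, list[str]] = {}
    code_subtypes: dict[int, list[str]] = {}
    subtype_to_disease: dict[str, int] = {}
    theme = {
        g: [f"meta{g}tok{i}" for i in range(config.meta_theme_tokens)] for g in range(G)
    }
    lo, hi = config.subtype_range
    for d in range(D):
        shared = [f"code{d}tok{i}" for i in range(config.code_tokens)]
        if config.subtype_counts is not None:
            n_sub = int(config.subtype_counts[d])
        else:
            n_sub = int(rng.integers(lo, hi + 1))
        code_subtypes[d] = []
        for k in range(n_sub):
            sid = f"S{d}_{k}"
            # token shapes must survive the package tokenizer unchanged
            spec = [f"kw{d}q{k}q{i}" for i in range(config.keywords_per_subtype)]
            specific[sid] = spec
            keywords[sid] = spec + shared + theme[meta_of[d]]
            code_subtypes[d].append(sid)
            subtype_to_disease[sid] = d

    background = [f"w{i}" for i in range(config.background_vocab_size)]
    ontology = CodeOntology(
        subtype_to_disease=subtype_to_disease,
        disease_to_meta={d: int(meta_of[d]) for d in range(D)},
        disease_names=[f"disease_{d}" for d in range(D)],
        meta_names=[f"meta_{g}" for g in range(G)],
        other_index=D - 1,
        strict_cardinality=(D == 42 and G == 18),
    )
    inventory = SubtypeInventory(
        keywords=keywords,
        specific=specific,
        code_subtypes=code_subtypes,
        background=background,
    )
    return ontology, inventory


def code_frequency_weights(n_codes: int, exponent: float) -> np.ndarray:
    """Truncated power-law sampling weights over code indices."""
    w = (np.arange(1, n_codes + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


def generate_corpus(
    ontology: CodeOntology,
    inventory: SubtypeInventory,
    config: GeneratorConfig,
    n: int,
    seed: int | None = None,
    domain: str = "synthA",
) -> list[Note]:
    """Sample ``n`` notes with planted subtypes and rolled-up labels.

    Per note: the code-set size is 1 + Poisson(mean - 1); codes are drawn
    without replacement under the long-tailed frequency weights; one subtype
    per code is chosen uniformly and its keyword set injected
    ``keyword_repeat`` times at random positions among background tokens up
    to a Poisson document length.  With zero label noise every label vector
    equals the rollup of the planted subtypes exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    D = ontology.n_diseases
    weights = code_frequency_weights(D, config.freq_exponent)
    notes = []
    n_bg = len(inventory.background)
    for i in range(n):
        k = min(1 + rng.poisson(config.mean_labels_per_note - 1.0), D)
        codes = rng.choice(D, size=k, replace=False, p=weights)
        subtypes = {
            inventory.code_subtypes[int(d)][
                rng.integers(len(inventory.code_subtypes[int(d)]))
            ]
            for d in codes
        }
        tokens: list[str] = []
        for sid in sorted(subtypes):
            tokens.extend(inventory.keywords[sid] * config.keyword_repeat)
        target_len = max(len(tokens), rng.poisson(config.doc_length_mean))
        n_fill = target_len - len(tokens)
        fill_ids = rng.integers(0, n_bg, size=n_fill)
        fill = [inventory.background[j] for j in fill_ids]
        numeric = rng.random(n_fill) < config.numeric_token_fraction
        for j in np.flatnonzero(numeric):
            fill[j] = str(rng.integers(0, 1000))
        tokens.extend(fill)
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]
        labels = rollup(subtypes, ontology)
        if config.label_flip_noise > 0:
            flips = rng.random(D) < config.label_flip_noise
            labels = np.where(flips, 1 - labels, labels).astype(np.int8)
        notes.append(
            Note(
                id=f"{domain}-{i}",
                text=" ".join(tokens),
                tokens=tokens,
                labels=labels,
                subtypes=subtypes,
                domain=domain,
            )
        )
    return notes


@dataclass
class ShiftResult:
    """Shifted notes plus the extended hierarchy covering novel subtypes."""

    notes: list[Note]
    ontology: CodeOntology
    inventory: SubtypeInventory


def apply_domain_shift(
    notes: list[Note],
    shift: ShiftConfig,
    ontology: CodeOntology,
    inventory: SubtypeInventory,
) -> ShiftResult:
    """Transform a source corpus into its cross-hospital counterpart.

    Order of operations per note: (1) planted subtypes are swapped, with the
    configured rate, for novel same-code subtypes whose specific keywords
    are unique to the shifted domain (shared code/meta tokens are kept);
    (2) documents are thinned to the target length ratio; (3) each remaining
    token occurrence is replaced with probability ``oov_prob`` by an
    out-of-vocabulary form.  Every transform preserves the note's label
    vector.  With all rates zero the corpus is returned unchanged.

    Returns the shifted notes together with an ontology and inventory
    extended by the novel subtypes, so rollup and subtype counting work on
    the shifted domain.
    """
    rng = np.random.default_rng(shift.seed)
    novel_of: dict[str, str] = {}          # source subtype -> its novel counterpart
    new_sub_to_dis = dict(ontology.subtype_to_disease)
    new_keywords = {s: list(v) for s, v in inventory.keywords.items()}
    new_specific = {s: list(v) for s, v in inventory.specific.items()}
    new_code_subtypes = {d: list(v) for d, v in inventory.code_subtypes.items()}
    abbrev: dict[str, str] = {}            # consistent per-type abbreviation forms
    oov_counter = 0

    def novel_subtype(sid: str) -> str:
        if sid not in novel_of:
            d = ontology.subtype_to_disease[sid]
            new_sid = f"{sid}_pp"
            spec = [f"pp{kw}" for kw in inventory.specific[sid]]
            shared = [t for t in inventory.keywords[sid] if t not in inventory.specific[sid]]
            novel_of[sid] = new_sid
            new_sub_to_dis[new_sid] = d
            new_specific[new_sid] = spec
            new_keywords[new_sid] = spec + shared
            new_code_subtypes[d].append(new_sid)
        return novel_of[sid]

    shifted: list[Note] = []
    for note in notes:
        tokens = list(note.tokens)
        subtypes = set(note.subtypes or ())
        # (1) subtype distribution shift
        kw_map: dict[str, str] = {}
        for sid in sorted(subtypes):
            if rng.random() < shift.subtype_replacement_rate:
                new_sid = novel_subtype(sid)
                subtypes.discard(sid)
                subtypes.add(new_sid)
                for old, new in zip(inventory.specific[sid], new_specific[new_sid]):
                    kw_map[old] = new
        if kw_map:
            tokens = [kw_map.get(t, t) for t in tokens]
        # (2) length rescaling: thin uniformly, keep at least one token
        if shift.length_scale < 1.0:
            keep = rng.random(len(tokens)) < shift.length_scale
            if not keep.any():
                keep[rng.integers(len(tokens))] = True
            tokens = [t for t, k in zip(tokens, keep) if k]
        # (3) abbreviation / OOV injection
        if shift.oov_prob > 0:
            replace = rng.random(len(tokens)) < shift.oov_prob
            for j in np.flatnonzero(replace):
                if rng.random() < shift.abbreviation_share:
                    t = tokens[j]
                    if t not in abbrev:
                        abbrev[t] = f"xx{t[:4]}{len(abbrev)}"
                    tokens[j] = abbrev[t]
                else:
                    tokens[j] = f"xxnoise{oov_counter}"
                    oov_counter += 1
        shifted.append(
            Note(
                id=note.id + "-shift",
                text=" ".join(tokens),
                tokens=tokens,
                labels=None if note.labels is None else note.labels.copy(),
                subtypes=subtypes,
                domain="synthB",
            )
        )

    # optional code-frequency re-weighting by seeded note subsampling
    if shift.code_reweight_exponent is not None:
        D = ontology.n_diseases
        new_w = code_frequency_weights(D, shift.code_reweight_exponent)
        new_w = new_w[rng.permutation(D)]      # different codes become frequent
        note_w = np.array(
            [new_w[np.flatnonzero(m.labels)].mean() if m.labels is not None and m.labels.any() else 1e-12
             for m in shifted]
        )
        note_w = note_w / note_w.sum()
        keep_idx = np.sort(
            rng.choice(len(shifted), size=max(1, len(shifted) // 2), replace=False, p=note_w)
        )
        shifted = [shifted[i] for i in keep_idx]

    new_ontology = CodeOntology(
        subtype_to_disease=new_sub_to_dis,
        disease_to_meta=dict(ontology.disease_to_meta),
        disease_names=list(ontology.disease_names),
        meta_names=list(ontology.meta_names),
        other_index=ontology.other_index,
        strict_cardinality=ontology.strict_cardinality,
    )
    new_inventory = SubtypeInventory(
        keywords=new_keywords,
        specific=new_specific,
        code_subtypes=new_code_subtypes,
        background=list(inventory.background),
    )
    return ShiftResult(notes=shifted, ontology=new_ontology, inventory=new_inventory)
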