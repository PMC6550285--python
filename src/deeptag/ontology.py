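"""Three-level diagnosis-code hierarchy and rollup.

The label space is a fixed set of top-level disease codes (42 in the standard
configuration: 41 disorder categories plus one bucket for non-disease codes),
each belonging to exactly one of a smaller set of expert-defined meta-diseases
(18 in the standard configuration).  Fine-grained "subtype" codes — codes lower
in the clinical terminology hierarchy — roll up many-to-one onto the top-level
codes.  The hierarchy is supplied as a flat TSV table rather than as a
terminology graph: only the binning is needed downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Standard label-space cardinalities: 42 top-level disease codes, 18 metas.
N_DISEASE_CODES = 42
N_META_DISEASES = 18


class OntologyError(ValueError):
    """Raised for malformed or inconsistent ontology tables."""


@dataclass
class CodeOntology:
    """A validated subtype -> disease-code -> meta-disease mapping.

    Parameters
    ----------
    subtype_to_disease
        Maps each subtype identifier to a disease-code index in
        ``0..n_diseases-1``.
    disease_to_meta
        Maps each disease-code index to a meta-disease index.
    disease_names, meta_names
        Display names, indexed positionally.
    other_index
        The single disease-code index reserved for non-disease codes, or
        ``None`` if the table does not designate one.
    strict_cardinality
        When True (the default for :func:`load_ontology`), enforce the
        standard 42/18 label space.  Toy ontologies used in tests and the
        scaled-down synthetic studies disable it.
    """

    subtype_to_disease: dict[str, int]
    disease_to_meta: dict[int, int]
    disease_names: list[str]
    meta_names: list[str]
    other_index: int | None = None
    strict_cardinality: bool = True
    _meta_members: dict[int, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        members: dict[int, list[int]] = {}
        for d in range(self.n_diseases):
            members.setdefault(self.disease_to_meta[d], []).append(d)
        self._meta_members = members

    # -- structure -----------------------------------------------------

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_metas(self) -> int:
        return len(self.meta_names)

    def meta_members(self, meta_index: int) -> list[int]:
        """Disease-code indices grouped under ``meta_index``."""
        return list(self._meta_members[meta_index])

    def meta_groups(self) -> list[list[int]]:
        """All meta groups as lists of disease indices, ordered by meta index."""
        return [self.meta_members(g) for g in sorted(self._meta_members)]

    def validate(self) -> None:
        n_d, n_g = self.n_diseases, self.n_metas
        if self.strict_cardinality and (n_d, n_g) != (N_DISEASE_CODES, N_META_DISEASES):
            raise OntologyError(
                f"expected {N_DISEASE_CODES} disease codes and "
                f"{N_META_DISEASES} meta-diseases, got {n_d}/{n_g}"
            )
        if set(self.disease_to_meta) != set(range(n_d)):
            raise OntologyError("disease_to_meta must cover indices 0..n_diseases-1")
        metas_used = set(self.disease_to_meta.values())
        if not metas_used <= set(range(n_g)):
            raise OntologyError("meta index out of range")
        if metas_used != set(range(n_g)):
            raise OntologyError("every meta-disease must contain at least one code")
        for s, d in self.subtype_to_disease.items():
            if not 0 <= d < n_d:
                raise OntologyError(f"subtype {s!r} maps to out-of-range disease {d}")
        if self.other_index is not None and not 0 <= self.other_index < n_d:
            raise OntologyError("other_index out of range")

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Write the rollup TSV (see :func:`load_ontology` for the format)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subtype_id\tdisease_index\tdisease_name\tmeta_index\tmeta_name\n")
            if self.other_index is not None:
                fh.write(f"# other_index={self.other_index}\n")
            for s in sorted(self.subtype_to_disease):
                d = self.subtype_to_disease[s]
                g = self.disease_to_meta[d]
                fh.write(
                    f"{s}\t{d}\t{self.disease_names[d]}\t{g}\t{self.meta_names[g]}\n"
                )


def load_ontology(path, strict_cardinality: bool = True) -> CodeOntology:
    """Load a rollup TSV into a validated :class:`CodeOntology`.

    Format: header line, then one row per subtype with columns
    ``subtype_id  disease_index  disease_name  meta_index  meta_name``
    (tab-separated, UTF-8).  ``#`` starts a comment; the special comment
    ``# other_index=K`` designates the non-disease bucket.

    Raises
    ------
    OntologyError
        On malformed rows (naming the offending line) or inconsistent maps
        (a subtype with two disease indices, a disease with two metas).
    """
    subtype_to_disease: dict[str, int] = {}
    disease_to_meta: dict[int, int] = {}
    disease_names: dict[int, str] = {}
    meta_names: dict[int, str] = {}
    other_index: int | None = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("other_index="):
                    other_index = int(body.split("=", 1)[1])
                continue
            if not line.strip() or lineno == 1 and line.startswith("subtype_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise OntologyError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            sid, d_str, d_name, g_str, g_name = parts
            try:
                d, g = int(d_str), int(g_str)
            except ValueError as exc:
                raise OntologyError(f"{path}:{lineno}: non-integer index") from exc
            if sid in subtype_to_disease and subtype_to_disease[sid] != d:
                raise OntologyError(
                    f"{path}:{lineno}: subtype {sid!r} mapped to diseases "
                    f"{subtype_to_disease[sid]} and {d}"
                )
            if d in disease_to_meta and disease_to_meta[d] != g:
                raise OntologyError(
                    f"{path}:{lineno}: disease {d} mapped to metas "
                    f"{disease_to_meta[d]} and {g}"
                )
            subtype_to_disease[sid] = d
            disease_to_meta[d] = g
            disease_names[d] = d_name
            meta_names[g] = g_name

    if not subtype_to_disease:
        raise OntologyError(f"{path}: empty ontology table")
    n_d = max(disease_names) + 1
    n_g = max(meta_names) + 1
    if set(disease_names) != set(range(n_d)):
        raise OntologyError(f"{path}: disease indices not contiguous from 0")
    if set(meta_names) != set(range(n_g)):
        raise OntologyError(f"{path}: meta indices not contiguous from 0")
    return CodeOntology(
        subtype_to_disease=subtype_to_disease,
        disease_to_meta=disease_to_meta,
        disease_names=[disease_names[i] for i in range(n_d)],
        meta_names=[meta_names[i] for i in range(n_g)],
        other_index=other_index,
        strict_cardinality=strict_cardinality,
    )


def rollup(
    subtype_codes: Iterable[str],
    ontology: CodeOntology,
    unknown: str = "lenient",
) -> np.ndarray:
    """Roll a set of subtype codes up to a binary top-level label vector.

    Position ``d`` of the returned vector is 1 iff some input subtype rolls
    up to disease code ``d``.  The operation is a set union: duplicate
    subtypes, or several subtypes of the same disease, still yield a single 1.

    Parameters
    ----------
    unknown
        Policy for subtypes absent from the ontology: ``"strict"`` raises
        ``KeyError``; ``"lenient"`` (default) maps them to the non-disease
        bucket ``other_index`` with a logged warning, matching how codes
        unique to an external hospital are absorbed.
    """
    vec = np.zeros(ontology.n_diseases, dtype=np.int8)
    empty = True
    for s in subtype_codes:
        empty = False
        d = ontology.subtype_to_disease.get(s)
        if d is None:
            if unknown == "strict":
                raise KeyError(f"unknown subtype {s!r}")
            if ontology.other_index is None:
                logger.warning("unknown subtype %r ignored (no other_index)", s)
                continue
            logger.warning("unknown subtype %r mapped to other_index", s)
            d = ontology.other_index
        vec[d] = 1
    if empty:
        warnings.warn("rollup of an empty subtype set yields an all-zero label vector")
    return vec


def count_subtypes(
    notes,
    ontology: CodeOntology,
    shared_with=None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Count distinct observed subtypes per disease code.

    For each disease index, counts the number of DISTINCT subtype codes that
    occur in ``notes`` (objects with a ``.subtypes`` set) and roll up to that
    index — the per-code diversity proxy.  If ``shared_with`` (a second note
    collection) is given, also returns the count of those subtypes that appear
    in both collections.
    """
    def observed(collection) -> dict[int, set[str]]:
        per: dict[int, set[str]] = {d: set() for d in range(ontology.n_diseases)}
        for note in collection:
            for s in note.subtypes or ():
                d = ontology.subtype_to_disease.get(s, ontology.other_index)
                if d is not None:
                    per[d].add(s)
        return per

    own = observed(notes)
    counts = np.array([len(own[d]) for d in range(ontology.n_diseases)])
    if shared_with is None:
        return counts
    other = observed(shared_with)
    shared = np.array(
        [len(own[d] & other[d]) for d in range(ontology.n_diseases)]
    )
    return counts, shared
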