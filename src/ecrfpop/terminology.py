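"""Coded clinical vocabulary: loading, indexing, and fuzzy concept mapping.

A terminology is a flat table of concepts (SNOMED-CT / RadLex style
identifiers, a semantic category, a preferred term and synonyms).  Surface
mentions are mapped onto concepts with a normalized longest-common-subsequence
(LCS) similarity, so that synonym variants and small typos still resolve to
the right code.
"""

from __future__ import annotations

import csv
import io
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

CATEGORIES = frozenset(
    {
        "medical_problem",
        "test",
        "treatment",
        "body_structure",
        "observable",
        "qualifier",
        "value",
    }
)


class TerminologyError(ValueError):
    """Raised for malformed terminology sources or invalid concepts."""


@dataclass(frozen=True)
class Concept:
    """A coded clinical concept with its surface synonyms.

    ``concept_id`` is a namespaced identifier such as ``"SCT:42842009"`` or
    ``"RID3277"``.  ``synonyms`` always contains ``preferred_term``.
    """

    concept_id: str
    category: str
    preferred_term: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.concept_id:
            raise TerminologyError("concept_id must be non-empty")
        if self.category not in CATEGORIES:
            raise TerminologyError(
                f"unknown category {self.category!r} for {self.concept_id}; "
                f"allowed: {sorted(CATEGORIES)}"
            )
        if not self.synonyms:
            raise TerminologyError(f"{self.concept_id}: synonyms must be non-empty")
        if self.preferred_term not in self.synonyms:
            object.__setattr__(
                self, "synonyms", (self.preferred_term,) + tuple(self.synonyms)
            )


@dataclass(frozen=True)
class MatchResult:
    """A scored candidate mapping of a surface string onto a concept."""

    concept_id: str
    matched_synonym: str
    score: float


def normalize(text: str) -> str:
    """Canonical string form used for all matching.

    NFKC fold, casefold, and removal of whitespace and punctuation, leaving a
    bare symbol sequence.  CJK text is unaffected beyond whitespace removal,
    so matching is effectively character-level in both scripts.
    """
    folded = unicodedata.normalize("NFKC", text).casefold()
    out = []
    for ch in folded:
        if ch.isspace():
            continue
        cat = unicodedata.category(ch)
        if cat.startswith("P"):
            continue
        out.append(ch)
    return "".join(out)


def lcs_length(a: Sequence, b: Sequence) -> int:
    """Length of the longest common subsequence of two symbol sequences.

    Classic O(len(a)*len(b)) dynamic programme with a two-row table.
    Symmetric in its arguments; empty inputs are allowed and give 0.
    """
    if len(a) > len(b):  # keep the inner row short
        a, b = b, a
    if not a:
        return 0
    prev = [0] * (len(a) + 1)
    for y in b:
        curr = [0]
        for i, x in enumerate(a):
            if x == y:
                curr.append(prev[i] + 1)
            else:
                curr.append(max(prev[i + 1], curr[i]))
        prev = curr
    return prev[-1]


def lcs_similarity(a: Sequence, b: Sequence) -> float:
    """Dice-style normalized LCS similarity: ``2*L / (|a| + |b|)`` in [0, 1]."""
    if not a and not b:
        raise ValueError("lcs_similarity is undefined for two empty sequences")
    return 2.0 * lcs_length(a, b) / (len(a) + len(b))


@dataclass
class Terminology:
    """An indexed collection of :class:`Concept`.

    Supports lookup by id and by exact normalized synonym, and fuzzy mapping
    via :meth:`map`.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    _by_norm: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def add(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise TerminologyError(f"duplicate concept_id {concept.concept_id!r}")
        self.concepts[concept.concept_id] = concept
        for syn in concept.synonyms:
            self._by_norm.setdefault(normalize(syn), []).append(concept.concept_id)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def get(self, concept_id: str) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise TerminologyError(f"unknown concept_id {concept_id!r}") from None

    def lookup_exact(self, text: str) -> list[Concept]:
        """Concepts having ``text`` as an exact normalized synonym."""
        return [self.concepts[cid] for cid in self._by_norm.get(normalize(text), [])]

    def map(
        self,
        text: str,
        category_filter: Optional[Iterable[str]] = None,
        threshold: float = 0.8,
        top_k: int = 5,
    ) -> list[MatchResult]:
        return map_mention(text, self, category_filter, threshold, top_k)


def map_mention(
    text: str,
    term: Terminology,
    category_filter: Optional[Iterable[str]] = None,
    threshold: float = 0.8,
    top_k: int = 5,
) -> list[MatchResult]:
    """Map a surface string onto terminology concepts by normalized LCS.

    Every synonym of every concept passing ``category_filter`` is scored with
    :func:`lcs_similarity` on normalized strings; one result per concept is
    kept (its best synonym).  Results with score >= ``threshold`` are returned
    sorted by (score desc, synonym length desc, concept_id asc), at most
    ``top_k`` of them.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if top_k < 1:
        raise ValueError("top_k must be positive")
    q = normalize(text)
    if not q:
        return []
    cats = set(category_filter) if category_filter is not None else None
    best: dict[str, MatchResult] = {}
    for concept in term.concepts.values():
        if cats is not None and concept.category not in cats:
            continue
        for syn in concept.synonyms:
            s = normalize(syn)
            if not s:
                continue
            # 2L/(|a|+|b|) <= 2*min/(|a|+|b|): skip hopeless length ratios
            if 2.0 * min(len(q), len(s)) / (len(q) + len(s)) < threshold:
                continue
            score = lcs_similarity(q, s)
            if score < threshold:
                continue
            prev = best.get(concept.concept_id)
            if (
                prev is None
                or score > prev.score
                or (score == prev.score and len(syn) > len(prev.matched_synonym))
            ):
                best[concept.concept_id] = MatchResult(concept.concept_id, syn, score)
    ranked = sorted(
        best.values(),
        key=lambda m: (-m.score, -len(m.matched_synonym), m.concept_id),
    )
    return ranked[:top_k]


_EXPECTED_HEADER = ["concept_id", "category", "preferred_term", "synonyms"]


def load_terminology(source: Union[str, Path, TextIO]) -> Terminology:
    """Load a terminology from a 4-column TSV (path, string, or stream).

    Columns: ``concept_id``, ``category``, ``preferred_term``,
    pipe-separated ``synonyms``.  Duplicate ids, unknown categories and empty
    sources are load errors.
    """
    if isinstance(source, Path):
        with open(source, encoding="utf-8", newline="") as fh:
            return _load_tsv(fh)
    if isinstance(source, str):
        if source and "\t" not in source and "\n" not in source:
            with open(source, encoding="utf-8", newline="") as fh:
                return _load_tsv(fh)
        return _load_tsv(io.StringIO(source))
    return _load_tsv(source)


def _load_tsv(fh: TextIO) -> Terminology:
    reader = csv.reader(fh, delimiter="\t")
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise TerminologyError("empty terminology source")
    if [c.strip() for c in rows[0]] == _EXPECTED_HEADER:
        rows = rows[1:]
    if not rows:
        raise TerminologyError("terminology source has a header but no rows")
    term = Terminology()
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 4:
            raise TerminologyError(
                f"row {lineno}: expected 4 tab-separated columns, got {len(row)}"
            )
        cid, cat, pref, syns = (c.strip() for c in row)
        synonyms = tuple(s.strip() for s in syns.split("|") if s.strip())
        if pref and pref not in synonyms:
            synonyms = (pref,) + synonyms
        term.add(Concept(cid, cat, pref, synonyms))
    return term
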