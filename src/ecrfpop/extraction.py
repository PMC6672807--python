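"""Rule-based clinical information extraction.

The pipeline follows the i2b2-style task decomposition — segmentation, named
entity recognition, assertion (negation) classification, relation extraction
and value association — but is fully deterministic: entities come from
dictionary lookup against a terminology (exact longest-match first, then
fuzzy LCS windows), assertions from a ConText-style cue/scope rule, relations
from same-sentence nearest-neighbour pairing over category signatures, and
numeric values are attached to the nearest observable.

All offsets are 0-based half-open character offsets into the raw document
text, so every mention and value can be highlighted back in its source.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

from .terminology import Terminology, map_mention, normalize

logger = logging.getLogger(__name__)

DOC_TYPES = ("admission_record", "imaging_report")

REL_SIGNATURES: dict[str, tuple[str, str]] = {
    # (arg1 category, arg2 category); arg2 is the right argument that "heads"
    "problem_treatment": ("medical_problem", "treatment"),
    "problem_test": ("medical_problem", "test"),
    "problem_problem": ("medical_problem", "medical_problem"),
    "bodystructure_observable": ("body_structure", "observable"),
    "problem_observable": ("medical_problem", "observable"),
    "observable_qualifier": ("observable", "qualifier"),
    "observable_value": ("observable", "value"),
}

DEFAULT_PRE_CUES = (
    "no", "not", "without", "denies", "denied", "deny", "negative",
    "absent", "free", "ruled",
    "无", "否认", "未见", "未", "不", "没有", "非",
)
DEFAULT_POST_CUES = ("absent", "negative", "denied", "unlikely", "阴性")
DEFAULT_BOUNDARY_CUES = (
    ",", "but", "however", "although", "except", "aside",
    "但", "但是", "然而", "除",
)
DEFAULT_UNITS = (
    "cm", "mm", "m", "%", "°c", "°f", "bpm", "kg", "g", "mg", "ml", "l",
    "mmhg", "s", "min", "h", "次/分",
)


@dataclass
class ExtractionConfig:
    """Tunable knobs of the deterministic pipeline."""

    threshold: float = 0.8          # fuzzy mapping similarity cutoff
    window: int = 5                 # assertion cue scope, in tokens
    max_token_distance: int = 12    # same-sentence relation pairing limit
    max_entity_tokens: int = 6      # widest fuzzy candidate window
    pre_cues: tuple[str, ...] = DEFAULT_PRE_CUES
    post_cues: tuple[str, ...] = DEFAULT_POST_CUES
    boundary_cues: tuple[str, ...] = DEFAULT_BOUNDARY_CUES
    units: tuple[str, ...] = DEFAULT_UNITS


@dataclass(frozen=True)
class Document:
    case_id: str
    doc_type: str
    text: str

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise ValueError(
                f"doc_type must be one of {DOC_TYPES}, got {self.doc_type!r}"
            )


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open character span."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


@dataclass
class Mention:
    span: Span
    surface: str
    category: str
    concept_id: Optional[str] = None
    assertion: str = "present"
    score: float = 1.0


@dataclass(frozen=True)
class Relation:
    rel_type: str
    arg1: int  # mention indices into ExtractionResult.mentions
    arg2: int


@dataclass
class ValueAssignment:
    observable: int  # mention index
    value: float
    unit: str
    source_span: Span
    related_problem: Optional[int] = None


@dataclass
class ExtractionResult:
    document: Document
    mentions: list[Mention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    value_assignments: list[ValueAssignment] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.mentions)
        text = self.document.text
        for m in self.mentions:
            if m.span.slice(text) != m.surface:
                raise ValueError(f"mention surface mismatch at {m.span}")
        for r in self.relations:
            if not (0 <= r.arg1 < n and 0 <= r.arg2 < n):
                raise ValueError(f"relation {r} references missing mention")
            c1, c2 = REL_SIGNATURES[r.rel_type]
            if self.mentions[r.arg1].category != c1 or self.mentions[r.arg2].category != c2:
                raise ValueError(f"relation {r} violates its category signature")
        for v in self.value_assignments:
            if not 0 <= v.observable < n:
                raise ValueError("value assignment references missing mention")
            if self.mentions[v.observable].category != "observable":
                raise ValueError("value assignment observable has wrong category")


# ---------------------------------------------------------------------------
# Segmentation

_CJK = r"㐀-䶿一-鿿"
# a "." splits sentences except between digits (decimal values stay intact)
_TERMINATOR = re.compile(r"(?<=\d)\.(?=\d)|(?P<t>[。，；！？;!?\n])|(?P<d>\.)")
_TOKEN = re.compile(rf"[{_CJK}]|\d+(?:\.\d+)?|[^\W\d_]+|[^\s{_CJK}]")


@dataclass(frozen=True)
class Sentence:
    span: Span
    tokens: tuple[Span, ...]


def _tokenize(text: str, start: int, end: int) -> tuple[Span, ...]:
    return tuple(
        Span(start + m.start(), start + m.end())
        for m in _TOKEN.finditer(text[start:end])
    )


def segment(text: str, cfg: Optional[ExtractionConfig] = None) -> list[Sentence]:
    """Split text into sentence spans carrying token spans.

    Sentences break on CJK and ASCII terminators and newlines; a period
    between two digits is treated as a decimal point.  Tokens are words or
    numbers, single characters inside CJK runs, and individual punctuation
    marks.  A terminator-free text is one sentence.
    """
    sentences: list[Sentence] = []
    pos = 0
    boundaries = [m.end() for m in _TERMINATOR.finditer(text) if m.lastgroup in ("t", "d")]
    boundaries.append(len(text))
    for b in boundaries:
        chunk = text[pos:b]
        stripped = chunk.strip()
        if stripped:
            s = pos + chunk.index(stripped[0])
            # trim trailing whitespace and the terminator itself
            e = pos + len(chunk.rstrip())
            core = text[s:e].rstrip("。，；！？;!?.")
            e = s + len(core.rstrip())
            if e > s:
                sentences.append(Sentence(Span(s, e), _tokenize(text, s, e)))
        pos = b
    return sentences


# ---------------------------------------------------------------------------
# Entity recognition

_NUMBER = re.compile(r"^\d+(?:\.\d+)?$")


def _candidate_windows(sent: Sentence, max_tokens: int):
    toks = sent.tokens
    for i in range(len(toks)):
        for j in range(i + 1, min(i + 1 + max_tokens, len(toks) + 1)):
            yield Span(toks[i].start, toks[j - 1].end)


def recognize_entities(
    doc: Document, term: Terminology, cfg: Optional[ExtractionConfig] = None
) -> list[Mention]:
    """Greedy longest-match dictionary scan with fuzzy fallback.

    Per sentence, every token window up to ``cfg.max_entity_tokens`` wide is a
    candidate: exact normalized synonym hits score 1.0, other windows are
    scored by LCS mapping at ``cfg.threshold``.  Overlaps resolve to the
    longer span, then the higher score, then the leftmost.  Numeric tokens
    become ``value`` mentions.
    """
    cfg = cfg or ExtractionConfig()
    text = doc.text
    exact_cands: list[Mention] = []
    fuzzy_cands: list[Mention] = []
    for sent in segment(text, cfg):
        for win in _candidate_windows(sent, cfg.max_entity_tokens):
            surface = win.slice(text)
            if _NUMBER.match(surface):
                continue
            exact = term.lookup_exact(surface)
            if exact:
                # deterministic pick among homonyms: lowest concept_id
                c = min(exact, key=lambda c: c.concept_id)
                exact_cands.append(
                    Mention(win, surface, c.category, c.concept_id, score=1.0)
                )
                continue
            if len(normalize(surface)) < 3:
                continue
            hits = map_mention(surface, term, None, cfg.threshold, 1)
            if hits:
                c = term.get(hits[0].concept_id)
                fuzzy_cands.append(
                    Mention(win, surface, c.category, c.concept_id, score=hits[0].score)
                )
        for tok in sent.tokens:
            s = tok.slice(text)
            if _NUMBER.match(s):
                fuzzy_cands.append(Mention(tok, s, "value", None, score=1.0))
    # exact dictionary hits outrank fuzzy windows; within each tier overlaps
    # resolve to the longer span, then the higher score, then the leftmost
    chosen: list[Mention] = []

    def _admit(cands: list[Mention]) -> None:
        cands.sort(key=lambda m: (-(m.span.end - m.span.start), -m.score, m.span.start))
        for cand in cands:
            if all(
                cand.span.end <= m.span.start or cand.span.start >= m.span.end
                for m in chosen
            ):
                chosen.append(cand)

    _admit(exact_cands)
    _admit(fuzzy_cands)
    chosen.sort(key=lambda m: m.span)
    return chosen


# ---------------------------------------------------------------------------
# Assertion classification

def classify_assertion(
    mention: Mention,
    sentence: Sentence,
    text: str,
    cfg: Optional[ExtractionConfig] = None,
) -> str:
    """Label a mention ``present`` or ``absent`` from in-sentence cues.

    A negation cue within ``cfg.window`` tokens before (pre-cue) or after
    (post-cue) the mention makes it absent, unless a boundary cue (comma,
    adversative conjunction) intervenes between cue and mention.
    """
    cfg = cfg or ExtractionConfig()
    toks = sentence.tokens
    tok_text = [normalize(t.slice(text)) or t.slice(text) for t in toks]
    first = next(
        (i for i, t in enumerate(toks) if t.end > mention.span.start), len(toks)
    )
    last = max(
        (i for i, t in enumerate(toks) if t.start < mention.span.end), default=first
    )
    pre = {normalize(c) for c in cfg.pre_cues}
    post = {normalize(c) for c in cfg.post_cues}
    bound = set(cfg.boundary_cues) | {normalize(c) for c in cfg.boundary_cues}
    for i in range(first - 1, max(first - 1 - cfg.window, -1), -1):
        if tok_text[i] in bound or toks[i].slice(text) in bound:
            break
        if tok_text[i] in pre:
            return "absent"
    for i in range(last + 1, min(last + 1 + cfg.window, len(toks))):
        if tok_text[i] in bound or toks[i].slice(text) in bound:
            break
        if tok_text[i] in post:
            return "absent"
    return "present"


# ---------------------------------------------------------------------------
# Relations and values

def _token_index(sentence: Sentence, span: Span) -> int:
    for i, t in enumerate(sentence.tokens):
        if t.end > span.start:
            return i
    return len(sentence.tokens)


def _sentence_of(sentences: list[Sentence], span: Span) -> Optional[int]:
    for i, s in enumerate(sentences):
        if s.span.start <= span.start and span.end <= s.span.end:
            return i
    return None


def extract_relations(
    mentions: list[Mention],
    sentences: list[Sentence],
    cfg: Optional[ExtractionConfig] = None,
) -> list[Relation]:
    """Nearest-neighbour pairing of category signatures within a sentence.

    For each relation type, each right-argument mention links to the nearest
    left-argument mention in the same sentence, at most
    ``cfg.max_token_distance`` tokens away; ties prefer the preceding
    mention.  A mention heads at most one relation per type.
    """
    cfg = cfg or ExtractionConfig()
    sent_of = [
        _sentence_of(sentences, m.span) for m in mentions
    ]
    relations: list[Relation] = []
    for rel_type, (cat1, cat2) in REL_SIGNATURES.items():
        for j, m2 in enumerate(mentions):
            if m2.category != cat2 or sent_of[j] is None:
                continue
            sent = sentences[sent_of[j]]
            tj = _token_index(sent, m2.span)
            best: Optional[tuple[int, int, int]] = None  # (dist, order, index)
            for i, m1 in enumerate(mentions):
                if i == j or m1.category != cat1 or sent_of[i] != sent_of[j]:
                    continue
                ti = _token_index(sent, m1.span)
                dist = abs(ti - tj)
                if dist > cfg.max_token_distance:
                    continue
                key = (dist, 0 if ti < tj else 1, i)
                if best is None or key < best:
                    best = key
            if best is not None:
                relations.append(Relation(rel_type, best[2], j))
    return relations


def associate_values(
    mentions: list[Mention],
    relations: list[Relation],
    sentences: list[Sentence],
    text: str,
    cfg: Optional[ExtractionConfig] = None,
) -> list[ValueAssignment]:
    """Attach each numeric token to the nearest observable in its sentence.

    Preference goes to the nearest preceding observable, falling back to the
    nearest following one.  An adjacent unit token (from the configured unit
    list) is captured; the related problem (or body structure) comes from an
    existing relation on that observable.  Numbers with no observable in the
    sentence are dropped and logged.
    """
    cfg = cfg or ExtractionConfig()
    unit_set = {u.casefold() for u in cfg.units}
    sent_of = [_sentence_of(sentences, m.span) for m in mentions]
    related: dict[int, int] = {}
    for r in relations:
        if r.rel_type in ("problem_observable", "bodystructure_observable"):
            # problem_observable preferred when both exist
            if r.arg2 not in related or r.rel_type == "problem_observable":
                related[r.arg2] = r.arg1
    out: list[ValueAssignment] = []
    for j, vm in enumerate(mentions):
        if vm.category != "value" or sent_of[j] is None:
            continue
        si = sent_of[j]
        obs_before = [
            i
            for i, m in enumerate(mentions)
            if m.category == "observable" and sent_of[i] == si and m.span.end <= vm.span.start
        ]
        obs_after = [
            i
            for i, m in enumerate(mentions)
            if m.category == "observable" and sent_of[i] == si and m.span.start >= vm.span.end
        ]
        if obs_before:
            obs = max(obs_before, key=lambda i: mentions[i].span.end)
        elif obs_after:
            obs = min(obs_after, key=lambda i: mentions[i].span.start)
        else:
            logger.info("dropped value %r: no observable in sentence", vm.surface)
            continue
        unit = ""
        source_end = vm.span.end
        sent = sentences[si]
        toks = sent.tokens
        vi = _token_index(sent, vm.span)
        k = vi + 1
        # units may tokenize into several pieces ("°" + "c"); try widening
        while k < len(toks) and k - vi <= 3:
            cand = text[toks[vi + 1].start : toks[k].end]
            if normalize(cand) in {normalize(u) for u in cfg.units} or cand.casefold() in unit_set:
                unit = cand
                source_end = toks[k].end
            k += 1
        out.append(
            ValueAssignment(
                observable=obs,
                value=float(vm.surface),
                unit=unit,
                source_span=Span(vm.span.start, source_end),
                related_problem=related.get(obs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full pipeline

def extract(
    doc: Document, term: Terminology, cfg: Optional[ExtractionConfig] = None
) -> ExtractionResult:
    """Run the full pipeline over one document."""
    cfg = cfg or ExtractionConfig()
    sentences = segment(doc.text, cfg)
    mentions = recognize_entities(doc, term, cfg)
    for k, m in enumerate(mentions):
        si = _sentence_of(sentences, m.span)
        if si is not None and m.category != "value":
            mentions[k] = replace(
                m, assertion=classify_assertion(m, sentences[si], doc.text, cfg)
            )
    relations = extract_relations(mentions, sentences, cfg)
    values = associate_values(mentions, relations, sentences, doc.text, cfg)
    result = ExtractionResult(doc, mentions, relations, values)
    result.validate()
    return result


def result_to_dict(res: ExtractionResult) -> dict:
    """JSON-ready representation (spans as [start, end))."""
    return {
        "case_id": res.document.case_id,
        "doc_type": res.document.doc_type,
        "mentions": [
            {
                "span": [m.span.start, m.span.end],
                "surface": m.surface,
                "category": m.category,
                "concept_id": m.concept_id,
                "assertion": m.assertion,
                "score": m.score,
            }
            for m in res.mentions
        ],
        "relations": [
            {"rel_type": r.rel_type, "arg1": r.arg1, "arg2": r.arg2}
            for r in res.relations
        ],
        "values": [
            {
                "observable": v.observable,
                "related_problem": v.related_problem,
                "value": v.value,
                "unit": v.unit,
                "source_span": [v.source_span.start, v.source_span.end],
            }
            for v in res.value_assignments
        ],
    }
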