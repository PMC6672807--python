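"""Automatic form filling from extraction results, with text provenance.

Every answer a machine writes into the form carries the character spans it
was read from, so a reviewer can jump "back to" the exact source sentence.
Elements only consult documents of their section's source type (admission
record vs imaging report) unless that check is disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .extraction import Document, ExtractionResult, Mention, Span
from .forms import Answer, AnswerSet, DataElement, FormDefinition, validate_bindings
from .terminology import Terminology

logger = logging.getLogger(__name__)

CONFLICT_POLICIES = ("last_mention_wins", "present_wins")


@dataclass
class PrepopulationConfig:
    conflict_policy: str = "last_mention_wins"
    require_source_doc_type_match: bool = True

    def __post_init__(self) -> None:
        if self.conflict_policy not in CONFLICT_POLICIES:
            raise ValueError(
                f"conflict_policy must be one of {CONFLICT_POLICIES}, "
                f"got {self.conflict_policy!r}"
            )


@dataclass
class CaseBundle:
    """One case: its documents and their extraction results, aligned."""

    case_id: str
    documents: list[Document]
    extractions: list[ExtractionResult]

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.extractions):
            raise ValueError("extractions must correspond one-to-one with documents")
        for doc, res in zip(self.documents, self.extractions):
            if res.document is not doc and res.document.text != doc.text:
                raise ValueError("extraction does not match its document")

    def for_doc_type(self, doc_type: Optional[str]) -> list[ExtractionResult]:
        if doc_type is None:
            return list(self.extractions)
        return [r for r in self.extractions if r.document.doc_type == doc_type]


def _concept_mentions(
    bundle: CaseBundle, concept_id: str, doc_type: Optional[str]
) -> list[tuple[str, Mention]]:
    """(doc_type, mention) pairs for a concept, in document then span order."""
    out: list[tuple[str, Mention]] = []
    for res in bundle.for_doc_type(doc_type):
        for m in res.mentions:
            if m.concept_id == concept_id:
                out.append((res.document.doc_type, m))
    return out


def _resolve_assertion(
    pairs: list[tuple[str, Mention]], policy: str, label: str
) -> tuple[Optional[str], list[tuple[str, Span]]]:
    """Resolve possibly conflicting assertions; return (label, provenance).

    Provenance is the spans of the mentions agreeing with the resolved label.
    """
    if not pairs:
        return None, []
    labels = {m.assertion for _, m in pairs}
    if len(labels) > 1:
        logger.warning("assertion conflict on %s; policy=%s", label, policy)
        if policy == "present_wins":
            resolved = "present"
        else:  # last_mention_wins, document order
            resolved = pairs[-1][1].assertion
    else:
        resolved = next(iter(labels))
    prov = [(dt, m.span) for dt, m in pairs if m.assertion == resolved]
    return resolved, prov


def answer_true_false(
    element: DataElement, bundle: CaseBundle, cfg: Optional[PrepopulationConfig] = None
) -> Answer:
    """Tri-state answer: true/false from resolved assertion, else not_mentioned."""
    cfg = cfg or PrepopulationConfig()
    doc_type = element.source_doc_type if cfg.require_source_doc_type_match else None
    pairs = _concept_mentions(bundle, element.binding.concept_id, doc_type)
    resolved, prov = _resolve_assertion(pairs, cfg.conflict_policy, element.element_id)
    if resolved is None:
        return Answer(element.element_id, "not_mentioned", [], "prepopulated")
    value = "true" if resolved == "present" else "false"
    return Answer(element.element_id, value, prov, "prepopulated")


def answer_multiple_choice(
    element: DataElement, bundle: CaseBundle, cfg: Optional[PrepopulationConfig] = None
) -> Answer:
    """Select every option whose bound concept resolves to assertion present."""
    cfg = cfg or PrepopulationConfig()
    doc_type = element.source_doc_type if cfg.require_source_doc_type_match else None
    selected: list[str] = []
    prov: list[tuple[str, Span]] = []
    for option_label, concept_id in element.binding.options:
        pairs = _concept_mentions(bundle, concept_id, doc_type)
        resolved, option_prov = _resolve_assertion(
            pairs, cfg.conflict_policy, f"{element.element_id}/{option_label}"
        )
        if resolved == "present":
            selected.append(option_label)
            prov.extend(option_prov)
    return Answer(element.element_id, frozenset(selected), prov, "prepopulated")


def answer_fill_in_blank(
    element: DataElement, bundle: CaseBundle, cfg: Optional[PrepopulationConfig] = None
) -> Answer:
    """Copy the matching extracted value (and unit) into the blank.

    Candidates are value assignments whose observable maps to the bound
    observable concept; those whose related problem matches the bound problem
    concept are preferred (the problem filter is waived when no candidate
    carries one).  First in document order wins among survivors.
    """
    cfg = cfg or PrepopulationConfig()
    doc_type = element.source_doc_type if cfg.require_source_doc_type_match else None
    b = element.binding
    candidates: list[tuple] = []  # (doc_type, ValueAssignment, problem concept id)
    for res in bundle.for_doc_type(doc_type):
        for va in res.value_assignments:
            obs = res.mentions[va.observable]
            if obs.concept_id != b.observable_concept_id:
                continue
            problem_cid = (
                res.mentions[va.related_problem].concept_id
                if va.related_problem is not None
                else None
            )
            candidates.append((res.document.doc_type, va, problem_cid))
    if not candidates:
        return Answer(element.element_id, None, [], "prepopulated")
    if b.related_problem_concept_id is not None and any(
        cid is not None for _, _, cid in candidates
    ):
        matching = [c for c in candidates if c[2] == b.related_problem_concept_id]
        if matching:
            candidates = matching
        # else: keep all, the problem filter found nothing better
    if len(candidates) > 1:
        logger.warning(
            "%s: %d candidate values, keeping first in document order",
            element.element_id, len(candidates),
        )
    dt, va, _ = candidates[0]
    if b.expected_unit and va.unit != b.expected_unit:
        logger.warning(
            "%s: unit %r does not match expected %r (value kept)",
            element.element_id, va.unit, b.expected_unit,
        )
    return Answer(
        element.element_id, (va.value, va.unit), [(dt, va.source_span)], "prepopulated"
    )


_KIND_DISPATCH = {
    "true_false": answer_true_false,
    "multiple_choice": answer_multiple_choice,
    "fill_in_blank": answer_fill_in_blank,
}


def prepopulate_case(
    form: FormDefinition,
    bundle: CaseBundle,
    cfg: Optional[PrepopulationConfig] = None,
    term: Optional[Terminology] = None,
) -> AnswerSet:
    """Fill every element of a form from one case's extractions.

    When a terminology is supplied the form's bindings are validated first
    and a failing report is an error.  Prepopulation is deterministic and
    idempotent; every non-empty answer carries at least one provenance span.
    """
    cfg = cfg or PrepopulationConfig()
    if term is not None:
        findings = validate_bindings(form, term)
        if findings:
            raise ValueError(
                "form failed binding validation: " + "; ".join(findings)
            )
    out = AnswerSet(case_id=bundle.case_id)
    for el in form.elements():
        out.answers[el.element_id] = _KIND_DISPATCH[el.element_kind](el, bundle, cfg)
    return out


def empty_baseline(form: FormDefinition, case_id: str) -> AnswerSet:
    """The all-blank starting point a manual data-enterer works from."""
    out = AnswerSet(case_id=case_id)
    for el in form.elements():
        if el.element_kind == "true_false":
            value: object = "not_mentioned"
        elif el.element_kind == "multiple_choice":
            value = frozenset()
        else:
            value = None
        out.answers[el.element_id] = Answer(el.element_id, value, [], "manual")
    return out
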