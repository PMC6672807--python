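"""Electronic case report form (eCRF) schemas, bindings and answer sets.

A form is a small questionnaire of data elements — tri-state true/false,
multiple choice, fill-in-the-blank — each bound to terminology concepts so
that it can be answered automatically from extracted text.  True/false
elements are split into two sections by source: section I answers from
admission records, section II from imaging reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .extraction import DOC_TYPES, Span
from .terminology import Terminology

SECTION_KINDS = ("true_false_I", "true_false_II", "multiple_choice", "fill_in_blank")
ELEMENT_KINDS = ("true_false", "multiple_choice", "fill_in_blank")
TRI_STATES = ("true", "false", "not_mentioned")
ENTRY_MODES = ("prepopulated", "manual", "modified")

_SECTION_ELEMENT_KIND = {
    "true_false_I": "true_false",
    "true_false_II": "true_false",
    "multiple_choice": "multiple_choice",
    "fill_in_blank": "fill_in_blank",
}
_SECTION_SOURCE = {
    "true_false_I": "admission_record",
    "true_false_II": "imaging_report",
}


class FormError(ValueError):
    """Malformed form definition or answer document."""


@dataclass
class Binding:
    """Concept binding of a data element.

    Exactly one of the three shapes is populated, matching the element kind:
    ``concept_id`` (true/false), ``options`` (multiple choice, ordered
    (label, concept_id) pairs) or the observable/problem pair with an
    ``expected_unit`` (fill-in-the-blank).
    """

    concept_id: Optional[str] = None
    options: Optional[tuple[tuple[str, str], ...]] = None
    observable_concept_id: Optional[str] = None
    related_problem_concept_id: Optional[str] = None
    expected_unit: str = ""


@dataclass
class DataElement:
    element_id: str
    label: str
    element_kind: str
    source_doc_type: str
    binding: Binding

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise FormError(f"{self.element_id}: unknown element_kind {self.element_kind!r}")
        if self.source_doc_type not in DOC_TYPES:
            raise FormError(f"{self.element_id}: unknown source_doc_type {self.source_doc_type!r}")
        b = self.binding
        if self.element_kind == "true_false" and not b.concept_id:
            raise FormError(f"{self.element_id}: true_false binding needs concept_id")
        if self.element_kind == "multiple_choice" and not b.options:
            raise FormError(f"{self.element_id}: multiple_choice binding needs options")
        if self.element_kind == "fill_in_blank" and not b.observable_concept_id:
            raise FormError(
                f"{self.element_id}: fill_in_blank binding needs observable_concept_id"
            )


@dataclass
class Section:
    section_kind: str
    elements: list[DataElement]

    def __post_init__(self) -> None:
        if self.section_kind not in SECTION_KINDS:
            raise FormError(f"unknown section_kind {self.section_kind!r}")
        want = _SECTION_ELEMENT_KIND[self.section_kind]
        for el in self.elements:
            if el.element_kind != want:
                raise FormError(
                    f"{el.element_id}: kind {el.element_kind} not allowed in "
                    f"section {self.section_kind}"
                )
            src = _SECTION_SOURCE.get(self.section_kind)
            if src and el.source_doc_type != src:
                raise FormError(
                    f"{el.element_id}: section {self.section_kind} answers from "
                    f"{src}, element sources from {el.source_doc_type}"
                )


@dataclass
class FormDefinition:
    form_id: str
    condition_label: str
    sections: list[Section]

    def __post_init__(self) -> None:
        if not 3 <= len(self.sections) <= 4:
            raise FormError(
                f"{self.form_id}: forms have 3 or 4 sections, got {len(self.sections)}"
            )
        seen: set[str] = set()
        for sec in self.sections:
            for el in sec.elements:
                if el.element_id in seen:
                    raise FormError(f"duplicate element_id {el.element_id!r}")
                seen.add(el.element_id)

    def elements(self) -> list[DataElement]:
        return [el for sec in self.sections for el in sec.elements]

    def element(self, element_id: str) -> DataElement:
        for el in self.elements():
            if el.element_id == element_id:
                return el
        raise FormError(f"unknown element_id {element_id!r}")

    def section_kind_of(self, element_id: str) -> str:
        for sec in self.sections:
            for el in sec.elements:
                if el.element_id == element_id:
                    return sec.section_kind
        raise FormError(f"unknown element_id {element_id!r}")


# ---------------------------------------------------------------------------
# Answers

Provenance = tuple[str, Span]  # (doc_type, span into that document's text)


@dataclass
class Answer:
    """One filled data element.

    ``value`` shape depends on the element kind: a tri-state string, a
    frozenset of selected option labels, a (number, unit) tuple, or ``None``
    for an empty blank.
    """

    element_id: str
    value: object
    provenance: list[Provenance] = field(default_factory=list)
    entry_mode: str = "manual"

    def __post_init__(self) -> None:
        if self.entry_mode not in ENTRY_MODES:
            raise FormError(f"{self.element_id}: bad entry_mode {self.entry_mode!r}")


@dataclass
class AnswerSet:
    case_id: str
    answers: dict[str, Answer] = field(default_factory=dict)
    participant_id: Optional[str] = None
    timings: dict[str, float] = field(default_factory=dict)  # section_kind -> s

    def total_time(self) -> float:
        return sum(self.timings.values())


def answers_equal(kind: str, a: object, b: object, tol: float = 1e-9) -> bool:
    """Element-level equality used for scoring, agreement and adjudication.

    Tri-states compare exactly; choice selections compare as sets; blanks
    compare numerically within ``tol`` after exact unit match, with two empty
    blanks equal.
    """
    if kind == "true_false":
        return a == b
    if kind == "multiple_choice":
        return frozenset(a or ()) == frozenset(b or ())
    if kind == "fill_in_blank":
        if a is None or b is None:
            return a is None and b is None
        (va, ua), (vb, ub) = a, b
        return ua == ub and math.isclose(va, vb, rel_tol=0.0, abs_tol=tol)
    raise FormError(f"unknown element kind {kind!r}")


# ---------------------------------------------------------------------------
# (De)serialization

def _binding_to_dict(el: DataElement) -> dict:
    b = el.binding
    if el.element_kind == "true_false":
        return {"concept_id": b.concept_id}
    if el.element_kind == "multiple_choice":
        return {"options": [[lab, cid] for lab, cid in b.options]}
    return {
        "observable_concept_id": b.observable_concept_id,
        "related_problem_concept_id": b.related_problem_concept_id,
        "expected_unit": b.expected_unit,
    }


def form_to_dict(form: FormDefinition) -> dict:
    return {
        "form_id": form.form_id,
        "condition_label": form.condition_label,
        "sections": [
            {
                "section_kind": sec.section_kind,
                "elements": [
                    {
                        "element_id": el.element_id,
                        "label": el.label,
                        "element_kind": el.element_kind,
                        "source_doc_type": el.source_doc_type,
                        "binding": _binding_to_dict(el),
                    }
                    for el in sec.elements
                ],
            }
            for sec in form.sections
        ],
    }


def form_from_dict(data: dict) -> FormDefinition:
    try:
        sections = []
        for sd in data["sections"]:
            elements = []
            for ed in sd["elements"]:
                bd = ed["binding"]
                binding = Binding(
                    concept_id=bd.get("concept_id"),
                    options=tuple((o[0], o[1]) for o in bd["options"])
                    if bd.get("options")
                    else None,
                    observable_concept_id=bd.get("observable_concept_id"),
                    related_problem_concept_id=bd.get("related_problem_concept_id"),
                    expected_unit=bd.get("expected_unit", ""),
                )
                elements.append(
                    DataElement(
                        ed["element_id"],
                        ed.get("label", ed["element_id"]),
                        ed["element_kind"],
                        ed["source_doc_type"],
                        binding,
                    )
                )
            sections.append(Section(sd["section_kind"], elements))
        return FormDefinition(data["form_id"], data.get("condition_label", ""), sections)
    except (KeyError, TypeError, IndexError) as exc:
        raise FormError(f"malformed form document: {exc!r}") from exc


def load_form(source: Union[str, Path, dict]) -> FormDefinition:
    """Load and structurally validate a form from JSON (path or dict)."""
    if isinstance(source, dict):
        return form_from_dict(source)
    with open(source, encoding="utf-8") as fh:
        return form_from_dict(json.load(fh))


def validate_bindings(form: FormDefinition, term: Terminology) -> list[str]:
    """Check every binding against the terminology; return findings.

    An empty report means prepopulation can resolve every binding.  Findings
    name missing concepts and category mismatches (value-category concepts
    cannot bind true/false or choice slots; the fill-in observable slot must
    bind an ``observable``).
    """
    findings: list[str] = []

    def check(eid: str, cid: Optional[str], slot: str, want: Optional[set] = None,
              forbid: Optional[set] = None) -> None:
        if cid is None:
            return
        if cid not in term:
            findings.append(f"{eid}: {slot} concept {cid!r} missing from terminology")
            return
        cat = term.get(cid).category
        if want and cat not in want:
            findings.append(
                f"{eid}: {slot} concept {cid!r} has category {cat}, expected {sorted(want)}"
            )
        if forbid and cat in forbid:
            findings.append(
                f"{eid}: {slot} concept {cid!r} has forbidden category {cat}"
            )

    for el in form.elements():
        b = el.binding
        if el.element_kind == "true_false":
            check(el.element_id, b.concept_id, "bound", forbid={"value"})
        elif el.element_kind == "multiple_choice":
            for lab, cid in b.options:
                check(el.element_id, cid, f"option {lab!r}", forbid={"value"})
        else:
            check(el.element_id, b.observable_concept_id, "observable slot",
                  want={"observable"})
            check(el.element_id, b.related_problem_concept_id, "problem slot",
                  want={"medical_problem", "body_structure"})
    return findings


def _value_to_json(kind: str, value: object):
    if kind == "multiple_choice":
        return sorted(value or ())
    if kind == "fill_in_blank":
        return None if value is None else [value[0], value[1]]
    return value


def _value_from_json(kind: str, raw):
    if kind == "multiple_choice":
        if raw is None:
            return frozenset()
        if not isinstance(raw, (list, tuple)):
            raise FormError(f"multiple_choice value must be a list, got {raw!r}")
        return frozenset(raw)
    if kind == "fill_in_blank":
        if raw is None:
            return None
        return (float(raw[0]), str(raw[1]))
    if raw not in TRI_STATES:
        raise FormError(f"true_false value must be one of {TRI_STATES}, got {raw!r}")
    return raw


def serialize_answers(answers: AnswerSet, form: FormDefinition) -> dict:
    """JSON-ready answer-set document; inverse of :func:`parse_answers`."""
    return {
        "case_id": answers.case_id,
        "participant_id": answers.participant_id,
        "timings": dict(answers.timings),
        "answers": {
            eid: {
                "value": _value_to_json(form.element(eid).element_kind, a.value),
                "provenance": [
                    {"doc_type": dt, "span": [sp.start, sp.end]}
                    for dt, sp in a.provenance
                ],
                "entry_mode": a.entry_mode,
            }
            for eid, a in answers.answers.items()
        },
    }


def parse_answers(doc: dict, form: FormDefinition) -> AnswerSet:
    """Parse an answer-set document, validating element ids and value shapes."""
    known = {el.element_id for el in form.elements()}
    out = AnswerSet(
        case_id=doc["case_id"],
        participant_id=doc.get("participant_id"),
        timings={k: float(v) for k, v in (doc.get("timings") or {}).items()},
    )
    for eid, ad in doc.get("answers", {}).items():
        if eid not in known:
            raise FormError(f"answer references unknown element_id {eid!r}")
        kind = form.element(eid).element_kind
        out.answers[eid] = Answer(
            element_id=eid,
            value=_value_from_json(kind, ad.get("value")),
            provenance=[
                (p["doc_type"], Span(p["span"][0], p["span"][1]))
                for p in ad.get("provenance", [])
            ],
            entry_mode=ad.get("entry_mode", "manual"),
        )
    return out
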