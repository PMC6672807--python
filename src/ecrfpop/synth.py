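"""Synthetic clinical cases and simulated data-entry behavior.

Real admission records and imaging reports cannot ship with the package, so
this module generates short clinical-style narratives with a known ground
truth: for every form element a state is drawn (affirmed, negated, or not
mentioned; numeric values for blanks), sentences are rendered from templates
into the matching document type, and the drawn truth is recorded as a gold
answer set.  Surface noise (synonym swaps, character typos) is injected at
configurable rates.

A participant model then simulates human review of prefilled forms: wrong
prefills are noticed with probability ``p_notice_error`` and, once noticed,
fixed correctly with probability ``p_fix_correct``; unnoticed wrong prefills
are kept (commission errors); correct prefills are spuriously altered with
probability ``p_spurious_change``.  Section times are lognormal, matching
the right skew of human response times.  ``run_experiment`` wires the whole
thing into a two-arm in-silico trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .evaluation import (
    AccuracyReport,
    ErrorBreakdown,
    GroupComparison,
    TimingRecord,
    classify_errors,
    compare_groups_log,
    error_percentages,
    score_accuracy,
)
from .extraction import Document, ExtractionConfig, extract
from .forms import (
    Answer,
    AnswerSet,
    FormDefinition,
    answers_equal,
    load_form,
)
from .prepopulate import CaseBundle, PrepopulationConfig, empty_baseline, prepopulate_case
from .terminology import Terminology, load_terminology

# ---------------------------------------------------------------------------
# Fixtures


def build_fixture_terminology() -> Terminology:
    """The deterministic built-in vocabulary (29 concepts, all 7 categories)."""
    src = resources.files("ecrfpop.data").joinpath("terminology_fixture.tsv")
    return load_terminology(src.read_text(encoding="utf-8"))


def build_fixture_form(condition_style: str = "chd_like") -> FormDefinition:
    """The built-in congenital-heart-disease or pneumonia style form."""
    name = {
        "chd_like": "form_chd.json",
        "pneumonia_like": "form_pneumonia.json",
    }[condition_style]
    import json

    src = resources.files("ecrfpop.data").joinpath(name)
    return load_form(json.loads(src.read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Case generation

DEFAULT_VALUE_RANGES = {
    "SCT:246116008": (0.2, 1.5, "cm"),
    "SYN:0501": (36.0, 41.0, "°C"),
    "SYN:0502": (20.0, 60.0, "bpm"),
    "SYN:0503": (40.0, 75.0, "%"),
}


@dataclass
class GeneratorConfig:
    """Study-like generation conditions.

    ``finding_prevalence`` is the probability a finding is mentioned at all
    (overridable per concept); a mentioned finding is negated with
    ``negation_prob``, otherwise affirmed.  Surface noise: a non-preferred
    synonym is used with ``synonym_variant_prob`` and a single character edit
    applied with ``typo_char_edit_prob``.
    """

    condition_style: str = "chd_like"
    finding_prevalence: float = 0.6
    prevalence_overrides: dict[str, float] = field(default_factory=dict)
    negation_prob: float = 0.3
    synonym_variant_prob: float = 0.2
    typo_char_edit_prob: float = 0.05
    value_ranges: dict[str, tuple[float, float, str]] = field(
        default_factory=lambda: dict(DEFAULT_VALUE_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.finding_prevalence,
            self.negation_prob,
            self.synonym_variant_prob,
            self.typo_char_edit_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for cid, (lo, hi, _) in self.value_ranges.items():
            if not lo < hi:
                raise ValueError(f"value range for {cid} needs min < max")


_PRESENT_TEMPLATES = (
    "{term} was noted.",
    "Physical examination revealed {term}.",
    "{term} was observed on review.",
)
_NEGATED_TEMPLATES = (
    "No {term} was found.",
    "The patient denies {term}.",
    "There was no {term}.",
)
_VALUE_TEMPLATES = (
    "{problem} {observable} {value} {unit}.",
    "The {observable} of {problem} is {value} {unit}.",
)
_FILLERS = {
    "admission_record": (
        "The patient was admitted for further evaluation.",
        "Past history was unremarkable.",
    ),
    "imaging_report": (
        "An imaging examination was performed on admission.",
        "Image quality was adequate.",
    ),
}


def _pick_surface(term: Terminology, concept_id: str, cfg: GeneratorConfig, rng) -> str:
    c = term.get(concept_id)
    surface = c.preferred_term
    alternates = [s for s in c.synonyms if s != c.preferred_term]
    if alternates and rng.random() < cfg.synonym_variant_prob:
        surface = alternates[rng.integers(len(alternates))]
    if rng.random() < cfg.typo_char_edit_prob and len(surface) > 3:
        i = int(rng.integers(1, len(surface) - 1))
        op = rng.integers(3)
        if op == 0:  # delete
            surface = surface[:i] + surface[i + 1 :]
        elif op == 1:  # substitute
            surface = surface[:i] + chr(ord("a") + int(rng.integers(26))) + surface[i + 1 :]
        else:  # duplicate
            surface = surface[:i] + surface[i] + surface[i:]
    return surface


def _prevalence(cfg: GeneratorConfig, concept_id: str) -> float:
    return cfg.prevalence_overrides.get(concept_id, cfg.finding_prevalence)


def generate_case(
    form: FormDefinition,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    term: Optional[Terminology] = None,
    case_id: str = "case-0",
) -> tuple[list[Document], AnswerSet]:
    """One synthetic case: [admission_record, imaging_report] plus gold answers.

    A fill-in-the-blank value is only planted when the tri-state element
    bound to its related problem (same document type, if the form has one)
    drew true, keeping the gold internally consistent.
    """
    term = term or build_fixture_terminology()
    sentences: dict[str, list[str]] = {"admission_record": [], "imaging_report": []}
    gold = AnswerSet(case_id=case_id)

    tf_truth: dict[tuple[str, str], str] = {}  # (doc_type, concept_id) -> tri-state
    for el in form.elements():
        if el.element_kind != "true_false":
            continue
        cid = el.binding.concept_id
        if rng.random() < _prevalence(cfg, cid):
            state = "false" if rng.random() < cfg.negation_prob else "true"
        else:
            state = "not_mentioned"
        tf_truth[(el.source_doc_type, cid)] = state
        gold.answers[el.element_id] = Answer(el.element_id, state)
        if state != "not_mentioned":
            surface = _pick_surface(term, cid, cfg, rng)
            pool = _PRESENT_TEMPLATES if state == "true" else _NEGATED_TEMPLATES
            tpl = pool[rng.integers(len(pool))]
            sentences[el.source_doc_type].append(tpl.format(term=surface))

    for el in form.elements():
        if el.element_kind != "multiple_choice":
            continue
        selected: list[str] = []
        for label, cid in el.binding.options:
            if rng.random() >= _prevalence(cfg, cid):
                continue
            negated = rng.random() < cfg.negation_prob
            surface = _pick_surface(term, cid, cfg, rng)
            pool = _NEGATED_TEMPLATES if negated else _PRESENT_TEMPLATES
            tpl = pool[rng.integers(len(pool))]
            sentences[el.source_doc_type].append(tpl.format(term=surface))
            if not negated:
                selected.append(label)
        gold.answers[el.element_id] = Answer(el.element_id, frozenset(selected))

    for el in form.elements():
        if el.element_kind != "fill_in_blank":
            continue
        b = el.binding
        problem_state = tf_truth.get((el.source_doc_type, b.related_problem_concept_id))
        if problem_state is None:
            plant = rng.random() < _prevalence(cfg, b.observable_concept_id)
        else:
            plant = problem_state == "true"
        if not plant:
            gold.answers[el.element_id] = Answer(el.element_id, None)
            continue
        lo, hi, unit = cfg.value_ranges.get(
            b.observable_concept_id, (0.1, 9.9, b.expected_unit)
        )
        value = round(float(rng.uniform(lo, hi)), 1)
        unit = b.expected_unit or unit
        obs_surface = _pick_surface(term, b.observable_concept_id, cfg, rng)
        prob_surface = (
            _pick_surface(term, b.related_problem_concept_id, cfg, rng)
            if b.related_problem_concept_id
            else ""
        )
        tpl = _VALUE_TEMPLATES[rng.integers(len(_VALUE_TEMPLATES))]
        sent = tpl.format(
            problem=prob_surface, observable=obs_surface, value=value, unit=unit
        ).replace("  ", " ")
        sentences[el.source_doc_type].append(sent[0].upper() + sent[1:])
        gold.answers[el.element_id] = Answer(el.element_id, (value, unit))

    docs = []
    for doc_type in ("admission_record", "imaging_report"):
        body = list(sentences[doc_type])
        rng.shuffle(body)
        lines = [_FILLERS[doc_type][0]] + body + [_FILLERS[doc_type][1]]
        docs.append(Document(case_id, doc_type, "\n".join(lines)))
    return docs, gold


def generate_cohort(
    form: FormDefinition,
    cfg: GeneratorConfig,
    n_cases: int,
    term: Optional[Terminology] = None,
) -> list[tuple[list[Document], AnswerSet]]:
    """``n_cases`` independent cases from a seed sequence rooted at cfg.seed."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    term = term or build_fixture_terminology()
    children = np.random.SeedSequence(cfg.seed).spawn(n_cases)
    return [
        generate_case(form, cfg, np.random.default_rng(ss), term, f"case-{i:03d}")
        for i, ss in enumerate(children)
    ]


# ---------------------------------------------------------------------------
# Participant behavior

DEFAULT_TIMING_MANUAL = {
    "true_false_I": (np.log(26.0), 0.35),
    "true_false_II": (np.log(49.0), 0.35),
    "multiple_choice": (np.log(10.0), 0.35),
    "fill_in_blank": (np.log(18.0), 0.35),
}
DEFAULT_TIMING_ASSISTED = {
    "true_false_I": (np.log(14.0), 0.35),
    "true_false_II": (np.log(35.0), 0.35),
    "multiple_choice": (np.log(7.5), 0.35),
    "fill_in_blank": (np.log(12.5), 0.35),
}


@dataclass
class BehaviorConfig:
    """How a simulated participant reviews (or enters) a form."""

    p_notice_error: float = 0.55
    p_fix_correct: float = 0.85
    p_spurious_change: float = 0.01
    timing: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIMING_ASSISTED)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_notice_error, self.p_fix_correct, self.p_spurious_change):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for kind, (_, sigma) in self.timing.items():
            if not sigma > 0:
                raise ValueError(f"timing sigma for {kind} must be > 0")

    @classmethod
    def manual_default(cls, seed: int = 0) -> "BehaviorConfig":
        # from-scratch entry: every element is attempted, ~90% land on gold
        return cls(
            p_notice_error=1.0,
            p_fix_correct=0.90,
            p_spurious_change=0.05,
            timing=dict(DEFAULT_TIMING_MANUAL),
            seed=seed,
        )

    @classmethod
    def assisted_default(cls, seed: int = 0) -> "BehaviorConfig":
        return cls(seed=seed)


def _random_wrong_value(el, gold_value, current_value, value_ranges, rng):
    """Uniform draw over the element's value space excluding gold and current."""
    kind = el.element_kind
    if kind == "true_false":
        pool = [
            v
            for v in ("true", "false", "not_mentioned")
            if v != gold_value and v != current_value
        ]
        return pool[rng.integers(len(pool))]
    if kind == "multiple_choice":
        labels = [lab for lab, _ in el.binding.options]
        for _ in range(64):
            sel = frozenset(l for l in labels if rng.random() < 0.5)
            if sel != frozenset(gold_value or ()) and sel != frozenset(
                current_value or ()
            ):
                return sel
        return frozenset(labels) - frozenset(gold_value or ())
    # fill_in_blank
    lo, hi, unit = value_ranges.get(
        el.binding.observable_concept_id, (0.1, 9.9, el.binding.expected_unit)
    )
    unit = el.binding.expected_unit or unit
    for _ in range(64):
        v = (round(float(rng.uniform(lo, hi)), 1), unit)
        if not answers_equal(kind, v, gold_value) and not answers_equal(
            kind, v, current_value
        ):
            return v
    return (hi + 0.1, unit)


def simulate_participant(
    gold: AnswerSet,
    prepop: AnswerSet,
    beh: BehaviorConfig,
    rng: np.random.Generator,
    form: FormDefinition,
    value_ranges: Optional[dict] = None,
    participant_id: str = "p0",
) -> tuple[AnswerSet, list[TimingRecord]]:
    """Simulate one participant finishing one case from a prefilled form."""
    value_ranges = value_ranges if value_ranges is not None else dict(DEFAULT_VALUE_RANGES)
    final = AnswerSet(case_id=gold.case_id, participant_id=participant_id)
    for el in form.elements():
        eid = el.element_id
        base = prepop.answers[eid]
        g = gold.answers[eid].value
        wrong = not answers_equal(el.element_kind, base.value, g)
        value = base.value
        changed = False
        if wrong:
            if rng.random() < beh.p_notice_error:
                changed = True
                if rng.random() < beh.p_fix_correct:
                    value = g
                else:
                    value = _random_wrong_value(el, g, base.value, value_ranges, rng)
        else:
            if rng.random() < beh.p_spurious_change:
                changed = True
                value = _random_wrong_value(el, g, base.value, value_ranges, rng)
        if changed:
            mode = "modified" if base.entry_mode == "prepopulated" else "manual"
        else:
            mode = base.entry_mode
        final.answers[eid] = Answer(eid, value, list(base.provenance), mode)
    timings: list[TimingRecord] = []
    for sec in form.sections:
        mu, sigma = beh.timing.get(sec.section_kind, (np.log(15.0), 0.35))
        secs = float(rng.lognormal(mu, sigma))
        timings.append(
            TimingRecord(participant_id, gold.case_id, sec.section_kind, secs)
        )
        final.timings[sec.section_kind] = secs
    return final, timings


# ---------------------------------------------------------------------------
# Whole-experiment simulation

@dataclass
class ExperimentReport:
    """Synthetic analogue of the study's accuracy / time / error tables."""

    n_cases: int
    n_participants_per_arm: int
    prepop_accuracy: dict[str, float]            # "NLP only" row, percent by kind
    accuracy_manual: AccuracyReport
    accuracy_assisted: AccuracyReport
    accuracy_comparison: GroupComparison         # manual vs assisted, log scale
    time_comparison: GroupComparison             # per-case total seconds
    error_breakdown: ErrorBreakdown              # assisted arm, Table-3 style
    n_wrong_prefills: int
    n_kept_wrong: int


def run_experiment(
    form: FormDefinition,
    gen_cfg: GeneratorConfig,
    beh_manual: BehaviorConfig,
    beh_assisted: BehaviorConfig,
    n_cases: int = 60,
    n_participants_per_arm: int = 12,
    master_seed: int = 0,
    term: Optional[Terminology] = None,
    ext_cfg: Optional[ExtractionConfig] = None,
) -> ExperimentReport:
    """Generate a cohort, prepopulate it, and simulate the two-arm trial."""
    term = term or build_fixture_terminology()
    ext_cfg = ext_cfg or ExtractionConfig()
    root = np.random.SeedSequence(master_seed)
    ss_cohort, ss_manual, ss_assisted = root.spawn(3)

    gen = GeneratorConfig(**{**gen_cfg.__dict__, "seed": int(ss_cohort.generate_state(1)[0] % (2**31))})
    cohort = generate_cohort(form, gen, n_cases, term)

    gold: dict[str, AnswerSet] = {}
    prepop: dict[str, AnswerSet] = {}
    baseline: dict[str, AnswerSet] = {}
    for docs, gold_set in cohort:
        extractions = [extract(d, term, ext_cfg) for d in docs]
        bundle = CaseBundle(gold_set.case_id, docs, extractions)
        prepop[gold_set.case_id] = prepopulate_case(
            form, bundle, PrepopulationConfig(), term
        )
        baseline[gold_set.case_id] = empty_baseline(form, gold_set.case_id)
        gold[gold_set.case_id] = gold_set

    prepop_report = score_accuracy({"nlp": prepop}, gold, form)
    prepop_accuracy = prepop_report.per_participant["nlp"]

    def run_arm(beh: BehaviorConfig, base: dict[str, AnswerSet], ss, tag: str):
        answer_sets: dict[str, dict[str, AnswerSet]] = {}
        all_timings: list[TimingRecord] = []
        for k, child in enumerate(ss.spawn(n_participants_per_arm)):
            pid = f"{tag}{k:02d}"
            rng = np.random.default_rng(child)
            per_case: dict[str, AnswerSet] = {}
            for case_id in sorted(gold):
                final, timings = simulate_participant(
                    gold[case_id], base[case_id], beh, rng, form,
                    gen.value_ranges, pid,
                )
                per_case[case_id] = final
                all_timings.extend(timings)
            answer_sets[pid] = per_case
        return answer_sets, all_timings

    manual_sets, manual_times = run_arm(beh_manual, baseline, ss_manual, "m")
    assisted_sets, assisted_times = run_arm(beh_assisted, prepop, ss_assisted, "a")

    acc_manual = score_accuracy(manual_sets, gold, form)
    acc_assisted = score_accuracy(assisted_sets, gold, form)

    from .evaluation import average_time_per_case

    t_manual = average_time_per_case(manual_times)
    t_assisted = average_time_per_case(assisted_times)
    acc_cmp = compare_groups_log(
        [acc_manual.per_participant[p]["overall"] for p in sorted(manual_sets)],
        [acc_assisted.per_participant[p]["overall"] for p in sorted(assisted_sets)],
    )
    time_cmp = compare_groups_log(
        [t_manual[p] for p in sorted(t_manual)],
        [t_assisted[p] for p in sorted(t_assisted)],
    )

    labelled: list[tuple[str, str]] = []
    n_wrong = n_kept = 0
    for pid, per_case in assisted_sets.items():
        for case_id, final in per_case.items():
            labels = classify_errors(prepop[case_id], final, gold[case_id], form)
            for eid, lab in labels.items():
                labelled.append((form.element(eid).element_kind, lab))
            for el in form.elements():
                g = gold[case_id].answers[el.element_id].value
                p = prepop[case_id].answers[el.element_id].value
                if not answers_equal(el.element_kind, p, g):
                    n_wrong += 1
                    if labels[el.element_id] == "error_without_modification":
                        n_kept += 1
    return ExperimentReport(
        n_cases=n_cases,
        n_participants_per_arm=n_participants_per_arm,
        prepop_accuracy=prepop_accuracy,
        accuracy_manual=acc_manual,
        accuracy_assisted=acc_assisted,
        accuracy_comparison=acc_cmp,
        time_comparison=time_cmp,
        error_breakdown=error_percentages(labelled),
        n_wrong_prefills=n_wrong,
        n_kept_wrong=n_kept,
    )
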