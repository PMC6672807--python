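"""Evaluation statistics for assisted versus manual form filling.

Implements double-entry adjudication into a gold standard, per-participant
accuracy scoring by element kind, between-group comparison of right-skewed
outcomes (accuracy, elapsed time) on the log scale — mean difference of logs
(MD), its Welch 95% CI, the geometric-mean ratio exp(MD), and a two-sided
Welch t test — and the commission/cognitive error taxonomy for reviewed
prefills: an error *without* modification is a wrong prefill the reviewer
kept (commission error); an error *with* modification is a final wrong value
the reviewer produced by editing (cognitive error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .forms import AnswerSet, FormDefinition, answers_equal

ERROR_LABELS = ("no_error", "error_with_modification", "error_without_modification")

# element-kind buckets used in reports; true/false is split by its section
REPORT_KINDS = ("true_false_I", "true_false_II", "multiple_choice", "fill_in_blank")


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Gold standard adjudication

@dataclass
class AdjudicationResult:
    gold: dict[str, AnswerSet]  # case_id -> adjudicated answers
    n_agree: int
    n_total: int
    resolved_by_third: int


def adjudicate(
    entries_a: Mapping[str, AnswerSet],
    entries_b: Mapping[str, AnswerSet],
    resolver: Mapping[str, AnswerSet],
    form: FormDefinition,
) -> AdjudicationResult:
    """Two-step double-entry adjudication.

    Where the two independent entries agree (element-level equality), the
    agreed answer is gold; where they disagree, the third entry resolves.  A
    disagreement the resolver does not cover is an error.
    """
    if set(entries_a) != set(entries_b):
        raise ValueError("rater A and B cover different cases")
    gold: dict[str, AnswerSet] = {}
    n_agree = n_total = 0
    for case_id in sorted(entries_a):
        a_set, b_set = entries_a[case_id], entries_b[case_id]
        out = AnswerSet(case_id=case_id)
        for el in form.elements():
            eid = el.element_id
            try:
                a, b = a_set.answers[eid], b_set.answers[eid]
            except KeyError as exc:
                raise ValueError(f"case {case_id}: missing answer for {eid}") from exc
            n_total += 1
            if answers_equal(el.element_kind, a.value, b.value):
                n_agree += 1
                out.answers[eid] = a
            else:
                try:
                    out.answers[eid] = resolver[case_id].answers[eid]
                except KeyError:
                    raise ValueError(
                        f"resolver missing disagreed element {eid!r} in case {case_id}"
                    ) from None
        gold[case_id] = out
    return AdjudicationResult(gold, n_agree, n_total, n_total - n_agree)


def consistency_rate(n_agree: int, n_total: int) -> float:
    """Inter-operator consistency as a percent, half-up to 2 decimals."""
    if n_total <= 0:
        raise ValueError("consistency_rate undefined for n_total == 0")
    if not 0 <= n_agree <= n_total:
        raise ValueError("need 0 <= n_agree <= n_total")
    return _round_half_up(100.0 * n_agree / n_total)


# ---------------------------------------------------------------------------
# Accuracy

@dataclass
class AccuracyReport:
    """Per-kind and overall accuracies, per participant and group summaries.

    ``per_participant[pid][kind]`` is a percent in [0, 100]; ``median`` /
    ``iqr`` summarize participants per kind ("overall" pools all elements).
    """

    per_participant: dict[str, dict[str, float]]
    median: dict[str, float]
    iqr: dict[str, tuple[float, float]]


def _kind_of(form: FormDefinition, element_id: str) -> str:
    kind = form.section_kind_of(element_id)
    return kind  # section kinds already name the report buckets


def score_accuracy(
    answer_sets: Mapping[str, Mapping[str, AnswerSet]],
    gold: Mapping[str, AnswerSet],
    form: FormDefinition,
) -> AccuracyReport:
    """Score participants against gold.

    ``answer_sets`` maps participant_id -> case_id -> AnswerSet.  Every
    participant must cover every gold case.
    """
    per_participant: dict[str, dict[str, float]] = {}
    for pid in sorted(answer_sets):
        cases = answer_sets[pid]
        missing = set(gold) - set(cases)
        if missing:
            raise ValueError(f"participant {pid} missing cases {sorted(missing)}")
        correct: dict[str, int] = {k: 0 for k in REPORT_KINDS}
        total: dict[str, int] = {k: 0 for k in REPORT_KINDS}
        for case_id, gold_set in gold.items():
            final = cases[case_id]
            for el in form.elements():
                eid = el.element_id
                kind = _kind_of(form, eid)
                total[kind] += 1
                g = gold_set.answers[eid].value
                f = final.answers[eid].value if eid in final.answers else None
                if eid in final.answers and answers_equal(el.element_kind, g, f):
                    correct[kind] += 1
        accs = {
            k: 100.0 * correct[k] / total[k] for k in REPORT_KINDS if total[k] > 0
        }
        accs["overall"] = 100.0 * sum(correct.values()) / sum(total.values())
        per_participant[pid] = accs
    kinds = sorted({k for accs in per_participant.values() for k in accs})
    median = {}
    iqr = {}
    for k in kinds:
        vals = np.array([accs[k] for accs in per_participant.values() if k in accs])
        median[k] = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        iqr[k] = (float(q1), float(q3))
    return AccuracyReport(per_participant, median, iqr)


# ---------------------------------------------------------------------------
# Timing

@dataclass(frozen=True)
class TimingRecord:
    participant_id: str
    case_id: str
    section_kind: str
    elapsed_seconds: float

    def __post_init__(self) -> None:
        if not self.elapsed_seconds > 0:
            raise ValueError("elapsed_seconds must be positive")


def average_time_per_case(
    records: Sequence[TimingRecord], section_kind: Optional[str] = None
) -> dict[str, float]:
    """Per-participant mean elapsed seconds per case (one section or summed)."""
    per: dict[str, dict[str, float]] = {}
    for r in records:
        if section_kind is not None and r.section_kind != section_kind:
            continue
        per.setdefault(r.participant_id, {}).setdefault(r.case_id, 0.0)
        per[r.participant_id][r.case_id] += r.elapsed_seconds
    return {
        pid: sum(by_case.values()) / len(by_case) for pid, by_case in per.items()
    }


# ---------------------------------------------------------------------------
# Group comparison on the log scale

@dataclass
class GroupComparison:
    md: float                   # mean(ln b) - mean(ln a)
    ci_low: float
    ci_high: float
    geometric_ratio: float      # exp(md)
    ratio_ci: tuple[float, float]
    p_value: float
    t_statistic: float
    dof: float
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]


def compare_groups_log(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare two groups of positive outcomes on the log scale.

    Group ``a`` is the reference (manual) arm and ``b`` the treated
    (assisted) arm, so accuracy gains give a positive MD and time savings a
    negative one.  The default test is Welch's two-sided t test with the
    Welch–Satterthwaite CI; ``equal_var=True`` switches to the pooled test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("log comparison requires strictly positive values")
    la, lb = np.log(a), np.log(b)
    md = float(lb.mean() - la.mean())
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    na, nb = la.size, lb.size
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        dof = float(na + nb - 2)
    else:
        se = math.sqrt(va / na + vb / nb)
        dof = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if se == 0.0:
        t_stat, p = 0.0, 1.0
        ci_low = ci_high = md
    else:
        t_stat = md / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), dof))
        tq = float(stats.t.ppf(1 - alpha / 2, dof))
        ci_low, ci_high = md - tq * se, md + tq * se
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return GroupComparison(
        md=md,
        ci_low=ci_low,
        ci_high=ci_high,
        geometric_ratio=math.exp(md),
        ratio_ci=(math.exp(ci_low), math.exp(ci_high)),
        p_value=p,
        t_statistic=t_stat,
        dof=dof,
        median_a=float(np.median(a)),
        iqr_a=(float(q1a), float(q3a)),
        median_b=float(np.median(b)),
        iqr_b=(float(q1b), float(q3b)),
    )


def percent_change_from_md(md: float) -> int:
    """Headline percent change implied by a log-scale mean difference.

    Positive MD -> integer percent increase of the geometric mean; negative
    MD -> the (positive) integer percent reduction is returned with a minus
    sign.  Rounding is half-up on the percent magnitude, matching how such
    changes are conventionally reported.
    """
    ratio = math.exp(md)
    if md >= 0:
        return int(_round_half_up(100.0 * (ratio - 1.0), 0))
    return -int(_round_half_up(100.0 * (1.0 - ratio), 0))


# ---------------------------------------------------------------------------
# Error taxonomy

def classify_errors(
    prepop: AnswerSet,
    final: AnswerSet,
    gold: AnswerSet,
    form: FormDefinition,
) -> dict[str, str]:
    """Label every element no_error / with-modification / without-modification.

    Requires a prepopulated baseline for each element in ``final``.
    """
    labels: dict[str, str] = {}
    for eid in final.answers:
        if eid not in prepop.answers:
            raise ValueError(
                f"element {eid!r} has no prepopulated baseline; "
                "the error taxonomy requires one"
            )
        kind = form.element(eid).element_kind
        g = gold.answers[eid].value
        f = final.answers[eid].value
        p = prepop.answers[eid].value
        if answers_equal(kind, f, g):
            labels[eid] = "no_error"
        elif answers_equal(kind, f, p):
            labels[eid] = "error_without_modification"
        else:
            labels[eid] = "error_with_modification"
    return labels


@dataclass
class ErrorBreakdown:
    """Counts and percents of the two error types, per kind and total.

    ``counts[kind] = (n_with, n_without)``; percents are shares of that
    kind's total errors, half-up to 2 decimals, ``None`` when the kind has
    no errors.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    percents: dict[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )


def error_percentages(
    labelled: Sequence[tuple[str, str]],
) -> ErrorBreakdown:
    """Aggregate (kind, label) pairs into the error table.

    ``labelled`` holds one entry per element occurrence, e.g.
    ``("true_false", "error_without_modification")``; no_error entries are
    ignored.  A "total" row pools all kinds.
    """
    out = ErrorBreakdown()
    kinds = sorted({k for k, _ in labelled}) + ["total"]
    for kind in kinds:
        pool = [
            lab
            for k, lab in labelled
            if (kind == "total" or k == kind) and lab != "no_error"
        ]
        n_with = sum(1 for lab in pool if lab == "error_with_modification")
        n_without = sum(1 for lab in pool if lab == "error_without_modification")
        out.counts[kind] = (n_with, n_without)
        n_err = n_with + n_without
        if n_err == 0:
            out.percents[kind] = (None, None)
        else:
            out.percents[kind] = (
                _round_half_up(100.0 * n_with / n_err),
                _round_half_up(100.0 * n_without / n_err),
            )
    return out
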