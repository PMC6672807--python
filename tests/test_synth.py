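"""Synthetic case generation and participant-behavior simulation."""

import math

import numpy as np
import pytest

import ecrfpop as ep
from ecrfpop.prepopulate import CaseBundle
from ecrfpop.terminology import CATEGORIES


def _prepop_cohort(form, term, cohort):
    out = {}
    for docs, gold in cohort:
        ext = [ep.extract(d, term) for d in docs]
        out[gold.case_id] = ep.prepopulate_case(
            form, CaseBundle(gold.case_id, docs, ext), term=term
        )
    return out


class TestFixtureTerminology:
    def test_printed_concepts_present_with_categories(self, term):
        assert term.get("SCT:246116008").category == "observable"
        assert term.get("SCT:3006004").category == "medical_problem"
        assert term.get("SCT:42842009").category == "medical_problem"
        assert term.get("RID3277").category == "medical_problem"

    def test_deterministic_and_rich_enough(self):
        a = ep.build_fixture_terminology()
        b = ep.build_fixture_terminology()
        assert sorted(a.concepts) == sorted(b.concepts)
        assert len(a) >= 24
        assert {c.category for c in a.concepts.values()} == set(CATEGORIES)


class TestGenerateCase:
    def test_degenerate_all_mentioned_affirmed(self, term, chd_form):
        cfg = ep.GeneratorConfig(
            finding_prevalence=1.0,
            negation_prob=0.0,
            synonym_variant_prob=0.0,
            typo_char_edit_prob=0.0,
        )
        docs, gold = ep.generate_case(chd_form, cfg, np.random.default_rng(0), term)
        by_type = {d.doc_type: d.text for d in docs}
        for el in chd_form.elements():
            if el.element_kind == "true_false":
                assert gold.answers[el.element_id].value == "true"
                pref = term.get(el.binding.concept_id).preferred_term
                assert pref.lower() in by_type[el.source_doc_type].lower()

    def test_all_negated_when_negation_prob_one(self, term, chd_form):
        cfg = ep.GeneratorConfig(
            finding_prevalence=1.0,
            negation_prob=1.0,
            synonym_variant_prob=0.0,
            typo_char_edit_prob=0.0,
        )
        _, gold = ep.generate_case(chd_form, cfg, np.random.default_rng(0), term)
        for el in chd_form.elements():
            if el.element_kind == "true_false":
                assert gold.answers[el.element_id].value == "false"
            elif el.element_kind == "multiple_choice":
                assert gold.answers[el.element_id].value == frozenset()
            else:  # no affirmed problem -> no planted value
                assert gold.answers[el.element_id].value is None

    def test_same_seed_identical_output(self, term, chd_form):
        cfg = ep.GeneratorConfig(seed=3)
        d1, g1 = ep.generate_case(chd_form, cfg, np.random.default_rng(99), term)
        d2, g2 = ep.generate_case(chd_form, cfg, np.random.default_rng(99), term)
        assert [d.text for d in d1] == [d.text for d in d2]
        assert {e: a.value for e, a in g1.answers.items()} == {
            e: a.value for e, a in g2.answers.items()
        }

    def test_blank_gold_consistent_with_problem_state(self, term, chd_form):
        # whenever a lesion size is planted, the VSD tri-state must be true
        cfg = ep.GeneratorConfig(seed=21)
        for docs, gold in ep.generate_cohort(chd_form, cfg, 40, term):
            if gold.answers["fib_vsd_size"].value is not None:
                assert gold.answers["tf2_vsd"].value == "true"


class TestGenerateCohort:
    def test_cohort_sizes(self, term, chd_form):
        cohort = ep.generate_cohort(chd_form, ep.GeneratorConfig(seed=1), 60, term)
        assert len(cohort) == 60
        assert sum(len(docs) for docs, _ in cohort) == 120

    def test_cohort_determinism(self, term, chd_form):
        c1 = ep.generate_cohort(chd_form, ep.GeneratorConfig(seed=4), 5, term)
        c2 = ep.generate_cohort(chd_form, ep.GeneratorConfig(seed=4), 5, term)
        assert [d.text for docs, _ in c1 for d in docs] == [
            d.text for docs, _ in c2 for d in docs
        ]

    def test_invalid_sizes_rejected(self, term, chd_form):
        with pytest.raises(ValueError):
            ep.generate_cohort(chd_form, ep.GeneratorConfig(), 0, term)


class TestZeroNoiseEndToEnd:
    def test_prepopulation_reproduces_gold_exactly(self, term, chd_form):
        cfg = ep.GeneratorConfig(
            synonym_variant_prob=0.0, typo_char_edit_prob=0.0, seed=17
        )
        cohort = ep.generate_cohort(chd_form, cfg, 20, term)
        prepop = _prepop_cohort(chd_form, term, cohort)
        for _, gold in cohort:
            pp = prepop[gold.case_id]
            for el in chd_form.elements():
                assert ep.answers_equal(
                    el.element_kind,
                    gold.answers[el.element_id].value,
                    pp.answers[el.element_id].value,
                ), f"{gold.case_id}/{el.element_id}"

    def test_typo_noise_does_not_improve_accuracy(self, term, chd_form):
        def acc(typo, seed):
            cfg = ep.GeneratorConfig(
                synonym_variant_prob=0.0, typo_char_edit_prob=typo, seed=seed
            )
            cohort = ep.generate_cohort(chd_form, cfg, 12, term)
            prepop = _prepop_cohort(chd_form, term, cohort)
            gold = {g.case_id: g for _, g in cohort}
            r = ep.score_accuracy({"nlp": prepop}, gold, chd_form)
            return r.per_participant["nlp"]["overall"]

        clean = np.mean([acc(0.0, s) for s in range(4)])
        noisy = np.mean([acc(0.6, s) for s in range(4)])
        assert noisy <= clean


class TestSimulateParticipant:
    def _wrong_prefills(self, chd_form, gold, rng):
        """Corrupt every answer to a wrong value, as a prepopulated baseline."""
        from ecrfpop.synth import DEFAULT_VALUE_RANGES, _random_wrong_value

        prepop = ep.AnswerSet(gold.case_id)
        for el in chd_form.elements():
            g = gold.answers[el.element_id].value
            wrong = _random_wrong_value(el, g, g, DEFAULT_VALUE_RANGES, rng)
            prepop.answers[el.element_id] = ep.Answer(
                el.element_id, wrong, [], "prepopulated"
            )
        return prepop

    def test_never_noticing_keeps_the_prefill(self, term, chd_form, rng):
        _, gold = ep.generate_case(
            chd_form, ep.GeneratorConfig(seed=2), np.random.default_rng(2), term
        )
        prepop = self._wrong_prefills(chd_form, gold, rng)
        beh = ep.BehaviorConfig(p_notice_error=0.0, p_spurious_change=0.0)
        final, _ = ep.simulate_participant(gold, prepop, beh, rng, chd_form)
        labels = ep.classify_errors(prepop, final, gold, chd_form)
        assert set(labels.values()) == {"error_without_modification"}

    def test_perfect_reviewer_reaches_gold(self, term, chd_form, rng):
        _, gold = ep.generate_case(
            chd_form, ep.GeneratorConfig(seed=2), np.random.default_rng(2), term
        )
        prepop = self._wrong_prefills(chd_form, gold, rng)
        beh = ep.BehaviorConfig(
            p_notice_error=1.0, p_fix_correct=1.0, p_spurious_change=0.0
        )
        final, _ = ep.simulate_participant(gold, prepop, beh, rng, chd_form)
        for el in chd_form.elements():
            assert ep.answers_equal(
                el.element_kind,
                final.answers[el.element_id].value,
                gold.answers[el.element_id].value,
            )
            assert final.answers[el.element_id].entry_mode == "modified"

    def test_kept_wrong_fraction_matches_notice_probability(self, term, chd_form):
        rng = np.random.default_rng(7)
        p_notice = 0.3
        beh = ep.BehaviorConfig(
            p_notice_error=p_notice, p_fix_correct=1.0, p_spurious_change=0.0
        )
        kept = wrong = 0
        cohort = ep.generate_cohort(chd_form, ep.GeneratorConfig(seed=6), 80, term)
        for _, gold in cohort:
            prepop = self._wrong_prefills(chd_form, gold, rng)
            final, _ = ep.simulate_participant(gold, prepop, beh, rng, chd_form)
            labels = ep.classify_errors(prepop, final, gold, chd_form)
            wrong += len(labels)
            kept += sum(
                1 for v in labels.values() if v == "error_without_modification"
            )
        assert wrong >= 500
        p_hat = kept / wrong
        half = 1.96 * math.sqrt(0.7 * 0.3 / wrong)
        assert abs(p_hat - (1 - p_notice)) < half

    def test_timings_are_positive_and_lognormal_scaled(self, term, chd_form):
        rng = np.random.default_rng(3)
        _, gold = ep.generate_case(
            chd_form, ep.GeneratorConfig(seed=2), np.random.default_rng(2), term
        )
        prepop = self._wrong_prefills(chd_form, gold, rng)
        _, timings = ep.simulate_participant(
            gold, prepop, ep.BehaviorConfig(), rng, chd_form
        )
        assert len(timings) == len(chd_form.sections)
        assert all(t.elapsed_seconds > 0 for t in timings)


class TestRunExperiment:
    def test_identical_arms_give_null_comparison(self, chd_form):
        beh = ep.BehaviorConfig.assisted_default()
        rep = ep.run_experiment(
            chd_form,
            ep.GeneratorConfig(),
            beh,
            beh,
            n_cases=6,
            n_participants_per_arm=6,
            master_seed=5,
        )
        # both arms review the SAME baselines? no: manual arm reviews the
        # empty baseline -- so compare the assisted arm against itself via
        # accuracy symmetry is not applicable; instead check the time MD,
        # whose generating distributions are identical across arms
        assert abs(rep.time_comparison.md) < 0.25
        assert rep.time_comparison.p_value > 0.01

    def test_perfect_assisted_arm_hits_100(self, chd_form):
        gen = ep.GeneratorConfig(synonym_variant_prob=0.0, typo_char_edit_prob=0.0)
        assisted = ep.BehaviorConfig(
            p_notice_error=1.0, p_fix_correct=1.0, p_spurious_change=0.0
        )
        rep = ep.run_experiment(
            chd_form,
            gen,
            ep.BehaviorConfig.manual_default(),
            assisted,
            n_cases=10,
            n_participants_per_arm=4,
            master_seed=2,
        )
        assert rep.prepop_accuracy["overall"] == 100.0
        for accs in rep.accuracy_assisted.per_participant.values():
            assert accs["overall"] == 100.0
        assert rep.accuracy_comparison.geometric_ratio == pytest.approx(
            math.exp(rep.accuracy_comparison.md)
        )

    def test_timing_ratio_recovers_lognormal_shift(self, chd_form):
        # assisted mu = manual mu + ln(2/3) for every section -> the
        # geometric-mean ratio of per-case times estimates 2/3
        shift = math.log(2 / 3)
        manual = ep.BehaviorConfig.manual_default()
        assisted = ep.BehaviorConfig(
            p_notice_error=1.0,
            p_fix_correct=1.0,
            p_spurious_change=0.0,
            timing={k: (mu + shift, s) for k, (mu, s) in manual.timing.items()},
        )
        rep = ep.run_experiment(
            chd_form,
            ep.GeneratorConfig(),
            manual,
            assisted,
            n_cases=20,
            n_participants_per_arm=8,
            master_seed=9,
        )
        # Monte-Carlo tolerance: sigma=0.35 over 4 sections x 20 cases
        assert rep.time_comparison.geometric_ratio == pytest.approx(2 / 3, rel=0.06)
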