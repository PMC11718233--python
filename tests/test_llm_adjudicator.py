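import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keeperllm import (
    BackendParams,
    LabelSet,
    MockBackend,
    PatientProfile,
    ProfileItem,
    PromptVariant,
    ReplayBackend,
    adjudicate_cohort,
    complete,
    confusion,
    labels_from_results,
    metrics,
    parse_response,
    serialize_profile,
    simulate_population,
    SimulationParams,
)
from keeperllm.llm_adjudicator import (
    SUPPORT_GROUPS,
    BackendError,
    PromptTooLargeError,
    TransientBackendError,
    results_from_jsonl,
)
from keeperllm.prompt_builder import DEFAULT_GROUPING, build_messages

from oracles import parse_verdict_by_words

PARAMS = BackendParams()


def make_profile(categories, person_id=1):
    items = [
        ProfileItem(cat, f"finding {i}", pd.Timestamp("2018-01-01"), -1)
        for i, cat in enumerate(categories)
    ]
    return PatientProfile(person_id, pd.Timestamp("2018-01-02"), 60, "female", items)


def messages_for(profile, disease="gout"):
    return build_messages(serialize_profile(profile), disease, PromptVariant.V4_uncertainty)


class FlakyBackend:
    """Fails transiently n times, then answers."""

    def __init__(self, failures, response="Summary: yes"):
        self.failures = failures
        self.calls = 0
        self.response = response

    def complete(self, messages, params):
        self.calls += 1
        if self.calls <= self.failures:
            raise TransientBackendError("rate limited")
        return self.response


class TestComplete:
    def test_mock_is_deterministic(self):
        msgs = messages_for(make_profile(["clinical_presentation", "treatment"]))
        backend = MockBackend()
        assert complete(msgs, PARAMS, backend) == complete(msgs, PARAMS, backend)

    def test_empty_messages_precondition(self):
        with pytest.raises(ValueError):
            complete([], PARAMS, MockBackend())

    def test_context_limit_error(self):
        backend = MockBackend(context_limit_chars=10)
        with pytest.raises(PromptTooLargeError):
            complete(messages_for(make_profile([])), PARAMS, backend)

    def test_retries_then_succeeds(self):
        backend = FlakyBackend(failures=2)
        out = complete([{"role": "user", "content": "x"}], PARAMS, backend, base_delay=0.001)
        assert out == "Summary: yes" and backend.calls == 3

    def test_exhausted_retries_raise(self):
        backend = FlakyBackend(failures=10)
        with pytest.raises(BackendError, match="after 3 attempts"):
            complete([{"role": "user", "content": "x"}], PARAMS, backend, base_delay=0.001)


class TestMockRule:
    def test_diagnosis_alone_is_insufficient(self):
        """An isolated index diagnosis yields 'no' even at min_support=1."""
        profile = make_profile(["preliminary_diagnosis"])
        backend = MockBackend(min_support_categories=1)
        verdict = parse_response(backend.complete(messages_for(profile), PARAMS))
        assert verdict.decision == "no"

    def test_diagnosis_symptom_treatment_is_yes(self):
        profile = make_profile(["preliminary_diagnosis", "clinical_presentation", "treatment"])
        backend = MockBackend(min_support_categories=2)
        verdict = parse_response(backend.complete(messages_for(profile), PARAMS))
        assert verdict.decision == "yes"

    def test_differential_veto(self):
        base = ["clinical_presentation", "treatment"]
        crowded = base + ["differential_diagnoses"] * 3
        with_veto = MockBackend(min_support_categories=2, differential_veto=True)
        without_veto = MockBackend(min_support_categories=2, differential_veto=False)
        v1 = parse_response(with_veto.complete(messages_for(make_profile(crowded)), PARAMS))
        v2 = parse_response(without_veto.complete(messages_for(make_profile(crowded)), PARAMS))
        assert v1.decision == "no" and v2.decision == "yes"

    def test_unrenderable_input_yields_indeterminate(self):
        raw = MockBackend().complete([{"role": "user", "content": "free text"}], PARAMS)
        assert parse_response(raw).decision == "indeterminate"

    def test_matches_independent_rule_reimplementation(self):
        """Mock decisions equal a direct count over profile items."""
        rng = np.random.default_rng(61)
        cats = list(DEFAULT_GROUPING)
        backend = MockBackend(min_support_categories=2, differential_veto=True)
        for _ in range(300):
            chosen = [cats[i] for i in rng.integers(0, len(cats), size=rng.integers(0, 7))]
            profile = make_profile(chosen)
            raw = backend.complete(messages_for(profile), PARAMS)
            got = parse_response(raw).decision
            support_groups = {
                DEFAULT_GROUPING[c] for c in chosen if DEFAULT_GROUPING[c] in SUPPORT_GROUPS
            }
            n_support = sum(1 for c in chosen if DEFAULT_GROUPING[c] in SUPPORT_GROUPS)
            n_diff = sum(1 for c in chosen if c == "differential_diagnoses")
            expect = "yes" if len(support_groups) >= 2 and not n_diff > n_support else "no"
            assert got == expect


class TestParser:
    @pytest.mark.parametrize(
        "raw,decision",
        [
            ("Long discussion...\n\nSummary: Yes, the patient had it.", "yes"),
            ("Summary: No.", "no"),
            ("blah blah, nothing conclusive anywhere", "indeterminate"),
            ("Summary: it is unclear, both yes and no apply", "indeterminate"),
            ("Summary: unclear\nSummary: yes definitely", "yes"),
            ("The answer is yes", "yes"),  # no header: final-200-character scan
            ("not sure, cannot decide", "indeterminate"),  # 'not' is not 'no'
            ("", "indeterminate"),
        ],
    )
    def test_examples(self, raw, decision):
        verdict = parse_response(raw)
        assert verdict.decision == decision
        assert verdict.effective_label == (decision == "yes")

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(
        st.text(
            alphabet=st.sampled_from(
                list("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
                     " \n\t.,:;!?'\"()-")
            ),
            max_size=400,
        )
    )
    def test_fuzz_total_and_matches_word_oracle(self, raw):
        """Parser never throws and agrees with an independent word-level oracle."""
        verdict = parse_response(raw)
        assert verdict.decision == parse_verdict_by_words(raw)


class TestReplay:
    def test_record_then_replay_byte_identical(self, tmp_path):
        msgs = messages_for(make_profile(["treatment", "clinical_presentation"]))
        transcript = tmp_path / "transcript.jsonl"
        recorder = ReplayBackend(transcript, record_from=MockBackend())
        first = recorder.complete(msgs, PARAMS)
        replayer = ReplayBackend(transcript)
        assert replayer.complete(msgs, PARAMS) == first

    def test_missing_key_is_error(self, tmp_path):
        transcript = tmp_path / "t.jsonl"
        transcript.write_text("")
        with pytest.raises(BackendError, match="no recorded response"):
            ReplayBackend(transcript).complete(
                [{"role": "user", "content": "x"}], PARAMS
            )


class TestAdjudicateCohort:
    def _profiles(self, n=10):
        return [
            make_profile(["preliminary_diagnosis", "clinical_presentation", "treatment"], pid)
            if pid % 2
            else make_profile(["preliminary_diagnosis"], pid)
            for pid in range(1, n + 1)
        ]

    def test_one_result_per_profile_and_stable(self):
        profiles = self._profiles()
        runs = [
            adjudicate_cohort(
                profiles, PromptVariant.V4_uncertainty, MockBackend(), PARAMS, "gout"
            )
            for _ in range(2)
        ]
        assert len(runs[0]) == 10
        assert [r.verdict.decision for r in runs[0]] == [r.verdict.decision for r in runs[1]]

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            adjudicate_cohort([], PromptVariant.V0_yes_no, MockBackend(), PARAMS, "gout")

    def test_resume_equals_uninterrupted(self, tmp_path):
        """Kill-and-resume produces a checkpoint identical to one uninterrupted run."""
        profiles = self._profiles(12)
        full = tmp_path / "full.jsonl"
        adjudicate_cohort(
            profiles, PromptVariant.V4_uncertainty, MockBackend(), PARAMS, "gout",
            checkpoint_path=full,
        )
        resumed = tmp_path / "resumed.jsonl"
        adjudicate_cohort(
            profiles[:5], PromptVariant.V4_uncertainty, MockBackend(), PARAMS, "gout",
            checkpoint_path=resumed,
        )
        adjudicate_cohort(
            profiles, PromptVariant.V4_uncertainty, MockBackend(), PARAMS, "gout",
            checkpoint_path=resumed,
        )
        assert resumed.read_bytes() == full.read_bytes()

    def test_per_person_failure_recorded_run_continues(self, tmp_path):
        class FailOn:
            def __init__(self, marker):
                self.marker = marker

            def complete(self, messages, params):
                if self.marker in messages[-1]["content"]:
                    raise BackendError("boom")
                return "Summary: no"

        profiles = self._profiles(4)
        results = adjudicate_cohort(
            profiles, PromptVariant.V0_yes_no, FailOn("finding 2"), PARAMS, "gout"
        )
        assert len(results) == 4
        failed = [r for r in results if r.error]
        ok = [r for r in results if not r.error]
        assert len(failed) == 2  # odd person ids carry the three-finding profile
        assert all(r.verdict is None for r in failed)
        assert all(r.verdict.decision == "no" for r in ok)

    def test_results_jsonl_round_trip(self, tmp_path):
        from keeperllm.llm_adjudicator import results_to_jsonl

        results = adjudicate_cohort(
            self._profiles(6), PromptVariant.V4_uncertainty, MockBackend(), PARAMS, "gout"
        )
        path = tmp_path / "r.jsonl"
        results_to_jsonl(results, path)
        again = results_from_jsonl(path)
        assert [r.person_id for r in again] == [r.person_id for r in results]
        assert [r.verdict.decision for r in again] == [r.verdict.decision for r in results]


def _pipeline_sensitivity(ra_template, p_symptom, seed=71):
    from keeperllm import (
        ConceptSet,
        ConceptSetItem,
        default_config_for_template,
        extract_profiles,
        first_occurrence_cohort,
    )

    params = SimulationParams(
        n_persons=600, prevalence=0.2, p_symptom_given_case=p_symptom,
        p_treatment_given_case=0.7, seed=seed,
    )
    store, truth = simulate_population(ra_template, params)
    config = default_config_for_template(ra_template)
    cs = ConceptSet(
        "dx", [ConceptSetItem(ra_template.diagnosis_root.concept_id, include_descendants=True)]
    )
    cohort = first_occurrence_cohort(store, cs)
    profiles = extract_profiles(store, cohort, config)
    results = adjudicate_cohort(
        profiles, PromptVariant.V4_uncertainty, MockBackend(), PARAMS,
        ra_template.disease_name,
    )
    pred = LabelSet(labels_from_results(results), "silver_llm")
    ref = LabelSet(truth.as_dict(), "truth").restrict(pred.roster)
    return metrics(confusion(ref, pred)).sensitivity


def test_mock_sensitivity_monotone_in_planted_signal(ra_template):
    """Stronger planted symptom signal never lowers pipeline sensitivity."""
    low = _pipeline_sensitivity(ra_template, 0.25)
    high = _pipeline_sensitivity(ra_template, 0.95)
    assert high >= low
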