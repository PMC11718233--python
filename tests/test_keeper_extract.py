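import numpy as np
import pandas as pd
import pytest

from keeperllm import (
    CdmStore,
    ConceptSet,
    ConceptSetItem,
    KeeperCategorySpec,
    KeeperConfig,
    TimeWindow,
    expand_concept_set,
    extract_profile,
    extract_profiles,
    load_keeper_config,
    save_keeper_config,
)
from keeperllm.keeper_extract import (
    ConfigError,
    profiles_from_jsonl,
    profiles_to_jsonl,
)
from keeperllm.phenotype_cohort import CohortEntry

from conftest import random_store_frames
from oracles import triple_filter_items


def _single_category_config(concept_ids, domains, start, end, category="clinical_presentation"):
    return KeeperConfig(
        disease_name="toy disease",
        conceptual_definition="a toy disease",
        categories=[
            KeeperCategorySpec(
                category,
                ConceptSet("set", [ConceptSetItem(c) for c in concept_ids]),
                set(domains),
                TimeWindow(start, end),
            )
        ],
    )


def _store_with_events(rows):
    """rows: (person_id, concept_id, date, domain, value)."""
    concepts = pd.DataFrame(
        {
            "concept_id": sorted({r[1] for r in rows}),
            "concept_name": [f"concept {c}" for c in sorted({r[1] for r in rows})],
            "domain": [
                next(r[3] for r in rows if r[1] == c) for c in sorted({r[1] for r in rows})
            ],
        }
    )
    events = pd.DataFrame(
        rows, columns=["person_id", "concept_id", "event_date", "domain", "value_as_number"]
    )
    persons = pd.DataFrame(
        {
            "person_id": sorted({r[0] for r in rows}),
            "year_of_birth": 1950,
            "gender_text": "female",
        }
    )
    return CdmStore(persons=persons, events=events, concepts=concepts, ancestry=None)


class TestConfig:
    def test_round_trip(self, tmp_path, ra_config):
        for ext in ("yaml", "json"):
            path = tmp_path / f"cfg.{ext}"
            save_keeper_config(ra_config, path)
            again = load_keeper_config(path)
            assert again == ra_config

    def test_shipped_illustrative_configs_load(self):
        from importlib import resources

        for name in ("rheumatoid_arthritis_keeper.yaml", "osteoporosis_keeper.yaml"):
            path = resources.files("keeperllm") / "configs" / name
            config = load_keeper_config(str(path))
            assert any(c.category_name == "clinical_presentation" for c in config.categories)
            symptoms = next(
                c for c in config.categories if c.category_name == "clinical_presentation"
            )
            assert (symptoms.window.start_offset_days, symptoms.window.end_offset_days) == (-30, 0)

    def test_inverted_window_fatal(self):
        with pytest.raises(ConfigError, match="inverted"):
            TimeWindow(5, -5)

    def test_unknown_category_fatal(self):
        with pytest.raises(ConfigError, match="unknown category"):
            _single_category_config([1], {"condition"}, -30, 0, category="vibes")

    def test_duplicate_categories_fatal(self, ra_config):
        with pytest.raises(ConfigError, match="duplicate"):
            KeeperConfig("x", "y", ra_config.categories + [ra_config.categories[0]])


class TestWindows:
    def test_boundary_inclusive(self):
        store = _store_with_events(
            [
                (1, 5, "2018-01-01", "condition", np.nan),   # day -30: included
                (1, 5, "2017-12-31", "condition", np.nan),   # day -31: excluded
                (1, 5, "2018-01-31", "condition", np.nan),   # day 0: included
            ]
        )
        config = _single_category_config([5], {"condition"}, -30, 0)
        profile = extract_profile(store, CohortEntry(1, pd.Timestamp("2018-01-31")), config)
        assert sorted(it.days_from_index for it in profile.items) == [-30, 0]

    def test_unbounded_past_history(self):
        """'At any point prior' captures a comorbidity 900 days back but not day 0."""
        store = _store_with_events(
            [
                (1, 5, "2015-07-16", "condition", np.nan),  # day -900
                (1, 5, "2018-01-01", "condition", np.nan),  # day 0
            ]
        )
        config = _single_category_config([5], {"condition"}, None, -1, category="comorbidities")
        profile = extract_profile(store, CohortEntry(1, pd.Timestamp("2018-01-01")), config)
        assert [it.days_from_index for it in profile.items] == [-900]


def test_duplicate_billing_rows_collapse_with_count():
    store = _store_with_events(
        [
            (1, 5, "2018-01-10", "condition", np.nan),
            (1, 5, "2018-01-10", "condition", np.nan),
            (1, 5, "2018-01-10", "condition", np.nan),
        ]
    )
    config = _single_category_config([5], {"condition"}, -30, 30)
    profile = extract_profile(store, CohortEntry(1, pd.Timestamp("2018-01-01")), config)
    assert len(profile.items) == 1 and profile.items[0].count == 3


def test_measurement_value_rendering():
    store = _store_with_events(
        [
            (1, 5, "2018-01-02", "measurement", 18.5),
            (1, 5, "2018-01-03", "measurement", np.nan),
        ]
    )
    config = _single_category_config(
        [5], {"measurement"}, -30, 30, category="diagnostic_procedures"
    )
    profile = extract_profile(store, CohortEntry(1, pd.Timestamp("2018-01-01")), config)
    texts = [it.value_text for it in profile.items]
    assert texts == ["18.5", "ordered, result not recorded"]


def test_profiles_preserve_cohort_order_and_fields(small_store, small_cohort, ra_config):
    profiles = extract_profiles(small_store, small_cohort, ra_config)
    assert [p.person_id for p in profiles] == list(small_cohort["person_id"])
    yob = small_store.persons.set_index("person_id")["year_of_birth"]
    for p in profiles[:10]:
        assert p.age_at_index == p.index_date.year - yob.loc[p.person_id]


def test_empty_cohort_gives_empty_list(small_store, ra_config):
    assert extract_profiles(small_store, pd.DataFrame(columns=["person_id", "index_date"]), ra_config) == []


def test_unknown_cohort_person_fatal(small_store, ra_config):
    cohort = pd.DataFrame({"person_id": [10**6], "index_date": [pd.Timestamp("2018-01-01")]})
    with pytest.raises(KeyError):
        extract_profiles(small_store, cohort, ra_config)


def test_items_match_triple_filter_oracle(small_store, small_cohort, ra_config):
    """Item sets equal brute-force (concept in set, domain match, date in window)."""
    profiles = extract_profiles(small_store, small_cohort, ra_config)
    by_pid = {p.person_id: p for p in profiles}
    name_to_id = dict(
        zip(small_store.concepts["concept_name"], small_store.concepts["concept_id"])
    )
    index_of = dict(zip(small_cohort["person_id"], small_cohort["index_date"]))
    for pid in list(by_pid)[:40]:
        profile = by_pid[pid]
        for spec in ra_config.categories:
            ids = expand_concept_set(spec.concept_set, small_store.ancestry)
            expected = triple_filter_items(
                small_store.events,
                pid,
                index_of[pid],
                ids,
                spec.domains,
                spec.window.start_offset_days,
                spec.window.end_offset_days,
            )
            got = {
                (name_to_id[it.concept_name], it.days_from_index)
                for it in profile.items
                if it.category_name == spec.category_name
            }
            assert got == expected


def test_window_containment_and_dimensionality_reduction(small_store, small_cohort, ra_config):
    """Every emitted item lies in its category window and concept set."""
    profiles = extract_profiles(small_store, small_cohort, ra_config)
    spec_of = {c.category_name: c for c in ra_config.categories}
    id_of = dict(zip(small_store.concepts["concept_name"], small_store.concepts["concept_id"]))
    for p in profiles:
        for it in p.items:
            spec = spec_of[it.category_name]
            assert spec.window.contains(it.days_from_index)
            assert id_of[it.concept_name] in expand_concept_set(
                spec.concept_set, small_store.ancestry
            )
            assert (it.event_date - p.index_date).days == it.days_from_index


def test_randomized_windows_match_oracle():
    """Random stores and random single-category configs agree with brute force."""
    rng = np.random.default_rng(53)
    for _ in range(30):
        persons, events, concepts = random_store_frames(rng, n_persons=6, n_events=60)
        store = CdmStore(persons=persons, events=events, concepts=concepts, ancestry=None)
        ids = list(rng.choice(concepts["concept_id"], size=3, replace=False))
        domains = set(rng.choice(list("cdm"), size=2, replace=False))
        domains = {
            {"c": "condition", "d": "drug", "m": "measurement"}[d] for d in domains
        }
        start = None if rng.random() < 0.3 else int(rng.integers(-400, 0))
        end = int(rng.integers(start if start is not None else -400, 400))
        config = _single_category_config([int(i) for i in ids], domains, start, end)
        pid = int(rng.integers(1, 7))
        index_date = pd.Timestamp("2017-06-01")
        profile = extract_profile(store, CohortEntry(pid, index_date), config)
        got = {
            (int(store.concepts.set_index("concept_name")["concept_id"][it.concept_name]),
             it.days_from_index)
            for it in profile.items
        }
        expected = triple_filter_items(
            store.events, pid, index_date, set(ids), domains, start, end
        )
        assert got == expected


def test_profiles_jsonl_round_trip(tmp_path, small_profiles):
    path = tmp_path / "profiles.jsonl"
    profiles_to_jsonl(small_profiles, path)
    again = profiles_from_jsonl(path)
    assert again == small_profiles
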