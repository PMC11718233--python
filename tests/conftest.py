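import numpy as np
import pandas as pd
import pytest

from keeperllm import (
    ConceptSet,
    ConceptSetItem,
    SimulationParams,
    default_config_for_template,
    extract_profiles,
    first_occurrence_cohort,
    rheumatoid_arthritis_template,
    simulate_population,
)


@pytest.fixture(scope="session")
def ra_template():
    return rheumatoid_arthritis_template()


@pytest.fixture(scope="session")
def ra_config(ra_template):
    return default_config_for_template(ra_template)


@pytest.fixture(scope="session")
def small_population(ra_template):
    """300-person simulated store with planted truth (seed 7)."""
    params = SimulationParams(n_persons=300, prevalence=0.15, seed=7)
    return simulate_population(ra_template, params)


@pytest.fixture(scope="session")
def small_store(small_population):
    return small_population[0]


@pytest.fixture(scope="session")
def small_truth(small_population):
    return small_population[1]


@pytest.fixture(scope="session")
def diagnosis_set(ra_template):
    return ConceptSet(
        "ra diagnoses",
        [ConceptSetItem(ra_template.diagnosis_root.concept_id, include_descendants=True)],
    )


@pytest.fixture(scope="session")
def small_cohort(small_store, diagnosis_set):
    return first_occurrence_cohort(small_store, diagnosis_set)


@pytest.fixture(scope="session")
def small_profiles(small_store, small_cohort, ra_config):
    return extract_profiles(small_store, small_cohort, ra_config)


def random_store_frames(rng: np.random.Generator, n_persons=8, n_concepts=6, n_events=40):
    """Tiny random-but-valid store ingredients for oracle checks."""
    domains = ["condition", "drug", "measurement", "procedure", "observation"]
    concept_ids = list(range(10, 10 + n_concepts))
    concepts = pd.DataFrame(
        {
            "concept_id": concept_ids,
            "concept_name": [f"concept {c}" for c in concept_ids],
            "domain": [domains[i % len(domains)] for i in range(n_concepts)],
        }
    )
    dom_of = dict(zip(concepts["concept_id"], concepts["domain"]))
    pids = rng.integers(1, n_persons + 1, size=n_events)
    cids = rng.choice(concept_ids, size=n_events)
    dates = pd.to_datetime("2017-01-01") + pd.to_timedelta(
        rng.integers(0, 365, size=n_events), unit="D"
    )
    events = pd.DataFrame(
        {
            "person_id": pids,
            "concept_id": cids,
            "event_date": dates,
            "domain": [dom_of[c] for c in cids],
        }
    )
    persons = pd.DataFrame(
        {
            "person_id": range(1, n_persons + 1),
            "year_of_birth": rng.integers(1940, 1990, size=n_persons),
            "gender_text": ["female" if i % 2 else "male" for i in range(n_persons)],
        }
    )
    return persons, events, concepts
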