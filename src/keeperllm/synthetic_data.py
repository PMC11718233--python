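"""Seeded synthetic OMOP populations with planted case/non-case structure.

Real claims and EHR sources cannot be redistributed, so every downstream
stage is exercised on simulated data: a toy concept hierarchy (one
diagnosis root with a few descendant codes plus auxiliary symptom /
comorbidity / treatment / differential / laboratory concepts) and a
longitudinal event simulator that plants signal consistent with the
default extraction windows:

* true cases get a descendant diagnosis code on their index date,
  symptoms 1-30 days before, treatments 0-90 days after, comorbidities
  31-1800 days before, and disease-relevant laboratory orders around
  index (results recorded only for a configurable fraction, emulating
  claims sources where most laboratory orders lack result values);
* non-cases may get a spurious isolated diagnosis code, or a
  differential diagnosis together with its own treatment, a shared
  symptom and a rule-out laboratory order (realistic false-positive
  bait for the adjudicator, and realistic non-case entrants for the
  high-sensitivity cohort);
* everyone accrues Poisson background events from an unrelated concept
  pool.

One global seed drives a per-person derived stream ``(seed, person_id)``
so enlarging the population never reshuffles existing persons.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .omop_store import CdmStore

#: Simulated observation window for index dates.
_WINDOW_START = dt.date(2015, 1, 1)
_WINDOW_END = dt.date(2019, 12, 31)


@dataclass(frozen=True)
class ToyConcept:
    concept_id: int
    concept_name: str
    domain: str = "condition"


@dataclass
class DiseaseTemplate:
    """Toy disease: one diagnosis root with descendants plus auxiliary concepts.

    Concept lists must be pairwise disjoint; all ids must be unique.
    """

    disease_name: str
    conceptual_definition: str
    diagnosis_root: ToyConcept
    diagnosis_codes: list[ToyConcept]        # descendants of the root, >= 2
    symptom_concepts: list[ToyConcept]
    comorbidity_concepts: list[ToyConcept]
    treatment_concepts: list[ToyConcept]
    differential_concepts: list[ToyConcept]
    differential_treatment_concepts: list[ToyConcept]
    lab_concepts: list[ToyConcept]
    background_concepts: list[ToyConcept] = field(default_factory=list)

    def concept_groups(self) -> dict[str, list[ToyConcept]]:
        return {
            "diagnosis_root": [self.diagnosis_root],
            "diagnosis_codes": self.diagnosis_codes,
            "symptom_concepts": self.symptom_concepts,
            "comorbidity_concepts": self.comorbidity_concepts,
            "treatment_concepts": self.treatment_concepts,
            "differential_concepts": self.differential_concepts,
            "differential_treatment_concepts": self.differential_treatment_concepts,
            "lab_concepts": self.lab_concepts,
            "background_concepts": self.background_concepts,
        }

    def all_concepts(self) -> list[ToyConcept]:
        out: list[ToyConcept] = []
        for group in self.concept_groups().values():
            out.extend(group)
        return out


@dataclass
class SimulationParams:
    """Population size, prevalence and planting probabilities.

    Probabilities are per relevant concept (e.g. each symptom concept is
    planted independently with ``p_symptom_given_case``).
    ``lab_result_recording_rate`` defaults to 0.3: roughly a third of
    laboratory orders in claims sources carry a numeric result.
    """

    n_persons: int = 2000
    prevalence: float = 0.1
    p_symptom_given_case: float = 0.8
    p_treatment_given_case: float = 0.8
    p_comorbidity_given_case: float = 0.4
    p_lab_given_case: float = 0.6
    p_spurious_diagnosis_given_noncase: float = 0.05
    p_differential_given_noncase: float = 0.10
    background_event_rate: float = 3.0
    lab_result_recording_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for f in fields(self):
            if f.name.startswith("p_") or f.name in (
                "prevalence",
                "lab_result_recording_rate",
            ):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name}={v} outside [0, 1]")
        if self.background_event_rate < 0:
            raise ValueError("background_event_rate must be >= 0")


@dataclass
class TruthLabels:
    """Planted case labels: person_id -> (true_case, true_index_date)."""

    frame: pd.DataFrame  # columns person_id, true_case, true_index_date

    def __post_init__(self) -> None:
        f = self.frame.copy()
        f["person_id"] = f["person_id"].astype(np.int64)
        f["true_case"] = f["true_case"].astype(bool)
        f["true_index_date"] = pd.to_datetime(f["true_index_date"])
        missing = f.loc[f["true_case"] & f["true_index_date"].isna(), "person_id"]
        if len(missing):
            raise ValueError(f"true cases without index date: {sorted(missing)[:10]}")
        self.frame = f.sort_values("person_id", kind="stable").reset_index(drop=True)

    def as_dict(self) -> dict[int, bool]:
        return dict(zip(self.frame["person_id"], self.frame["true_case"]))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["true_index_date"] = out["true_index_date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "TruthLabels":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def rheumatoid_arthritis_template() -> DiseaseTemplate:
    """Illustrative rheumatoid-arthritis template (synthetic toy vocabulary)."""
    return DiseaseTemplate(
        disease_name="rheumatoid arthritis",
        conceptual_definition=(
            "A chronic autoimmune inflammatory arthritis characterized by "
            "persistent symmetric polyarthritis of small joints, morning "
            "stiffness, and positive serologic markers such as rheumatoid "
            "factor or anti-CCP antibodies."
        ),
        diagnosis_root=ToyConcept(80809, "Rheumatoid arthritis"),
        diagnosis_codes=[
            ToyConcept(80810, "Seropositive rheumatoid arthritis"),
            ToyConcept(80811, "Rheumatoid arthritis of multiple joints"),
            ToyConcept(80812, "Seronegative rheumatoid arthritis"),
        ],
        symptom_concepts=[
            ToyConcept(20001, "Joint pain"),
            ToyConcept(20002, "Joint swelling"),
            ToyConcept(20003, "Morning stiffness"),
            ToyConcept(20004, "Fatigue"),
        ],
        comorbidity_concepts=[
            ToyConcept(21001, "Osteoporosis without current fracture"),
            ToyConcept(21002, "Sicca syndrome"),
        ],
        treatment_concepts=[
            ToyConcept(30001, "Methotrexate", "drug"),
            ToyConcept(30002, "Adalimumab", "drug"),
            ToyConcept(30003, "Sulfasalazine", "drug"),
        ],
        differential_concepts=[
            ToyConcept(22001, "Osteoarthritis"),
            ToyConcept(22002, "Psoriatic arthritis"),
            ToyConcept(22003, "Systemic lupus erythematosus"),
        ],
        differential_treatment_concepts=[
            ToyConcept(31001, "Topical diclofenac", "drug"),
            ToyConcept(31002, "Intra-articular corticosteroid injection", "drug"),
        ],
        lab_concepts=[
            ToyConcept(40001, "Rheumatoid factor measurement", "measurement"),
            ToyConcept(40002, "Anti-CCP antibody measurement", "measurement"),
            ToyConcept(40003, "C-reactive protein measurement", "measurement"),
        ],
        background_concepts=_default_background(),
    )


def osteoporosis_template() -> DiseaseTemplate:
    """Illustrative osteoporosis template (synthetic toy vocabulary)."""
    return DiseaseTemplate(
        disease_name="osteoporosis",
        conceptual_definition=(
            "A skeletal disorder characterized by decreased bone density and "
            "strength, leading to fragile bones and an increased risk of "
            "fractures."
        ),
        diagnosis_root=ToyConcept(80502, "Osteoporosis"),
        diagnosis_codes=[
            ToyConcept(80503, "Postmenopausal osteoporosis"),
            ToyConcept(80504, "Senile osteoporosis"),
            ToyConcept(80505, "Drug-induced osteoporosis"),
        ],
        symptom_concepts=[
            ToyConcept(20101, "Joint pain of pelvic region"),
            ToyConcept(20102, "Back pain"),
            ToyConcept(20103, "Loss of height"),
        ],
        comorbidity_concepts=[
            ToyConcept(21101, "Fracture of bone"),
            ToyConcept(21102, "Vitamin D deficiency"),
        ],
        treatment_concepts=[
            ToyConcept(30101, "Zoledronic acid", "drug"),
            ToyConcept(30102, "Alendronate", "drug"),
            ToyConcept(30103, "Denosumab", "drug"),
        ],
        differential_concepts=[
            ToyConcept(22101, "Osteomalacia"),
            ToyConcept(22102, "Malignant neoplastic disease"),
        ],
        differential_treatment_concepts=[
            ToyConcept(31101, "Calcitriol", "drug"),
        ],
        lab_concepts=[
            ToyConcept(40101, "Bone density measurement", "measurement"),
            ToyConcept(40102, "Serum calcium measurement", "measurement"),
        ],
        background_concepts=_default_background(),
    )


def _default_background() -> list[ToyConcept]:
    """Unrelated noise concepts shared by the shipped templates."""
    return [
        ToyConcept(90001, "Acute upper respiratory infection"),
        ToyConcept(90002, "Essential hypertension"),
        ToyConcept(90003, "Type 2 diabetes mellitus"),
        ToyConcept(90004, "Lisinopril", "drug"),
        ToyConcept(90005, "Atorvastatin", "drug"),
        ToyConcept(90006, "Screening colonoscopy", "procedure"),
        ToyConcept(90007, "Influenza vaccination", "procedure"),
        ToyConcept(90008, "Lipid panel", "measurement"),
        ToyConcept(90009, "Outpatient visit", "visit"),
        ToyConcept(90010, "Tobacco use", "observation"),
    ]


DEFAULT_TEMPLATES = {
    "ra": rheumatoid_arthritis_template,
    "osteoporosis": osteoporosis_template,
}


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

def build_toy_vocabulary(template: DiseaseTemplate) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concept and reflexively-closed ancestry tables for a template.

    The hierarchy is a single star: the diagnosis root is ancestor of each
    descendant diagnosis code; every concept is its own descendant.
    Overlapping concept lists or duplicate ids are fatal.
    """
    groups = template.concept_groups()
    seen: dict[int, str] = {}
    for group_name, concepts in groups.items():
        for c in concepts:
            if c.concept_id in seen:
                raise ValueError(
                    f"concept id {c.concept_id} appears in both "
                    f"{seen[c.concept_id]} and {group_name}"
                )
            seen[c.concept_id] = group_name
    if len(template.diagnosis_codes) < 2:
        raise ValueError("diagnosis root needs >= 2 descendant codes")

    all_concepts = template.all_concepts()
    concepts = pd.DataFrame(
        {
            "concept_id": [c.concept_id for c in all_concepts],
            "concept_name": [c.concept_name for c in all_concepts],
            "domain": [c.domain for c in all_concepts],
        }
    )
    root = template.diagnosis_root.concept_id
    pairs = [(root, d.concept_id) for d in template.diagnosis_codes]
    pairs += [(c.concept_id, c.concept_id) for c in all_concepts]
    ancestry = pd.DataFrame(pairs, columns=["ancestor_concept_id", "descendant_concept_id"])
    ancestry = ancestry.drop_duplicates().sort_values(
        ["ancestor_concept_id", "descendant_concept_id"], kind="stable"
    ).reset_index(drop=True)
    return concepts, ancestry


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _person_rng(seed: int, person_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, person_id]))


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def simulate_population(
    template: DiseaseTemplate, params: SimulationParams
) -> tuple[CdmStore, TruthLabels]:
    """Simulate a longitudinal coded population with planted truth.

    Fully reproducible given ``params.seed``; person ``i`` is driven by the
    derived stream ``(seed, i)``, so growing ``n_persons`` leaves earlier
    persons' records unchanged.
    """
    persons = []
    labels = []
    ev_person: list[int] = []
    ev_concept: list[int] = []
    ev_date: list[dt.date] = []
    ev_domain: list[str] = []
    ev_value: list[float] = []
    ev_unit: list[str | None] = []

    def emit(pid: int, c: ToyConcept, date: dt.date, value: float | None = None,
             unit: str | None = None) -> None:
        ev_person.append(pid)
        ev_concept.append(c.concept_id)
        ev_date.append(date)
        ev_domain.append(c.domain)
        ev_value.append(np.nan if value is None else value)
        ev_unit.append(unit)

    bg_pool = template.background_concepts
    for pid in range(1, params.n_persons + 1):
        rng = _person_rng(params.seed, pid)
        year_of_birth = int(rng.integers(1935, 1996))
        gender = "female" if rng.random() < 0.5 else "male"
        persons.append((pid, year_of_birth, gender))

        is_case = bool(rng.random() < params.prevalence)
        index_date: dt.date | None = None
        if is_case:
            index_date = _random_date(rng, _WINDOW_START, _WINDOW_END)
            code = template.diagnosis_codes[int(rng.integers(len(template.diagnosis_codes)))]
            emit(pid, code, index_date)
            for c in template.symptom_concepts:
                if rng.random() < params.p_symptom_given_case:
                    emit(pid, c, index_date - dt.timedelta(days=int(rng.integers(1, 31))))
            for c in template.treatment_concepts:
                if rng.random() < params.p_treatment_given_case:
                    emit(pid, c, index_date + dt.timedelta(days=int(rng.integers(0, 91))))
            for c in template.comorbidity_concepts:
                if rng.random() < params.p_comorbidity_given_case:
                    emit(pid, c, index_date - dt.timedelta(days=int(rng.integers(31, 1801))))
            for c in template.lab_concepts:
                if rng.random() < params.p_lab_given_case:
                    date = index_date - dt.timedelta(days=int(rng.integers(0, 31)))
                    if rng.random() < params.lab_result_recording_rate:
                        emit(pid, c, date, value=float(np.round(rng.normal(50.0, 15.0), 1)),
                             unit="IU/mL")
                    else:
                        emit(pid, c, date)
        else:
            pseudo_index = _random_date(rng, _WINDOW_START, _WINDOW_END)
            if rng.random() < params.p_spurious_diagnosis_given_noncase:
                code = template.diagnosis_codes[
                    int(rng.integers(len(template.diagnosis_codes)))
                ]
                emit(pid, code, pseudo_index)
            if rng.random() < params.p_differential_given_noncase:
                diff = template.differential_concepts[
                    int(rng.integers(len(template.differential_concepts)))
                ]
                emit(pid, diff, pseudo_index)
                if template.differential_treatment_concepts:
                    tr = template.differential_treatment_concepts[
                        int(rng.integers(len(template.differential_treatment_concepts)))
                    ]
                    emit(pid, tr, pseudo_index + dt.timedelta(days=int(rng.integers(0, 31))))
                # shared presentation and a rule-out laboratory order: the
                # differential shares symptoms with the disease, and a
                # work-up is typically ordered to exclude it
                if template.symptom_concepts:
                    sym = template.symptom_concepts[
                        int(rng.integers(len(template.symptom_concepts)))
                    ]
                    emit(pid, sym, pseudo_index - dt.timedelta(days=int(rng.integers(1, 31))))
                if template.lab_concepts:
                    lab = template.lab_concepts[int(rng.integers(len(template.lab_concepts)))]
                    date = pseudo_index + dt.timedelta(days=int(rng.integers(0, 15)))
                    if rng.random() < params.lab_result_recording_rate:
                        emit(pid, lab, date, value=float(np.round(rng.normal(20.0, 8.0), 1)),
                             unit="IU/mL")
                    else:
                        emit(pid, lab, date)

        n_background = int(rng.poisson(params.background_event_rate))
        for _ in range(n_background):
            c = bg_pool[int(rng.integers(len(bg_pool)))]
            date = _random_date(rng, _WINDOW_START, _WINDOW_END)
            if c.domain == "measurement" and rng.random() < params.lab_result_recording_rate:
                emit(pid, c, date, value=float(np.round(rng.normal(100.0, 20.0), 1)), unit="mg/dL")
            else:
                emit(pid, c, date)

        labels.append((pid, is_case, index_date))

    concepts, ancestry = build_toy_vocabulary(template)
    store = CdmStore(
        persons=pd.DataFrame(persons, columns=["person_id", "year_of_birth", "gender_text"]),
        events=pd.DataFrame(
            {
                "person_id": ev_person,
                "concept_id": ev_concept,
                "event_date": pd.to_datetime(ev_date),
                "domain": ev_domain,
                "value_as_number": ev_value,
                "unit": ev_unit,
            }
        ),
        concepts=concepts,
        ancestry=ancestry,
    )
    truth = TruthLabels(
        pd.DataFrame(labels, columns=["person_id", "true_case", "true_index_date"])
    )
    return store, truth


# ---------------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------------

def truth_summary(labels, ndigits: int = 1) -> dict:
    """Counts and case fraction for a boolean label collection.

    Accepts :class:`TruthLabels`, a mapping person_id -> bool, or any
    object exposing ``as_dict``. ``case_pct`` is the percentage rounded
    half-away-from-zero to ``ndigits`` decimals (display convention).
    """
    if hasattr(labels, "as_dict"):
        mapping = labels.as_dict()
    else:
        mapping = dict(labels)
    if not mapping:
        raise ValueError("empty labels")
    n = len(mapping)
    n_cases = sum(bool(v) for v in mapping.values())
    frac = n_cases / n
    from .evaluation import round_half_away_from_zero

    return {
        "n_persons": n,
        "n_cases": n_cases,
        "case_fraction": frac,
        "case_pct": round_half_away_from_zero(100.0 * frac, ndigits),
    }
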