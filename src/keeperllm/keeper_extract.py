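"""Standardized patient-profile extraction (the KEEPER step).

For each cohort entry, extract the person's coded events that fall in
pre-specified clinical categories — each category a concept set, a set
of domains, and a time window anchored at the index date — and present
them as a standardized, dimensionality-reduced profile ordered by
category, date and concept name.

Window semantics: offsets are signed days relative to index (0 = index
day), bounds inclusive at both ends. "Within 30 days before index" is
``[-30, 0]``; "at any point prior" is ``(-inf, -1]`` (start ``None``).
Index-day coding belongs to clinical presentation; strictly-prior
history windows avoid double-counting the index diagnosis. Duplicate
identical (concept, date) rows — common in claims, one line per billing
row — are collapsed to a single item with an occurrence count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .omop_store import DOMAINS, CdmStore
from .phenotype_cohort import ConceptSet, ConceptSetItem, expand_concept_set

#: Closed enum of profile categories, in canonical presentation order.
CATEGORY_NAMES = (
    "clinical_presentation",
    "disease_history",
    "preliminary_diagnosis",
    "diagnostic_procedures",
    "differential_diagnoses",
    "treatment",
    "follow_up_care",
    "complications",
    "comorbidities",
    "risk_factors",
)


class ConfigError(Exception):
    """Invalid extraction configuration."""


@dataclass(frozen=True)
class TimeWindow:
    """Inclusive day-offset window relative to index; start None = -inf."""

    start_offset_days: int | None
    end_offset_days: int

    def __post_init__(self) -> None:
        if self.start_offset_days is not None and self.start_offset_days > self.end_offset_days:
            raise ConfigError(
                f"inverted window [{self.start_offset_days}, {self.end_offset_days}]"
            )

    def contains(self, days_from_index: int) -> bool:
        if self.start_offset_days is not None and days_from_index < self.start_offset_days:
            return False
        return days_from_index <= self.end_offset_days


@dataclass
class KeeperCategorySpec:
    category_name: str
    concept_set: ConceptSet
    domains: set[str]
    window: TimeWindow

    def __post_init__(self) -> None:
        if self.category_name not in CATEGORY_NAMES:
            raise ConfigError(f"unknown category {self.category_name!r}")
        unknown = set(self.domains) - set(DOMAINS)
        if unknown:
            raise ConfigError(f"unknown domains {sorted(unknown)} in {self.category_name}")
        if not self.concept_set.items:
            raise ConfigError(f"empty concept set in {self.category_name}")


@dataclass
class KeeperConfig:
    disease_name: str
    conceptual_definition: str
    categories: list[KeeperCategorySpec]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ConfigError("config needs >= 1 category")
        names = [c.category_name for c in self.categories]
        if len(names) != len(set(names)):
            raise ConfigError(f"duplicate category names: {names}")

    def category_order(self) -> list[str]:
        return [c.category_name for c in self.categories]


@dataclass(frozen=True)
class ProfileItem:
    category_name: str
    concept_name: str
    event_date: pd.Timestamp
    days_from_index: int
    value_text: str | None = None
    count: int = 1


@dataclass
class PatientProfile:
    person_id: int
    index_date: pd.Timestamp
    age_at_index: int
    gender_text: str
    items: list[ProfileItem] = field(default_factory=list)

    def items_by_category(self) -> dict[str, list[ProfileItem]]:
        out: dict[str, list[ProfileItem]] = {}
        for it in self.items:
            out.setdefault(it.category_name, []).append(it)
        return out


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def _config_to_dict(config: KeeperConfig) -> dict:
    return {
        "disease_name": config.disease_name,
        "conceptual_definition": config.conceptual_definition,
        "categories": [
            {
                "category": c.category_name,
                "domains": sorted(c.domains),
                "window": {
                    "start": c.window.start_offset_days,
                    "end": c.window.end_offset_days,
                },
                "concept_set": {
                    "name": c.concept_set.name,
                    "items": [
                        {
                            "concept_id": it.concept_id,
                            "include_descendants": it.include_descendants,
                            "is_excluded": it.is_excluded,
                        }
                        for it in c.concept_set.items
                    ],
                },
            }
            for c in config.categories
        ],
    }


def _config_from_dict(d: dict) -> KeeperConfig:
    cats = []
    for c in d["categories"]:
        cs = c["concept_set"]
        cats.append(
            KeeperCategorySpec(
                category_name=c["category"],
                concept_set=ConceptSet(
                    name=cs.get("name", c["category"]),
                    items=[
                        ConceptSetItem(
                            concept_id=int(it["concept_id"]),
                            include_descendants=bool(it.get("include_descendants", False)),
                            is_excluded=bool(it.get("is_excluded", False)),
                        )
                        for it in cs["items"]
                    ],
                ),
                domains=set(c["domains"]),
                window=TimeWindow(c["window"].get("start"), c["window"]["end"]),
            )
        )
    return KeeperConfig(
        disease_name=d["disease_name"],
        conceptual_definition=d.get("conceptual_definition", ""),
        categories=cats,
    )


def load_keeper_config(path: str | Path) -> KeeperConfig:
    """Load and validate a category/window configuration (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return _config_from_dict(d)


def save_keeper_config(config: KeeperConfig, path: str | Path) -> None:
    path = Path(path)
    d = _config_to_dict(config)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def default_config_for_template(template) -> KeeperConfig:
    """Extraction config aligned with a synthetic disease template.

    Windows follow the usual clinical-reasoning pattern: symptoms within
    30 days before index, disease history and comorbidities strictly
    prior, laboratory work and differential diagnoses around index,
    treatments after index.
    """
    def cs(name: str, concepts, include_descendants: bool = False) -> ConceptSet:
        return ConceptSet(
            name=name,
            items=[
                ConceptSetItem(c.concept_id, include_descendants=include_descendants)
                for c in concepts
            ],
        )

    diag = [template.diagnosis_root]
    return KeeperConfig(
        disease_name=template.disease_name,
        conceptual_definition=template.conceptual_definition,
        categories=[
            KeeperCategorySpec(
                "clinical_presentation",
                cs("symptoms", template.symptom_concepts),
                {"condition", "observation"},
                TimeWindow(-30, 0),
            ),
            KeeperCategorySpec(
                "disease_history",
                cs("prior diagnoses", diag, include_descendants=True),
                {"condition"},
                TimeWindow(None, -1),
            ),
            KeeperCategorySpec(
                "preliminary_diagnosis",
                cs("index diagnoses", diag, include_descendants=True),
                {"condition"},
                TimeWindow(0, 30),
            ),
            KeeperCategorySpec(
                "diagnostic_procedures",
                cs("laboratory tests", template.lab_concepts),
                {"measurement", "procedure"},
                TimeWindow(-30, 30),
            ),
            KeeperCategorySpec(
                "differential_diagnoses",
                cs("differential diagnoses", template.differential_concepts),
                {"condition"},
                TimeWindow(-90, 30),
            ),
            KeeperCategorySpec(
                "treatment",
                cs("treatments", template.treatment_concepts),
                {"drug"},
                TimeWindow(0, 90),
            ),
            KeeperCategorySpec(
                "comorbidities",
                cs("comorbidities", template.comorbidity_concepts),
                {"condition"},
                TimeWindow(None, -1),
            ),
        ],
    )


def concept_sets_for_template(template) -> list[ConceptSet]:
    """Concept sets whose union defines the high-sensitivity cohort."""
    return [
        ConceptSet(
            "diagnoses",
            [ConceptSetItem(template.diagnosis_root.concept_id, include_descendants=True)],
        ),
        ConceptSet("symptoms", [ConceptSetItem(c.concept_id) for c in template.symptom_concepts]),
        ConceptSet(
            "treatments", [ConceptSetItem(c.concept_id) for c in template.treatment_concepts]
        ),
        ConceptSet(
            "laboratory tests", [ConceptSetItem(c.concept_id) for c in template.lab_concepts]
        ),
    ]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _format_value(value, unit) -> str | None:
    if pd.isna(value):
        return None
    v = float(value)
    text = f"{v:g}"
    return f"{text} {unit}" if unit else text


def extract_profiles(
    store: CdmStore, cohort: pd.DataFrame, config: KeeperConfig
) -> list[PatientProfile]:
    """Extract one profile per cohort entry, preserving cohort order.

    For each category, a person's items are exactly their events whose
    concept is in the expanded category set, whose domain is among the
    category's domains, and whose date lies inside the category window
    (inclusive bounds; unbounded past when start is None). Measurements
    without a recorded value are emitted as "ordered, result not
    recorded".
    """
    if cohort.empty:
        return []
    cohort = cohort[["person_id", "index_date"]].copy()
    cohort["person_id"] = cohort["person_id"].astype("int64")
    cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    known = set(store.persons["person_id"])
    missing = sorted(set(cohort["person_id"]) - known)
    if missing:
        raise KeyError(f"cohort persons not in store: {missing[:10]}")

    names = store.concepts.set_index("concept_id")["concept_name"]
    ev = store.events

    per_person: dict[int, list[ProfileItem]] = {int(p): [] for p in cohort["person_id"]}
    for spec in config.categories:
        ids = expand_concept_set(spec.concept_set, store.ancestry)
        sub = ev[ev["concept_id"].isin(ids) & ev["domain"].isin(spec.domains)]
        if sub.empty:
            continue
        merged = cohort.merge(sub, on="person_id", how="inner")
        if merged.empty:
            continue
        days = (merged["event_date"] - merged["index_date"]).dt.days
        mask = days <= spec.window.end_offset_days
        if spec.window.start_offset_days is not None:
            mask &= days >= spec.window.start_offset_days
        merged = merged[mask]
        if merged.empty:
            continue
        merged = merged.assign(days_from_index=days[mask])
        is_measurement = merged["domain"].isin(("measurement", "observation"))
        grouped = (
            merged.groupby(
                ["person_id", "concept_id", "event_date"], as_index=False, dropna=False
            )
            .agg(
                days_from_index=("days_from_index", "first"),
                value_as_number=("value_as_number", "first"),
                unit=("unit", "first"),
                domain=("domain", "first"),
                count=("concept_id", "size"),
            )
        )
        for row in grouped.itertuples(index=False):
            value_text = None
            if row.domain in ("measurement", "observation"):
                value_text = _format_value(row.value_as_number, row.unit)
                if value_text is None:
                    value_text = "ordered, result not recorded"
            per_person[int(row.person_id)].append(
                ProfileItem(
                    category_name=spec.category_name,
                    concept_name=str(names.loc[row.concept_id]),
                    event_date=pd.Timestamp(row.event_date),
                    days_from_index=int(row.days_from_index),
                    value_text=value_text,
                    count=int(row.count),
                )
            )
        del is_measurement

    order = {name: i for i, name in enumerate(config.category_order())}
    yob = store.persons.set_index("person_id")["year_of_birth"]
    gender = store.persons.set_index("person_id")["gender_text"]
    profiles = []
    for row in cohort.itertuples(index=False):
        pid = int(row.person_id)
        items = sorted(
            per_person[pid],
            key=lambda it: (order[it.category_name], it.event_date, it.concept_name),
        )
        profiles.append(
            PatientProfile(
                person_id=pid,
                index_date=pd.Timestamp(row.index_date),
                age_at_index=int(row.index_date.year - yob.loc[pid]),
                gender_text=str(gender.loc[pid]),
                items=items,
            )
        )
    return profiles


def extract_profile(store: CdmStore, entry, config: KeeperConfig) -> PatientProfile:
    """Extract a single profile for one (person_id, index_date) entry."""
    cohort = pd.DataFrame(
        {"person_id": [entry.person_id], "index_date": [entry.index_date]}
    )
    return extract_profiles(store, cohort, config)[0]


# ---------------------------------------------------------------------------
# Profile I/O
# ---------------------------------------------------------------------------

def profile_to_dict(profile: PatientProfile) -> dict:
    return {
        "person_id": profile.person_id,
        "index_date": profile.index_date.strftime("%Y-%m-%d"),
        "age_at_index": profile.age_at_index,
        "gender_text": profile.gender_text,
        "items": [
            {
                "category": it.category_name,
                "concept_name": it.concept_name,
                "event_date": it.event_date.strftime("%Y-%m-%d"),
                "days_from_index": it.days_from_index,
                "value_text": it.value_text,
                "count": it.count,
            }
            for it in profile.items
        ],
    }


def profile_from_dict(d: dict) -> PatientProfile:
    return PatientProfile(
        person_id=int(d["person_id"]),
        index_date=pd.Timestamp(d["index_date"]),
        age_at_index=int(d["age_at_index"]),
        gender_text=d["gender_text"],
        items=[
            ProfileItem(
                category_name=it["category"],
                concept_name=it["concept_name"],
                event_date=pd.Timestamp(it["event_date"]),
                days_from_index=int(it["days_from_index"]),
                value_text=it.get("value_text"),
                count=int(it.get("count", 1)),
            )
            for it in d["items"]
        ],
    )


def profiles_to_jsonl(profiles: list[PatientProfile], path) -> None:
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(json.dumps(profile_to_dict(p), sort_keys=True) + "\n")


def profiles_from_jsonl(path) -> list[PatientProfile]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(profile_from_dict(json.loads(line)))
    return out
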