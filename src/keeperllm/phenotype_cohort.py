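"""Concept sets, descendant expansion, and cohort construction.

A phenotype algorithm here is the first-occurrence skeleton: a concept
set (with include-descendants / exclude flags in the OHDSI concept-set
expression shape), a domain, and the rule "index date = date of the
person's earliest qualifying event". High-sensitivity cohorts take the
union of several concept sets across all domains and draw a seeded
random sample of eligible persons, indexing each at their earliest
union event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .omop_store import DOMAINS, CdmStore

logger = logging.getLogger(__name__)


class UnknownConceptError(Exception):
    """A concept-set item references an id absent from the vocabulary."""


@dataclass(frozen=True)
class ConceptSetItem:
    concept_id: int
    include_descendants: bool = False
    is_excluded: bool = False


@dataclass
class ConceptSet:
    name: str
    items: list[ConceptSetItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"concept set {self.name!r} has no items")

    # -- OHDSI concept-set expression JSON -------------------------------
    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "expression": {
                "items": [
                    {
                        "concept": {"CONCEPT_ID": it.concept_id},
                        "includeDescendants": it.include_descendants,
                        "isExcluded": it.is_excluded,
                    }
                    for it in self.items
                ]
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ConceptSet":
        items_raw = d.get("expression", d).get("items", [])
        items = []
        for it in items_raw:
            cid = it["concept"]["CONCEPT_ID"] if "concept" in it else it["concept_id"]
            items.append(
                ConceptSetItem(
                    concept_id=int(cid),
                    include_descendants=bool(
                        it.get("includeDescendants", it.get("include_descendants", False))
                    ),
                    is_excluded=bool(it.get("isExcluded", it.get("is_excluded", False))),
                )
            )
        return cls(name=d.get("name", "unnamed"), items=items)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ConceptSet":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


class CohortEntry(NamedTuple):
    person_id: int
    index_date: pd.Timestamp


def expand_concept_set(cs: ConceptSet, ancestry: pd.DataFrame) -> frozenset[int]:
    """Resolve a concept set to the set of concept ids it denotes.

    Included ids are the union over items of the item itself plus, when
    flagged, all its descendants per the (reflexively closed) ancestry
    table; excluded items' expansions are then subtracted.
    """
    known = set(ancestry["descendant_concept_id"]) | set(ancestry["ancestor_concept_id"])
    unknown = sorted({it.concept_id for it in cs.items} - known)
    if unknown:
        raise UnknownConceptError(
            f"concept set {cs.name!r} references unknown concept ids: {unknown}"
        )

    def one(item: ConceptSetItem) -> set[int]:
        if item.include_descendants:
            mask = ancestry["ancestor_concept_id"] == item.concept_id
            return set(ancestry.loc[mask, "descendant_concept_id"]) | {item.concept_id}
        return {item.concept_id}

    included: set[int] = set()
    excluded: set[int] = set()
    for it in cs.items:
        (excluded if it.is_excluded else included).update(one(it))
    return frozenset(included - excluded)


def first_occurrence_cohort(
    store: CdmStore, cs: ConceptSet, domain: str | None = "condition"
) -> pd.DataFrame:
    """One row per person with >= 1 qualifying event; index = earliest date.

    Same-day ties are broken by smallest concept_id (affects only which
    event is deemed the qualifying one, not the index date). Returns a
    DataFrame with columns person_id, index_date, sorted by person_id.
    """
    ids = expand_concept_set(cs, store.ancestry)
    ev = store.events
    mask = ev["concept_id"].isin(ids)
    if domain is not None:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        mask &= ev["domain"] == domain
    sub = ev.loc[mask, ["person_id", "event_date", "concept_id"]]
    if sub.empty:
        return pd.DataFrame(columns=["person_id", "index_date"])
    sub = sub.sort_values(["person_id", "event_date", "concept_id"], kind="stable")
    first = sub.groupby("person_id", as_index=False).first()
    out = first.rename(columns={"event_date": "index_date"})[["person_id", "index_date"]]
    return out.sort_values("person_id", kind="stable").reset_index(drop=True)


def high_sensitivity_cohort(
    store: CdmStore,
    concept_sets: list[ConceptSet],
    sample_size: int,
    seed: int,
) -> pd.DataFrame:
    """Seeded sample of persons with any event in the union of concept sets.

    A deliberately over-inclusive cohort (any related diagnosis, symptom,
    treatment, complication or laboratory code, in any domain) meant to
    contain nearly all true cases. Index date is the person's earliest
    union event. If fewer persons are eligible than ``sample_size``, all
    eligible are returned with a logged warning.
    """
    if not concept_sets:
        raise ValueError("at least one concept set required")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    union: set[int] = set()
    for cs in concept_sets:
        union |= expand_concept_set(cs, store.ancestry)
    ev = store.events
    sub = ev.loc[ev["concept_id"].isin(union), ["person_id", "event_date", "concept_id"]]
    if sub.empty:
        raise ValueError("no persons eligible for the high-sensitivity cohort")
    sub = sub.sort_values(["person_id", "event_date", "concept_id"], kind="stable")
    first = sub.groupby("person_id", as_index=False).first()
    eligible = first.rename(columns={"event_date": "index_date"})[["person_id", "index_date"]]

    if sample_size >= len(eligible):
        if sample_size > len(eligible):
            logger.warning(
                "sample_size %d exceeds %d eligible persons; returning all",
                sample_size,
                len(eligible),
            )
        picked = eligible
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(eligible), size=sample_size, replace=False)
        picked = eligible.iloc[np.sort(idx)]
    return picked.sort_values("person_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def cohort_to_csv(cohort: pd.DataFrame, path, cohort_name: str = "cohort") -> None:
    out = cohort.copy()
    out.insert(0, "cohort_name", cohort_name)
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["index_date"] = pd.to_datetime(df["index_date"])
    return df[["person_id", "index_date"]]


def cohort_entries(cohort: pd.DataFrame) -> list[CohortEntry]:
    return [
        CohortEntry(int(r.person_id), pd.Timestamp(r.index_date))
        for r in cohort.itertuples(index=False)
    ]
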