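"""Minimal OMOP CDM v5.x table store.

Reads, validates and queries the subset of OMOP Common Data Model tables
needed for profile extraction: ``person``, the five clinical event tables
plus ``visit_occurrence``, and the vocabulary tables ``concept`` and
``concept_ancestor``. Events from all domains are unified into a single
long table with columns ``person_id, concept_id, event_date, domain,
value_as_number, unit`` so downstream code never branches on OMOP table
names.

Dates are day-resolution ISO-8601; ``*_datetime`` columns are ignored.
Reflexive ancestry rows (every concept its own descendant) are added at
load time if absent, so descendant expansion never special-cases self.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Supported clinical domains.
DOMAINS = ("condition", "drug", "measurement", "procedure", "observation", "visit")

#: domain -> (OMOP table name, concept-id column, date column)
DOMAIN_TABLES: dict[str, tuple[str, str, str]] = {
    "condition": ("condition_occurrence", "condition_concept_id", "condition_start_date"),
    "drug": ("drug_exposure", "drug_concept_id", "drug_exposure_start_date"),
    "measurement": ("measurement", "measurement_concept_id", "measurement_date"),
    "procedure": ("procedure_occurrence", "procedure_concept_id", "procedure_date"),
    "observation": ("observation", "observation_concept_id", "observation_date"),
    "visit": ("visit_occurrence", "visit_concept_id", "visit_start_date"),
}

#: OMOP domain_id spelling <-> internal domain enum.
_DOMAIN_ID_TO_DOMAIN = {
    "Condition": "condition",
    "Drug": "drug",
    "Measurement": "measurement",
    "Procedure": "procedure",
    "Observation": "observation",
    "Visit": "visit",
}
_DOMAIN_TO_DOMAIN_ID = {v: k for k, v in _DOMAIN_ID_TO_DOMAIN.items()}

EVENT_COLUMNS = ["person_id", "concept_id", "event_date", "domain", "value_as_number", "unit"]


class CdmError(Exception):
    """Base error for CDM reading/validation failures."""


class MissingTableError(CdmError):
    """A required OMOP table file is absent."""


class ReferentialIntegrityError(CdmError):
    """Events or ancestry rows reference ids absent from person/concept."""


class UnknownPersonError(CdmError):
    """A queried person_id does not exist in the person table."""


@dataclass
class CdmStore:
    """In-memory bundle of OMOP-shaped event and vocabulary tables.

    Attributes
    ----------
    persons : DataFrame with columns person_id, year_of_birth, gender_text.
    events : DataFrame with :data:`EVENT_COLUMNS`; one row per coded event.
    concepts : DataFrame with concept_id, concept_name, domain.
    ancestry : DataFrame with ancestor_concept_id, descendant_concept_id,
        reflexively closed.
    """

    persons: pd.DataFrame
    events: pd.DataFrame
    concepts: pd.DataFrame
    ancestry: pd.DataFrame
    extra_columns: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.persons = _canonical_persons(self.persons)
        self.events = _canonical_events(self.events)
        self.concepts = _canonical_concepts(self.concepts)
        self.ancestry = ensure_reflexive(self.ancestry, self.concepts["concept_id"])
        validate_store(self)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def concept_name(self, concept_id: int) -> str:
        row = self.concepts.loc[self.concepts["concept_id"] == concept_id, "concept_name"]
        if row.empty:
            raise KeyError(f"unknown concept_id {concept_id}")
        return str(row.iloc[0])

    def events_by_domain(self, domain: str) -> pd.DataFrame:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return self.events[self.events["domain"] == domain]

    def equals(self, other: "CdmStore") -> bool:
        """Field-for-field equality on the canonical representation."""
        return (
            self.persons.equals(other.persons)
            and self.events.equals(other.events)
            and self.concepts.equals(other.concepts)
            and self.ancestry.equals(other.ancestry)
        )


def _canonical_persons(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["person_id"] = df["person_id"].astype(np.int64)
    df["year_of_birth"] = df["year_of_birth"].astype(np.int64)
    if "gender_text" not in df.columns:
        df["gender_text"] = "unknown"
    df["gender_text"] = df["gender_text"].astype(str)
    df = df[["person_id", "year_of_birth", "gender_text"]]
    return df.sort_values("person_id", kind="stable").reset_index(drop=True)


def _canonical_events(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    df = df.copy()
    df["person_id"] = df["person_id"].astype(np.int64)
    df["concept_id"] = df["concept_id"].astype(np.int64)
    df["event_date"] = pd.to_datetime(df["event_date"]).dt.normalize()
    df["domain"] = df["domain"].astype(str)
    if "value_as_number" not in df.columns:
        df["value_as_number"] = np.nan
    df["value_as_number"] = pd.to_numeric(df["value_as_number"], errors="coerce")
    if "unit" not in df.columns:
        df["unit"] = None
    df["unit"] = df["unit"].where(df["unit"].notna() & (df["unit"] != ""), None)
    df = df[EVENT_COLUMNS]
    df = df.sort_values(
        ["person_id", "event_date", "domain", "concept_id"], kind="stable"
    ).reset_index(drop=True)
    return df


def _canonical_concepts(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["concept_id"] = df["concept_id"].astype(np.int64)
    df["concept_name"] = df["concept_name"].astype(str)
    df["domain"] = df["domain"].astype(str)
    bad = sorted(set(df["domain"]) - set(DOMAINS))
    if bad:
        raise CdmError(f"unsupported concept domains: {bad}")
    if df["concept_id"].duplicated().any():
        dupes = sorted(df.loc[df["concept_id"].duplicated(), "concept_id"])
        raise CdmError(f"duplicate concept ids: {dupes}")
    df = df[["concept_id", "concept_name", "domain"]]
    return df.sort_values("concept_id", kind="stable").reset_index(drop=True)


def ensure_reflexive(ancestry: pd.DataFrame, concept_ids: pd.Series) -> pd.DataFrame:
    """Add missing (c, c) rows so every concept is its own descendant."""
    if ancestry is None or len(ancestry) == 0:
        ancestry = pd.DataFrame(columns=["ancestor_concept_id", "descendant_concept_id"])
    ancestry = ancestry[["ancestor_concept_id", "descendant_concept_id"]].copy()
    reflexive = pd.DataFrame(
        {
            "ancestor_concept_id": concept_ids.to_numpy(),
            "descendant_concept_id": concept_ids.to_numpy(),
        }
    )
    out = pd.concat([ancestry, reflexive], ignore_index=True)
    out = out.astype(np.int64).drop_duplicates()
    out = out.sort_values(
        ["ancestor_concept_id", "descendant_concept_id"], kind="stable"
    ).reset_index(drop=True)
    return out


def validate_store(store: CdmStore) -> None:
    """Check referential integrity; raise with offending ids listed."""
    known_persons = set(store.persons["person_id"])
    known_concepts = set(store.concepts["concept_id"])

    orphan_persons = sorted(set(store.events["person_id"]) - known_persons)
    if orphan_persons:
        raise ReferentialIntegrityError(
            f"events reference unknown person_ids: {orphan_persons[:20]}"
        )
    orphan_concepts = sorted(set(store.events["concept_id"]) - known_concepts)
    if orphan_concepts:
        raise ReferentialIntegrityError(
            f"events reference unknown concept_ids: {orphan_concepts[:20]}"
        )
    # event domain must match the concept's domain
    merged = store.events.merge(
        store.concepts[["concept_id", "domain"]],
        on="concept_id",
        suffixes=("", "_vocab"),
    )
    mismatch = merged[merged["domain"] != merged["domain_vocab"]]
    if not mismatch.empty:
        pairs = sorted(set(zip(mismatch["concept_id"], mismatch["domain"])))
        raise ReferentialIntegrityError(f"event domain mismatches vocabulary: {pairs[:20]}")
    anc_ids = set(store.ancestry["ancestor_concept_id"]) | set(
        store.ancestry["descendant_concept_id"]
    )
    orphan_anc = sorted(anc_ids - known_concepts)
    if orphan_anc:
        raise ReferentialIntegrityError(f"ancestry references unknown concept_ids: {orphan_anc[:20]}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_table(path: Path, fmt: str) -> pd.DataFrame:
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "columnar":
        return pd.read_parquet(path)
    raise ValueError(f"unknown format {fmt!r}")


def _table_path(directory: Path, table: str, fmt: str) -> Path:
    ext = "csv" if fmt == "csv" else "parquet"
    return directory / f"{table}.{ext}"


def read_cdm(directory: str | Path, fmt: str = "csv", lenient: bool = False) -> CdmStore:
    """Read a directory of OMOP-named table files into a validated store.

    ``person`` and ``concept`` are required; ``concept_ancestor`` and the
    per-domain event tables are optional. Rows with unparseable dates or
    dangling concept/person ids are fatal by default; with ``lenient=True``
    they are dropped and reported through the module logger.
    """
    directory = Path(directory)
    for required in ("person", "concept"):
        if not _table_path(directory, required, fmt).exists():
            raise MissingTableError(f"required table file missing: {required}")

    person_raw = _read_table(_table_path(directory, "person", fmt), fmt)
    if "gender_text" not in person_raw.columns and "gender_concept_id" in person_raw.columns:
        person_raw["gender_text"] = person_raw["gender_concept_id"].map(
            {8507: "male", 8532: "female"}
        ).fillna("unknown")

    concept_raw = _read_table(_table_path(directory, "concept", fmt), fmt)
    if "domain" not in concept_raw.columns and "domain_id" in concept_raw.columns:
        concept_raw["domain"] = concept_raw["domain_id"].map(_DOMAIN_ID_TO_DOMAIN)

    anc_path = _table_path(directory, "concept_ancestor", fmt)
    ancestry = (
        _read_table(anc_path, fmt)
        if anc_path.exists()
        else pd.DataFrame(columns=["ancestor_concept_id", "descendant_concept_id"])
    )

    frames = []
    for domain, (table, concept_col, date_col) in DOMAIN_TABLES.items():
        path = _table_path(directory, table, fmt)
        if not path.exists():
            continue
        raw = _read_table(path, fmt)
        frame = pd.DataFrame(
            {
                "person_id": raw["person_id"],
                "concept_id": raw[concept_col],
                "event_date": raw[date_col],
                "domain": domain,
            }
        )
        frame["value_as_number"] = (
            pd.to_numeric(raw["value_as_number"], errors="coerce")
            if "value_as_number" in raw.columns
            else np.nan
        )
        frame["unit"] = raw["unit"] if "unit" in raw.columns else None

        parsed = pd.to_datetime(frame["event_date"], format="%Y-%m-%d", errors="coerce")
        bad = frame[parsed.isna()]
        if not bad.empty:
            msg = f"{table}: {len(bad)} rows with unparseable dates (e.g. {bad['event_date'].iloc[0]!r})"
            if lenient:
                logger.warning("dropping %s", msg)
                frame = frame[parsed.notna()]
                parsed = parsed[parsed.notna()]
            else:
                raise CdmError(msg)
        frame["event_date"] = parsed
        logger.info("%s: %d rows", table, len(frame))
        frames.append(frame)

    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )

    if lenient and len(events):
        known_c = set(concept_raw["concept_id"].astype(np.int64))
        known_p = set(person_raw["person_id"].astype(np.int64))
        mask = events["concept_id"].astype(np.int64).isin(known_c) & events[
            "person_id"
        ].astype(np.int64).isin(known_p)
        if (~mask).any():
            logger.warning("dropping %d events with dangling ids", int((~mask).sum()))
            events = events[mask]

    return CdmStore(persons=person_raw, events=events, concepts=concept_raw, ancestry=ancestry)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_cdm(store: CdmStore, directory: str | Path, fmt: str = "csv") -> dict[str, int]:
    """Write a store to OMOP-named table files.

    Column and row order are stable (rows sorted by person_id, date,
    concept_id), so identical stores produce byte-identical files.
    Returns a manifest mapping file name to row count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = _table_path(directory, name, fmt)
        if fmt == "csv":
            df.to_csv(path, index=False, lineterminator="\n")
        else:
            df.to_parquet(path, index=False)
        manifest[path.name] = len(df)

    _write("person", store.persons)

    concept_out = store.concepts.copy()
    concept_out["domain_id"] = concept_out["domain"].map(_DOMAIN_TO_DOMAIN_ID)
    _write("concept", concept_out[["concept_id", "concept_name", "domain", "domain_id"]])
    _write("concept_ancestor", store.ancestry)

    for domain, (table, concept_col, date_col) in DOMAIN_TABLES.items():
        sub = store.events_by_domain(domain)
        out = pd.DataFrame(
            {
                "person_id": sub["person_id"],
                concept_col: sub["concept_id"],
                date_col: sub["event_date"].dt.strftime("%Y-%m-%d"),
            }
        )
        if domain in ("measurement", "observation"):
            out["value_as_number"] = sub["value_as_number"]
            out["unit"] = sub["unit"]
        out = out.sort_values(
            ["person_id", date_col, concept_col], kind="stable"
        ).reset_index(drop=True)
        _write(table, out)
    return manifest


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def events_for_person(
    store: CdmStore, person_id: int, domains: set[str] | None = None
) -> pd.DataFrame:
    """All events for one person, sorted by (event_date, domain, concept_id).

    Raises :class:`UnknownPersonError` for ids absent from the person table,
    which is distinct from a known person with zero events (empty frame).
    """
    if person_id not in set(store.persons["person_id"]):
        raise UnknownPersonError(f"person_id {person_id} not in store")
    sub = store.events[store.events["person_id"] == person_id]
    if domains is not None:
        unknown = set(domains) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains: {sorted(unknown)}")
        sub = sub[sub["domain"].isin(domains)]
    return sub.sort_values(
        ["event_date", "domain", "concept_id"], kind="stable"
    ).reset_index(drop=True)
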