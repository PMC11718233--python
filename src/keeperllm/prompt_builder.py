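"""Profile serialization and staged system/main prompt construction.

The system prompt is built cumulatively over six variants, mirroring an
iterative chain-of-thought prompt-engineering ladder:

* ``V0_yes_no`` — bare binary instruction (always demanding a final
  ``Summary`` section with an explicit yes/no);
* ``V1_discuss_evidence`` — adds Part 1: discuss evidence for and
  against the disease;
* ``V2_write_narrative`` — adds Part 2: generate a clinical narrative;
* ``V3_diagnosis_insufficient`` — adds Part 3: a diagnosis alone is
  insufficient evidence;
* ``V4_uncertainty`` — adds Part 4: guidance on handling uncertainty;
* ``V5_few_shot`` — same system text as V4; two worked examples (one
  positive, one negative, both synthetic) are delivered as few-shot
  messages instead of system text.

Profiles are rendered with relative days rather than calendar dates so
prompt bytes are stable across synthetic regenerations; calendar-date
rendering is available by flag. Wording lives in plain-text template
files under ``templates/``; where the published figure text was not
fully legible the templates are reconstructed with neutral phrasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import pandas as pd

from .keeper_extract import CATEGORY_NAMES, PatientProfile, ProfileItem


class PromptVariant(Enum):
    V0_yes_no = 0
    V1_discuss_evidence = 1
    V2_write_narrative = 2
    V3_diagnosis_insufficient = 3
    V4_uncertainty = 4
    V5_few_shot = 5

    @property
    def level(self) -> int:
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "PromptVariant":
        for v in cls:
            if v.name == s or v.name.lower() == s.lower() or s == str(v.value):
                return v
        raise ValueError(f"unknown prompt variant {s!r}")


#: Display groups combine extraction categories into the sections shown
#: to the reviewer; e.g. disease history, symptoms, comorbidities and
#: risk factors all render under "Diagnoses recorded prior to the visit".
DEFAULT_GROUPING: dict[str, str] = {
    "clinical_presentation": "Diagnoses recorded prior to the visit",
    "disease_history": "Diagnoses recorded prior to the visit",
    "comorbidities": "Diagnoses recorded prior to the visit",
    "risk_factors": "Diagnoses recorded prior to the visit",
    "preliminary_diagnosis": "Diagnosis recorded at the visit",
    "differential_diagnoses": "Differential diagnoses",
    "diagnostic_procedures": "Laboratory tests and measurements",
    "treatment": "Treatments",
    "follow_up_care": "Diagnoses and care recorded after the visit",
    "complications": "Diagnoses and care recorded after the visit",
}

DISPLAY_GROUP_ORDER = (
    "Diagnoses recorded prior to the visit",
    "Diagnosis recorded at the visit",
    "Differential diagnoses",
    "Laboratory tests and measurements",
    "Treatments",
    "Diagnoses and care recorded after the visit",
)

EMPTY_GROUP_LINE = "- none recorded"


from functools import lru_cache


@lru_cache(maxsize=None)
def _template(name: str) -> str:
    return (resources.files("keeperllm") / "templates" / name).read_text().strip()


_PART_FILES = (
    "part1_evidence.txt",
    "part2_narrative.txt",
    "part3_diagnosis_insufficient.txt",
    "part4_uncertainty.txt",
)


@dataclass(frozen=True)
class FewShotExample:
    main_prompt: str
    ideal_response: str


@dataclass
class PromptBundle:
    system_prompt: str
    main_prompt: str
    disease_name: str
    person_id: int
    variant: PromptVariant
    few_shot_messages: list[FewShotExample] = field(default_factory=list)

    def messages(self) -> list[dict]:
        msgs = [{"role": "system", "content": self.system_prompt}]
        for ex in self.few_shot_messages:
            msgs.append({"role": "user", "content": ex.main_prompt})
            msgs.append({"role": "assistant", "content": ex.ideal_response})
        msgs.append({"role": "user", "content": self.main_prompt})
        return msgs


# ---------------------------------------------------------------------------
# Profile serialization
# ---------------------------------------------------------------------------

def _render_item(item: ProfileItem, use_calendar_dates: bool) -> str:
    when = (
        item.event_date.strftime("%Y-%m-%d")
        if use_calendar_dates
        else f"day {item.days_from_index:d}"
    )
    parts = [when]
    if item.value_text is not None:
        parts.append(item.value_text)
    line = f"- {item.concept_name} ({', '.join(parts)})"
    if item.count > 1:
        line += f" (x{item.count})"
    return line


def serialize_profile(
    profile: PatientProfile,
    grouping: dict[str, str] | None = None,
    use_calendar_dates: bool = False,
) -> str:
    """Render a profile as deterministic display-grouped text.

    Every display group appears (empty ones as an explicit "none
    recorded" line); a profile category not covered by the grouping is
    fatal. Items keep their extraction order (category, date, name)
    within each group.
    """
    grouping = DEFAULT_GROUPING if grouping is None else grouping
    uncovered = {it.category_name for it in profile.items} - set(grouping)
    if uncovered:
        raise KeyError(f"categories not covered by grouping: {sorted(uncovered)}")

    group_order = [g for g in DISPLAY_GROUP_ORDER if g in grouping.values()]
    seen = set(group_order)
    for cat in CATEGORY_NAMES:
        g = grouping.get(cat)
        if g is not None and g not in seen:
            group_order.append(g)
            seen.add(g)

    by_group: dict[str, list[str]] = {g: [] for g in group_order}
    for item in profile.items:
        by_group[grouping[item.category_name]].append(
            _render_item(item, use_calendar_dates)
        )

    lines = [f"Patient: {profile.age_at_index}-year-old {profile.gender_text}", ""]
    for g in group_order:
        lines.append(f"## {g}")
        lines.extend(by_group[g] or [EMPTY_GROUP_LINE])
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"


# ---------------------------------------------------------------------------
# Prompt construction
# ---------------------------------------------------------------------------

def build_system_prompt(variant: PromptVariant, disease_name: str) -> str:
    """Cumulative system prompt: V0 base, then Parts 1..4; V5 equals V4."""
    parts = [_template("system_base.txt").format(disease_name=disease_name)]
    for k in range(min(variant.level, 4)):
        parts.append(_template(_PART_FILES[k]).format(disease_name=disease_name))
    return "\n\n".join(parts)


def build_main_prompt(
    profile_text: str, disease_name: str, conceptual_definition: str = ""
) -> str:
    definition = conceptual_definition or f"the clinical condition {disease_name}"
    return _template("main_prompt.txt").format(
        disease_name=disease_name,
        conceptual_definition=definition,
        profile_text=profile_text.rstrip(),
    )


def default_few_shot_examples(disease_name: str) -> list[FewShotExample]:
    """Two synthetic worked examples: one clear case, one clear non-case.

    Entirely fabricated profiles (no real or simulated patient behind
    them); shipped as the default example pair for the few-shot variant.
    """
    positive_profile = PatientProfile(
        person_id=0,
        index_date=pd.Timestamp("2017-06-01"),
        age_at_index=58,
        gender_text="female",
        items=[
            ProfileItem("clinical_presentation", "Compatible symptom", pd.Timestamp("2017-05-20"), -12),
            ProfileItem("preliminary_diagnosis", f"{disease_name} (diagnosis code)", pd.Timestamp("2017-06-01"), 0),
            ProfileItem("diagnostic_procedures", "Confirmatory laboratory test", pd.Timestamp("2017-06-01"), 0, value_text="positive result"),
            ProfileItem("treatment", "Disease-specific treatment", pd.Timestamp("2017-06-15"), 14),
        ],
    )
    negative_profile = PatientProfile(
        person_id=0,
        index_date=pd.Timestamp("2018-02-10"),
        age_at_index=45,
        gender_text="male",
        items=[
            ProfileItem("preliminary_diagnosis", f"{disease_name} (diagnosis code)", pd.Timestamp("2018-02-10"), 0),
        ],
    )
    pos_response = (
        f"Evidence for: compatible symptoms preceding the index date, a confirmatory "
        f"laboratory result, and initiation of a disease-specific treatment shortly "
        f"after the diagnosis code.\n"
        f"Evidence against: none of note.\n"
        f"Clinical narrative: the patient presented with compatible symptoms, was "
        f"diagnosed at the index visit, testing confirmed the diagnosis, and "
        f"treatment was started.\n\n"
        f"Summary: Yes, the patient had {disease_name} on the index date."
    )
    neg_response = (
        f"Evidence for: a single diagnosis code on the index date.\n"
        f"Evidence against: there are neither compatible symptoms, nor laboratory "
        f"results, nor any disease-specific treatment; an isolated code without "
        f"corroboration is insufficient.\n"
        f"Clinical narrative: an isolated diagnosis code was recorded, most "
        f"consistent with a rule-out evaluation or a coding error.\n\n"
        f"Summary: No, the patient did not have {disease_name} on the index date."
    )
    return [
        FewShotExample(build_main_prompt(serialize_profile(positive_profile), disease_name), pos_response),
        FewShotExample(build_main_prompt(serialize_profile(negative_profile), disease_name), neg_response),
    ]


def build_messages(
    profile_text: str,
    disease_name: str,
    variant: PromptVariant,
    conceptual_definition: str = "",
    few_shot_examples: list[FewShotExample] | None = None,
) -> list[dict]:
    """Ordered chat messages: system, [example user/assistant]*k, main user.

    The few-shot variant requires examples; passing ``None`` uses the
    shipped synthetic pair, while an explicit empty list is fatal.
    """
    system = build_system_prompt(variant, disease_name)
    main = build_main_prompt(profile_text, disease_name, conceptual_definition)
    messages = [{"role": "system", "content": system}]
    if variant.level == 5:
        if few_shot_examples is None:
            few_shot_examples = default_few_shot_examples(disease_name)
        if not few_shot_examples:
            raise ValueError("few-shot variant requires at least one example")
        for ex in few_shot_examples:
            messages.append({"role": "user", "content": ex.main_prompt})
            messages.append({"role": "assistant", "content": ex.ideal_response})
    messages.append({"role": "user", "content": main})
    return messages


def build_bundle(
    profile: PatientProfile,
    disease_name: str,
    variant: PromptVariant,
    conceptual_definition: str = "",
    grouping: dict[str, str] | None = None,
    few_shot_examples: list[FewShotExample] | None = None,
) -> PromptBundle:
    profile_text = serialize_profile(profile, grouping)
    if variant.level == 5 and few_shot_examples is None:
        few_shot_examples = default_few_shot_examples(disease_name)
    return PromptBundle(
        system_prompt=build_system_prompt(variant, disease_name),
        main_prompt=build_main_prompt(profile_text, disease_name, conceptual_definition),
        disease_name=disease_name,
        person_id=profile.person_id,
        variant=variant,
        few_shot_messages=few_shot_examples or [],
    )


# ---------------------------------------------------------------------------
# Message I/O
# ---------------------------------------------------------------------------

def messages_to_jsonl(records: list[tuple[int, list[dict]]], path) -> None:
    """Write (person_id, messages) records, one JSON object per line."""
    with open(path, "w") as fh:
        for person_id, messages in records:
            fh.write(
                json.dumps({"person_id": person_id, "messages": messages}, sort_keys=True)
                + "\n"
            )


def messages_from_jsonl(path) -> list[tuple[int, list[dict]]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append((int(d["person_id"]), d["messages"]))
    return out
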