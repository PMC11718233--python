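"""Text-completion backend contract, deterministic mock, and verdict parsing.

Backends implement a single ``complete(messages, params) -> text``
contract at temperature 0. Three are provided:

* :class:`MockBackend` — a deterministic rule-based adjudicator that
  parses the canonical profile rendering out of the main prompt and
  answers from simple evidence counting; it makes the whole pipeline
  testable offline and its verdicts move sensibly with planted signal.
* :class:`ReplayBackend` — replays a recorded transcript (JSONL keyed
  by a hash of the messages), supporting regression tests against any
  real model without network access.
* :class:`HttpBackend` — one neutral chat-completions request shape
  over HTTP; provider adapters translate if needed.

Responses are parsed conservatively: only the last ``Summary`` section's
explicit whole-word yes/no counts; both or neither present means
indeterminate, and indeterminate is interpreted as 'no' for metric
purposes. Negation phrases are deliberately not interpreted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
import urllib.request
from dataclasses import dataclass, field

from .prompt_builder import (
    DEFAULT_GROUPING,
    EMPTY_GROUP_LINE,
    FewShotExample,
    PromptVariant,
    build_messages,
    serialize_profile,
)

logger = logging.getLogger(__name__)


class BackendError(Exception):
    """Backend failed to produce a response."""


class TransientBackendError(BackendError):
    """Retryable failure (timeouts, rate limits, connection resets)."""


class PromptTooLargeError(BackendError):
    """The serialized messages exceed the backend's context limit."""


@dataclass
class BackendParams:
    temperature: float = 0.0
    max_output_tokens: int = 1024
    model_name: str = "mock"
    endpoint: str | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class Verdict:
    decision: str  # yes | no | indeterminate
    summary_text: str
    raw_response: str

    @property
    def effective_label(self) -> bool:
        """Binary label for metrics; indeterminate coerces to no."""
        return self.decision == "yes"


@dataclass
class AdjudicationResult:
    person_id: int
    variant_id: str
    verdict: Verdict | None
    error: str | None = None
    backend_metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Completion wrapper
# ---------------------------------------------------------------------------

def complete(
    messages: list[dict],
    params: BackendParams,
    backend,
    max_retries: int = 3,
    base_delay: float = 0.1,
) -> str:
    """Call a backend with bounded exponential-backoff retries.

    Stateless per call. Raises :class:`PromptTooLargeError` when the
    messages exceed the backend's declared context limit, and
    :class:`BackendError` after exhausting retries.
    """
    if not messages:
        raise ValueError("messages must be non-empty")
    limit = getattr(backend, "context_limit_chars", None)
    if limit is not None:
        size = sum(len(m.get("content", "")) for m in messages)
        if size > limit:
            raise PromptTooLargeError(
                f"messages total {size} characters, backend limit is {limit}"
            )
    last: Exception | None = None
    for attempt in range(max_retries):
        try:
            return backend.complete(messages, params)
        except TransientBackendError as exc:  # retryable
            last = exc
            delay = base_delay * (2**attempt)
            logger.warning("attempt %d failed (%s); retrying in %.2fs", attempt + 1, exc, delay)
            time.sleep(delay)
    raise BackendError(f"backend failed after {max_retries} attempts: {last}")


# ---------------------------------------------------------------------------
# Mock backend
# ---------------------------------------------------------------------------

#: Display groups counted as corroborating support by the mock rule:
#: symptoms/history/comorbidities (prior), treatments, complications
#: (post-visit). Laboratory orders and the index diagnosis itself are
#: deliberately not support.
SUPPORT_GROUPS = (
    "Diagnoses recorded prior to the visit",
    "Treatments",
    "Diagnoses and care recorded after the visit",
)
DIFFERENTIAL_GROUP = "Differential diagnoses"


def _parse_profile_groups(text: str) -> dict[str, int] | None:
    """Item counts per display group from the canonical rendering."""
    groups: dict[str, int] = {}
    current: str | None = None
    for line in text.splitlines():
        if line.startswith("## "):
            current = line[3:].strip()
            groups[current] = 0
        elif line.startswith("- ") and current is not None:
            if line.strip() != EMPTY_GROUP_LINE:
                groups[current] += 1
    return groups or None


@dataclass
class MockBackend:
    """Deterministic rule-based adjudicator over the canonical rendering.

    Answers yes iff the number of non-empty supporting display groups
    (prior diagnoses incl. symptoms/history, treatments, post-visit
    care) reaches ``min_support_categories`` and,
    when ``differential_veto`` is set, differential-diagnosis items do
    not outnumber the supporting items. A diagnosis code alone is never
    sufficient. Unrenderable input yields a response with no Summary
    section, exercising the parser's indeterminate path.
    """

    min_support_categories: int = 2
    differential_veto: bool = True
    context_limit_chars: int | None = None

    def complete(self, messages: list[dict], params: BackendParams) -> str:
        main = next(
            (m["content"] for m in reversed(messages) if m.get("role") == "user"), ""
        )
        disease = _disease_from_prompt(main)
        groups = _parse_profile_groups(main)
        if groups is None:
            # deliberately free of yes/no tokens and of a Summary header,
            # so downstream parsing lands on the indeterminate path
            return (
                "The provided text could not be interpreted as a structured "
                "patient profile; a determination was not possible."
            )
        n_support_groups = sum(1 for g in SUPPORT_GROUPS if groups.get(g, 0) > 0)
        n_support_items = sum(groups.get(g, 0) for g in SUPPORT_GROUPS)
        n_differential = groups.get(DIFFERENTIAL_GROUP, 0)
        decision_yes = n_support_groups >= self.min_support_categories
        vetoed = self.differential_veto and n_differential > n_support_items
        if vetoed:
            decision_yes = False

        lines = [
            f"Evidence for: {n_support_items} corroborating finding(s) across "
            f"{n_support_groups} supporting group(s).",
            f"Evidence against: {n_differential} differential-diagnosis finding(s); "
            "an isolated diagnosis code would be insufficient.",
            "Clinical narrative: the coded record was weighed for corroboration "
            "of the index diagnosis against competing explanations.",
            "",
        ]
        if decision_yes:
            lines.append(f"Summary: Yes, the patient had {disease} on the index date.")
        else:
            lines.append(
                f"Summary: No, the data lack sufficient corroborating evidence "
                f"that the patient had {disease}."
            )
        return "\n".join(lines)


def _disease_from_prompt(main_prompt: str) -> str:
    m = re.search(r"Did this patient have (.+?) on the index date", main_prompt)
    return m.group(1) if m else "the disease of interest"


def mock_complete(
    messages: list[dict],
    min_support_categories: int = 2,
    differential_veto: bool = True,
) -> str:
    """Functional form of :class:`MockBackend` for one-off calls."""
    backend = MockBackend(
        min_support_categories=min_support_categories,
        differential_veto=differential_veto,
    )
    return backend.complete(messages, BackendParams())


# ---------------------------------------------------------------------------
# Replay and HTTP backends
# ---------------------------------------------------------------------------

def _messages_key(messages: list[dict]) -> str:
    blob = json.dumps(messages, sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


class ReplayBackend:
    """Replay stored transcripts byte-for-byte; optionally record misses.

    Transcript format: JSONL of ``{"key": <sha256 of messages>,
    "messages": [...], "response": <text>}``.
    """

    def __init__(self, transcript_path, record_from=None):
        self.transcript_path = transcript_path
        self.record_from = record_from
        self._responses: dict[str, str] = {}
        try:
            with open(transcript_path) as fh:
                for line in fh:
                    if line.strip():
                        d = json.loads(line)
                        self._responses[d["key"]] = d["response"]
        except FileNotFoundError:
            if record_from is None:
                raise

    def complete(self, messages: list[dict], params: BackendParams) -> str:
        key = _messages_key(messages)
        if key in self._responses:
            return self._responses[key]
        if self.record_from is None:
            raise BackendError(f"no recorded response for messages key {key[:12]}…")
        response = self.record_from.complete(messages, params)
        self._responses[key] = response
        with open(self.transcript_path, "a") as fh:
            fh.write(
                json.dumps(
                    {"key": key, "messages": messages, "response": response},
                    sort_keys=True,
                )
                + "\n"
            )
        return response


class HttpBackend:
    """Minimal chat-completions HTTP client (stdlib only, no SDK)."""

    def __init__(self, endpoint: str, api_key: str | None = None, timeout: float = 60.0,
                 context_limit_chars: int | None = None):
        self.endpoint = endpoint
        self.api_key = api_key
        self.timeout = timeout
        self.context_limit_chars = context_limit_chars

    def complete(self, messages: list[dict], params: BackendParams) -> str:
        body = json.dumps(
            {
                "model": params.model_name,
                "messages": messages,
                "temperature": params.temperature,
                "max_tokens": params.max_output_tokens,
            }
        ).encode("utf-8")
        req = urllib.request.Request(
            self.endpoint, data=body, headers={"Content-Type": "application/json"}
        )
        if self.api_key:
            req.add_header("Authorization", f"Bearer {self.api_key}")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except Exception as exc:  # connection problems are retryable
            raise TransientBackendError(str(exc)) from exc
        try:
            return payload["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendError(f"malformed completion payload: {payload!r}") from exc


# ---------------------------------------------------------------------------
# Response parsing
# ---------------------------------------------------------------------------

_SUMMARY_RE = re.compile(r"summary", re.IGNORECASE)
_YES_RE = re.compile(r"\byes\b", re.IGNORECASE)
_NO_RE = re.compile(r"\bno\b", re.IGNORECASE)


def parse_response(raw: str) -> Verdict:
    """Parse free text into a binary verdict; total on arbitrary input.

    The text after the last occurrence of a ``summary`` header is
    scanned for whole-word yes/no. Both present, or neither, yields
    ``indeterminate`` (effective no). Without any summary header the
    final 200 characters are scanned under the same rule.
    """
    if not isinstance(raw, str):
        raw = "" if raw is None else str(raw)
    matches = list(_SUMMARY_RE.finditer(raw))
    section = raw[matches[-1].end():] if matches else raw[-200:]
    has_yes = _YES_RE.search(section) is not None
    has_no = _NO_RE.search(section) is not None
    if has_yes and not has_no:
        decision = "yes"
    elif has_no and not has_yes:
        decision = "no"
    else:
        decision = "indeterminate"
    return Verdict(decision=decision, summary_text=section.strip(), raw_response=raw)


# ---------------------------------------------------------------------------
# Cohort-scale adjudication
# ---------------------------------------------------------------------------

def _result_to_dict(r: AdjudicationResult) -> dict:
    return {
        "person_id": r.person_id,
        "variant": r.variant_id,
        "decision": r.verdict.decision if r.verdict else None,
        "effective_label": r.verdict.effective_label if r.verdict else False,
        "raw_response": r.verdict.raw_response if r.verdict else None,
        "error": r.error,
        "backend_metadata": r.backend_metadata,
    }


def _result_from_dict(d: dict) -> AdjudicationResult:
    verdict = None
    if d.get("decision") is not None:
        verdict = parse_response(d.get("raw_response") or "")
    return AdjudicationResult(
        person_id=int(d["person_id"]),
        variant_id=d["variant"],
        verdict=verdict,
        error=d.get("error"),
        backend_metadata=d.get("backend_metadata", {}),
    )


def results_from_jsonl(path) -> list[AdjudicationResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(_result_from_dict(json.loads(line)))
    return out


def labels_from_results(results: list[AdjudicationResult]) -> dict[int, bool]:
    """person_id -> effective binary label (errors and indeterminates -> no)."""
    return {
        r.person_id: bool(r.verdict.effective_label) if r.verdict else False
        for r in results
    }


def adjudicate_cohort(
    profiles,
    variant: PromptVariant,
    backend,
    params: BackendParams,
    disease_name: str,
    conceptual_definition: str = "",
    checkpoint_path=None,
    grouping: dict[str, str] | None = None,
    few_shot_examples: list[FewShotExample] | None = None,
    max_retries: int = 3,
) -> list[AdjudicationResult]:
    """Adjudicate every profile, streaming results and supporting resume.

    With ``checkpoint_path``, results are appended to a JSONL file as
    they are produced and persons already present in the file are
    skipped on rerun, so an interrupted run resumed with the same
    arguments yields a file identical to an uninterrupted one (long
    adjudications over tens of thousands of profiles make this
    essential). Per-person backend failures are recorded and the run
    continues; a failure summary is logged at the end.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    grouping = DEFAULT_GROUPING if grouping is None else grouping

    done: list[AdjudicationResult] = []
    done_ids: set[int] = set()
    if checkpoint_path is not None:
        try:
            done = results_from_jsonl(checkpoint_path)
            done_ids = {r.person_id for r in done}
        except FileNotFoundError:
            pass

    sink = open(checkpoint_path, "a") if checkpoint_path is not None else None
    results = list(done)
    n_failures = 0
    try:
        for profile in profiles:
            if profile.person_id in done_ids:
                continue
            try:
                messages = build_messages(
                    serialize_profile(profile, grouping),
                    disease_name,
                    variant,
                    conceptual_definition,
                    few_shot_examples,
                )
                raw = complete(messages, params, backend, max_retries=max_retries)
                result = AdjudicationResult(
                    person_id=profile.person_id,
                    variant_id=variant.name,
                    verdict=parse_response(raw),
                    backend_metadata={"model_name": params.model_name},
                )
            except BackendError as exc:
                n_failures += 1
                result = AdjudicationResult(
                    person_id=profile.person_id,
                    variant_id=variant.name,
                    verdict=None,
                    error=str(exc),
                    backend_metadata={"model_name": params.model_name},
                )
            results.append(result)
            if sink is not None:
                sink.write(json.dumps(_result_to_dict(result), sort_keys=True) + "\n")
                sink.flush()
    finally:
        if sink is not None:
            sink.close()
    if n_failures:
        logger.warning("%d of %d adjudications failed", n_failures, len(results))
    return results


def results_to_jsonl(results: list[AdjudicationResult], path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(_result_to_dict(r), sort_keys=True) + "\n")
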