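"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is a deliberately naive reimplementation (explicit loops,
graph traversal, word scanning) that shares no code with the library
path it checks.
"""

from __future__ import annotations

import re

import pandas as pd
from scipy.stats import beta


def reachable_descendants(edges: list[tuple[int, int]], root: int) -> set[int]:
    """Transitive-reflexive closure below ``root`` by graph traversal."""
    children: dict[int, set[int]] = {}
    for a, b in edges:
        children.setdefault(a, set()).add(b)
    seen = {root}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):  # depth-first walk
            if child not in seen:
                seen.add(child)
                stack.append(child)
    return seen


def expand_by_reachability(items, edges, all_ids) -> set[int]:
    """Concept-set expansion via per-item reachability, include minus exclude."""
    included: set[int] = set()
    excluded: set[int] = set()
    for concept_id, include_descendants, is_excluded in items:
        ids = (
            reachable_descendants(edges, concept_id)
            if include_descendants
            else {concept_id}
        )
        (excluded if is_excluded else included).update(ids)
    return included - excluded


def first_occurrence_scan(events: pd.DataFrame, ids: set[int], domain: str | None):
    """Per-person min-date scan over raw event rows."""
    best: dict[int, pd.Timestamp] = {}
    for row in events.itertuples(index=False):
        if row.concept_id not in ids:
            continue
        if domain is not None and row.domain != domain:
            continue
        pid = int(row.person_id)
        if pid not in best or row.event_date < best[pid]:
            best[pid] = row.event_date
    return best


def triple_filter_items(
    events: pd.DataFrame,
    person_id: int,
    index_date: pd.Timestamp,
    ids: set[int],
    domains: set[str],
    start,  # None = unbounded past
    end: int,
) -> set[tuple[int, int]]:
    """(concept_id, days_from_index) pairs passing the three filters."""
    out = set()
    for row in events.itertuples(index=False):
        if int(row.person_id) != person_id:
            continue
        if row.concept_id not in ids or row.domain not in domains:
            continue
        days = (row.event_date - index_date).days
        if start is not None and days < start:
            continue
        if days > end:
            continue
        out.add((int(row.concept_id), days))
    return out


def vote_count(reviews: pd.DataFrame, leave_out=None) -> dict[int, bool]:
    """Majority vote by explicit per-person tally; even split -> negative."""
    out = {}
    for pid, row in reviews.iterrows():
        votes = [bool(v) for col, v in row.items() if col != leave_out]
        out[int(pid)] = sum(votes) > len(votes) / 2
    return out


_WORD = re.compile(r"[a-z0-9_]+")


def parse_verdict_by_words(raw: str) -> str:
    """Word-level reimplementation of the summary-section yes/no rule."""
    lower = raw.lower()
    pos = lower.rfind("summary")
    section = lower[pos + len("summary"):] if pos >= 0 else lower[-200:]
    words = set(_WORD.findall(section))
    has_yes, has_no = "yes" in words, "no" in words
    if has_yes and not has_no:
        return "yes"
    if has_no and not has_yes:
        return "no"
    return "indeterminate"


def clopper_pearson_by_beta(successes: int, n: int, level: float = 0.95):
    """Exact binomial interval straight from beta quantiles."""
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else beta.ppf(alpha / 2, successes, n - successes + 1)
    hi = 1.0 if successes == n else beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return float(lo), float(hi)
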