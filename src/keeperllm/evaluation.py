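"""Reference standards, classification metrics, and operating characteristics.

Conventions for binary adjudicators:

* AUC is the mean of sensitivity and specificity (the receiver operator
  curve of a binary reviewer has a single interior point);
* confidence intervals are exact Clopper–Pearson by default (printed
  validation intervals are typically asymmetric), Wilson on request;
* indeterminate adjudications enter the metrics as negative
  predictions, but are tallied separately in reports;
* display rounding is half-away-from-zero (percentages at one decimal,
  AUC at two), full precision retained in machine output;
* leave-one-out majority votes resolve an even split as negative, with
  the tie recorded per person.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


class RosterMismatchError(Exception):
    """Reference and prediction label sets cover different persons."""


class UndefinedMetricError(Exception):
    """A requested metric has an empty denominator."""


@dataclass
class LabelSet:
    """Binary labels for a roster of persons, with provenance.

    Provenance is one of truth / external_gold / majority_vote /
    silver_llm / reviewer.
    """

    labels: dict[int, bool]
    provenance: str = "truth"

    def __post_init__(self) -> None:
        self.labels = {int(k): bool(v) for k, v in self.labels.items()}

    @property
    def roster(self) -> frozenset[int]:
        return frozenset(self.labels)

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    def __len__(self) -> int:
        return len(self.labels)

    def restrict(self, persons) -> "LabelSet":
        persons = set(persons)
        missing = sorted(persons - self.roster)
        if missing:
            raise RosterMismatchError(f"persons missing from label set: {missing[:10]}")
        return LabelSet({p: self.labels[p] for p in persons}, self.provenance)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            sorted(self.labels.items()), columns=["person_id", "label"]
        )
        df["label"] = df["label"].astype(int)
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, provenance: str = "external_gold") -> "LabelSet":
        df = pd.read_csv(path)
        label_col = "label" if "label" in df.columns else "true_case"
        return cls(dict(zip(df["person_id"], df[label_col].astype(bool))), provenance)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsResult:
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    ci_sensitivity: tuple[float, float] | None
    ci_specificity: tuple[float, float] | None
    n_pos: int
    n_neg: int
    undefined: list[str] = field(default_factory=list)


@dataclass
class OperatingCharacteristics:
    """PPV and sensitivity of a phenotype algorithm against a reference."""

    ppv: float
    ppv_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    n_flagged: int
    n_silver_pos: int
    tp: int


# ---------------------------------------------------------------------------
# Rounding helpers (display convention)
# ---------------------------------------------------------------------------

def round_half_away_from_zero(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (display convention), not banker's."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(x: float, ndigits: int = 1) -> str:
    return f"{round_half_away_from_zero(100.0 * x, ndigits):.{ndigits}f}%"


# ---------------------------------------------------------------------------
# Counts and metrics
# ---------------------------------------------------------------------------

def confusion(reference: LabelSet, predictions: LabelSet) -> ConfusionCounts:
    """Standard 2x2 tally; rosters must be identical."""
    if reference.roster != predictions.roster:
        only_ref = sorted(reference.roster - predictions.roster)
        only_pred = sorted(predictions.roster - reference.roster)
        raise RosterMismatchError(
            f"roster mismatch; only in reference: {only_ref[:10]}, "
            f"only in predictions: {only_pred[:10]}"
        )
    tp = fp = tn = fn = 0
    for pid, truth in reference.labels.items():
        pred = predictions.labels[pid]
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def binomial_interval(
    successes: int,
    n: int,
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> tuple[float, float]:
    """Two-sided binomial CI; Clopper–Pearson exact (default) or Wilson.

    Boundary cases are exact: 0 successes gives lower bound 0, and
    ``successes == n`` gives upper bound 1.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"invalid counts: {successes}/{n}")
    sm_method = {"clopper_pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method=sm_method)
    lo = 0.0 if successes == 0 or np.isnan(lo) else float(lo)
    hi = 1.0 if successes == n or np.isnan(hi) else float(hi)
    return lo, hi


def auc_from_rates(sensitivity: float, specificity: float) -> float:
    """AUC of a binary adjudicator: mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def metrics(
    counts: ConfusionCounts,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> MetricsResult:
    """Sensitivity, specificity and AUC with binomial CIs.

    A metric with an empty denominator is returned as None and flagged
    in ``undefined`` rather than silently reported as 0.
    """
    undefined = []
    sens = spec = auc = None
    ci_sens = ci_spec = None
    if counts.n_pos >= 1:
        sens = counts.tp / counts.n_pos
        ci_sens = binomial_interval(counts.tp, counts.n_pos, ci_method, level)
    else:
        undefined.append("sensitivity")
    if counts.n_neg >= 1:
        spec = counts.tn / counts.n_neg
        ci_spec = binomial_interval(counts.tn, counts.n_neg, ci_method, level)
    else:
        undefined.append("specificity")
    if sens is not None and spec is not None:
        auc = auc_from_rates(sens, spec)
    else:
        undefined.append("auc")
    return MetricsResult(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_sensitivity=ci_sens,
        ci_specificity=ci_spec,
        n_pos=counts.n_pos,
        n_neg=counts.n_neg,
        undefined=undefined,
    )


def metrics_from_rates(sensitivity_pct: float, specificity_pct: float) -> dict:
    """Display-precision AUC from printed sensitivity/specificity percentages.

    Input on the percent scale (e.g. 86.8); returns the AUC on the unit
    scale rounded to two decimals with ties away from zero, alongside the
    unrounded value.
    """
    auc = auc_from_rates(sensitivity_pct / 100.0, specificity_pct / 100.0)
    return {"auc": auc, "auc_2dp": round_half_away_from_zero(auc, 2)}


# ---------------------------------------------------------------------------
# Majority-vote gold standards
# ---------------------------------------------------------------------------

def majority_vote_gold(
    reviews: pd.DataFrame, leave_out=None
) -> tuple[LabelSet, list[int]]:
    """Leave-one-out majority vote over a complete person x reviewer block.

    ``reviews`` is indexed by person_id with one boolean column per
    reviewer; missing cells are fatal (review designs are complete
    blocks). With ``leave_out`` set, that reviewer's column is removed
    before voting, so a reviewer is never evaluated against their own
    votes. An exact tie among the remaining reviewers resolves to
    negative; tied persons are returned alongside the labels.
    """
    if reviews.isna().any().any():
        bad = reviews[reviews.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete review matrix; missing cells for persons {bad[:10]}")
    if reviews.shape[1] < 3:
        raise ValueError("majority vote requires >= 3 reviewers before leave-out")
    votes = reviews.astype(bool)
    if leave_out is not None:
        if leave_out not in votes.columns:
            raise KeyError(f"unknown reviewer {leave_out!r}")
        votes = votes.drop(columns=[leave_out])
    n_reviewers = votes.shape[1]
    pos_votes = votes.sum(axis=1)
    labels = pos_votes * 2 > n_reviewers
    ties = sorted(int(p) for p in votes.index[pos_votes * 2 == n_reviewers])
    return (
        LabelSet(dict(zip(votes.index.astype(int), labels)), provenance="majority_vote"),
        ties,
    )


# ---------------------------------------------------------------------------
# Operating characteristics against a silver standard
# ---------------------------------------------------------------------------

def operating_characteristics(
    silver: LabelSet,
    algorithm_flags: LabelSet,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> OperatingCharacteristics:
    """PPV and sensitivity of algorithm flags against a reference standard.

    PPV = tp / n_flagged and sensitivity = tp / n_silver_pos, each with a
    binomial CI. Zero flagged persons or zero reference positives make
    the corresponding metric undefined and are fatal.
    """
    if silver.roster != algorithm_flags.roster:
        raise RosterMismatchError(
            f"roster mismatch: {sorted(silver.roster ^ algorithm_flags.roster)[:10]}"
        )
    tp = sum(
        1 for p, flagged in algorithm_flags.labels.items() if flagged and silver.labels[p]
    )
    n_flagged = algorithm_flags.n_positive
    n_silver_pos = silver.n_positive
    if n_flagged < 1:
        raise UndefinedMetricError("no persons flagged by the algorithm; PPV undefined")
    if n_silver_pos < 1:
        raise UndefinedMetricError("no reference positives; sensitivity undefined")
    return OperatingCharacteristics(
        ppv=tp / n_flagged,
        ppv_ci=binomial_interval(tp, n_flagged, ci_method, level),
        sensitivity=tp / n_silver_pos,
        sensitivity_ci=binomial_interval(tp, n_silver_pos, ci_method, level),
        n_flagged=n_flagged,
        n_silver_pos=n_silver_pos,
        tp=tp,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def evaluation_report(rows: list[dict]) -> pd.DataFrame:
    """Long-format performance table at display precision.

    Each input row carries a ``label`` (prompt variant, model or
    reviewer) and a :class:`MetricsResult` under ``metrics``, plus an
    optional count of indeterminate verdicts. Percentages are shown at
    one decimal and AUC at two; raw values are kept in ``*_raw``
    columns.
    """
    if not rows:
        raise ValueError("no results to report")
    records = []
    for row in rows:
        m: MetricsResult = row["metrics"]
        rec = {
            "label": row["label"],
            "n": m.n_pos + m.n_neg,
            "n_pos": m.n_pos,
            "n_neg": m.n_neg,
            "sensitivity": format_percent(m.sensitivity) if m.sensitivity is not None else "undefined",
            "specificity": format_percent(m.specificity) if m.specificity is not None else "undefined",
            "auc": (
                f"{round_half_away_from_zero(m.auc, 2):.2f}" if m.auc is not None else "undefined"
            ),
            "sensitivity_ci": (
                f"{format_percent(m.ci_sensitivity[0])}-{format_percent(m.ci_sensitivity[1])}"
                if m.ci_sensitivity
                else ""
            ),
            "specificity_ci": (
                f"{format_percent(m.ci_specificity[0])}-{format_percent(m.ci_specificity[1])}"
                if m.ci_specificity
                else ""
            ),
            "n_indeterminate": int(row.get("n_indeterminate", 0)),
            "sensitivity_raw": m.sensitivity,
            "specificity_raw": m.specificity,
            "auc_raw": m.auc,
        }
        records.append(rec)
    return pd.DataFrame(records)


def report_to_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# Review-effort accounting
# ---------------------------------------------------------------------------

#: The manual-review design of the validation study this package
#: operationalizes: a 358-review development set plus three test sets
#: reviewed as complete reviewer x disease x case blocks.
STUDY_REVIEW_DESIGN: list[dict] = [
    {"set": "development", "reviews": 358},
    {"set": "test_set_1", "n_reviewers": 4, "n_diseases": 4, "n_cases_per_disease": 20},
    {"set": "test_set_2", "n_reviewers": 5, "n_diseases": 4, "n_cases_per_disease": 20},
    {"set": "test_set_3", "n_reviewers": 5, "n_diseases": 6, "n_cases_per_disease": 25},
]


def count_reviews(design: list[dict]) -> int:
    """Total manual case reviews implied by a block review design."""
    total = 0
    for row in design:
        if "reviews" in row:
            total += int(row["reviews"])
        else:
            total += (
                int(row["n_reviewers"])
                * int(row["n_diseases"])
                * int(row["n_cases_per_disease"])
            )
    return total
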