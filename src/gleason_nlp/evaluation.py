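"""Accuracy and workload arithmetic for the three extraction strategies.

Against per-task gold labels, three allocation strategies are compared:

* ``human_alone``  -- a human extracts every task;
* ``nlp_alone``    -- the automated pipeline extracts every task;
* ``nlp_assisted`` -- uncomplicated tasks go to the pipeline, complicated
  tasks to a human, so the human workload fraction equals the complicated
  fraction.

NLP correctness is judged by exact triple equality against gold (not_found
matches not_found).  Human correctness is either supplied (real review data)
or simulated with a per-stratum Bernoulli error model -- a clearly labeled
simulation, not a claim about real annotators.  Accuracy differences are
tested with a two-sided Fisher exact test computed by full hypergeometric
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import hypergeom

#: default simulated human error rates per triage stratum (observed review
#: rates: 10/381 on uncomplicated tasks, 0/19 on complicated tasks)
DEFAULT_HUMAN_ERROR_RATES = {
    "uncomplicated": 10 / 381,
    "complicated": 0.0,
}

STRATEGIES = ("human_alone", "nlp_alone", "nlp_assisted")


@dataclass(frozen=True)
class TaskOutcome:
    patient_id: str
    specimen_type: str
    triage: str  # "uncomplicated" | "complicated"
    nlp_correct: bool
    human_correct: bool


@dataclass
class StrategyCounts:
    errors: int
    total: int
    accuracy_percent: float


@dataclass
class StrategyReport:
    strategies: dict
    workload_fraction_human: float
    stratum_counts: dict
    p_values: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {
            "strategies": {
                name: {
                    "errors": c.errors,
                    "total": c.total,
                    "accuracy_percent": c.accuracy_percent,
                }
                for name, c in self.strategies.items()
            },
            "workload_fraction_human": self.workload_fraction_human,
            "stratum_counts": self.stratum_counts,
        }
        if self.p_values is not None:
            out["p_values"] = self.p_values
        return out


def accuracy_percent(errors: int, total: int) -> float:
    """100 x (total - errors) / total, half-away-from-zero at 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= errors <= total:
        raise ValueError("errors must satisfy 0 <= errors <= total")
    value = Decimal(100) * Decimal(total - errors) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def score_tasks(
    predicted: Mapping,
    gold: Mapping,
    *,
    human_error_rates: Optional[Mapping] = None,
    rng: Optional[np.random.Generator] = None,
    human_outcomes: Optional[Mapping] = None,
) -> list[TaskOutcome]:
    """Match pipeline output to gold labels, one outcome per task.

    ``predicted`` and ``gold`` are mappings ``(patient_id, specimen_type) ->
    {"triple": (P,S,T) | None, ...}``; predicted entries also carry
    ``"triage"``.  The NLP answer is the pre-human draft aggregate.  Human
    correctness comes from ``human_outcomes`` (same keys, booleans) when
    available, otherwise from a Bernoulli draw at the stratum error rate.
    """
    if set(predicted) != set(gold):
        only_pred = sorted(set(predicted) - set(gold))[:3]
        only_gold = sorted(set(gold) - set(predicted))[:3]
        raise ValueError(
            f"predicted/gold task mismatch (e.g. only-predicted {only_pred}, "
            f"only-gold {only_gold})"
        )
    rates = dict(DEFAULT_HUMAN_ERROR_RATES)
    if human_error_rates:
        rates.update(human_error_rates)
    if human_outcomes is None and any(r > 0 for r in rates.values()) and rng is None:
        raise ValueError("simulating human extraction requires an rng")

    outcomes = []
    for key in sorted(predicted):
        pred, ref = predicted[key], gold[key]
        triage = pred["triage"]
        nlp_correct = pred["triple"] == ref["triple"]
        if human_outcomes is not None:
            human_correct = bool(human_outcomes[key])
        elif rng is not None:
            human_correct = bool(rng.random() >= rates[triage])
        else:
            human_correct = True
        outcomes.append(
            TaskOutcome(
                patient_id=key[0],
                specimen_type=key[1],
                triage=triage,
                nlp_correct=nlp_correct,
                human_correct=human_correct,
            )
        )
    return outcomes


def strategy_accuracies(outcomes: Iterable[TaskOutcome]) -> StrategyReport:
    """Error counts and accuracies for the three allocation strategies."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    total = len(outcomes)
    stratum = {
        s: {"total": 0, "nlp_errors": 0, "human_errors": 0}
        for s in ("uncomplicated", "complicated")
    }
    for o in outcomes:
        counts = stratum[o.triage]
        counts["total"] += 1
        counts["nlp_errors"] += not o.nlp_correct
        counts["human_errors"] += not o.human_correct

    human_errors = sum(s["human_errors"] for s in stratum.values())
    nlp_errors = sum(s["nlp_errors"] for s in stratum.values())
    assisted_errors = (
        stratum["uncomplicated"]["nlp_errors"] + stratum["complicated"]["human_errors"]
    )
    strategies = {
        "human_alone": StrategyCounts(
            human_errors, total, accuracy_percent(human_errors, total)
        ),
        "nlp_alone": StrategyCounts(
            nlp_errors, total, accuracy_percent(nlp_errors, total)
        ),
        "nlp_assisted": StrategyCounts(
            assisted_errors, total, accuracy_percent(assisted_errors, total)
        ),
    }
    return StrategyReport(
        strategies=strategies,
        workload_fraction_human=stratum["complicated"]["total"] / total,
        stratum_counts=stratum,
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value by full hypergeometric enumeration.

    With margins fixed, the p-value sums the point probabilities of every
    table whose probability does not exceed the observed table's (within a
    relative tolerance of 1e-7 guarding floating-point ties).
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"table cells must be non-negative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table must have at least one positive margin")
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    included = pmf <= p_obs * (1 + 1e-7)
    if included.all():  # every table is as extreme; the masses sum to 1 exactly
        return 1.0
    return min(1.0, float(pmf[included].sum()))


def compare_report(report: StrategyReport) -> StrategyReport:
    """Attach pairwise Fisher p-values to a strategy report (in place).

    Compared on error/correct 2x2 tables: assisted vs human alone, assisted
    vs NLP alone, and human vs NLP restricted to the complicated stratum.
    """

    def table(errors1, total1, errors2, total2):
        return [[errors1, total1 - errors1], [errors2, total2 - errors2]]

    s = report.strategies
    p_values = {
        "nlp_assisted_vs_human_alone": fisher_exact_two_sided(
            table(
                s["nlp_assisted"].errors,
                s["nlp_assisted"].total,
                s["human_alone"].errors,
                s["human_alone"].total,
            )
        ),
        "nlp_assisted_vs_nlp_alone": fisher_exact_two_sided(
            table(
                s["nlp_assisted"].errors,
                s["nlp_assisted"].total,
                s["nlp_alone"].errors,
                s["nlp_alone"].total,
            )
        ),
    }
    complicated = report.stratum_counts["complicated"]
    if complicated["total"] > 0:
        p_values["human_vs_nlp_complicated"] = fisher_exact_two_sided(
            table(
                complicated["human_errors"],
                complicated["total"],
                complicated["nlp_errors"],
                complicated["total"],
            )
        )
    report.p_values = p_values
    return report
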