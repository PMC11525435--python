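"""Checks that the log file records what actually happened.

Three audits: (1) logged event content against ground-truth annotations
(manual notes during a test run, or fixture truth), (2) logged responses
against a preplanned response sequence, and (3) compliance of the realized
event sequence with the experimental-design rules (balancing, order
constraints, blocks).  For a functioning setup every mismatch count should
be zero; any deviation requires fixing the experimental software and
retesting, never silent repair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import EventLog

__all__ = [
    "ContentReport",
    "ResponsePlan",
    "DesignRuleSet",
    "compare_event_content",
    "check_response_plan",
    "validate_design_rules",
]


@dataclass
class ContentReport:
    """Outcome of a content audit.

    ``mismatches`` rows carry the event index, the offending field and the
    logged vs. true value, so every error is exactly locatable.
    """

    n_conditions_tested: int
    n_events_tested: int
    events_per_condition: dict[tuple, int]
    mismatches: pd.DataFrame
    uncovered_conditions: list[tuple] = field(default_factory=list)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    @property
    def passed(self) -> bool:
        return self.n_mismatches == 0 and not self.uncovered_conditions

    def __str__(self) -> str:
        return (
            f"{self.n_mismatches} mismatch(es) / {self.n_events_tested} events "
            f"tested across {self.n_conditions_tested} condition(s)"
        )


def _condition_key(row: pd.Series, factors: Sequence[str]) -> tuple:
    return tuple(row[f] for f in factors)


def compare_event_content(
    log: EventLog,
    truth: EventLog | pd.DataFrame,
    fields: Sequence[str] | None = None,
) -> ContentReport:
    """Compare logged event content with ground-truth annotations.

    ``truth`` uses the same schema as the log (a subset of rows is allowed),
    keyed by ``event_index``.  Every annotated row is checked field by field;
    a condition is a realized combination of factor levels, and coverage
    shortfalls (realized combinations with no annotated event) are listed.
    """
    truth_df = truth.df if isinstance(truth, EventLog) else truth
    log_df = log.controlled.df if "event_class" in log.df.columns else log.df
    if "event_class" in truth_df.columns:
        truth_df = truth_df[truth_df["event_class"] == "controlled"]
    factors = log.factor_columns
    fields = list(fields) if fields is not None else factors
    unknown = set(truth_df["event_index"]) - set(log_df["event_index"])
    if unknown:
        raise KeyError(f"truth refers to unknown event_index values {sorted(unknown)}")

    indexed = log_df.set_index("event_index")
    rows = []
    tested_conditions: dict[tuple, int] = {}
    for _, trow in truth_df.iterrows():
        lrow = indexed.loc[trow["event_index"]]
        key = _condition_key(trow, factors)
        tested_conditions[key] = tested_conditions.get(key, 0) + 1
        for f in fields:
            if lrow[f] != trow[f]:
                rows.append(
                    {
                        "event_index": trow["event_index"],
                        "field": f,
                        "logged": lrow[f],
                        "truth": trow[f],
                    }
                )
    realized = {
        _condition_key(r, factors) for _, r in log_df.iterrows()
    }
    uncovered = sorted(realized - set(tested_conditions))
    mism = pd.DataFrame(rows, columns=["event_index", "field", "logged", "truth"])
    return ContentReport(
        n_conditions_tested=len(tested_conditions),
        n_events_tested=len(truth_df),
        events_per_condition=tested_conditions,
        mismatches=mism,
        uncovered_conditions=uncovered,
    )


@dataclass
class ResponsePlan:
    """Ordered, preplanned response sequence for the log-fidelity test.

    ``presses`` is the executed order of key presses, each ``(key, count)``:
    count > 1 encodes deliberate multiple presses of the same key for one
    event.  Deliberate wrong keys and between-event presses are simply part
    of the sequence — the log must reproduce all of them.
    """

    presses: list[tuple[str, int]]

    @property
    def flattened(self) -> list[str]:
        out: list[str] = []
        for key, count in self.presses:
            out.extend([key] * count)
        return out

    @property
    def n_presses(self) -> int:
        return len(self.flattened)


def check_response_plan(
    log: EventLog, plan: ResponsePlan | list[tuple[str, int]]
) -> ContentReport:
    """Positional comparison of executed vs. logged responses.

    Reports the number of response types, responses per type, and the count
    of inaccurately logged responses out of the total planned.  Missing
    logged presses (including a missing repeat of a multi-press entry) count
    as mismatches; extra logged presses count as "unexpected" mismatches.
    """
    if not isinstance(plan, ResponsePlan):
        plan = ResponsePlan(list(plan))
    df = log.df
    if "event_class" in df.columns:
        df = df[df["event_class"] == "uncontrolled"]
    if "response_key" not in df.columns:
        raise ValueError("event log has no response_key column")
    logged = list(df["response_key"])
    executed = plan.flattened

    rows = []
    pos = 0
    for key, count in plan.presses:
        for r in range(count):
            if pos >= len(logged):
                rows.append(
                    {
                        "event_index": pos,
                        "field": "response_key",
                        "logged": "<missing repeat>" if r > 0 else "<missing>",
                        "truth": key,
                    }
                )
            elif logged[pos] != key:
                rows.append(
                    {
                        "event_index": pos,
                        "field": "response_key",
                        "logged": logged[pos],
                        "truth": key,
                    }
                )
            pos += 1
    for extra_pos in range(len(executed), len(logged)):
        rows.append(
            {
                "event_index": extra_pos,
                "field": "response_key",
                "logged": logged[extra_pos],
                "truth": "<unexpected>",
            }
        )

    per_type: dict[tuple, int] = {}
    for key in executed:
        per_type[(key,)] = per_type.get((key,), 0) + 1
    mism = pd.DataFrame(rows, columns=["event_index", "field", "logged", "truth"])
    return ContentReport(
        n_conditions_tested=len(per_type),
        n_events_tested=len(executed),
        events_per_condition=per_type,
        mismatches=mism,
    )


@dataclass
class DesignRuleSet:
    """Experimental-design requirements to enforce on the realized log.

    ``expected_counts`` maps factor-level combinations (tuples ordered as
    ``factors``) to expected event counts and must sum to the number of
    events.  ``max_consecutive`` limits run lengths per factor ("no more
    than k consecutive same-level events").  ``blocks`` optionally gives
    per-block expected counts, each block a dict with ``n_events`` and an
    ``expected_counts`` mapping.  ``predicates`` are custom callables
    ``seq -> list of violating row positions``.
    """

    factors: list[str]
    expected_counts: dict[tuple, int] | None = None
    max_consecutive: dict[str, int] | None = None
    blocks: list[dict] | None = None
    predicates: dict[str, Callable[[pd.DataFrame], list[int]]] | None = None


def _run_violations(levels: Sequence, k: int) -> list[int]:
    """Start positions of runs longer than k consecutive identical levels."""
    out = []
    run_start, run_len = 0, 1
    for i in range(1, len(levels)):
        if levels[i] == levels[i - 1]:
            run_len += 1
            if run_len == k + 1:
                out.append(run_start)
        else:
            run_start, run_len = i, 1
    return out


def validate_design_rules(log: EventLog, rules: DesignRuleSet) -> dict:
    """Check the realized event sequence against the design rules.

    Returns a per-rule compliance report: events compliant out of total,
    plus violation locations.  Any deviation means the realized sequence
    does not comply with the study plan.
    """
    df = log.controlled.df if "event_class" in log.df.columns else log.df
    for f in rules.factors:
        if f not in df.columns:
            raise KeyError(f"rule references unknown factor {f!r}")
    n = len(df)
    report: dict[str, dict] = {}

    if rules.expected_counts is not None:
        if sum(rules.expected_counts.values()) != n:
            raise ValueError(
                "expected counts sum to "
                f"{sum(rules.expected_counts.values())} but log has {n} events"
            )
        observed = df.groupby(rules.factors, sort=False).size()
        combos = {}
        bad_events = 0
        for combo, expected in rules.expected_counts.items():
            key = combo if len(rules.factors) > 1 else combo[0]
            got = int(observed.get(key, 0))
            combos[combo] = {"expected": expected, "observed": got}
            bad_events += abs(got - expected)
        for combo in observed.index:
            tcombo = combo if isinstance(combo, tuple) else (combo,)
            if tcombo not in rules.expected_counts:
                combos[tcombo] = {"expected": 0, "observed": int(observed[combo])}
                bad_events += int(observed[combo])
        report["balanced_counts"] = {
            "compliant": n - min(bad_events, n),
            "total": n,
            "per_combination": combos,
            "passed": bad_events == 0,
        }

    if rules.max_consecutive:
        for factor, k in rules.max_consecutive.items():
            viol = _run_violations(list(df[factor]), k)
            report[f"max_{k}_consecutive_{factor}"] = {
                "compliant": n - len(viol),
                "total": n,
                "violation_rows": viol,
                "passed": not viol,
            }

    if rules.blocks:
        start = 0
        block_entries = []
        ok = True
        for b, block in enumerate(rules.blocks):
            stop = start + int(block["n_events"])
            sub = df.iloc[start:stop]
            observed = sub.groupby(rules.factors, sort=False).size()
            entry = {"block": b, "n_events": len(sub), "counts": {}}
            for combo, expected in block.get("expected_counts", {}).items():
                key = combo if len(rules.factors) > 1 else combo[0]
                got = int(observed.get(key, 0))
                entry["counts"][combo] = {"expected": expected, "observed": got}
                ok = ok and got == expected
            block_entries.append(entry)
            start = stop
        report["blocks"] = {"per_block": block_entries, "passed": ok, "total": n}

    if rules.predicates:
        for name, fn in rules.predicates.items():
            viol = list(fn(df))
            report[name] = {
                "compliant": n - len(viol),
                "total": n,
                "violation_rows": viol,
                "passed": not viol,
            }

    report["passed"] = all(
        v.get("passed", True) for v in report.values() if isinstance(v, dict)
    )
    return report
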