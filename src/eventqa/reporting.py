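"""Assemble QA results into the standardized report.

The report mirrors the testing framework's sections: visual geometry,
controlled-event content, response (uncontrolled-event) content, timing
(one block per discrepancy kind, in milliseconds), design compliance, and
peripheral triggers.  Sections that were not measured are marked
"not performed" rather than omitted, so the report always documents what
was and was not tested.  Timing values are converted from seconds to
milliseconds at rendering time only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .content_validation import ContentReport
from .core import DeltaSeries
from .timing_metrics import DEFAULT_SD_WARN_S, summarize

__all__ = ["QAReport", "build_report", "render_report"]

_TIMING_KINDS = (
    "log_timing",
    "duration_vs_plan",
    "trigger_jitter",
    "trigger_delay",
    "response_timing",
)

NOT_PERFORMED = {"status": "not performed"}


def _ms(x: float) -> float:
    return round(float(x) * 1000.0, 4)


@dataclass
class QAReport:
    """Machine-readable QA report; every numeric field traces back to a
    computed artifact."""

    geometry: dict = field(default_factory=lambda: dict(NOT_PERFORMED))
    content: dict = field(default_factory=lambda: dict(NOT_PERFORMED))
    response: dict = field(default_factory=lambda: dict(NOT_PERFORMED))
    timing: dict = field(default_factory=dict)
    design: dict = field(default_factory=lambda: dict(NOT_PERFORMED))
    trigger: dict = field(default_factory=lambda: dict(NOT_PERFORMED))

    @property
    def sections(self) -> dict:
        return {
            "geometry": self.geometry,
            "content": self.content,
            "response": self.response,
            "timing": self.timing or dict(NOT_PERFORMED),
            "design": self.design,
            "trigger": self.trigger,
        }

    @property
    def overall_status(self) -> str:
        worst = "pass"
        order = {"pass": 0, "not performed": 0, "warn": 1, "fail": 2}
        for sec in self.sections.values():
            statuses = [sec.get("status", "pass")]
            statuses += [
                v.get("status", "pass") for v in sec.values() if isinstance(v, dict)
            ]
            for s in statuses:
                if order.get(s, 0) > order[worst]:
                    worst = s
        return worst

    def to_dict(self) -> dict:
        return {"sections": self.sections, "overall_status": self.overall_status}

    @classmethod
    def from_dict(cls, d: dict) -> "QAReport":
        s = d["sections"]
        return cls(
            geometry=s["geometry"],
            content=s["content"],
            response=s["response"],
            timing={} if s["timing"] == NOT_PERFORMED else s["timing"],
            design=s["design"],
            trigger=s["trigger"],
        )


def _content_section(report: ContentReport, what: str) -> dict:
    return {
        "status": "pass" if report.passed else "fail",
        f"n_{what}_types": report.n_conditions_tested,
        "n_tested": report.n_events_tested,
        "per_type": {"/".join(map(str, k)): v for k, v in report.events_per_condition.items()},
        "n_inaccurate": report.n_mismatches,
        "mismatch_locations": report.mismatches.to_dict("records"),
        "uncovered_conditions": ["/".join(map(str, c)) for c in report.uncovered_conditions],
    }


def _timing_section(series: DeltaSeries, sd_warn_s: float) -> dict:
    s = summarize(series)
    status = "pass"
    if s["sd_s"] > sd_warn_s or abs(s["mean_s"]) > max(s["sd_s"], sd_warn_s):
        status = "warn"
    return {
        "status": status,
        "mean_ms": _ms(s["mean_s"]),
        "sd_ms": _ms(s["sd_s"]),
        "n": s["n"],
        "max_abs_ms": _ms(s["max_abs_s"]),
        "low_n": s["low_n"],
    }


def build_report(
    geometry: dict | None = None,
    content: ContentReport | None = None,
    response: ContentReport | None = None,
    timing: dict[str, DeltaSeries] | None = None,
    design: dict | None = None,
    trigger_content: ContentReport | None = None,
    trigger_jitter: DeltaSeries | None = None,
    trigger_delay: DeltaSeries | None = None,
    trigger_delay_same_clock: bool = True,
    sd_warn_s: float = DEFAULT_SD_WARN_S,
) -> QAReport:
    """Populate the standardized report from computed artifacts.

    Content/design sections fail on any mismatch (the expected count of
    inaccurately logged events is zero); timing sections warn when the SD
    exceeds ``sd_warn_s`` (default 5 ms) or the mean strays from zero.
    """
    rep = QAReport()
    if geometry is not None:
        g = dict(geometry)
        g["status"] = "pass"
        if g.get("off_center"):
            g["note"] = "off-center eccentricities use the small-tilt approximation"
        rep.geometry = g
    if content is not None:
        rep.content = _content_section(content, "condition")
    if response is not None:
        rep.response = _content_section(response, "response")
    if timing:
        for kind, series in timing.items():
            if kind not in _TIMING_KINDS:
                raise ValueError(f"unknown timing kind {kind!r}")
            rep.timing[kind] = _timing_section(series, sd_warn_s)
    if design is not None:
        rep.design = {
            "status": "pass" if design.get("passed") else "fail",
            "rules": {
                k: v for k, v in design.items() if isinstance(v, dict)
            },
        }
    trig: dict = {}
    if trigger_content is not None:
        trig["content"] = _content_section(trigger_content, "code")
    if trigger_jitter is not None:
        trig["jitter"] = _timing_section(trigger_jitter, sd_warn_s)
    if trigger_delay is not None:
        trig["delay"] = _timing_section(trigger_delay, sd_warn_s)
        trig["delay"]["same_clock_asserted"] = trigger_delay_same_clock
        if not trigger_delay_same_clock:
            trig["delay"]["status"] = "warn"
            trig["delay"]["note"] = (
                "delay estimates are only valid when photodiode and trigger "
                "streams share a clock"
            )
    if trig:
        rep.trigger = trig
    if all(
        sec == NOT_PERFORMED for sec in (rep.geometry, rep.content, rep.response, rep.design, rep.trigger)
    ) and not rep.timing:
        raise ValueError("at least one computed artifact is required")
    return rep


def _md_section(title: str, sec: dict, indent: int = 0) -> list[str]:
    pad = "  " * indent
    lines = [f"{pad}## {title}" if indent == 0 else f"{pad}- **{title}**"]
    for key, val in sec.items():
        if isinstance(val, dict):
            lines += _md_section(key, val, indent + 1)
        elif isinstance(val, list):
            if val:
                lines.append(f"{pad}  - {key}: {val}")
        else:
            lines.append(f"{pad}  - {key}: {val}")
    return lines


def render_report(report: QAReport, format: str = "markdown") -> str:
    """Render a QA report as markdown (human-readable) or JSON (lossless).

    The JSON twin round-trips: ``QAReport.from_dict(json.loads(doc))``
    equals the original.
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, default=_jsonify)
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")
    lines = [
        "# Experimental environment QA report",
        "",
        f"Overall status: **{report.overall_status}**",
        "",
    ]
    for name, sec in report.sections.items():
        lines += _md_section(name, sec)
        lines.append("")
    return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
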