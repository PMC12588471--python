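"""Deterministic rendering of study reports.

Formatting follows the conventions of replication-report tables in this
field: percentages and their standard errors to two decimals, p-values to
three, e.g. ``49.65 ± 0.14; p = 0.013``.
"""

from __future__ import annotations

import json

import pandas as pd

_ARM_LABEL = {"human": "", "reg": " (REG)"}


def format_result(hit_pct: float, se_pct: float, p_value: float) -> str:
    return f"{hit_pct:.2f} ± {se_pct:.2f}; p = {p_value:.3f}"


def render_study_table(reports: list, style: str = "table") -> str:
    """Render ConditionReports as a fixed-format text table, CSV or JSON."""
    if not reports:
        raise ValueError("no reports to render")
    rows = []
    for r in reports:
        row = {
            "Condition": r.condition + _ARM_LABEL.get(r.arm, f" ({r.arm})"),
            "Result (%)": format_result(r.hit_pct, r.se_pct, r.p_value),
            "No. Trials": r.n,
        }
        for name in ("uniform", "buj", "replication"):
            row[f"BF01 ({name})"] = (
                f"{r.bf01[name]:.3g}" if r.bf01 and name in r.bf01 else ""
            )
        row["Decision"] = r.decision
        rows.append(row)
    frame = pd.DataFrame(rows)
    if style == "csv":
        return frame.to_csv(index=False)
    if style == "json":
        return json.dumps(rows, indent=2)
    if style == "table":
        return frame.to_string(index=False)
    raise ValueError(f"unknown style {style!r}")
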