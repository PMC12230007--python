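"""Rendering of comparison results as CSV-ready frames and text tables.

The text layout mirrors the conventional pre/post results table:
one row per variable with baseline and follow-up summaries, the model
p-value, and the standardized effect size with its 95% CI; categorical
variables additionally list per-level counts (percentages) indented under
their row.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .analysis import ComparisonResult

__all__ = ["results_frame", "render_text", "default_plan"]


def default_plan() -> list[dict]:
    """The standard scored-cohort plan: five domains + composite + class."""
    plan = [
        {"variable": v, "family": "linear"}
        for v in ("sensory", "psychological", "cognitive",
                  "vitality", "locomotion", "composite")
    ]
    plan.append({"variable": "category", "family": "ordinal-logistic",
                 "type": "ordinal", "levels": ["low", "moderate", "high"]})
    return plan


def _fmt(x, nd=2) -> str:
    if x is None:
        return ""
    return f"{x:.{nd}f}"


def _fmt_p(p) -> str:
    if p is None:
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _summary_str(summary: dict) -> str:
    if not summary:
        return ""
    if "levels" in summary:
        return f"n={summary['n']}"
    return (
        f"{_fmt(summary['median'])} ({_fmt(summary['p25'])}-"
        f"{_fmt(summary['p75'])})"
    )


def _es_str(res: ComparisonResult) -> str:
    if res.effect_size is None:
        return ""
    lo, hi = res.es_ci if res.es_ci else (None, None)
    return f"{_fmt(res.effect_size)} ({_fmt(lo)} to {_fmt(hi)})"


def results_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten results to one machine-readable row per variable."""
    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "family": r.family,
            "estimate": r.estimate,
            "p_value": r.p_value,
            "effect_size": r.effect_size,
            "es_ci_low": r.es_ci[0] if r.es_ci else None,
            "es_ci_high": r.es_ci[1] if r.es_ci else None,
            "es_band": r.es_band,
            "error": r.error,
        }
        for tp, summary in (("baseline", r.baseline_summary),
                            ("followup", r.followup_summary)):
            if summary and "levels" not in summary:
                for k in ("n", "mean", "sd", "median", "p25", "p75"):
                    row[f"{tp}_{k}"] = summary.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def render_text(results: Sequence[ComparisonResult]) -> str:
    """Fixed-width text report with Baseline / Follow-up / p / effect size."""
    header = ("Variable", "Baseline", "Follow-up", "p-value",
              "Effect size (95% CI)")
    lines: list[tuple[str, ...]] = [header]
    for r in results:
        if r.error:
            lines.append((r.variable, "", "", "", f"FAILED: {r.error}"))
            continue
        lines.append((
            r.variable,
            _summary_str(r.baseline_summary),
            _summary_str(r.followup_summary),
            _fmt_p(r.p_value),
            _es_str(r),
        ))
        if r.baseline_summary and "levels" in r.baseline_summary:
            levels = r.baseline_summary["levels"]
            for lev in levels:
                b = r.baseline_summary["levels"].get(lev, {})
                f = (r.followup_summary.get("levels", {}) or {}).get(lev, {})
                lines.append((
                    f"  {lev}",
                    f"{b.get('n', 0)} ({_fmt(b.get('pct'), 1)})",
                    f"{f.get('n', 0)} ({_fmt(f.get('pct'), 1)})",
                    "", "",
                ))
    widths = [max(len(row[i]) for row in lines) for i in range(len(header))]
    out = []
    for j, row in enumerate(lines):
        out.append("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip())
        if j == 0:
            out.append("  ".join("-" * w for w in widths))
    return "\n".join(out) + "\n"
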