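"""Shape analysis outputs into report tables (CSV) plus full-precision JSON sidecars.

The CSV schemas mirror the conventional presentation: a baseline
characteristics table, a domain-score comparison table with a post hoc
column, and per-group regression tables reporting ``OR (95% CI)`` with
p-values.  The JSON sidecars carry unrounded estimates, CIs, p-values, group
sizes, and any degeneracy flags, so downstream consumers never have to parse
the display strings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .stats import GroupComparisonRow, PosthocResult, RegressionEffect

__all__ = [
    "comparison_frame",
    "posthoc_frame",
    "effects_frame",
    "write_table",
]


def _fmt_p(p: float) -> str:
    if p != p:  # nan
        return "—"
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0").replace("0.", ".")


def comparison_frame(rows: Sequence[GroupComparisonRow], posthoc: Sequence[PosthocResult] = ()) -> pd.DataFrame:
    """Group-comparison rows as a table, optionally with a post hoc column."""
    by_domain: dict[str, list[str]] = {}
    for ph in posthoc:
        by_domain.setdefault(ph.domain, []).append(f"{ph.direction} ({_fmt_p(ph.p_value)})")
    recs = []
    for r in rows:
        rec = {"variable": r.variable, **r.summaries, "test": r.test,
               "statistic": r.statistic, "p_value": r.p_value, "p_display": _fmt_p(r.p_value),
               "degenerate": r.degenerate}
        if posthoc:
            rec["posthoc"] = "; ".join(by_domain.get(r.variable, [])) or "—"
        recs.append(rec)
    return pd.DataFrame(recs)


def posthoc_frame(posthoc: Sequence[PosthocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"domain": p.domain, "group_a": p.pair[0], "group_b": p.pair[1],
             "direction": p.direction, "t_statistic": p.t_statistic, "p_value": p.p_value}
            for p in posthoc
        ]
    )


def effects_frame(effects: Sequence[RegressionEffect]) -> pd.DataFrame:
    """Regression effects with a display column like ``1.058 (1.006-1.114)``."""
    recs = []
    for e in effects:
        disp = (
            f"{e.or_or_hr:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f})"
            if e.or_or_hr is not None and e.or_or_hr == e.or_or_hr
            else (f"{e.estimate:.3f} ({e.ci_low:.3f}-{e.ci_high:.3f})" if e.estimate == e.estimate else "—")
        )
        recs.append({**dataclasses.asdict(e), "display": disp, "p_display": _fmt_p(e.p_value)})
    return pd.DataFrame(recs)


def write_table(df: pd.DataFrame, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a report CSV and, if given, its JSON sidecar next to it."""
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar is not None:
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, default=str)
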