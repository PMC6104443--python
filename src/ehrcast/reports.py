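"""Human-readable report rendering (parameter and milestone tables)."""

from __future__ import annotations

import pandas as pd

from .estimation import FitResult
from .forecasting import LeapfrogReport, MilestoneTable
from .generations import GenerationsModel

__all__ = ["parameter_table", "milestone_table_text", "leapfrog_text"]


def parameter_table(model: GenerationsModel) -> pd.DataFrame:
    """Rows M, p, q; one column per stage (the published table layout)."""
    cols = {f"Stage {s}": i for i, s in enumerate(model.stage_labels)}
    return pd.DataFrame(
        {
            name: [model.m[i], model.p[i], model.q[i]]
            for name, i in cols.items()
        },
        index=["M", "p", "q"],
    )


def fit_report_text(fit: FitResult) -> str:
    df = parameter_table(fit.model)
    lines = [
        df.to_string(float_format=lambda v: f"{v:.4g}"),
        "",
        f"SSE: {fit.sse:.4f}   adjusted R2: "
        + (f"{fit.adj_r2:.4f}" if fit.adj_r2 is not None else "undefined"),
        f"cells: {fit.n_obs}   free parameters: {fit.n_params}   "
        f"restarts: {fit.n_restarts_used}",
        "unconverged stages: "
        + (", ".join(str(s) for s, ok in fit.converged.items() if not ok) or "none"),
        "boundary estimates: "
        + (
            "; ".join(
                f"stage {s}: {','.join(names)}"
                for s, names in fit.boundary.items()
                if names
            )
            or "none"
        ),
    ]
    return "\n".join(lines)


def milestone_table_text(table: MilestoneTable) -> str:
    """Two milestone rows by stage columns, the published layout."""
    df = table.to_frame().set_index("stage")
    wide = pd.DataFrame(
        {
            f"Stage {s}": [
                df.loc[s, "mid_year"],
                df.loc[s, "max_year"],
                "yes" if df.loc[s, "peaked"] else "no",
                df.loc[s, "stall_count"],
            ]
            for s in df.index
        },
        index=["50% year", "max year", "peaked", "stall count"],
    )
    return wide.to_string(float_format=lambda v: f"{v:.0f}")


def leapfrog_text(report: LeapfrogReport) -> str:
    lines = ["Leapfrogging signals:"]
    for s, v in report.never_exceeds_predecessor.items():
        if v:
            lines.append(
                f"  stage {s}: occupancy never exceeds stage {s - 1}'s (flag A)"
            )
    for s, iv in report.cumulative_flat_while_successor_grows.items():
        if iv:
            lines.append(
                f"  stage {s}: cumulative flat over {iv[0]}-{iv[1]} while "
                f"stage {s + 1} grows (flag B)"
            )
    if len(lines) == 1:
        lines.append("  none detected")
    return "\n".join(lines)
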