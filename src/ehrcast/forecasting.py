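"""Forecasting, adoption milestones, stalling and leapfrogging signals.

Milestone conventions
---------------------
*Mid-point year* of a stage is defined on cumulative entrants: the
first grid year in which A_i (units that have ever reached stage >= i)
attains half of its value at the forecast horizon.  Occupancy of a
transient stage never approaches a stable total, so a cumulative
reading is the only one that is well defined for every stage; it also
allows a stage's mid-point to trail its occupancy peak, which happens
for early-launching generations with slow late-stage outflow.

*Max year* is the earliest grid year attaining the maximum occupancy
S_i; a stage "peaked" only if that year precedes the horizon and its
occupancy has strictly declined by the horizon.  A stage with no
successor has non-decreasing occupancy and therefore never peaks
before the horizon.

Launch-offset calibration
-------------------------
The source panel never reveals when each stage became adoptable, so
launch offsets are calibrated against per-stage mid-point anchor
years: for each stage a 1-D root search finds the offset at which the
model-implied (continuous-time) mid-point equals the anchor, sweeping
the stages Gauss--Seidel style until the offsets stop moving.  For
early stages the cumulative curve is dominated by later generations'
direct entrants and the anchor can be unreachable for every offset;
those stages fall back to anchoring the generation's own adoption
curve via the closed-form t50, and the residual mid-point discrepancy
is reported.  ``strict=True`` raises instead, listing the offending
stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bass import mid_time
from .generations import CurveSet, GenerationsModel, generations_curves
from .estimation import StageYearPanel

__all__ = [
    "MilestoneRow",
    "MilestoneTable",
    "LeapfrogReport",
    "CalibrationResult",
    "InfeasibleAnchorsError",
    "forecast",
    "milestones",
    "stall_counts",
    "detect_leapfrogging",
    "calibrate_launch_offsets",
]


class InfeasibleAnchorsError(ValueError):
    """Raised in strict calibration when anchors cannot be attained."""

    def __init__(self, stages: list[int]):
        self.stages = stages
        super().__init__(
            f"mid-point anchors unreachable for stages {stages} under the "
            "cumulative-entrants definition (typically early stages whose "
            "cumulative curve is dominated by later generations, or anchors "
            "ordered against the maturation ladder)"
        )


def forecast(model: GenerationsModel) -> CurveSet:
    """Evaluate the model on its annual calendar grid base..horizon."""
    years = np.arange(model.base_year, model.horizon_year + 1, dtype=float)
    return generations_curves(model, years)


@dataclass
class MilestoneRow:
    stage: int
    mid_year: int | None
    max_year: int | None
    peaked: bool | None
    stall_count: float | None


@dataclass
class MilestoneTable:
    rows: list[MilestoneRow]

    def row(self, stage: int) -> MilestoneRow:
        for r in self.rows:
            if r.stage == stage:
                return r
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "mid_year": r.mid_year,
                    "max_year": r.max_year,
                    "peaked": r.peaked,
                    "stall_count": r.stall_count,
                }
                for r in self.rows
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict("records"), indent=2))


def milestones(curves: CurveSet) -> MilestoneTable:
    """Extract per-stage mid-point / peak milestones from annual curves.

    A stage whose curves are identically zero gets a row of missing
    values rather than raising.
    """
    years = curves.years.astype(int)
    horizon = int(years[-1])
    rows = []
    for i, stage in enumerate(curves.stage_labels):
        S, A = curves.S[i], curves.A[i]
        if A[-1] <= 0.0:
            rows.append(MilestoneRow(stage, None, None, None, None))
            continue
        mid_year = int(years[np.argmax(A >= 0.5 * A[-1])])
        k = int(np.argmax(S))  # argmax returns the earliest maximizer
        max_year = int(years[k])
        peaked = bool(max_year < horizon and S[k] > S[-1])
        rows.append(MilestoneRow(stage, mid_year, max_year, peaked, float(S[-1])))
    return MilestoneTable(rows)


def stall_counts(curves: CurveSet, year: int) -> dict[int, float]:
    """Occupancy of every stage at ``year`` (must be on the grid)."""
    matches = np.nonzero(curves.years.astype(int) == int(year))[0]
    if matches.size == 0:
        raise ValueError(f"year {year} is not on the evaluated grid")
    k = int(matches[0])
    return {stage: float(curves.S[i, k]) for i, stage in enumerate(curves.stage_labels)}


# --------------------------------------------------------------------
# leapfrogging


@dataclass
class LeapfrogReport:
    """Per-stage leapfrogging signals.

    ``never_exceeds_predecessor[s]`` -- stage s's occupancy stays below
    its predecessor's maximum over the whole range (flag A): adopters
    passed through s too quickly for it to fill, or skipped it.

    ``cumulative_flat_while_successor_grows[s]`` -- a window over which
    cumulative entrants into stage s are flat while entrants into
    stage s+1 keep growing (flag B): new arrivals at s+1 cannot have
    come through s.  Value is the (start, end) year interval or None.
    """

    never_exceeds_predecessor: dict[int, bool]
    cumulative_flat_while_successor_grows: dict[int, tuple[int, int] | None]

    def flagged(self) -> list[int]:
        a = [s for s, v in self.never_exceeds_predecessor.items() if v]
        b = [s for s, v in self.cumulative_flat_while_successor_grows.items() if v]
        return sorted(set(a) | set(b))

    def to_dict(self) -> dict:
        return {
            "never_exceeds_predecessor": {
                str(k): bool(v) for k, v in self.never_exceeds_predecessor.items()
            },
            "cumulative_flat_while_successor_grows": {
                str(k): (list(v) if v else None)
                for k, v in self.cumulative_flat_while_successor_grows.items()
            },
        }


def _as_curves(panel_or_curves) -> tuple[np.ndarray, list[int], np.ndarray, np.ndarray]:
    if isinstance(panel_or_curves, CurveSet):
        c = panel_or_curves
        return c.years.astype(int), list(c.stage_labels), c.S, c.A
    panel: StageYearPanel = panel_or_curves
    return (
        panel.years.astype(int),
        list(panel.stage_labels),
        panel.counts,
        panel.stage_or_higher(),
    )


def detect_leapfrogging(
    panel_or_curves,
    *,
    eps: float = 0.01,
    window: int = 3,
) -> LeapfrogReport:
    """Flag stages whose curves show generation-skipping signatures.

    Works on observed panels and on model curve sets alike.  ``eps``
    is the per-year relative-growth threshold below which a cumulative
    curve counts as flat (default 1 %/year); ``window`` the minimum
    number of consecutive years (default 3).

    Raises on fewer than 2 stages or fewer than 2 years.
    """
    years, stages, S, A = _as_curves(panel_or_curves)
    if len(stages) < 2:
        raise ValueError("leapfrog detection needs at least 2 stages")
    if years.size < 2:
        raise ValueError("leapfrog detection needs at least 2 years")

    flag_a: dict[int, bool] = {}
    for i in range(1, len(stages)):
        flag_a[stages[i]] = bool(S[i].max() < S[i - 1].max())

    flag_b: dict[int, tuple[int, int] | None] = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        growth = np.where(A[:, :-1] > 0, np.diff(A, axis=1) / A[:, :-1], np.inf)
    # growth[i, k] is the relative growth of A_i from years[k] to years[k+1];
    # a year-step is "flat while successor grows" if stage i is below eps
    # while stage i+1 is above and has mass.
    for i in range(len(stages) - 1):
        ok = (growth[i] < eps) & (growth[i + 1] > eps) & (A[i + 1, :-1] > 0)
        run_start, best = None, None
        for k, v in enumerate(ok):
            if v and run_start is None:
                run_start = k
            if (not v or k == ok.size - 1) and run_start is not None:
                end = k if v else k - 1
                if years[end + 1] - years[run_start] + 1 >= window + 1:
                    best = (int(years[run_start]), int(years[end + 1]))
                    break
                run_start = None
        flag_b[stages[i]] = best
    flag_b[stages[-1]] = None
    return LeapfrogReport(flag_a, flag_b)


# --------------------------------------------------------------------
# launch-offset calibration


@dataclass
class CalibrationResult:
    """Calibrated offsets plus per-stage achieved-vs-anchor residuals."""

    tau: np.ndarray
    residual_years: dict[int, float]
    fallback_stages: list[int]

    def model(self, template: GenerationsModel) -> GenerationsModel:
        return template.replace(tau=self.tau)


def _mid_ratio_gap(model: GenerationsModel, i: int, anchor: float) -> float:
    """A_i(anchor) - 0.5 A_i(horizon); its root in tau_i places the
    continuous mid-point exactly at the anchor year."""
    grid = np.array([anchor, float(model.horizon_year)])
    c = generations_curves(model, grid)
    return float(c.A[i, 0] - 0.5 * c.A[i, 1])


def calibrate_launch_offsets(
    template: GenerationsModel,
    anchors: dict[int, float],
    *,
    strict: bool = False,
    max_sweeps: int = 50,
    tol: float = 1e-8,
) -> CalibrationResult:
    """Find per-stage launch offsets whose mid-point years hit anchors.

    Parameters
    ----------
    template : GenerationsModel
        Supplies (m, p, q) per stage, the base year and the horizon.
    anchors : mapping stage label -> anchor calendar year
        One anchor per stage is required.
    strict : bool
        Raise :class:`InfeasibleAnchorsError` if any stage's anchor is
        unreachable under the cumulative-entrants mid definition;
        otherwise those stages use the closed-form own-curve fallback
        tau = anchor - t50(p, q) and report a nonzero residual.

    Returns
    -------
    CalibrationResult
        Offsets are expressed in years relative to the base year.
    """
    labels = template.stage_labels
    missing = [s for s in labels if s not in anchors]
    if missing:
        raise ValueError(f"anchors missing for stages {missing}")
    anchor_vec = np.array([float(anchors[s]) for s in labels])
    n = len(labels)

    # start from the decoupled closed-form solution
    t50 = np.array([mid_time(g.params) for g in template.generations])
    tau_cal = anchor_vec - t50 - template.base_year
    fallback = set()

    lo = template.base_year - 50.0 + 1e-6
    model = template.replace(tau=tau_cal)
    for _ in range(max_sweeps):
        delta = 0.0
        for i in range(n):
            hi = float(model.horizon_year) - 1e-6

            def gap(tau_i: float) -> float:
                tt = model.tau.copy()
                tt[i] = tau_i
                return _mid_ratio_gap(model.replace(tau=tt), i, anchor_vec[i])

            g_lo, g_hi = gap(lo - template.base_year), gap(hi - template.base_year)
            if g_lo * g_hi > 0:
                fallback.add(labels[i])
                new = anchor_vec[i] - t50[i] - template.base_year
            else:
                fallback.discard(labels[i])
                new = brentq(
                    gap, lo - template.base_year, hi - template.base_year, xtol=1e-10
                )
            delta = max(delta, abs(new - model.tau[i]))
            tt = model.tau.copy()
            tt[i] = new
            model = model.replace(tau=tt)
        if delta < tol:
            break

    if strict and fallback:
        raise InfeasibleAnchorsError(sorted(fallback))

    # achieved (grid) mid-years vs anchors
    table = milestones(forecast(model))
    residuals = {
        s: (float(table.row(s).mid_year - anchors[s]) if table.row(s).mid_year else np.nan)
        for s in labels
    }
    return CalibrationResult(
        tau=model.tau, residual_years=residuals, fallback_stages=sorted(fallback)
    )
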