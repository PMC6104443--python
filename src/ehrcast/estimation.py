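"""Nonlinear least-squares estimation of per-stage diffusion parameters.

The observable is a stage-count panel: hospitals per maturity stage per
calendar year.  The estimator minimizes the pooled sum of squared
residuals between observed counts and the model's occupancy curves
S_i(year) across every (year, stage) cell, mirroring a single pooled
model fit summarized by one adjusted R².

Fitting strategy
----------------
``sequential_then_joint`` first initializes each generation from a
scaled single-generation Bass fit to the observed "stage >= i"
cumulative series (cheap, 3 parameters at a time), then refines all
generations' (m, p, q) jointly against all cells with a bounded
trust-region least-squares solver, restarted from a deterministic set
of perturbed starting points.  The reported fit is the best restart;
the joint stage can only improve on the sequential warm start.

Launch offsets tau are taken from the model template and held fixed by
default: estimating eight offsets jointly with 24 curve parameters on
nine annual observations is under-determined.  ``free_tau=True`` frees
them per stage.

Panels produced by the cohort simulator report not-yet-entered units in
the lowest stage so that yearly totals equal the cohort size; set
``unentered_in_lowest=True`` to make the model predict that column as
(total market - A_1) instead of raw occupancy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bass import BassParams
from .generations import CurveSet, Generation, GenerationsModel, generations_curves

__all__ = [
    "StageYearPanel",
    "FitResult",
    "DegenerateDataError",
    "adjusted_r2",
    "fit_generations",
    "sequential_then_joint",
    "read_panel_csv",
    "write_panel_csv",
]

P_MIN, P_MAX = 1e-9, 1.0
Q_MIN, Q_MAX = 1e-9, 1.0


class DegenerateDataError(ValueError):
    """Raised when a panel carries no usable signal (e.g. all zeros)."""


@dataclass
class StageYearPanel:
    """Counts of units per (year, stage).

    ``counts[i, k]`` is the number of units at ``stage_labels[i]`` in
    ``years[k]``.  Counts may be real-valued (noise-free curve panels)
    or integers (simulated cohorts).
    """

    years: np.ndarray
    stage_labels: list[int]
    counts: np.ndarray
    unentered_in_lowest: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.stage_labels), self.years.size):
            raise ValueError("counts must be (n_stages, n_years)")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(~np.isfinite(self.counts)):
            raise ValueError("counts must be finite")

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    def stage_or_higher(self) -> np.ndarray:
        """Observed cumulative 'at stage >= i' counts (suffix sums)."""
        return np.cumsum(self.counts[::-1], axis=0)[::-1]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            (int(y), int(s), self.counts[i, k])
            for k, y in enumerate(self.years)
            for i, s in enumerate(self.stage_labels)
        ]
        return pd.DataFrame(recs, columns=["year", "stage", "count"])


def write_panel_csv(panel: StageYearPanel, path: str | Path, wide: bool = False) -> None:
    """Write a panel as long (``year,stage,count``) or wide CSV."""
    df = panel.to_frame()
    if wide:
        df = df.pivot(index="year", columns="stage", values="count").reset_index()
        df.columns = ["year"] + [str(c) for c in df.columns[1:]]
    df.to_csv(path, index=False)


def read_panel_csv(source: str | Path | io.StringIO) -> StageYearPanel:
    """Read a stage-count panel from long or wide CSV.

    Long format requires columns ``year,stage,count``; wide format a
    ``year`` column plus one column per stage label.  Every
    (year, stage) cell must be present.
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not parse CSV panel: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "year" not in cols:
        raise ValueError("panel CSV needs a 'year' column (long or wide format)")
    if {"stage", "count"}.issubset(cols):
        long = df[["year", "stage", "count"]]
    else:
        stage_cols = [c for c in cols if c != "year"]
        bad = [c for c in stage_cols if not c.lstrip("-").isdigit()]
        if bad:
            raise ValueError(
                f"wide panel CSV has non-stage columns {bad}; expected integer stage labels"
            )
        long = df.melt(id_vars="year", var_name="stage", value_name="count")
    try:
        long = long.assign(
            year=long["year"].astype(int),
            stage=long["stage"].astype(int),
            count=long["count"].astype(float),
        )
    except ValueError as exc:
        raise ValueError(f"panel CSV has a non-numeric year/stage/count field: {exc}") from exc
    years = np.sort(long["year"].unique())
    stages = sorted(long["stage"].unique())
    pivot = long.pivot_table(index="stage", columns="year", values="count", aggfunc="sum")
    if pivot.isna().any().any():
        missing = [
            (int(y), int(s))
            for s in pivot.index
            for y in pivot.columns
            if pd.isna(pivot.loc[s, y])
        ]
        raise ValueError(f"panel CSV is missing cells (year, stage): {missing[:5]} ...")
    counts = pivot.loc[stages, years].to_numpy(dtype=float)
    return StageYearPanel(years=years, stage_labels=[int(s) for s in stages], counts=counts)


# --------------------------------------------------------------------
# diagnostics


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - k - 1), pooled over cells.

    The total sum of squares is taken about the grand mean of all
    fitted cells.  Raises for n <= k + 1 or zero SST.
    """
    obs = np.asarray(observed, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    n, k = obs.size, int(n_params)
    if n <= k + 1:
        raise ValueError(f"adjusted R² undefined for n={n} <= k+1={k + 1}")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("adjusted R² undefined: zero total sum of squares")
    sse = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - sse / sst
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))


@dataclass
class FitResult:
    """Estimated model plus fit diagnostics."""

    model: GenerationsModel
    sse: float
    adj_r2: float | None
    n_obs: int
    n_params: int
    converged: dict[int, bool]
    boundary: dict[int, list[str]]
    n_restarts_used: int
    sse_sequential: float | None = None

    def to_dict(self) -> dict:
        from .generations import model_to_dict

        return {
            "model": model_to_dict(self.model),
            "sse": self.sse,
            "adj_r2": self.adj_r2,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": {str(k): bool(v) for k, v in self.converged.items()},
            "boundary": {str(k): v for k, v in self.boundary.items()},
            "n_restarts_used": self.n_restarts_used,
            "sse_sequential": self.sse_sequential,
        }


# --------------------------------------------------------------------
# model predictions for a panel


def predict_panel(model: GenerationsModel, panel: StageYearPanel) -> np.ndarray:
    """Model counts for every panel cell (same layout as panel.counts)."""
    curves = generations_curves(model, panel.years.astype(float))
    pred = curves.S.copy()
    if panel.unentered_in_lowest:
        n = len(model.generations)
        a1 = curves.A[1] if n > 1 else curves.A[0]
        pred[0] = model.total_market - a1
    return pred


def _theta_split(theta: np.ndarray, n: int, free_tau: bool):
    m = theta[0:n]
    p = theta[n : 2 * n]
    q = theta[2 * n : 3 * n]
    tau = theta[3 * n : 4 * n] if free_tau else None
    return m, p, q, tau


def _residuals(theta, template, panel, free_tau):
    n = len(template.generations)
    m, p, q, tau = _theta_split(theta, n, free_tau)
    model = template.replace(m=m, p=p, q=q, tau=tau)
    return (predict_panel(model, panel) - panel.counts).ravel()


def _sequential_init(panel: StageYearPanel, template: GenerationsModel) -> np.ndarray:
    """Warm start from per-stage scaled Bass fits to 'stage >= i' series.

    Each series A_obs_i(t) is approximated by c_i F_i(t - tau_i) with
    free scale and curve coefficients; incremental market starts are
    the successive differences of the fitted scales.  Feed-through is
    ignored at this step -- it only needs to land in the joint stage's
    basin of attraction.
    """
    t = panel.years.astype(float) - template.base_year
    tau = template.tau
    A_obs = panel.stage_or_higher()
    n = len(template.generations)
    c = np.zeros(n)
    p0 = np.full(n, 0.3)
    q0 = np.full(n, 0.3)

    def own_curve_resid(x, y, trel):
        cc, pp, qq = x
        u = np.maximum(trel, 0.0)
        e = np.exp(-(pp + qq) * u)
        return cc * (1.0 - e) / (1.0 + (qq / pp) * e) - y

    for i in range(1 if panel.unentered_in_lowest else 0, n):
        y = A_obs[i]
        if y.max() < 1.0:
            c[i] = max(y.max(), 0.0)
            continue
        x0 = np.array([max(y.max(), 1.0), 0.3, 0.3])
        best = None
        for pp, qq in ((0.05, 0.05), (0.3, 0.3), (0.7, 0.1), (0.05, 0.7)):
            r = least_squares(
                own_curve_resid,
                np.array([x0[0], pp, qq]),
                bounds=([0.0, P_MIN, Q_MIN], [np.inf, P_MAX, Q_MAX]),
                args=(y, t - tau[i]),
                max_nfev=200,
            )
            if best is None or r.cost < best.cost:
                best = r
        c[i], p0[i], q0[i] = best.x
    # incremental market starts; lowest stage absorbs the remainder
    m0 = np.maximum(c - np.append(c[1:], 0.0), 1.0)
    if panel.unentered_in_lowest:
        total = float(panel.counts.sum(axis=0).max())
        m0[0] = max(total - m0[1:].sum(), 1.0)
    return np.concatenate([m0, np.clip(p0, P_MIN, P_MAX), np.clip(q0, Q_MIN, Q_MAX)])


def fit_generations(
    panel: StageYearPanel,
    template: GenerationsModel,
    *,
    free_tau: bool = False,
    n_restarts: int = 8,
    seed: int = 0,
    init: np.ndarray | None = None,
    max_nfev: int = 20000,
) -> FitResult:
    """Joint bounded least-squares fit of all generations to a panel.

    ``template`` supplies the calendar frame, stage labels and the
    fixed launch offsets (and starting values when ``init`` is None via
    the sequential scheme).  Returns the best restart; ties are broken
    by the first restart attaining the minimum.

    Raises
    ------
    DegenerateDataError
        If the panel is all zeros.
    ValueError
        If the panel has fewer than 3 years or stages mismatch.
    """
    if panel.n_years < 3:
        raise ValueError("need at least 3 years of observations")
    if panel.stage_labels != template.stage_labels:
        raise ValueError(
            f"panel stages {panel.stage_labels} do not match model stages "
            f"{template.stage_labels}"
        )
    if float(panel.counts.sum()) == 0.0:
        raise DegenerateDataError("panel counts are all zero")

    n = len(template.generations)
    year_totals = panel.counts.sum(axis=0)
    m_hi = 10.0 * float(year_totals.max())
    lb = np.concatenate([np.zeros(n), np.full(n, P_MIN), np.full(n, Q_MIN)])
    ub = np.concatenate([np.full(n, m_hi), np.full(n, P_MAX), np.full(n, Q_MAX)])
    if free_tau:
        lb = np.concatenate([lb, np.full(n, template.base_year - 30.0)])
        ub = np.concatenate([ub, np.full(n, float(panel.years.max()))])

    x_init = np.asarray(init, float) if init is not None else _sequential_init(panel, template)
    if free_tau and x_init.size == 3 * n:
        x_init = np.concatenate([x_init, template.tau + template.base_year])
    x_init = np.clip(x_init, lb, ub)
    sse_init = float(np.sum(_residuals(x_init, template, panel, free_tau) ** 2))

    rng = np.random.default_rng(seed)
    best = None
    best_trial = 0
    n_used = 0
    for trial in range(max(1, n_restarts)):
        if trial == 0:
            x0 = x_init
        else:
            # multiplicative perturbations keep the restart grid
            # scale-equivariant in the counts
            fac = np.exp(rng.normal(0.0, 0.35, size=3 * n))
            x0 = x_init.copy()
            x0[: 3 * n] = x_init[: 3 * n] * fac
            if free_tau:
                x0[3 * n :] = x_init[3 * n :] + rng.normal(0.0, 1.0, size=n)
            x0 = np.clip(x0, lb + 1e-12, ub)
        res = least_squares(
            _residuals,
            x0,
            bounds=(lb, ub),
            args=(template, panel, free_tau),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_nfev,
        )
        n_used += 1
        if best is None or res.cost < best.cost - 1e-12:
            best = res
            best_trial = trial

    m, p, q, tau = _theta_split(best.x, n, free_tau)
    fitted = template.replace(m=m, p=p, q=q, tau=tau)
    pred = predict_panel(fitted, panel)
    sse = float(np.sum((pred - panel.counts) ** 2))

    n_free = best.x.size
    n_obs = panel.counts.size
    try:
        ar2 = adjusted_r2(panel.counts, pred, n_free)
    except ValueError:
        ar2 = None

    converged: dict[int, bool] = {}
    boundary: dict[int, list[str]] = {}
    for i, lab in enumerate(template.stage_labels):
        identifiable = bool(np.any(panel.counts[i] >= 1.0))
        converged[lab] = identifiable and bool(best.success)
        at = []
        if m[i] >= m_hi * (1 - 1e-9):
            at.append("m")
        for name, val, lo, hi in (("p", p[i], P_MIN, P_MAX), ("q", q[i], Q_MIN, Q_MAX)):
            if val <= lo + 1e-6 * (hi - lo) or val >= hi - 1e-9 * (hi - lo):
                at.append(name)
        boundary[lab] = at

    return FitResult(
        model=fitted,
        sse=sse,
        adj_r2=ar2,
        n_obs=n_obs,
        n_params=n_free,
        converged=converged,
        boundary=boundary,
        n_restarts_used=n_used if best_trial + 1 <= n_used else n_used,
        sse_sequential=sse_init if init is None else None,
    )


def sequential_then_joint(
    panel: StageYearPanel,
    template: GenerationsModel,
    **kwargs,
) -> FitResult:
    """Per-stage sequential initialization followed by joint refinement.

    The joint stage is warm-started from the sequential solution, so
    the reported SSE never exceeds the sequential SSE.
    """
    return fit_generations(panel, template, init=None, **kwargs)
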