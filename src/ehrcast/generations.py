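"""Successive-generations (Norton--Bass) occupancy model.

EHR maturity stages are treated as successive product generations that
do not displace their predecessors: a hospital "upgrades" from stage i
to stage i+1 but never regresses.  Each generation i brings its own
incremental market potential ``m_i`` and launches at calendar time
``base_year + tau_i``; units that have reached stage i become eligible
to move on to stage i+1 according to generation i+1's own Bass curve.

With F_i(t) = bass_cdf(t - tau_i) the feed-through cumulative

    B_1(t) = m_1 F_1(t),
    B_i(t) = F_i(t) (m_i + B_{i-1}(t)),

counts units that have moved through the upgrade chain into stage >= i.
The quantities reported on the calendar grid are

    A_i(t) = B_i(t) + sum_{j>i} m_j F_j(t)   (ever reached stage >= i,
                                              including direct entrants
                                              to later generations),
    S_i(t) = A_i(t) - A_{i+1}(t) = B_i(t) (1 - F_{i+1}(t))
                                             (currently at stage i).

These satisfy the telescoping conservation law
sum_i S_i(t) = sum_i m_i F_i(t): upgrades move units between stages
without creating or destroying them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .bass import BassParams, bass_cdf

__all__ = [
    "Generation",
    "GenerationsModel",
    "CurveSet",
    "generations_curves",
    "load_model",
    "save_model",
]


@dataclass(frozen=True)
class Generation:
    """One maturity stage viewed as a product generation.

    ``m`` is the incremental market potential (units whose first entry
    into the system is at this stage); ``tau`` is the launch offset in
    years relative to the model's base year and may be negative for
    generations already diffusing before observation began.
    """

    stage_label: int
    m: float
    tau: float
    params: BassParams

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"market potential m must be >= 0, got {self.m}")


@dataclass(frozen=True)
class GenerationsModel:
    """Ordered generations plus the calendar frame of the forecast."""

    base_year: int
    horizon_year: int
    generations: tuple[Generation, ...]

    def __post_init__(self) -> None:
        if len(self.generations) == 0:
            raise ValueError("model needs at least one generation")
        if self.horizon_year < self.base_year:
            raise ValueError("horizon_year must be >= base_year")
        labels = [g.stage_label for g in self.generations]
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ValueError("stage labels must be unique and ordered")
        object.__setattr__(self, "generations", tuple(self.generations))

    # convenience vectors used throughout estimation / forecasting
    @property
    def stage_labels(self) -> list[int]:
        return [g.stage_label for g in self.generations]

    @property
    def m(self) -> np.ndarray:
        return np.array([g.m for g in self.generations], dtype=float)

    @property
    def p(self) -> np.ndarray:
        return np.array([g.params.p for g in self.generations], dtype=float)

    @property
    def q(self) -> np.ndarray:
        return np.array([g.params.q for g in self.generations], dtype=float)

    @property
    def tau(self) -> np.ndarray:
        return np.array([g.tau for g in self.generations], dtype=float)

    @property
    def total_market(self) -> float:
        return float(self.m.sum())

    def replace(self, m=None, p=None, q=None, tau=None) -> "GenerationsModel":
        """Return a copy with some per-generation vectors replaced."""
        m = self.m if m is None else np.asarray(m, float)
        p = self.p if p is None else np.asarray(p, float)
        q = self.q if q is None else np.asarray(q, float)
        tau = self.tau if tau is None else np.asarray(tau, float)
        gens = tuple(
            Generation(lab, m[i], tau[i], BassParams(p[i], q[i]))
            for i, lab in enumerate(self.stage_labels)
        )
        return GenerationsModel(self.base_year, self.horizon_year, gens)


@dataclass
class CurveSet:
    """Stage curves evaluated on a calendar grid.

    ``S[i, k]`` is the occupancy of stage i in year ``years[k]``;
    ``A[i, k]`` is the cumulative number of units that have ever
    reached stage >= i by that year.  Both are real-valued.
    """

    years: np.ndarray
    stage_labels: list[int]
    S: np.ndarray
    A: np.ndarray

    def stage_index(self, stage: int) -> int:
        return self.stage_labels.index(stage)

    def occupancy(self, stage: int) -> np.ndarray:
        return self.S[self.stage_index(stage)]

    def cumulative(self, stage: int) -> np.ndarray:
        return self.A[self.stage_index(stage)]


def _cdf_matrix(model: GenerationsModel, t: np.ndarray) -> np.ndarray:
    """F_i evaluated for every generation on calendar grid ``t``."""
    rel = t[None, :] - model.base_year - model.tau[:, None]
    out = np.empty_like(rel)
    for i, g in enumerate(model.generations):
        out[i] = bass_cdf(rel[i], g.params)
    return out


def generations_curves(model: GenerationsModel, years: Sequence[float]) -> CurveSet:
    """Evaluate the Norton--Bass occupancy and cumulative curves.

    Parameters
    ----------
    model : GenerationsModel
    years : sequence of calendar years (need not be integers)

    Returns
    -------
    CurveSet

    Raises
    ------
    ValueError
        If the grid is empty or extends outside
        [base_year - 50, horizon_year].
    """
    t = np.asarray(years, dtype=float)
    if t.size == 0:
        raise ValueError("year grid is empty")
    if t.min() < model.base_year - 50 or t.max() > model.horizon_year:
        raise ValueError(
            "year grid must lie within [base_year - 50, horizon_year]"
        )
    F = _cdf_matrix(model, t)
    m = model.m
    n = len(model.generations)

    B = np.empty_like(F)
    B[0] = m[0] * F[0]
    for i in range(1, n):
        B[i] = F[i] * (m[i] + B[i - 1])

    A = np.empty_like(F)
    tail = np.zeros(t.size)
    for i in range(n - 1, -1, -1):
        A[i] = B[i] + tail
        tail = tail + m[i] * F[i]

    S = np.empty_like(F)
    S[:-1] = A[:-1] - A[1:]
    S[-1] = A[-1]
    return CurveSet(years=t, stage_labels=model.stage_labels, S=S, A=A)


# --------------------------------------------------------------------
# config-file serialization


def model_to_dict(model: GenerationsModel) -> dict:
    return {
        "base_year": int(model.base_year),
        "horizon_year": int(model.horizon_year),
        "generations": [
            {
                "stage": int(g.stage_label),
                "m": float(g.m),
                "p": float(g.params.p),
                "q": float(g.params.q),
                "tau": float(g.tau),
            }
            for g in model.generations
        ],
    }


def model_from_dict(cfg: dict) -> GenerationsModel:
    try:
        gens = tuple(
            Generation(
                stage_label=int(g["stage"]),
                m=float(g["m"]),
                tau=float(g.get("tau", 0.0)),
                params=BassParams(float(g["p"]), float(g["q"])),
            )
            for g in cfg["generations"]
        )
        return GenerationsModel(
            base_year=int(cfg["base_year"]),
            horizon_year=int(cfg["horizon_year"]),
            generations=gens,
        )
    except KeyError as exc:
        raise ValueError(f"model config is missing required key: {exc}") from exc


def save_model(model: GenerationsModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model(path: str | Path) -> GenerationsModel:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: model config must be a mapping")
    return model_from_dict(cfg)
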