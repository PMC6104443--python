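"""Synthetic EMRAM-like hospital cohorts.

The real survey data behind staged-EHR diffusion studies is
proprietary; this module generates panels with the statistical
structure that estimation and forecasting assume, so the whole
pipeline is testable offline.

Two generating modes are provided:

* ``deterministic`` -- the aggregate occupancy curves of a generations
  model are scaled to the cohort size and integerized with
  largest-remainder rounding, so the aggregate panel equals the model
  exactly up to rounding; hospital-level trajectories are assigned by
  rank against the "stage >= i" cumulative curves, which are
  non-decreasing in time, making every trajectory monotone by
  construction.  Used for estimator-correctness (parameter recovery)
  experiments.

* ``stochastic`` -- each hospital advances stage-by-stage with an
  annual upgrade probability 1 - exp(-(p_j + q_j F_j(t - tau_j)))
  toward the next generation j, chained within a year so that a
  hospital can climb several stages at once (leapfrogging).  The
  hazard micro-model is an approximation to the aggregate recursion
  (exact for a single generation); used for robustness experiments.

Hospitals that have not yet entered any generation are reported at the
lowest stage -- an EMRAM cohort has no state below Stage 0 -- so yearly
panel totals always equal the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bass import bass_cdf
from .estimation import StageYearPanel
from .generations import GenerationsModel, generations_curves

__all__ = [
    "CohortSpec",
    "simulate_panel",
    "add_observation_noise",
    "trajectories_to_frame",
    "write_trajectories_csv",
]


@dataclass
class CohortSpec:
    """Conditions of a simulated hospital cohort.

    Defaults emulate the published study's scale: roughly 5200 US
    hospitals observed annually from 2006 to 2014.
    """

    model: GenerationsModel
    n_units: int = 5200
    first_year: int = 2006
    last_year: int = 2014
    mode: str = "deterministic"
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")
        if self.noise < 0:
            raise ValueError("noise sd must be >= 0")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.model.total_market <= 0:
            raise ValueError("model has zero total market")


def _largest_remainder(v: np.ndarray, total: int) -> np.ndarray:
    """Integerize non-negative ``v`` (summing to ``total``) preserving
    the total exactly; ties broken deterministically by index."""
    fl = np.floor(v)
    k = int(round(total - fl.sum()))
    order = np.lexsort((np.arange(v.size), -(v - fl)))
    out = fl.astype(int)
    out[order[:k]] += 1
    return out


def _deterministic_counts(spec: CohortSpec, years: np.ndarray) -> np.ndarray:
    model = spec.model
    curves = generations_curves(model, years.astype(float))
    mtot = model.total_market
    n_st = len(model.stage_labels)
    scale = spec.n_units / mtot
    counts = np.zeros((n_st, years.size), dtype=int)
    for k in range(years.size):
        v = curves.S[:, k].copy()
        # not-yet-entered units are observationally at the lowest stage
        v[0] += mtot - curves.A[0, k]
        counts[:, k] = _largest_remainder(np.maximum(v, 0.0) * scale, spec.n_units)
    # rank thresholds K[i] = units at stage >= i must be non-decreasing in
    # time (cumulative entrants never leave); largest-remainder rounding can
    # break that by one unit in rare ties, so repair monotonically.
    K = np.cumsum(counts[::-1], axis=0)[::-1]
    K = np.maximum.accumulate(K, axis=1)
    K = np.maximum.accumulate(K[::-1], axis=0)[::-1]  # keep K non-increasing in stage
    K[0] = spec.n_units
    counts = (K - np.vstack([K[1:], np.zeros((1, years.size), dtype=int)])).astype(int)
    return counts


def _stochastic_counts(spec: CohortSpec, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-level chained-hazard simulation.

    Each unit belongs to a home generation, allocated in proportion to
    the incremental market potentials (a unit from generation g's own
    market enters the system at stage g).  A unit that has entered
    generation j attempts generation j+1 each year with probability
    1 - exp(-(p_{j+1} + q_{j+1} F_{j+1})), the hazard evaluated at the
    step midpoint; draws are chained within a year so a unit can climb
    several stages at once.  In expectation the aggregate reproduces
    the Norton--Bass recursion (exactly for a single generation, up to
    the annual-hazard discretization for coupled generations).

    The hazard clock of every generation runs from its launch for all
    units alike (a unit that reaches stage j late has accumulated
    upgrade propensity it expresses immediately), which is realized by
    per-unit uniform thresholds: home-h unit has entered generation g
    >= h in year t iff u_j <= F_j(t - tau_j) for every j in h..g.  The
    implied per-year upgrade probability among units not yet moved is
    1 - exp(-integral of (p_j + q_j F_j)), i.e. exactly the Bass
    hazard, and several thresholds crossed in one year produce a
    multi-stage climb (leapfrogging).
    """
    model = spec.model
    rng = np.random.default_rng(spec.seed)
    n_gen = len(model.generations)
    tau = model.tau
    F_tab = np.array(
        [
            bass_cdf(years.astype(float) - model.base_year - tau[j], g.params)
            for j, g in enumerate(model.generations)
        ]
    )  # (n_gen, n_years)

    home = np.repeat(
        np.arange(n_gen),
        _largest_remainder(model.m * spec.n_units / model.total_market, spec.n_units),
    )
    u = rng.random((spec.n_units, n_gen))
    # crossed[i, j, k]: unit i's threshold for generation j crossed by year k
    crossed = u[:, :, None] <= F_tab[None, :, :]
    # eligibility is chained from the home generation upward
    gens = np.arange(n_gen)
    below_home = gens[None, :] < home[:, None]
    chain = np.logical_or(crossed, below_home[:, :, None])
    entered_upto = np.cumprod(chain, axis=1).astype(bool)  # all of h..j crossed
    entered = np.logical_and(entered_upto, ~below_home[:, :, None])
    n_entered = entered.sum(axis=1)  # (units, years)
    state = np.where(n_entered > 0, home[:, None] + n_entered - 1, -1)  # -1 = not entered
    labels = np.array(model.stage_labels)
    stages = labels[np.maximum(state, 0)]  # un-entered observed at lowest stage
    counts = np.zeros((len(labels), years.size), dtype=int)
    for i, lab in enumerate(labels):
        counts[i] = (stages == lab).sum(axis=0)
    return counts, stages  # stages: (units, years)


def simulate_panel(spec: CohortSpec) -> tuple[pd.DataFrame, StageYearPanel]:
    """Simulate hospital trajectories and the aggregate stage panel.

    Returns
    -------
    trajectories : DataFrame with columns unit_id, year, stage
        Every unit's stage path; stages are non-decreasing over years.
    panel : StageYearPanel
        Aggregate counts; every yearly total equals ``spec.n_units``.
    """
    model = spec.model
    years = np.arange(spec.first_year, spec.last_year + 1)
    if years.min() < model.base_year - 50 or years.max() > model.horizon_year:
        raise ValueError("cohort years outside the model's calendar range")

    if spec.mode == "deterministic":
        counts = _deterministic_counts(spec, years)
        K = np.cumsum(counts[::-1], axis=0)[::-1]
        ranks = np.arange(1, spec.n_units + 1)[:, None]  # (units, 1)
        # unit r is at the highest stage i with K[i] >= r
        level = (K[None, :, :] >= ranks[:, :, None]).sum(axis=1) - 1  # (units, years)
        stages = np.array(model.stage_labels)[level]
    else:
        counts, stages = _stochastic_counts(spec, years)

    panel = StageYearPanel(
        years=years,
        stage_labels=list(model.stage_labels),
        counts=counts.astype(float),
        unentered_in_lowest=True,
    )
    if spec.noise > 0:
        panel = add_observation_noise(panel, spec.noise, spec.seed + 1)

    n_units, n_years = stages.shape
    traj = pd.DataFrame(
        {
            "unit_id": np.repeat(np.arange(n_units), n_years),
            "year": np.tile(years, n_units),
            "stage": stages.ravel(),
        }
    )
    return traj, panel


def add_observation_noise(panel: StageYearPanel, sd: float, seed: int) -> StageYearPanel:
    """Multiplicative observation noise on counts.

    Each cell is scaled by (1 + N(0, sd)), clipped at zero and rounded
    to whole units.  ``sd = 0`` returns the panel unchanged.
    """
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return panel
    rng = np.random.default_rng(seed)
    noisy = np.round(np.maximum(panel.counts * (1.0 + rng.normal(0.0, sd, panel.counts.shape)), 0.0))
    return StageYearPanel(
        years=panel.years,
        stage_labels=list(panel.stage_labels),
        counts=noisy,
        unentered_in_lowest=panel.unentered_in_lowest,
    )


def trajectories_to_frame(traj: pd.DataFrame) -> pd.DataFrame:
    return traj


def write_trajectories_csv(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)
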