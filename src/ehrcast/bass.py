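"""Single-generation Bass diffusion curves in closed form.

The Bass model describes the diffusion of an innovation through a fixed
population of eventual adopters.  The cumulative adopted fraction F(t)
obeys

    dF/dt = (p + q F) (1 - F),        F(0) = 0,

where ``p`` (1/year) is the external-influence ("innovation")
coefficient -- adoption pressure independent of how many peers have
adopted -- and ``q`` (1/year) is the internal-influence ("imitation")
coefficient, the word-of-mouth term.  The solution is the familiar
S-curve

    F(t) = (1 - exp(-(p+q) t)) / (1 + (q/p) exp(-(p+q) t)),

with F identically 0 before launch (t <= 0).  All functions here accept
scalar or array ``t`` and are the exact closed forms; no numerical
integration is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BassParams",
    "InvalidParameterError",
    "bass_cdf",
    "bass_rate",
    "peak_time",
    "mid_time",
]


class InvalidParameterError(ValueError):
    """Raised when Bass coefficients are outside their admissible range."""


@dataclass(frozen=True)
class BassParams:
    """Bass diffusion coefficients for one generation.

    Parameters
    ----------
    p : float
        External-motivation (innovation) coefficient, 1/year.
        Must satisfy 0 < p <= 1.
    q : float
        Internal-motivation (imitation) coefficient, 1/year.
        Must satisfy 0 <= q <= 1.

    Notes
    -----
    ``p = 0`` is rejected: without external influence the curve never
    leaves zero.  ``q = 0`` is a valid limit and reduces the model to
    exponential first-purchase adoption 1 - exp(-p t); the closed forms
    used here contain no division by ``q``, so the limit is exact.
    """

    p: float
    q: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.p) or self.p <= 0.0:
            raise InvalidParameterError(f"p must be positive, got {self.p!r}")
        if self.p > 1.0:
            raise InvalidParameterError(f"p must be <= 1, got {self.p!r}")
        if not np.isfinite(self.q) or self.q < 0.0:
            raise InvalidParameterError(f"q must be >= 0, got {self.q!r}")
        if self.q > 1.0:
            raise InvalidParameterError(f"q must be <= 1, got {self.q!r}")


def bass_cdf(t, params: BassParams):
    """Cumulative adopted fraction F(t) since launch.

    ``t`` is time in years since the generation's launch; negative
    times (pre-launch) return 0.  Returns a scalar for scalar input,
    else an ndarray.
    """
    p, q = params.p, params.q
    tt = np.asarray(t, dtype=float)
    u = np.maximum(tt, 0.0)
    e = np.exp(-(p + q) * u)
    out = (1.0 - e) / (1.0 + (q / p) * e)
    if np.ndim(t) == 0:
        return float(out)
    return out


def bass_rate(t, params: BassParams):
    """Instantaneous adoption rate f(t) = dF/dt = (p + qF)(1 - F).

    Zero before launch; equals ``p`` at the launch instant.
    """
    tt = np.asarray(t, dtype=float)
    F = np.asarray(bass_cdf(tt, params))
    out = (params.p + params.q * F) * (1.0 - F)
    out = np.where(tt < 0.0, 0.0, out)
    if np.ndim(t) == 0:
        return float(out)
    return out


def peak_time(params: BassParams):
    """Time of the interior adoption-rate maximum, or ``None``.

    The rate f(t) has an interior maximum at t* = ln(q/p)/(p+q) when
    q > p.  When q < p the rate is maximal at launch and decays, so no
    interior peak exists and ``None`` is returned.  The boundary q == p
    gives t* = 0 (returned as 0.0, the degenerate "peak at launch").
    """
    p, q = params.p, params.q
    if q < p:
        return None
    return float(np.log(q / p) / (p + q))


def mid_time(params: BassParams) -> float:
    """Time t50 at which F reaches one half: ln(2 + q/p)/(p+q).

    For q = 0 this is the exponential half-life ln(2)/p.  Always
    defined since p > 0.
    """
    p, q = params.p, params.q
    return float(np.log(2.0 + q / p) / (p + q))
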