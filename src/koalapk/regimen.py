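"""Multiple-dose reasoning: accumulation, steady state, superposition and
time inside a therapeutic concentration window.

The study regimen is one oral 15 mg/kg dose followed, 24 h later, by the
same dose every 12 h on five occasions (doses at 0, 24, 36, 48, 60, 72 h).
The accumulation factor (1 - e^(-n k tau)) / (1 - e^(-k tau)) compares
exposure after the n-th repeated dose with a single dose; the therapeutic
window defaults to the 4-20 ug/mL range suggested for analgesia in humans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, ValidationError
from .synthetic import SimulationParams, bateman

__all__ = [
    "DoseRegimen",
    "TherapeuticWindow",
    "accumulation_factor",
    "time_to_steady_state",
    "superpose",
    "time_in_window",
]


@dataclass(frozen=True)
class DoseRegimen:
    """Dose amount, route and dosing times for superposition."""

    dose: float  # mg/kg
    route: str
    dose_times: tuple[float, ...]
    tau: float  # h, inter-dose interval of the regular part

    def __post_init__(self) -> None:
        if not self.dose_times:
            raise ValidationError("dose_times must be non-empty")
        if self.dose_times[0] != 0:
            raise ValidationError("first dose must be at t = 0")
        if any(b <= a for a, b in zip(self.dose_times, self.dose_times[1:])):
            raise ValidationError("dose_times must be strictly increasing")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.dose <= 0:
            raise ValidationError("dose must be positive")
        object.__setattr__(self, "dose_times", tuple(float(t) for t in self.dose_times))

    @classmethod
    def study_regimen(cls, dose: float = 15.0, route: str = "oral") -> "DoseRegimen":
        """The published koala regimen: dose at 0, then every 12 h from 24 h."""
        return cls(dose=dose, route=route, dose_times=(0, 24, 36, 48, 60, 72), tau=12.0)


@dataclass(frozen=True)
class TherapeuticWindow:
    """Closed concentration interval regarded as therapeutic (ug/mL)."""

    low: float = 4.0
    high: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValidationError("require 0 < low < high")


def accumulation_factor(ke: float, tau: float, n: int) -> float:
    """(1 - e^(-n ke tau)) / (1 - e^(-ke tau)).

    Equals 1 at n = 1, is non-decreasing in n, and tends to
    1/(1 - e^(-ke tau)) at steady state.
    """
    if ke <= 0 or tau <= 0:
        raise ValidationError("ke and tau must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    x = math.exp(-ke * tau)
    return (1.0 - x**n) / (1.0 - x)


def time_to_steady_state(t_half: float, n_half_lives: int = 5) -> float:
    """Rule-of-thumb time to steady state: n half-lives (default 5)."""
    if t_half <= 0:
        raise ValidationError("t_half must be positive")
    if n_half_lives < 1:
        raise ValidationError("n_half_lives must be >= 1")
    return n_half_lives * t_half


def superpose(
    regimen: DoseRegimen,
    ka: float,
    ke: float,
    scale: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Multiple-dose concentration curve by linear superposition.

    Each dose contributes a Bateman curve shifted to its dose time (zero
    before it); the result is linear in ``scale``.
    """
    if ka <= 0 or ke <= 0:
        raise ValidationError("ka and ke must be positive")
    if ka == ke:
        raise DegenerateModelError("ka == ke: superposition model is degenerate")
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("t_grid must be sorted")
    p = SimulationParams(scale=scale, ka=ka, ke=ke, cv=0.0)
    total = np.zeros_like(t)
    for td in regimen.dose_times:
        total += bateman(t - td, p)
    return total


def _crossings(t1, c1, t2, c2, bound, log_interp):
    """Time where the interpolant crosses ``bound`` inside [t1, t2]."""
    if log_interp and c1 > 0 and c2 > 0 and c1 != c2:
        return t1 + (t2 - t1) * math.log(bound / c1) / math.log(c2 / c1)
    return t1 + (t2 - t1) * (bound - c1) / (c2 - c1)


def time_in_window(
    times: np.ndarray,
    concentrations: np.ndarray,
    window: TherapeuticWindow = TherapeuticWindow(),
    log_falling: bool = False,
) -> float:
    """Total time (h) the curve spends inside the closed window.

    Crossing times are located by linear interpolation between bracketing
    samples; with ``log_falling`` the interpolation is exponential on
    strictly decreasing positive segments instead.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2 or c.shape != t.shape:
        raise ValidationError("need >= 2 aligned samples")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    lo, hi = window.low, window.high
    total = 0.0
    for i in range(t.size - 1):
        t1, t2 = t[i], t[i + 1]
        c1, c2 = c[i], c[i + 1]
        if c1 == c2:
            total += (t2 - t1) if lo <= c1 <= hi else 0.0
            continue
        use_log = log_falling and c2 < c1 and c1 > 0 and c2 > 0
        # the interpolant is monotone, so the in-window sub-interval is the
        # pre-image of [lo, hi] clipped to the segment
        ta = _crossings(t1, c1, t2, c2, lo, use_log)
        tb = _crossings(t1, c1, t2, c2, hi, use_log)
        left, right = min(ta, tb), max(ta, tb)
        total += max(0.0, min(right, t2) - max(left, t1))
    return total
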