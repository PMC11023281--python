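"""Microsomal substrate-depletion analysis: first-order depletion slope,
in-vitro half-life and intrinsic clearance.

The depletion method treats the substrate at t = 0 as 100% and regresses
ln(% remaining) on incubation time; the slope -k gives

    in-vitro t1/2 = -0.693 / k          (min)
    Clint = (0.693 / t1/2) * (uL incubation volume / mg protein)

The 0.693 constant (rather than ln 2 to full precision) matches the
convention these assays are reported with; ``exact_ln2`` switches to ln 2.
A species whose slope is not significantly below zero is reported as a
distinct "no depletion" state, never as an infinite half-life.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoDepletionError, TooFewPointsError, ValidationError

__all__ = [
    "DepletionAssay",
    "ClintResult",
    "NoDepletion",
    "depletion_slope",
    "invitro_half_life",
    "intrinsic_clearance",
    "analyze_assay",
    "summarize_assays",
]

HALF_LIFE_CONSTANT = 0.693
SIGNIFICANCE_LEVEL = 0.05  # one-sided test that the slope is below zero


@dataclass(frozen=True)
class DepletionAssay:
    """One substrate-depletion time course (% remaining vs minutes)."""

    species_label: str
    times: np.ndarray  # min
    remaining: np.ndarray  # percent of t=0 substrate
    protein_conc: float  # mg/mL
    incubation_volume: float  # uL
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.remaining, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "remaining", r)
        if t.ndim != 1 or r.shape != t.shape:
            raise ValidationError("times and remaining must be 1-d and equal length")
        if t.size == 0 or t[0] != 0:
            raise ValidationError("a t = 0 sample must be present (and first)")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if abs(r[0] - 100.0) > 1e-9:
            raise ValidationError("remaining at t = 0 must be 100%")
        if np.any(r <= 0):
            raise ValidationError("remaining must be positive (log transform)")
        if self.protein_conc <= 0 or self.incubation_volume <= 0:
            raise ValidationError("protein_conc and incubation_volume must be positive")

    @classmethod
    def from_concentrations(
        cls,
        species_label: str,
        times,
        concentrations,
        protein_conc: float,
        incubation_volume: float,
        replicate: int = 1,
    ) -> "DepletionAssay":
        """Build from raw concentrations: % remaining = 100 * c / c[0]."""
        c = np.asarray(concentrations, dtype=float)
        if c.size == 0 or c[0] <= 0:
            raise ValidationError("t = 0 concentration must be positive")
        return cls(
            species_label=species_label,
            times=times,
            remaining=100.0 * c / c[0],
            protein_conc=protein_conc,
            incubation_volume=incubation_volume,
            replicate=replicate,
        )

    @property
    def protein_mass(self) -> float:
        """mg of microsomal protein in the incubation."""
        return self.protein_conc * self.incubation_volume / 1000.0


@dataclass(frozen=True)
class ClintResult:
    """Depletion rate, in-vitro half-life and intrinsic clearance."""

    species_label: str
    replicate: int
    k: float  # 1/min, signed slope (negative for depletion)
    t_half_vitro: float  # min
    clint: float  # uL/(min mg protein)


@dataclass(frozen=True)
class NoDepletion:
    """Result state for assays without measurable substrate depletion."""

    species_label: str
    replicate: int
    slope: float
    p_one_sided: float


def depletion_slope(assay: DepletionAssay) -> float:
    """OLS slope of ln(% remaining) vs time (1/min; negative for depletion)."""
    if assay.times.size < 3:
        raise TooFewPointsError("need >= 3 time points for the depletion slope")
    res = stats.linregress(assay.times, np.log(assay.remaining))
    return float(res.slope)


def invitro_half_life(k: float, half_life_constant: float = HALF_LIFE_CONSTANT) -> float:
    """In-vitro half-life -0.693/k (min) for a negative depletion slope."""
    if k >= 0:
        raise NoDepletionError("non-negative slope: no depletion half-life exists")
    return -half_life_constant / k


def intrinsic_clearance(
    t_half_vitro: float,
    incubation_volume: float,
    protein_mass: float,
    half_life_constant: float = HALF_LIFE_CONSTANT,
) -> float:
    """Clint = (0.693/t1/2) * (volume/protein mass), uL/(min mg)."""
    if t_half_vitro <= 0 or incubation_volume <= 0 or protein_mass <= 0:
        raise ValidationError("all inputs must be positive")
    return (half_life_constant / t_half_vitro) * (incubation_volume / protein_mass)


def analyze_assay(
    assay: DepletionAssay, exact_ln2: bool = False
) -> Union[ClintResult, NoDepletion]:
    """Slope, significance check, half-life and Clint for one assay.

    Declares "no depletion" when the slope is >= 0 or not significantly
    below 0 at the 5% level (one-sided t-test from the regression).
    """
    if assay.times.size < 3:
        raise TooFewPointsError("need >= 3 time points")
    res = stats.linregress(assay.times, np.log(assay.remaining))
    slope = float(res.slope)
    if slope < 0:
        p_one = float(res.pvalue) / 2.0
    else:
        p_one = 1.0 - float(res.pvalue) / 2.0
    if slope >= 0 or p_one >= SIGNIFICANCE_LEVEL:
        return NoDepletion(
            species_label=assay.species_label,
            replicate=assay.replicate,
            slope=slope,
            p_one_sided=p_one,
        )
    const = np.log(2.0) if exact_ln2 else HALF_LIFE_CONSTANT
    t_half = invitro_half_life(slope, const)
    clint = intrinsic_clearance(t_half, assay.incubation_volume, assay.protein_mass, const)
    return ClintResult(
        species_label=assay.species_label,
        replicate=assay.replicate,
        k=slope,
        t_half_vitro=t_half,
        clint=clint,
    )


def summarize_assays(
    assays: Iterable[DepletionAssay], exact_ln2: bool = False
) -> pd.DataFrame:
    """Per-species mean +/- SD of in-vitro t1/2 and Clint.

    Half-life and Clint are computed per replicate first and then averaged
    (mean of ratios, not ratio of means).  A species whose replicates all
    show no depletion is reported with status ``no depletion``; a species
    with some non-depleting replicates is summarised over the depleting ones
    and flagged ``partial depletion``.
    """
    groups: dict[str, list] = {}
    for a in assays:
        groups.setdefault(a.species_label, []).append(a)
    if not groups:
        raise ValidationError("no assays supplied")
    rows = []
    for species, group in groups.items():
        results = [analyze_assay(a, exact_ln2=exact_ln2) for a in group]
        depleting = [r for r in results if isinstance(r, ClintResult)]
        if not depleting:
            rows.append(
                {
                    "species": species, "n": len(results), "status": "no depletion",
                    "t_half_mean": np.nan, "t_half_sd": np.nan,
                    "clint_mean": np.nan, "clint_sd": np.nan,
                }
            )
            continue
        th = np.array([r.t_half_vitro for r in depleting])
        cl = np.array([r.clint for r in depleting])
        status = "ok" if len(depleting) == len(results) else "partial depletion"
        rows.append(
            {
                "species": species,
                "n": len(results),
                "status": status,
                "t_half_mean": th.mean(),
                "t_half_sd": th.std(ddof=1) if th.size > 1 else np.nan,
                "clint_mean": cl.mean(),
                "clint_sd": cl.std(ddof=1) if cl.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
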