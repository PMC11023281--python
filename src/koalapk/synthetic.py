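"""Study-like synthetic data generators.

The study this package was written around never published its raw plasma
data, so every generator here emulates the published design instead: eight
koalas dosed orally (or two subcutaneously) with paracetamol at 15 mg/kg,
serial sampling at 0.25/0.5/1/2/4/8/12 h with a 24 h trough, later samples
at 48/72/78 h, an assay LLOQ of 0.625 ug/mL, one-compartment first-order
absorption kinetics with median ka = 0.22 /h and ke = 0.125 /h, a single-dose
Cmax around 17 ug/mL, multiplicative lognormal residual error, first-order
in-vitro substrate depletion, and small paired pre/post analyte panels.

All generators are pure functions of their parameters and seed; subject-level
streams are spawned from the study seed so that adding a subject never
perturbs the data of earlier subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import DegenerateModelError, ValidationError
from .invitro import DepletionAssay
from .nca import DEFAULT_LLOQ, ConcentrationTimeProfile
from .paired_stats import PairedPanel

if TYPE_CHECKING:  # circular at runtime: regimen imports bateman from here
    from .regimen import DoseRegimen

__all__ = [
    "SimulationParams",
    "PRESETS",
    "bateman",
    "simulate_profile",
    "simulate_study",
    "simulate_depletion",
    "simulate_paired_panel",
]

#: serial samples after the first dose (h)
DEFAULT_SCHEDULE = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
#: trough samples just before the 24/48/72 h doses plus the final 78 h draw
EXTRA_TIMES = (48.0, 72.0, 78.0)

_KA_DEFAULT = 0.22  # 1/h, median oral absorption rate constant
_KE_DEFAULT = 0.125  # 1/h, median oral elimination rate constant
_CMAX_TARGET = 17.0  # ug/mL, single-dose peak the generator is scaled to


def _sigma_from_cv(cv: float) -> float:
    """Lognormal sigma giving an exact coefficient of variation ``cv``."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _peak_height(ka: float, ke: float) -> float:
    """Unit-scale Bateman peak value (at t = ln(ka/ke)/(ka-ke))."""
    tp = math.log(ka / ke) / (ka - ke)
    return ka / (ka - ke) * (math.exp(-ke * tp) - math.exp(-ka * tp))


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the one-compartment first-order-absorption generator.

    ``scale`` is the lumped coefficient F*D/V (ug/mL); when omitted it is set
    so the analytic single-dose peak equals ~17 ug/mL.  ``cv`` is the
    multiplicative lognormal residual coefficient of variation.
    """

    scale: float | None = None
    ka: float = _KA_DEFAULT
    ke: float = _KE_DEFAULT
    cv: float = 0.10
    seed: int = 0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE + EXTRA_TIMES
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0:
            raise ValidationError("ka and ke must be positive")
        if self.ka == self.ke:
            raise DegenerateModelError("ka == ke is not supported")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if self.lloq <= 0:
            raise ValidationError("lloq must be positive")
        if any(t < 0 for t in self.schedule) or np.any(np.diff(self.schedule) <= 0):
            raise ValidationError("schedule must be strictly increasing and >= 0")
        if self.scale is None:
            object.__setattr__(
                self, "scale", _CMAX_TARGET / _peak_height(self.ka, self.ke)
            )
        elif self.scale <= 0:
            raise ValidationError("scale must be positive")
        object.__setattr__(self, "schedule", tuple(float(t) for t in self.schedule))


#: named parameter sets understood by the ``simulate`` CLI subcommand
PRESETS: dict[str, dict] = {
    "koala-oral-15mgkg": dict(ka=_KA_DEFAULT, ke=_KE_DEFAULT, cv=0.10),
    "koala-sc-15mgkg": dict(ka=3.659, ke=0.134, cv=0.10),  # median s.c. rates
    "noise-free": dict(ka=_KA_DEFAULT, ke=_KE_DEFAULT, cv=0.0),
}


def bateman(t: np.ndarray | float, p: SimulationParams) -> np.ndarray | float:
    """Noise-free one-compartment curve scale*ka/(ka-ke)*(e^-ke t - e^-ka t).

    Zero for t <= 0 (pre-dose).
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.where(
        t_arr > 0,
        p.scale * p.ka / (p.ka - p.ke)
        * (np.exp(-p.ke * np.maximum(t_arr, 0.0)) - np.exp(-p.ka * np.maximum(t_arr, 0.0))),
        0.0,
    )
    return float(out) if np.isscalar(t) else out


def _apply_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values.copy()
    sigma = _sigma_from_cv(cv)
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def simulate_profile(
    p: SimulationParams,
    subject_id: str = "SIM1",
    route: str = "oral",
    dose: float = 15.0,
    rng: np.random.Generator | None = None,
    curve: np.ndarray | None = None,
) -> ConcentrationTimeProfile:
    """Sample one noisy profile at the schedule times.

    Values below the LLOQ keep their simulated value but are flagged BLQ.
    ``curve`` overrides the noise-free single-dose curve (used for multiple
    dosing); ``rng`` overrides the stream derived from ``p.seed``.
    """
    times = np.array(p.schedule, dtype=float)
    clean = bateman(times, p) if curve is None else np.asarray(curve, dtype=float)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    noisy = _apply_noise(clean, p.cv, rng)
    return ConcentrationTimeProfile(
        subject_id=subject_id,
        route=route,
        dose=dose,
        times=times,
        concentrations=noisy,
        blq=noisy < p.lloq,
        lloq=p.lloq,
    )


def simulate_study(
    n_subjects: int = 8,
    p: SimulationParams | None = None,
    regimen: "DoseRegimen | None" = None,
    bsv_cv: float = 0.20,
    route: str = "oral",
    dose: float = 15.0,
) -> list[ConcentrationTimeProfile]:
    """Simulate a cohort with between-subject variability.

    Each subject draws lognormal (median-1) random effects with coefficient
    of variation ``bsv_cv`` on ka, ke and scale from a stream spawned off the
    study seed.  With a ``regimen`` the single-dose curve is replaced by its
    superposition over the dose times before residual noise is applied.
    """
    if p is None:
        p = SimulationParams()
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    streams = np.random.SeedSequence(p.seed).spawn(n_subjects)
    sigma = _sigma_from_cv(bsv_cv) if bsv_cv > 0 else 0.0
    profiles = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        eff = np.exp(rng.normal(0.0, sigma, size=3)) if sigma else np.ones(3)
        p_i = SimulationParams(
            scale=p.scale * eff[0],
            ka=p.ka * eff[1],
            ke=p.ke * eff[2],
            cv=p.cv,
            seed=p.seed,
            schedule=p.schedule,
            lloq=p.lloq,
        )
        curve = None
        if regimen is not None and len(regimen.dose_times) > 1:
            from .regimen import superpose  # deferred: regimen imports bateman

            curve = superpose(
                regimen, p_i.ka, p_i.ke, p_i.scale, np.array(p_i.schedule)
            )
        profiles.append(
            simulate_profile(
                p_i, subject_id=f"SIM{i + 1}", route=route, dose=dose,
                rng=rng, curve=curve,
            )
        )
    return profiles


def simulate_depletion(
    k: float,
    times: Sequence[float] = (0.0, 30.0, 60.0),
    cv: float = 0.02,
    seed: int = 0,
    species_label: str = "synthetic",
    replicate: int = 1,
    protein_conc: float = 0.5,
    incubation_volume: float = 1000.0,
) -> DepletionAssay:
    """First-order in-vitro substrate depletion, remaining% = 100 e^(-k t).

    ``k`` >= 0 is the depletion rate in 1/min (0 gives the flat no-depletion
    fixture); the t = 0 anchor is forced to exactly 100%.
    """
    if k < 0:
        raise ValidationError("depletion rate k must be >= 0")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    remaining = _apply_noise(100.0 * np.exp(-k * t), cv, rng)
    remaining[0] = 100.0
    return DepletionAssay(
        species_label=species_label,
        replicate=replicate,
        times=t,
        remaining=remaining,
        protein_conc=protein_conc,
        incubation_volume=incubation_volume,
    )


def simulate_paired_panel(
    n: int = 6,
    shift: float = 4.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 25.0,
    baseline_sd: float = 5.0,
    analyte: str = "ALT",
    units: str = "U/L",
) -> PairedPanel:
    """Pre/post analyte panel: post = pre + shift + N(0, noise_sd).

    Defaults echo the study's ALT finding (a rise of about +4 U/L in all six
    animals).
    """
    if n < 2:
        raise ValidationError("a paired panel needs n >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pre = rng.normal(baseline_mean, baseline_sd, size=n)
    post = pre + shift + rng.normal(0.0, noise_sd, size=n)
    return PairedPanel(
        analyte=analyte,
        units=units,
        subjects=tuple(f"K{i + 1}" for i in range(n)),
        pre=pre,
        post=post,
    )
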