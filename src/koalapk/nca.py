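"""Non-compartmental analysis of single-dose concentration-time profiles.

Implements the standard extravascular NCA workflow: observed Cmax/Tmax, a
log-linear terminal fit selected by adjusted r-squared over contiguous
post-peak tails, half-life, linear-up/log-down trapezoidal AUC and linear
AUMC with the usual Clast/ke extrapolations, mean residence time, apparent
clearance and volume (both confounded with bioavailability F after oral or
subcutaneous dosing), and the absorption rate constant by the method of
residuals (feathering).

Units follow small-animal PK convention: time in hours, concentration in
ug/mL, dose in mg/kg.  Because 1 mg / (1 ug/mL) = 1 L, Cl/F emerges directly
in L/(kg h) and Vz/F in L/kg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    AllBLQError,
    KoalaPKError,
    KoalaPKWarning,
    NonDecliningTerminalError,
    NonPositiveResidualError,
    TooFewPointsError,
    UnreliableAbsorptionError,
    ValidationError,
)

__all__ = [
    "ConcentrationTimeProfile",
    "TerminalFit",
    "NCAResult",
    "fit_terminal_phase",
    "half_life",
    "cmax_tmax",
    "auc_trapezoid",
    "auc_extrapolate",
    "aumc_trapezoid",
    "aumc_extrapolate",
    "mrt",
    "clearance_over_f",
    "volume_over_f",
    "ka_method_of_residuals",
    "run_nca",
]

DEFAULT_LLOQ = 0.625  # ug/mL, the assay's lower limit of quantification

ROUTES = ("oral", "subcutaneous")

#: decimals used when formatting results for reports (full precision is kept
#: internally); rate constants / half-lives / volumes get 3, areas and
#: concentrations 2, times 1.
REPORT_DECIMALS = {
    "ka": 3,
    "ke": 3,
    "t_half": 3,
    "tmax": 1,
    "cmax": 2,
    "auc_0_t": 2,
    "auc_0_inf": 2,
    "auc_ratio": 2,
    "aumc_0_inf": 2,
    "mrt": 3,
    "vz_f": 3,
    "cl_f": 3,
}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention used in PK reporting."""
    if not np.isfinite(x):
        return x
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's plasma concentration-time series.

    ``blq`` flags observations below the limit of quantification; if omitted
    it is derived as ``concentrations < lloq``.  Times must be strictly
    increasing and non-negative; concentrations non-negative.
    """

    subject_id: str
    route: str
    dose: float  # mg/kg
    times: np.ndarray  # h
    concentrations: np.ndarray  # ug/mL
    blq: np.ndarray | None = None
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.route not in ROUTES:
            raise ValidationError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if self.dose <= 0:
            raise ValidationError("dose must be positive")
        if self.lloq <= 0:
            raise ValidationError("lloq must be positive")
        if t.ndim != 1 or c.shape != t.shape:
            raise ValidationError("times and concentrations must be 1-d and equal length")
        if t.size and t[0] < 0:
            raise ValidationError("times must be >= 0")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(c)):
            raise ValidationError("times and concentrations must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be non-negative")
        if self.blq is None:
            flags = c < self.lloq
        else:
            flags = np.asarray(self.blq, dtype=bool)
            if flags.shape != t.shape:
                raise ValidationError("blq flags must match times in length")
        object.__setattr__(self, "blq", flags)

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of observations at or above the LLOQ."""
        return ~self.blq

    @property
    def n_quantifiable(self) -> int:
        return int(self.quantifiable.sum())


@dataclass(frozen=True)
class TerminalFit:
    """Log-linear fit of the terminal elimination phase.

    ``ke`` is the (positive) elimination rate constant, i.e. minus the OLS
    slope of ln C versus t over ``points_used`` (indices into the profile).
    """

    ke: float  # 1/h
    intercept: float  # ln(ug/mL)
    points_used: tuple[int, ...]
    r_squared: float

    def __post_init__(self) -> None:
        if self.ke <= 0:
            raise ValidationError("terminal fit requires a declining phase (ke > 0)")
        if len(self.points_used) < 2:
            raise ValidationError("terminal fit needs at least 2 points")

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        """Back-extrapolated terminal concentration at time(s) ``t``."""
        return np.exp(self.intercept - self.ke * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class NCAResult:
    """The full set of non-compartmental indices for one profile.

    ``ka`` is NaN when the method of residuals was infeasible (too few
    pre-peak points or non-positive residuals); the reason is recorded in
    ``notes``.  Bioavailability F is deliberately not estimated, so clearance
    and volume are apparent (Cl/F, Vz/F).
    """

    subject_id: str
    route: str
    dose: float
    ka: float
    ke: float
    t_half: float
    tmax: float
    cmax: float
    auc_0_t: float
    auc_0_inf: float
    auc_ratio: float
    aumc_0_inf: float
    mrt: float
    vz_f: float
    cl_f: float
    terminal_fit: TerminalFit
    t_end: float
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self, rounded: bool = False) -> dict:
        d = {
            "subject_id": self.subject_id,
            "route": self.route,
            "dose_mg_per_kg": self.dose,
            "t_end": self.t_end,
            "ka": self.ka,
            "ke": self.ke,
            "t_half": self.t_half,
            "tmax": self.tmax,
            "cmax": self.cmax,
            "auc_0_t": self.auc_0_t,
            "auc_0_inf": self.auc_0_inf,
            "auc_ratio": self.auc_ratio,
            "aumc_0_inf": self.aumc_0_inf,
            "mrt": self.mrt,
            "vz_f": self.vz_f,
            "cl_f": self.cl_f,
            "terminal_r_squared": self.terminal_fit.r_squared,
            "terminal_n_points": len(self.terminal_fit.points_used),
            "notes": "; ".join(self.notes),
        }
        if rounded:
            for key, nd in REPORT_DECIMALS.items():
                d[key] = round_half_up(d[key], nd)
        return d


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------


def _ols_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(c) on t; returns (slope, intercept, r_squared)."""
    y = np.log(c)
    slope, intercept = np.polyfit(t, y, 1)
    yhat = intercept + slope * t
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), min(r2, 1.0)


def cmax_tmax(profile: ConcentrationTimeProfile) -> tuple[float, float]:
    """Observed maximum concentration and its time (earliest on ties)."""
    q = profile.quantifiable
    if not q.any():
        raise AllBLQError(f"{profile.subject_id}: no quantifiable observations")
    c = profile.concentrations[q]
    t = profile.times[q]
    i = int(np.argmax(c))  # argmax returns the first maximum; times are sorted
    return float(c[i]), float(t[i])


def fit_terminal_phase(
    profile: ConcentrationTimeProfile, min_points: int = 3
) -> TerminalFit:
    """Select and fit the log-linear terminal elimination phase.

    Candidate point sets are the contiguous tails (of at least ``min_points``
    quantifiable points) of the post-peak observations; the tail with the
    highest adjusted r-squared wins, ties going to the longer tail.  Points
    strictly after Tmax are preferred; when they are too few the Tmax point
    itself is admitted (with a warning), which is the only way profiles whose
    observed peak is the first usable sample can be fitted at all.
    """
    if min_points < 3:
        raise ValidationError("min_points must be >= 3")
    q = profile.quantifiable
    if q.sum() < min_points:
        raise TooFewPointsError(
            f"{profile.subject_id}: {int(q.sum())} quantifiable points < {min_points}"
        )
    _, tmax = cmax_tmax(profile)
    idx_all = np.flatnonzero(q)
    post = [int(i) for i in idx_all if profile.times[i] > tmax]
    if len(post) < min_points:
        at_peak = [int(i) for i in idx_all if profile.times[i] == tmax]
        post = at_peak + post
        if len(post) < min_points:
            raise TooFewPointsError(
                f"{profile.subject_id}: only {len(post)} usable points at/after Tmax"
            )
        warnings.warn(
            f"{profile.subject_id}: terminal fit includes the Tmax observation",
            KoalaPKWarning,
            stacklevel=2,
        )

    best: tuple[float, int, TerminalFit] | None = None
    # longest tail first so that on (near-)ties the longer tail is kept
    for start in range(0, len(post) - min_points + 1):
        idx = post[start:]
        t = profile.times[idx]
        c = profile.concentrations[idx]
        if np.any(c <= 0):
            continue
        slope, intercept, r2 = _ols_loglinear(t, c)
        if slope >= 0:
            continue
        n = len(idx)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        fit = TerminalFit(ke=-slope, intercept=intercept, points_used=tuple(idx), r_squared=r2)
        if best is None or adj > best[0] + 1e-9:
            best = (adj, n, fit)
    if best is None:
        raise NonDecliningTerminalError(
            f"{profile.subject_id}: no declining terminal phase found"
        )
    return best[2]


def half_life(ke: float) -> float:
    """Elimination half-life ln 2 / ke (hours)."""
    if ke <= 0:
        raise ValidationError("ke must be positive")
    return math.log(2.0) / ke


def _interval_auc(t1: float, c1: float, t2: float, c2: float, method: str) -> float:
    """Area of one interval under the chosen trapezoidal dialect."""
    dt = t2 - t1
    log_ok = c1 > 0 and c2 > 0 and c1 != c2
    if method == "linear-up-log-down":
        use_log = log_ok and c2 < c1
    elif method == "log":
        use_log = log_ok
    else:
        raise ValidationError(f"unknown AUC method {method!r}")
    if use_log:
        return (c1 - c2) / math.log(c1 / c2) * dt
    return 0.5 * (c1 + c2) * dt


def _integration_series(
    profile: ConcentrationTimeProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Times/concentrations usable for integration.

    Leading below-LLOQ points are kept with concentration 0 (pre-dose
    baseline); embedded and trailing below-LLOQ points are dropped, so the
    series ends at the last quantifiable observation.
    """
    q = profile.quantifiable
    if q.sum() < 1:
        raise AllBLQError(f"{profile.subject_id}: no quantifiable observations")
    first = int(np.flatnonzero(q)[0])
    last = int(np.flatnonzero(q)[-1])
    ts, cs = [], []
    for i in range(last + 1):
        if i < first:
            ts.append(profile.times[i])
            cs.append(0.0)
        elif q[i]:
            ts.append(profile.times[i])
            cs.append(profile.concentrations[i])
    return np.array(ts), np.array(cs)


def _interp_conc(t1: float, c1: float, t2: float, c2: float, t: float, method: str) -> float:
    """Concentration at ``t`` inside an interval, matching the area rule."""
    frac = (t - t1) / (t2 - t1)
    log_ok = c1 > 0 and c2 > 0 and c1 != c2
    down = c2 < c1
    if method == "log" and log_ok or (method == "linear-up-log-down" and log_ok and down):
        return c1 * (c2 / c1) ** frac
    return c1 + (c2 - c1) * frac


def auc_trapezoid(
    profile: ConcentrationTimeProfile,
    t_end: float,
    method: str = "linear-up-log-down",
) -> float:
    """AUC from the first usable observation to ``t_end`` (ug h/mL).

    ``linear-up-log-down`` (default) applies the linear rule on
    non-decreasing segments and the logarithmic rule
    (dC / dlnC * dt) on strictly decreasing positive segments; ``log``
    applies the logarithmic rule wherever it is defined.
    """
    t, c = _integration_series(profile)
    if t.size < 2:
        raise TooFewPointsError("need at least 2 usable points for AUC")
    if t_end > t[-1] + 1e-12:
        raise ValidationError(
            f"t_end={t_end} beyond last quantifiable observation at {t[-1]}"
        )
    if t_end < t[1]:
        raise ValidationError("t_end falls before the second usable observation")
    total = 0.0
    for i in range(t.size - 1):
        if t[i] >= t_end:
            break
        if t[i + 1] <= t_end:
            total += _interval_auc(t[i], c[i], t[i + 1], c[i + 1], method)
        else:  # partial interval: interpolate the endpoint consistently
            c_end = _interp_conc(t[i], c[i], t[i + 1], c[i + 1], t_end, method)
            total += _interval_auc(t[i], c[i], t_end, c_end, method)
            break
    return total


def aumc_trapezoid(profile: ConcentrationTimeProfile, t_end: float) -> float:
    """Area under the first-moment curve t*C(t), linear trapezoid (ug h^2/mL).

    The logarithmic rule is not applied to the moment curve: t*C is zero at
    t = 0 whenever sampling starts at dosing, where the log rule is undefined.
    """
    t, c = _integration_series(profile)
    if t.size < 2:
        raise TooFewPointsError("need at least 2 usable points for AUMC")
    if t_end > t[-1] + 1e-12:
        raise ValidationError("t_end beyond last quantifiable observation")
    y = t * c
    total = 0.0
    for i in range(t.size - 1):
        if t[i] >= t_end:
            break
        if t[i + 1] <= t_end:
            total += 0.5 * (y[i] + y[i + 1]) * (t[i + 1] - t[i])
        else:
            frac = (t_end - t[i]) / (t[i + 1] - t[i])
            y_end = y[i] + (y[i + 1] - y[i]) * frac
            total += 0.5 * (y[i] + y_end) * (t_end - t[i])
            break
    return total


def auc_extrapolate(c_last: float, ke: float) -> float:
    """Extrapolated tail area Clast/ke (ug h/mL)."""
    if c_last <= 0 or ke <= 0:
        raise ValidationError("c_last and ke must be positive")
    return c_last / ke


def aumc_extrapolate(c_last: float, t_last: float, ke: float) -> float:
    """Extrapolated first-moment tail (Clast*tlast/ke) + Clast/ke^2."""
    if c_last <= 0 or ke <= 0:
        raise ValidationError("c_last and ke must be positive")
    if t_last < 0:
        raise ValidationError("t_last must be >= 0")
    return c_last * t_last / ke + c_last / ke**2


def mrt(aumc_0_inf: float, auc_0_inf: float) -> float:
    """Mean residence time AUMC0-inf / AUC0-inf (hours)."""
    if aumc_0_inf <= 0 or auc_0_inf <= 0:
        raise ValidationError("areas must be positive")
    return aumc_0_inf / auc_0_inf


def clearance_over_f(dose: float, auc_0_inf: float) -> float:
    """Apparent clearance Dose/AUC0-inf in L/(kg h).

    Dose in mg/kg over AUC in ug h/mL: 1 mg / (1 ug/mL) = 1 L, so no
    numeric conversion factor is needed.
    """
    if dose <= 0 or auc_0_inf <= 0:
        raise ValidationError("dose and AUC must be positive")
    return dose / auc_0_inf


def volume_over_f(cl_f: float, ke: float) -> float:
    """Apparent volume of distribution Cl/F / ke in L/kg."""
    if cl_f <= 0 or ke <= 0:
        raise ValidationError("cl_f and ke must be positive")
    return cl_f / ke


def ka_method_of_residuals(
    profile: ConcentrationTimeProfile,
    terminal: TerminalFit,
    min_points: int = 2,
) -> float:
    """Absorption rate constant by the method of residuals (feathering).

    The terminal line is back-extrapolated to the pre-peak times; residuals
    r(t) = exp(intercept - ke t) - C(t) must be positive, and their
    log-linear slope gives -ka.  Requires ka > ke (no flip-flop handling).
    """
    q = profile.quantifiable
    _, tmax = cmax_tmax(profile)
    pre = np.flatnonzero(q & (profile.times < tmax))
    if pre.size < min_points:
        raise TooFewPointsError(
            f"{profile.subject_id}: {pre.size} pre-peak points < {min_points}"
        )
    t = profile.times[pre]
    c = profile.concentrations[pre]
    resid = terminal.predict(t) - c
    if np.any(resid <= 0):
        raise NonPositiveResidualError(
            f"{profile.subject_id}: observation above the back-extrapolated terminal line"
        )
    slope, _, _ = _ols_loglinear(t, resid)
    ka = -slope
    if ka <= terminal.ke:
        raise UnreliableAbsorptionError(
            f"{profile.subject_id}: ka={ka:.4f} <= ke={terminal.ke:.4f}"
        )
    if pre.size == 2:
        warnings.warn(
            f"{profile.subject_id}: ka estimated from only 2 residual points",
            KoalaPKWarning,
            stacklevel=2,
        )
    return float(ka)


def run_nca(
    profile: ConcentrationTimeProfile,
    t_end: float = 24.0,
    min_points: int = 3,
    auc_method: str = "linear-up-log-down",
) -> NCAResult:
    """Orchestrate the full NCA for one profile.

    AUC0-inf = AUC0-t + Clast/ke and AUMC0-inf = AUMC0-t + tail term, where
    Clast/tlast refer to the last quantifiable observation at or before
    ``t_end``.  Component failures are re-raised with a stage label; an
    infeasible ka is recorded as NaN with a note rather than aborting.
    """
    notes: list[str] = []

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except KoalaPKError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    cmax, tmax = stage("cmax", cmax_tmax, profile)
    terminal = stage("terminal-fit", fit_terminal_phase, profile, min_points)
    ke = terminal.ke
    t_h = stage("half-life", half_life, ke)

    t_int, c_int = _integration_series(profile)
    t_last = min(t_end, float(t_int[-1]))
    if t_last < t_end:
        notes.append(f"integration truncated at last quantifiable sample t={t_last}")
    # Clast at the integration endpoint
    i_last = int(np.searchsorted(t_int, t_last, side="right")) - 1
    if t_int[i_last] == t_last:
        c_last = float(c_int[i_last])
    else:
        c_last = _interp_conc(
            t_int[i_last], c_int[i_last], t_int[i_last + 1], c_int[i_last + 1],
            t_last, auc_method,
        )

    auc_t = stage("auc", auc_trapezoid, profile, t_last, auc_method)
    aumc_t = stage("aumc", aumc_trapezoid, profile, t_last)
    auc_inf = auc_t + stage("auc-extrapolation", auc_extrapolate, c_last, ke)
    aumc_inf = aumc_t + stage("aumc-extrapolation", aumc_extrapolate, c_last, t_last, ke)

    mrt_val = stage("mrt", mrt, aumc_inf, auc_inf)
    cl_f = stage("clearance", clearance_over_f, profile.dose, auc_inf)
    vz_f = stage("volume", volume_over_f, cl_f, ke)

    try:
        ka = ka_method_of_residuals(profile, terminal)
    except (TooFewPointsError, NonPositiveResidualError, UnreliableAbsorptionError) as exc:
        ka = float("nan")
        notes.append(f"ka not estimated: {exc}")

    return NCAResult(
        subject_id=profile.subject_id,
        route=profile.route,
        dose=profile.dose,
        ka=ka,
        ke=ke,
        t_half=t_h,
        tmax=tmax,
        cmax=cmax,
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        auc_ratio=auc_t / auc_inf,
        aumc_0_inf=aumc_inf,
        mrt=mrt_val,
        vz_f=vz_f,
        cl_f=cl_f,
        terminal_fit=terminal,
        t_end=t_last,
        notes=tuple(notes),
    )
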