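"""Multiple-dose one-compartment pharmacokinetics with first-order absorption.

A single oral dose produces the classic Bateman profile
``Gamma * (exp(-ke*t) - exp(-ka*t))`` with absorption rate ``ka``,
elimination rate ``ke`` (``ka > ke``) and concentration scale
``Gamma = F*D*ka / (Vd*(ka-ke))``. Repeated dosing every ``tau`` hours
superposes shifted copies; the closed form groups them through the
accumulation constants ``alpha = exp(ka*tau)`` and ``epsilon = exp(ke*tau)``.

``alpha`` reaches ~1e18 for a fast absorber dosed daily, and its powers
overflow double precision long before a 10-day course ends, so the closed
form is always evaluated dose-by-dose as ``exp(-k*(t - j*tau))`` — the
mathematically identical, overflow-safe regrouping of
``exp(-k*t) * sum_j exp(k*tau)^j``.

Two sources for the constants are supported: ``derived`` recomputes
``Gamma``, ``alpha``, ``epsilon`` from the raw PK inputs, while ``printed``
takes them verbatim from the shipped data table (and back-solves ``ka``,
``ke`` from ``alpha``, ``epsilon``). The printed constants are the ones the
simulations downstream are calibrated against — the shipped imatinib
``Gamma`` is not reproduced by the listed volume of distribution (it implies
roughly 400 L rather than 435 L), so ``printed`` is the default mode.

All public time arguments are minutes since the first dose; concentrations
are nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PKError",
    "PKInputs",
    "PKConstants",
    "DoseSchedule",
    "ConcentrationSeries",
    "ConcentrationProfile",
    "pk_constants",
    "printed_constants",
    "plasma_concentration",
    "dose_times_minutes",
    "make_profile",
    "concentration_series",
    "steady_state_summary",
]

MINUTES_PER_HOUR = 60.0


class PKError(ValueError):
    """Raised for degenerate or out-of-domain pharmacokinetic inputs."""


@dataclass(frozen=True)
class PKInputs:
    """Raw per-drug pharmacokinetic inputs.

    F is the oral bioavailability (fraction), D_mass the dose in mg, M the
    molar mass in g/mol, ka the absorption rate constant in h^-1, t_half_e
    the elimination half-life in h, Vd the volume of distribution in L and
    tau the dosing interval in h.
    """

    F: float
    D_mass: float
    M: float
    ka: float
    t_half_e: float
    Vd: float
    tau: float = 24.0

    def __post_init__(self) -> None:
        for name in ("F", "D_mass", "M", "ka", "t_half_e", "Vd", "tau"):
            if not getattr(self, name) > 0:
                raise PKError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.F > 1.0:
            raise PKError(f"bioavailability F must be in (0, 1], got {self.F}")
        if math.isclose(self.ka, self.ke, rel_tol=1e-12):
            raise PKError(
                "ka == ke makes Gamma = F*D*ka/(Vd*(ka-ke)) singular; "
                "the one-compartment Bateman solution does not apply"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant ln2/t_half, h^-1."""
        return math.log(2.0) / self.t_half_e

    @property
    def D_mol(self) -> float:
        """Dose in moles."""
        return self.D_mass / 1000.0 / self.M


@dataclass(frozen=True)
class PKConstants:
    """Dosing constants driving the concentration curve.

    Gamma is the concentration scale in nM; alpha and epsilon are the
    per-interval accumulation factors for absorption and elimination.
    ``source`` records whether they were derived from raw inputs or taken
    verbatim from the shipped table.
    """

    Gamma: float
    alpha: float
    epsilon: float
    ka: float
    ke: float
    tau: float
    source: str = "derived"

    def __post_init__(self) -> None:
        if not self.Gamma > 0:
            raise PKError(f"Gamma must be > 0, got {self.Gamma}")
        if not self.alpha > self.epsilon > 1.0:
            raise PKError(
                f"need alpha > epsilon > 1 (fast absorption, daily accumulation); "
                f"got alpha={self.alpha}, epsilon={self.epsilon}"
            )

    @property
    def ka_per_min(self) -> float:
        return self.ka / MINUTES_PER_HOUR

    @property
    def ke_per_min(self) -> float:
        return self.ke / MINUTES_PER_HOUR

    @property
    def tau_min(self) -> float:
        return self.tau * MINUTES_PER_HOUR


@dataclass(frozen=True)
class DoseSchedule:
    """A course of daily doses, optionally with jittered dose times.

    ``jitter_width`` is the half-width (h) of a centred uniform perturbation
    applied to every dose time after the first; the first dose anchors t=0
    so the concentration starts at exactly zero. ``jitter_width=0``
    reproduces the regular schedule to machine precision.
    """

    n_days: int
    jitter_width: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise PKError(f"n_days must be >= 1, got {self.n_days}")
        if self.jitter_width < 0:
            raise PKError(f"jitter_width must be >= 0, got {self.jitter_width}")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Plasma concentration sampled on a time grid (minutes, nM)."""

    times: np.ndarray
    values: np.ndarray


# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------


def pk_constants(inputs: PKInputs) -> PKConstants:
    """Derive Gamma (nM), alpha and epsilon from raw PK inputs."""
    ka, ke = inputs.ka, inputs.ke
    gamma_molar = inputs.F * inputs.D_mol * ka / (inputs.Vd * (ka - ke))
    return PKConstants(
        Gamma=gamma_molar * 1e9,
        alpha=math.exp(ka * inputs.tau),
        epsilon=math.exp(ke * inputs.tau),
        ka=ka,
        ke=ke,
        tau=inputs.tau,
        source="derived",
    )


def printed_constants(
    Gamma: float, alpha: float, epsilon: float, tau: float = 24.0
) -> PKConstants:
    """Constants taken verbatim from the shipped table.

    ka and ke are back-solved from alpha and epsilon so that the curve is
    self-consistent with the printed accumulation factors.
    """
    return PKConstants(
        Gamma=Gamma,
        alpha=alpha,
        epsilon=epsilon,
        ka=math.log(alpha) / tau,
        ke=math.log(epsilon) / tau,
        tau=tau,
        source="printed",
    )


# ---------------------------------------------------------------------------
# Concentration curves
# ---------------------------------------------------------------------------


def _superpose(
    t_min: np.ndarray, dose_times_min: np.ndarray, constants: PKConstants
) -> np.ndarray:
    """Sum of Bateman terms over the doses taken at or before each t."""
    ka, ke = constants.ka_per_min, constants.ke_per_min
    dt = t_min[:, None] - dose_times_min[None, :]
    active = dt >= 0.0
    dt = np.where(active, dt, 0.0)
    terms = np.exp(-ke * dt) - np.exp(-ka * dt)
    return constants.Gamma * np.sum(np.where(active, terms, 0.0), axis=1)


def plasma_concentration(t, constants: PKConstants):
    """Closed-form multi-dose concentration C(t) in nM, t in minutes.

    Doses fall at 0, tau, 2*tau, ...; the dose at exactly t is included
    from t onward (it contributes zero there). Scalar in, scalar out.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise PKError("time since first dose must be >= 0")
    n_max = int(np.floor(t_arr.max() / constants.tau_min))
    doses = np.arange(n_max + 1) * constants.tau_min
    values = _superpose(t_arr, doses, constants)
    return float(values[0]) if np.isscalar(t) or np.ndim(t) == 0 else values


def dose_times_minutes(schedule: DoseSchedule, constants: PKConstants) -> np.ndarray:
    """Dose times in minutes, jittered after the first dose if requested."""
    tau_min = constants.tau_min
    times = np.arange(schedule.n_days, dtype=float) * tau_min
    if schedule.jitter_width > 0 and schedule.n_days > 1:
        if schedule.jitter_width >= constants.tau / 2.0:
            raise PKError("jitter_width must be < tau/2 to keep doses ordered")
        rng = np.random.default_rng(schedule.seed)
        half_width_min = schedule.jitter_width * MINUTES_PER_HOUR
        times[1:] += rng.uniform(-half_width_min, half_width_min, schedule.n_days - 1)
    return times


@dataclass(frozen=True)
class ConcentrationProfile:
    """Callable concentration curve C(t_min) -> nM for a fixed dose pattern.

    ``breakpoints`` exposes the dose times so ODE integrators can split at
    the non-smooth points of the curve.
    """

    dose_times: np.ndarray
    constants: PKConstants

    def __call__(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        values = _superpose(t_arr, self.dose_times, self.constants)
        return float(values[0]) if np.ndim(t) == 0 else values

    @property
    def breakpoints(self) -> np.ndarray:
        return self.dose_times


def make_profile(schedule: DoseSchedule, constants: PKConstants) -> ConcentrationProfile:
    return ConcentrationProfile(dose_times_minutes(schedule, constants), constants)


def concentration_series(
    schedule: DoseSchedule, constants: PKConstants, grid_step: float = 1.0
) -> ConcentrationSeries:
    """Sample the dosing course on a regular grid (grid_step in minutes)."""
    if not grid_step > 0:
        raise PKError(f"grid_step must be > 0, got {grid_step}")
    profile = make_profile(schedule, constants)
    duration = schedule.n_days * constants.tau_min
    times = np.arange(0.0, duration + 0.5 * grid_step, grid_step)
    return ConcentrationSeries(times=times, values=profile(times))


def steady_state_summary(
    series: ConcentrationSeries, day: int, tau_min: float = 1440.0
) -> tuple[float, float, float]:
    """(min, max, midpoint) concentration over the 24 h window of ``day``.

    ``day`` is the 0-based dosing-interval index; the midpoint is the value
    half an interval after that day's dose, linearly interpolated on the
    stored grid.
    """
    start, end = day * tau_min, (day + 1) * tau_min
    mask = (series.times >= start) & (series.times < end)
    if not np.any(mask) or series.times[-1] < end - 1e-9:
        raise PKError(f"series does not cover day {day}")
    window = series.values[mask]
    midpoint = float(np.interp(start + tau_min / 2.0, series.times, series.values))
    return float(window.min()), float(window.max()), midpoint
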