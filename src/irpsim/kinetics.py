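"""Time-dependent 4-state kinetics of an inhibited kinase.

The enzyme is modelled as a continuous-time linear system over four states:
free inactive ``E_I``, free active ``E_A``, active substrate(+ATP)-bound
``E_AS``, and one inhibitor-bound state — ``E_IR`` for an inactive-state
binder or ``E_AR`` for an active-state binder. Substrate is held at a fixed
concentration (perfect replenishment), ATP is in surplus, and product release
returns the enzyme to ``E_A`` at rate ``kcat``, so the state equations are

    d[Ex]/dt = -[Ex] * sum_y k(x->y) + sum_y [Ey] * k(y->x),

a linear ODE whose generator depends on time only through the plasma
inhibitor concentration ``R(t)``. Columns of the generator sum to zero, so
total enzyme is conserved by construction.

The untreated system has a closed-form quasi-equilibrium: state occupancies
proportional to the Boltzmann-type weights ``{1, f, f*[S]/K_M}`` (``f`` the
conformational factor), which is the exact ``R = 0`` fixed point of the
generator and serves as the initial condition for every treatment
simulation. With inhibitor the same weight construction adds ``[R]/R_D`` on
the bound state, giving the closed-form inhibited rate used for
cross-checks; in particular the rate at any constant ``R`` is
``rate(0) * IC50/(IC50+R)``.

Two integrators are provided: a fixed-step forward-Euler reference at a
millisecond step (bit-reproducible, compiled with numba when available) and
a default adaptive stiff integrator (LSODA) that splits the time axis at
dose times, where the concentration curve is non-smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import (
    ACTIVE_BINDER,
    INACTIVE_BINDER,
    ParameterError,
    VariantDrugParameters,
)

__all__ = [
    "StabilityError",
    "StateSpace",
    "StateVector",
    "Trajectory",
    "SimulationConfig",
    "state_space",
    "build_generator",
    "generator_parts",
    "initial_state",
    "integrate",
    "product_rate_series",
    "analytic_product_rate",
]

#: Reference fixed Euler step: 1 ms expressed in minutes.
EULER_DT_MIN = 1.0 / 60000.0

#: Concentrations this far below zero are numerical noise; anything worse
#: indicates an unstable step size.
NEGATIVE_TOL = 1e-12

try:  # compiled Euler kernel; the pure-numpy fallback is ~100x slower
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class StabilityError(RuntimeError):
    """Raised when an integration step drives a concentration negative."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels for one binding mode."""

    labels: tuple[str, ...]
    binding_mode: str

    @property
    def bound_index(self) -> int:
        return 3

    @property
    def bound_label(self) -> str:
        return self.labels[3]


def state_space(binding_mode: str) -> StateSpace:
    if binding_mode == INACTIVE_BINDER:
        return StateSpace(("E_I", "E_A", "E_AS", "E_IR"), binding_mode)
    if binding_mode == ACTIVE_BINDER:
        return StateSpace(("E_I", "E_A", "E_AS", "E_AR"), binding_mode)
    raise ParameterError(f"unknown binding mode {binding_mode!r}")


@dataclass(frozen=True)
class StateVector:
    """Concentrations (uM) of the four states at one time (min)."""

    space: StateSpace
    concentrations: np.ndarray
    time: float = 0.0

    def __getitem__(self, label: str) -> float:
        return float(self.concentrations[self.space.labels.index(label)])

    @property
    def total(self) -> float:
        return float(self.concentrations.sum())


@dataclass(frozen=True)
class Trajectory:
    """Stored samples of a simulation run.

    ``states`` is (n_times, 4) in uM, ``inhibitor_conc`` the driving plasma
    concentration in nM, ``product_rate`` = kcat*[E_AS] in uM/min.
    """

    space: StateSpace
    times: np.ndarray
    states: np.ndarray
    inhibitor_conc: np.ndarray
    product_rate: np.ndarray

    def state_at(self, index: int) -> StateVector:
        return StateVector(self.space, self.states[index], float(self.times[index]))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``method`` is ``"adaptive"`` (LSODA, default) or ``"euler_fixed"`` (the
    forward-Euler reference at ``dt`` minutes). ``output_dt`` is the stored
    sample spacing; with Euler the stride is rounded to whole steps.
    """

    method: str = "adaptive"
    duration: float = 14400.0
    dt: float = EULER_DT_MIN
    output_dt: float = 1.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "euler_fixed"):
            raise ParameterError(f"unknown integration method {self.method!r}")
        if not (self.dt > 0 and self.duration > 0 and self.output_dt > 0):
            raise ParameterError("dt, duration and output_dt must all be > 0")


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generator_parts(params: VariantDrugParameters) -> tuple[np.ndarray, np.ndarray]:
    """Split the generator as M(R) = M0 + R*M1.

    M0 carries the concentration-independent rates, M1 the inhibitor-binding
    structure (per-nM), so the time-dependent right-hand side is a cheap
    matrix update. Both parts have zero column sums.
    """
    S = params.thermo.S
    konS_S = params.substrate.konS * S
    koffS = params.substrate.koffS
    kcat = params.variant.kcat
    konR = params.inhibitor.konR
    koffR = params.inhibitor.koffR

    M0 = np.zeros((4, 4))
    # conformational exchange E_I <-> E_A
    M0[1, 0] += params.ktransI
    M0[0, 0] -= params.ktransI
    M0[0, 1] += params.ktransA
    M0[1, 1] -= params.ktransA
    # substrate binding E_A <-> E_AS; catalysis returns E_AS -> E_A
    M0[2, 1] += konS_S
    M0[1, 1] -= konS_S
    M0[1, 2] += koffS + kcat
    M0[2, 2] -= koffS + kcat
    # inhibitor unbinding from the bound state
    b = 0 if params.drug.binding_mode == INACTIVE_BINDER else 1
    M0[b, 3] += koffR
    M0[3, 3] -= koffR

    M1 = np.zeros((4, 4))
    M1[3, b] += konR
    M1[b, b] -= konR
    return M0, M1


def build_generator(params: VariantDrugParameters, R: float) -> np.ndarray:
    """Rate generator at inhibitor concentration R (nM); columns sum to zero."""
    if R < 0:
        raise ParameterError(f"inhibitor concentration must be >= 0, got {R}")
    M0, M1 = generator_parts(params)
    return M0 + R * M1


# ---------------------------------------------------------------------------
# Initial conditions and closed forms
# ---------------------------------------------------------------------------


def initial_state(
    params: VariantDrugParameters, Etot: Optional[float] = None
) -> StateVector:
    """Untreated quasi-equilibrium occupancies (the exact R=0 fixed point).

    Weights {1, f, f*[S]/K_M, 0} normalised to the total enzyme
    concentration; the inhibitor-bound state starts empty.
    """
    if Etot is None:
        Etot = params.thermo.Etot
    f = params.thermo_factor
    s_over_km = params.thermo.S / params.variant.KM
    W0 = f * (1.0 + s_over_km) + 1.0
    conc = np.array([1.0, f, f * s_over_km, 0.0]) * (Etot / W0)
    return StateVector(state_space(params.drug.binding_mode), conc, 0.0)


def analytic_product_rate(params: VariantDrugParameters, R: float = 0.0) -> float:
    """Closed-form quasi-equilibrium product formation rate (uM/min) at fixed R.

    For an inactive-state binder the bound weight [R]/R_D attaches to the
    inactive state; for an active-state binder it rides on the active
    conformational factor. Equivalent to rate(0)*IC50/(IC50+R).
    """
    if R < 0:
        raise ParameterError(f"inhibitor concentration must be >= 0, got {R}")
    f = params.thermo_factor
    s_over_km = params.thermo.S / params.variant.KM
    r_over_rd = R / params.inhibitor.RD
    if params.drug.binding_mode == INACTIVE_BINDER:
        Wtot = f * (1.0 + s_over_km) + (1.0 + r_over_rd)
    else:
        Wtot = f * (1.0 + s_over_km + r_over_rd) + 1.0
    return params.variant.kcat * params.thermo.Etot * f * s_over_km / Wtot


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _euler_chunk(y, M0, M1, R_steps, dt):  # pragma: no cover - compiled
        # fully unrolled 4-state step; M1 only couples the binding pair
        y0, y1, y2, y3 = y[0], y[1], y[2], y[3]
        n = R_steps.shape[0]
        for k in range(n):
            R = R_steps[k]
            d0 = M0[0, 0] * y0 + M0[0, 1] * y1 + M0[0, 2] * y2 + M0[0, 3] * y3
            d1 = M0[1, 0] * y0 + M0[1, 1] * y1 + M0[1, 2] * y2 + M0[1, 3] * y3
            d2 = M0[2, 0] * y0 + M0[2, 1] * y1 + M0[2, 2] * y2 + M0[2, 3] * y3
            d3 = M0[3, 0] * y0 + M0[3, 1] * y1 + M0[3, 2] * y2 + M0[3, 3] * y3
            d0 += R * (M1[0, 0] * y0 + M1[0, 1] * y1)
            d1 += R * (M1[1, 0] * y0 + M1[1, 1] * y1)
            d3 += R * (M1[3, 0] * y0 + M1[3, 1] * y1)
            y0 += dt * d0
            y1 += dt * d1
            y2 += dt * d2
            y3 += dt * d3
        return np.array([y0, y1, y2, y3])

else:  # pragma: no cover

    def _euler_chunk(y, M0, M1, R_steps, dt):
        for R in R_steps:
            y = y + dt * ((M0 + R * M1) @ y)
        return y


def _check_nonnegative(y: np.ndarray, t: float, config: SimulationConfig) -> None:
    if y.min() < -NEGATIVE_TOL:
        raise StabilityError(
            f"state concentration {y.min():.3e} uM at t={t:.3f} min is below "
            f"-{NEGATIVE_TOL:g}; reduce the step size (dt={config.dt:g} min)"
        )


def _integrate_euler(
    y0: np.ndarray,
    M0: np.ndarray,
    M1: np.ndarray,
    conc_fn: Callable,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    stride = max(1, round(config.output_dt / config.dt))
    n_out = int(round(config.duration / (stride * config.dt)))
    dt = config.dt
    out_times = np.empty(n_out + 1)
    out_states = np.empty((n_out + 1, 4))
    out_times[0], out_states[0] = 0.0, y0
    y = y0.copy()
    for i in range(n_out):
        t0 = i * stride * dt
        step_times = t0 + np.arange(stride) * dt
        R_steps = np.asarray(conc_fn(step_times), dtype=float)
        y = _euler_chunk(y, M0, M1, R_steps, dt)
        t1 = (i + 1) * stride * dt
        _check_nonnegative(y, t1, config)
        out_times[i + 1] = t1
        out_states[i + 1] = y
    return out_times, out_states


def _integrate_adaptive(
    y0: np.ndarray,
    M0: np.ndarray,
    M1: np.ndarray,
    conc_fn: Callable,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    n_out = int(np.floor(config.duration / config.output_dt + 1e-9))
    out_times = np.arange(n_out + 1) * config.output_dt
    # the integration range always covers the last stored sample, which can
    # sit a rounding error past the nominal duration
    end = max(config.duration, float(out_times[-1]))
    # Split at dose times: the concentration has slope breaks there.
    breaks = np.asarray(getattr(conc_fn, "breakpoints", ()), dtype=float)
    edges = np.unique(
        np.concatenate([[0.0, end], breaks[(breaks > 0) & (breaks < end)]])
    )

    def rhs(t, y):
        return (M0 + float(conc_fn(t)) * M1) @ y

    def jac(t, y):
        return M0 + float(conc_fn(t)) * M1

    states = np.empty((out_times.size, 4))
    states[0] = y0
    y = y0.copy()
    filled = 1
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = out_times[(out_times > a) & (out_times <= b)]
        # always evaluate the segment end so the carried state is y(b)
        t_eval_full = t_eval if t_eval.size and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            jac=jac,
            t_eval=t_eval_full,
            rtol=config.rel_tol,
            atol=config.abs_tol,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise StabilityError(f"adaptive integration failed on [{a}, {b}]: {sol.message}")
        if t_eval.size:
            states[filled : filled + t_eval.size] = sol.y[:, : t_eval.size].T
            filled += t_eval.size
        y = sol.y[:, -1]
        _check_nonnegative(y, b, config)
    assert filled == out_times.size, "output grid not fully covered by segments"
    return out_times, states


def integrate(
    init: StateVector,
    params: VariantDrugParameters,
    conc_fn: Callable,
    config: SimulationConfig = SimulationConfig(),
) -> Trajectory:
    """Advance the 4-state system under a time-varying inhibitor concentration.

    ``conc_fn`` maps time (min) to plasma concentration (nM); if it exposes a
    ``breakpoints`` attribute (dose times), the adaptive integrator splits
    there. Returns samples every ``config.output_dt`` minutes.
    """
    expected = state_space(params.drug.binding_mode)
    if init.space.labels != expected.labels:
        raise ParameterError(
            f"initial state has labels {init.space.labels}, "
            f"but drug {params.drug.name!r} needs {expected.labels}"
        )
    y0 = np.asarray(init.concentrations, dtype=float)
    M0, M1 = generator_parts(params)
    if config.method == "euler_fixed":
        times, states = _integrate_euler(y0, M0, M1, conc_fn, config)
    else:
        times, states = _integrate_adaptive(y0, M0, M1, conc_fn, config)
    conc = np.asarray(conc_fn(times), dtype=float)
    rate = params.variant.kcat * states[:, 2]
    return Trajectory(expected, times, states, conc, rate)


def constant_concentration(R: float) -> Callable:
    """A conc_fn holding the inhibitor at a fixed concentration (nM)."""
    if R < 0:
        raise ParameterError(f"inhibitor concentration must be >= 0, got {R}")

    def fn(t):
        return np.full(np.shape(t), float(R)) if np.ndim(t) else float(R)

    return fn


def product_rate_series(traj: Trajectory) -> np.ndarray:
    """kcat*[E_AS] (uM/min) at each stored sample."""
    if traj.times.size == 0:
        raise ParameterError("trajectory is empty")
    return traj.product_rate
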