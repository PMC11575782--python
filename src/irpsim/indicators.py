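"""Resistance indicators and variant x drug comparison reports.

The model's headline indicator is the *inhibitory reduction prowess* (IRP):
the percentage by which the product formation rate at the steady-state
inter-dose midpoint falls below the untreated rate,

    IRP = (rate[R=0] - rate[steady-state + 0.5 day]) / rate[R=0] * 100%.

A high IRP means the treatment suppresses catalysis throughout the dosing
cycle; resistant combinations show low IRP. The midpoint is taken at 9.5
days after the first dose (day-10 of a once-daily course is safely in the
periodic steady state) and the day-10 minimum and maximum product rates
bound the daily swing.

The incumbent selection heuristics computed alongside for comparison:

- relative IC50, ``IC50_mut / IC50_wt`` per drug;
- effective IC50 ratio, ``IC50 / (IC50 + [R](t))`` against the actual
  fluctuating plasma concentration — values above 0.5 mean the drug
  concentration sits below the IC50, a "state of resistance";
- catalytic efficiency ``kcat/K_M`` and the substrate saturation fraction
  ``[S]/([S]+K_M)``, which do not depend on the inhibitor at all.

``comparison_report`` runs the whole pipeline (parameter derivation ->
dosing curve -> ODE integration -> indicators) for each combination and
tabulates the results next to the clinical resistance annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ConfigurationError,
    DrugSpec,
    EnzymeVariant,
    ParameterError,
    ThermoConfig,
    VariantDrugParameters,
    build_parameter_set,
)
from . import pharmacokinetics as pk
from .kinetics import (
    SimulationConfig,
    Trajectory,
    analytic_product_rate,
    initial_state,
    integrate,
)

__all__ = [
    "IndicatorReport",
    "irp",
    "effective_ic50_ratio",
    "effective_ratio_day_series",
    "relative_ic50",
    "catalytic_efficiency",
    "saturation",
    "drug_constants",
    "simulate_combination",
    "comparison_report",
    "report_frame",
]

TAU_MIN = 1440.0


@dataclass(frozen=True)
class IndicatorReport:
    """All indicators for one variant x drug combination.

    ``irp_mid`` is the day-10 midpoint IRP (%); ``irp_min``/``irp_max`` the
    IRP range over the day-10 window. ``eff_ic50_ratio_series`` samples
    IC50/(IC50+[R]) at 1-min resolution over the steady-state day.
    """

    variant: str
    drug: str
    irp_mid: float
    irp_min: float
    irp_max: float
    eff_ic50_ratio_series: np.ndarray
    relative_ic50: float
    catalytic_efficiency: float
    saturation: float
    vmax: float
    resistant_annotation: str

    @property
    def eff_ratio_mid(self) -> float:
        return float(self.eff_ic50_ratio_series[len(self.eff_ic50_ratio_series) // 2])


# ---------------------------------------------------------------------------
# Elementary indicators
# ---------------------------------------------------------------------------


def irp(
    traj: Trajectory, baseline: float, day: int = 9
) -> tuple[float, float, float]:
    """(midpoint, min, max) IRP in % over the 24 h window of ``day``.

    The midpoint IRP is evaluated at ``day + 0.5`` days after the first
    dose; the range comes from the extreme product rates over the window
    (the daily maximum rate gives the minimum IRP and vice versa).
    """
    if not baseline > 0:
        raise ParameterError(f"baseline rate must be > 0, got {baseline}")
    start, end = day * TAU_MIN, (day + 1) * TAU_MIN
    if traj.times[-1] < end - 1e-9:
        raise ParameterError(
            f"trajectory ends at {traj.times[-1]:.0f} min but the day-{day + 1} "
            f"window needs {end:.0f} min"
        )
    mask = (traj.times >= start) & (traj.times < end)
    window = traj.product_rate[mask]
    rate_mid = float(np.interp(start + TAU_MIN / 2.0, traj.times, traj.product_rate))
    to_irp = lambda rate: (baseline - rate) / baseline * 100.0
    return to_irp(rate_mid), to_irp(window.max()), to_irp(window.min())


def effective_ic50_ratio(ic50: float, R) -> float | np.ndarray:
    """IC50/(IC50+[R]); > 0.5 exactly when the concentration is below the IC50."""
    if not ic50 > 0:
        raise ParameterError(f"IC50 must be > 0, got {ic50}")
    return ic50 / (ic50 + np.asarray(R, dtype=float)) if np.ndim(R) else ic50 / (ic50 + R)


def effective_ratio_day_series(
    ic50: float,
    profile: pk.ConcentrationProfile,
    day: int = 9,
    grid_step: float = 1.0,
) -> np.ndarray:
    """IC50/(IC50+[R](t)) sampled over the 24 h window of ``day``."""
    times = np.arange(day * TAU_MIN, (day + 1) * TAU_MIN, grid_step)
    return np.asarray(effective_ic50_ratio(ic50, profile(times)))


def relative_ic50(ic50_mut: float, ic50_wt: float) -> float:
    """Fold change of the IC50 relative to the wild type."""
    if not (ic50_mut > 0 and ic50_wt > 0):
        raise ParameterError("both IC50 values must be > 0")
    return ic50_mut / ic50_wt


def catalytic_efficiency(kcat: float, KM: float) -> float:
    """kcat/K_M, uM^-1 min^-1."""
    if not (kcat > 0 and KM > 0):
        raise ParameterError("kcat and KM must be > 0")
    return kcat / KM


def saturation(S: float, KM: float) -> float:
    """Substrate saturation fraction [S]/([S]+K_M)."""
    if S < 0 or not KM > 0:
        raise ParameterError(f"need S >= 0 and KM > 0, got S={S}, KM={KM}")
    return S / (S + KM)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def drug_constants(drug: DrugSpec, pk_mode: str = "printed") -> pk.PKConstants:
    """PK constants for a drug, from printed table values or raw inputs."""
    if drug.pk is None:
        raise ConfigurationError(f"drug {drug.name!r} has no PK inputs")
    if pk_mode == "derived":
        return pk.pk_constants(drug.pk.inputs)
    if pk_mode == "printed":
        return drug.pk.printed
    raise ConfigurationError(f"pk_mode must be 'printed' or 'derived', got {pk_mode!r}")


def simulate_combination(
    params: VariantDrugParameters,
    constants: pk.PKConstants,
    schedule: Optional[pk.DoseSchedule] = None,
    sim_config: Optional[SimulationConfig] = None,
) -> tuple[Trajectory, float]:
    """Run the dosing-course simulation; returns (trajectory, untreated rate)."""
    if schedule is None:
        schedule = pk.DoseSchedule(n_days=10)
    if sim_config is None:
        sim_config = SimulationConfig(duration=schedule.n_days * constants.tau_min)
    profile = pk.make_profile(schedule, constants)
    traj = integrate(initial_state(params), params, profile, sim_config)
    return traj, analytic_product_rate(params, R=0.0)


def comparison_report(
    variants: Sequence[EnzymeVariant],
    drugs: Sequence[DrugSpec],
    annotations: Mapping[tuple[str, str], str],
    thermo: ThermoConfig = ThermoConfig(),
    pk_mode: str = "printed",
    sim_config: Optional[SimulationConfig] = None,
    schedule: Optional[pk.DoseSchedule] = None,
    day: int = 9,
) -> list[IndicatorReport]:
    """One IndicatorReport per variant x drug, from the full pipeline.

    The wild type must be present (first or anywhere) in ``variants``: it
    anchors both the cross-variant rate transfer and the relative IC50.
    Deterministic for a fixed schedule seed and simulation config.
    """
    wt = next((v for v in variants if v.ddG == 0.0 and "wild" in v.name.lower()), None)
    if wt is None:
        raise ConfigurationError("variant list must include the wild type")
    if not drugs:
        raise ConfigurationError("drug list is empty")

    reports: list[IndicatorReport] = []
    for drug in drugs:
        constants = drug_constants(drug, pk_mode)
        sched = schedule if schedule is not None else pk.DoseSchedule(n_days=day + 1)
        profile = pk.make_profile(sched, constants)
        wt_params = build_parameter_set(wt, drug, thermo)
        for variant in variants:
            params = (
                wt_params
                if variant is wt
                else build_parameter_set(variant, drug, thermo, wt_reference=wt_params)
            )
            traj, baseline = simulate_combination(params, constants, sched, sim_config)
            irp_mid, irp_min, irp_max = irp(traj, baseline, day=day)
            ic50 = variant.ic50(drug.name)
            reports.append(
                IndicatorReport(
                    variant=variant.name,
                    drug=drug.name,
                    irp_mid=irp_mid,
                    irp_min=irp_min,
                    irp_max=irp_max,
                    eff_ic50_ratio_series=effective_ratio_day_series(ic50, profile, day),
                    relative_ic50=relative_ic50(ic50, wt.ic50(drug.name)),
                    catalytic_efficiency=catalytic_efficiency(variant.kcat, variant.KM),
                    saturation=saturation(thermo.S, variant.KM),
                    vmax=variant.kcat * thermo.Etot,
                    resistant_annotation=annotations.get(
                        (variant.name, drug.name), "sensitive"
                    ),
                )
            )
    return reports


def report_frame(reports: Iterable[IndicatorReport]) -> pd.DataFrame:
    """Flatten reports to a DataFrame (series summarised by mid/min/max)."""
    rows = []
    for r in reports:
        series = r.eff_ic50_ratio_series
        rows.append(
            {
                "variant": r.variant,
                "drug": r.drug,
                "irp_mid_pct": r.irp_mid,
                "irp_min_pct": r.irp_min,
                "irp_max_pct": r.irp_max,
                "eff_ic50_ratio_mid": r.eff_ratio_mid,
                "eff_ic50_ratio_min": float(series.min()),
                "eff_ic50_ratio_max": float(series.max()),
                "relative_ic50": r.relative_ic50,
                "catalytic_efficiency_uM_min": r.catalytic_efficiency,
                "saturation": r.saturation,
                "vmax_uM_min": r.vmax,
                "resistant_annotation": r.resistant_annotation,
            }
        )
    return pd.DataFrame(rows)
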