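"""Microscopic rate constants for Abl1 variant x inhibitor combinations.

The dynamic model needs a full set of elementary rate constants (substrate
on/off, inhibitor on/off, active<->inactive conformational exchange) for every
enzyme variant and drug, but only composite quantities are measurable:
``kcat``, the Michaelis constant ``K_M``, the inhibitor ``IC50`` and the
residence time ``t_R``. This module implements the quasi-equilibrium
back-calculation from those measurables.

The derivation chain, in the order it runs:

1. ``koffR = 1/t_R`` for the wild type (:func:`residence_to_koff`).
2. The inhibitor dissociation constant ``R_D`` from the IC50 via the
   quasi-equilibrium weights: ``R_D = IC50/(eta+1)`` for an inactive-state
   binder, ``R_D = IC50*f/(eta+1)`` for an active-state binder, with
   ``eta = f*(1+[S]/K_M)`` and ``f`` the Boltzmann factor of the
   inactive->active free-energy difference (:func:`dissociation_constant`).
3. ``konR = koffR/R_D`` (:func:`kon_from_koff`).
4. Substrate rates from ``kcat`` and ``K_M = (kcat+koffS)/konS``: the wild
   type is assumed to catalyse more often than it releases substrate
   (``koffS = kcat/2``); mutants the opposite (``koffS = 2*kcat``), floored
   so that no mutant out-competes the wild type on substrate association
   (:func:`substrate_rates`).
5. Cross-variant transfer rules: inactive binders keep the wild-type
   ``koffR`` for every mutant; the active binder keeps the wild-type
   ``konR`` except for ATP-site mutants, where it is rescaled by the
   variant's substrate on-rate ratio (:func:`inhibitor_rates_for_variant`).

Units are explicit and never mixed: the inhibitor domain works in nM
(IC50, R_D, konR in nM^-1 min^-1), the enzyme/substrate domain in uM
(K_M, [S], konS in uM^-1 min^-1); all times are minutes. ``konR*[R]`` and
``konS*[S]`` both reduce to min^-1, so the two domains never meet in a
single expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "R_KCAL_PER_MOL_K",
    "ParameterError",
    "ConfigurationError",
    "EnzymeVariant",
    "DrugSpec",
    "ThermoConfig",
    "SubstrateRates",
    "InhibitorRates",
    "VariantDrugParameters",
    "residence_to_koff",
    "thermo_factor",
    "eta",
    "dissociation_constant",
    "kon_from_koff",
    "substrate_rates",
    "inhibitor_rates_for_variant",
    "trans_rates",
    "mutant_dG",
    "build_parameter_set",
]

#: Molar gas constant in kcal/(mol*K), used by the per-mole convention.
R_KCAL_PER_MOL_K = 1.9872e-3

INACTIVE_BINDER = "inactive_binder"
ACTIVE_BINDER = "active_binder"
BINDING_MODES = (INACTIVE_BINDER, ACTIVE_BINDER)

THERMO_CONVENTIONS = ("effective_unity", "per_mole_RT")


class ParameterError(ValueError):
    """Raised when measured inputs are mutually inconsistent or out of domain."""


class ConfigurationError(ValueError):
    """Raised when a requested variant/drug combination cannot be assembled."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnzymeVariant:
    """One form of the Abl1 kinase (wild type or mutant).

    Parameters
    ----------
    name:
        Variant identifier, e.g. ``"Wild-type"`` or ``"E255K"``.
    kcat:
        Catalytic turnover number, min^-1.
    KM:
        Michaelis constant, uM.
    ddG:
        Shift of the inactive->active free-energy difference relative to the
        wild type, kcal/mol (0 for the wild type).
    ic50_by_drug:
        Map drug name -> IC50 in nM.
    atp_site_mutant:
        True when the mutated residue forms or borders the ATP pocket
        (position 315); controls the active-binder ``konR`` transfer rule.
    """

    name: str
    kcat: float
    KM: float
    ddG: float = 0.0
    ic50_by_drug: Mapping[str, float] = field(default_factory=dict)
    atp_site_mutant: bool = False

    def __post_init__(self) -> None:
        if not self.kcat > 0:
            raise ParameterError(f"{self.name}: kcat must be > 0, got {self.kcat}")
        if not self.KM > 0:
            raise ParameterError(f"{self.name}: KM must be > 0, got {self.KM}")
        for drug, ic50 in self.ic50_by_drug.items():
            if not ic50 > 0:
                raise ParameterError(
                    f"{self.name}: IC50 for {drug} must be > 0, got {ic50}"
                )

    def ic50(self, drug_name: str) -> float:
        try:
            return float(self.ic50_by_drug[drug_name])
        except KeyError:
            raise ConfigurationError(
                f"variant {self.name!r} has no IC50 for drug {drug_name!r}"
            ) from None


@dataclass(frozen=True)
class DrugSpec:
    """An Abl1 inhibitor: identity, conformational binding mode, residence time.

    ``koffR_printed`` carries the literature unbinding rate when it differs
    from ``1/tR`` beyond rounding (the shipped dasatinib pair is internally
    inconsistent; every downstream derived constant follows the printed
    ``koffR``, so that column takes precedence when present).
    """

    name: str
    binding_mode: str
    tR: float
    koffR_printed: Optional[float] = None
    pk: Optional[object] = None  # PKInputs; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        if self.binding_mode not in BINDING_MODES:
            raise ParameterError(
                f"{self.name}: binding_mode must be one of {BINDING_MODES}, "
                f"got {self.binding_mode!r}"
            )
        if not self.tR > 0:
            raise ParameterError(f"{self.name}: residence time must be > 0")

    @property
    def koffR_wt(self) -> float:
        """Wild-type unbinding rate constant, min^-1."""
        if self.koffR_printed is not None:
            return float(self.koffR_printed)
        return residence_to_koff(self.tR)


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic and concentration context shared by all derivations.

    ``convention`` selects how the inactive->active free energy enters:

    - ``"effective_unity"`` (default): the Boltzmann factor is taken as
      exactly 1 for every variant. The wild-type free-energy difference is
      about -1 kcal/mol and the mutational shifts are fractions of kcal/mol,
      so the factor is of order one; the unity choice is the effective
      parameterisation under which every published derived constant is
      reproduced, and it keeps the conformational exchange symmetric
      (ktransA = ktransI).
    - ``"per_mole_RT"``: the literal ``exp(-(dG_WT+ddG)/(R*T))`` with R in
      kcal/(mol*K); provided for sensitivity analysis.
    """

    dG_WT: float = -1.0
    convention: str = "effective_unity"
    temperature: float = 300.0
    S: float = 10.0
    Etot: float = 1.0

    def __post_init__(self) -> None:
        if self.convention not in THERMO_CONVENTIONS:
            raise ParameterError(
                f"convention must be one of {THERMO_CONVENTIONS}, got {self.convention!r}"
            )
        if not self.temperature > 0:
            raise ParameterError("temperature must be > 0")
        if self.S < 0:
            raise ParameterError("substrate concentration must be >= 0")
        if not self.Etot > 0:
            raise ParameterError("total enzyme concentration must be > 0")


@dataclass(frozen=True)
class SubstrateRates:
    """Substrate binding rate constants: konS in uM^-1 min^-1, koffS in min^-1."""

    konS: float
    koffS: float

    def __post_init__(self) -> None:
        if not self.konS > 0 or not self.koffS > 0:
            raise ParameterError(
                f"substrate rates must be > 0, got konS={self.konS}, koffS={self.koffS}"
            )


@dataclass(frozen=True)
class InhibitorRates:
    """Inhibitor binding constants: RD in nM, konR in nM^-1 min^-1, koffR in min^-1."""

    RD: float
    konR: float
    koffR: float

    def __post_init__(self) -> None:
        if not (self.RD > 0 and self.konR > 0 and self.koffR > 0):
            raise ParameterError(
                f"inhibitor rates must be > 0, got RD={self.RD}, "
                f"konR={self.konR}, koffR={self.koffR}"
            )


@dataclass(frozen=True)
class VariantDrugParameters:
    """Complete derived rate-constant set for one variant x drug simulation."""

    variant: EnzymeVariant
    drug: DrugSpec
    substrate: SubstrateRates
    inhibitor: InhibitorRates
    ktransA: float
    ktransI: float
    thermo: ThermoConfig

    @property
    def thermo_factor(self) -> float:
        return thermo_factor(self.thermo, self.variant.ddG)


# ---------------------------------------------------------------------------
# Elementary derivations
# ---------------------------------------------------------------------------


def residence_to_koff(tR: float) -> float:
    """Unbinding rate constant (min^-1) from a residence time (min)."""
    if not tR > 0:
        raise ParameterError(f"residence time must be > 0, got {tR}")
    return 1.0 / tR


def thermo_factor(thermo: ThermoConfig, ddG: float) -> float:
    """Boltzmann factor of the variant's inactive->active free-energy difference.

    Under ``effective_unity`` this is exactly 1 for every ddG; under
    ``per_mole_RT`` it is ``exp(-(dG_WT+ddG)/(R*T))``.
    """
    if thermo.convention == "effective_unity":
        return 1.0
    dG = thermo.dG_WT + ddG
    return math.exp(-dG / (R_KCAL_PER_MOL_K * thermo.temperature))


def eta(factor: float, S: float, KM: float) -> float:
    """Occupancy weight of the substrate-accessible states, f*(1+[S]/K_M)."""
    if not KM > 0:
        raise ParameterError(f"KM must be > 0, got {KM}")
    if S < 0:
        raise ParameterError(f"substrate concentration must be >= 0, got {S}")
    return factor * (1.0 + S / KM)


def dissociation_constant(
    ic50: float, mode: str, eta_value: float, factor: float
) -> float:
    """Inhibitor dissociation constant R_D (nM) from the IC50 (nM).

    At ``[R] = IC50`` the product formation rate halves, which pins the
    dissociation constant to ``IC50/(eta+1)`` for an inactive-state binder
    and ``IC50*f/(eta+1)`` for an active-state binder.
    """
    if not ic50 > 0:
        raise ParameterError(f"IC50 must be > 0, got {ic50}")
    if eta_value < 0:
        raise ParameterError(f"eta must be >= 0, got {eta_value}")
    if mode == INACTIVE_BINDER:
        return ic50 / (eta_value + 1.0)
    if mode == ACTIVE_BINDER:
        return ic50 * factor / (eta_value + 1.0)
    raise ParameterError(f"unknown binding mode {mode!r}")


def kon_from_koff(koffR: float, RD: float) -> float:
    """Binding rate constant konR = koffR/R_D (nM^-1 min^-1)."""
    if not koffR > 0:
        raise ParameterError(f"koffR must be > 0, got {koffR}")
    if not RD > 0:
        raise ParameterError(f"RD must be > 0, got {RD}")
    return koffR / RD


def substrate_rates(
    kcat: float, KM: float, konS_WT: Optional[float] = None, is_wt: bool = False
) -> SubstrateRates:
    """Substrate on/off rates from kcat and K_M.

    Wild type: catalysis beats release, ``koffS = kcat/2``, then
    ``konS = (kcat+koffS)/K_M``. Mutant: release beats catalysis,
    ``koffS = 2*kcat`` hence ``konS = 3*kcat/K_M`` — unless that on-rate
    would fall below the wild type's, in which case the mutant inherits the
    wild-type on-rate and ``koffS = K_M*konS_WT - kcat`` (the mutant must
    still compete with the wild type for substrate in untreated conditions).

    Both branches satisfy ``(kcat+koffS)/konS = K_M`` exactly by construction.
    """
    if not kcat > 0 or not KM > 0:
        raise ParameterError(f"kcat and KM must be > 0, got kcat={kcat}, KM={KM}")
    if is_wt:
        koffS = kcat / 2.0
        return SubstrateRates(konS=(kcat + koffS) / KM, koffS=koffS)
    if konS_WT is None or not konS_WT > 0:
        raise ParameterError("mutant derivation needs the wild-type konS (> 0)")
    candidate = 3.0 * kcat / KM
    if candidate >= konS_WT:
        return SubstrateRates(konS=candidate, koffS=2.0 * kcat)
    koffS = KM * konS_WT - kcat
    if not koffS > 0:
        raise ParameterError(
            f"inconsistent inputs: fallback koffS = KM*konS_WT - kcat = {koffS} <= 0"
        )
    return SubstrateRates(konS=konS_WT, koffS=koffS)


def inhibitor_rates_for_variant(
    drug: DrugSpec,
    variant: EnzymeVariant,
    wt_rates: InhibitorRates,
    konS_ratio: float,
    RD_mut: float,
) -> InhibitorRates:
    """Transfer wild-type binding kinetics to a mutant.

    Inactive binders interact with the bound state in essentially the
    wild-type way, so ``koffR`` is conserved and ``konR = koffR/R_D``.
    The active binder competes with ATP for the active-state pocket: its
    ``konR`` is conserved for mutations away from the pocket and rescaled by
    the substrate on-rate ratio (a proxy for the changed ATP-site
    association) for ATP-site mutants; ``koffR`` then follows from R_D.
    """
    if not konS_ratio > 0:
        raise ParameterError(f"konS ratio must be > 0, got {konS_ratio}")
    if drug.binding_mode == INACTIVE_BINDER:
        koffR = wt_rates.koffR
        return InhibitorRates(RD=RD_mut, koffR=koffR, konR=kon_from_koff(koffR, RD_mut))
    konR = wt_rates.konR * (konS_ratio if variant.atp_site_mutant else 1.0)
    return InhibitorRates(RD=RD_mut, konR=konR, koffR=konR * RD_mut)


def trans_rates(variant: EnzymeVariant) -> tuple[float, float]:
    """Conformational exchange rates (ktransA, ktransI), min^-1.

    Exchange is fast (order konS*[S]) and symmetric, consistent with a
    near-unity conformational Boltzmann factor: 60 min^-1 for every variant,
    reduced to 55 min^-1 for G250E whose stability shift is the largest.
    """
    k = 55.0 if variant.name == "G250E" else 60.0
    return (k, k)


def mutant_dG(dG_WT: float, ddG: float) -> float:
    """Mutant inactive->active free-energy difference, kcal/mol."""
    return dG_WT + ddG


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def build_parameter_set(
    variant: EnzymeVariant,
    drug: DrugSpec,
    thermo: ThermoConfig = ThermoConfig(),
    wt_reference: Optional[VariantDrugParameters] = None,
) -> VariantDrugParameters:
    """Assemble the full rate-constant set for one variant x drug pair.

    ``wt_reference`` must be the wild-type parameter set for the same drug
    when ``variant`` is a mutant; pass ``None`` for the wild type itself.
    """
    factor = thermo_factor(thermo, variant.ddG)
    eta_value = eta(factor, thermo.S, variant.KM)
    RD = dissociation_constant(
        variant.ic50(drug.name), drug.binding_mode, eta_value, factor
    )

    if wt_reference is None:
        substrate = substrate_rates(variant.kcat, variant.KM, is_wt=True)
        koffR = drug.koffR_wt
        inhibitor = InhibitorRates(RD=RD, koffR=koffR, konR=kon_from_koff(koffR, RD))
    else:
        konS_WT = wt_reference.substrate.konS
        substrate = substrate_rates(variant.kcat, variant.KM, konS_WT=konS_WT)
        inhibitor = inhibitor_rates_for_variant(
            drug,
            variant,
            wt_reference.inhibitor,
            konS_ratio=substrate.konS / konS_WT,
            RD_mut=RD,
        )

    # Detailed balance between the conformations: ktransI/ktransA equals the
    # Boltzmann factor (exactly 1 under the default convention).
    ktransA, ktransI = trans_rates(variant)
    ktransI = ktransA * factor
    return VariantDrugParameters(
        variant=variant,
        drug=drug,
        substrate=substrate,
        inhibitor=inhibitor,
        ktransA=ktransA,
        ktransI=ktransI,
        thermo=thermo,
    )
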