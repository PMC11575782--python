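"""Fixture tables, validation, synthetic variants, and pipeline orchestration.

The package ships its measured inputs as five delimited-text tables
(``src/irpsim/data``): catalytic parameters and IC50s per variant, inhibitor
residence times and binding modes, conformational free-energy shifts,
pharmacokinetic inputs with the printed dosing constants, and clinical
resistance annotations. :func:`load_fixtures` parses and validates them into
typed domain objects; headers carry units in the column names and a renamed
or missing column raises :class:`SchemaError` naming the offending field.

:func:`synthesize_variant` draws reproducible hypothetical enzyme variants
(log-uniform kinetic and inhibition parameters) so property tests can sweep
the derivation and simulation machinery far beyond the shipped tables.

:func:`run_pipeline` is the batch driver behind the CLI ``report`` command:
derive parameters, build the dosing curve, integrate, compute indicators,
and write deterministic CSV output, logging the provenance of every derived
constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ConfigurationError,
    DrugSpec,
    EnzymeVariant,
    ThermoConfig,
    VariantDrugParameters,
    build_parameter_set,
)
from . import pharmacokinetics as pk
from .kinetics import SimulationConfig
from .indicators import comparison_report, report_frame

__all__ = [
    "SchemaError",
    "DrugPK",
    "FixtureBundle",
    "RunConfig",
    "load_fixtures",
    "write_fixtures",
    "synthesize_variant",
    "run_pipeline",
]

logger = logging.getLogger("irpsim")

DRUG_NAMES = ("imatinib", "ponatinib", "dasatinib")

_SCHEMAS = {
    "catalytic_params": [
        "variant",
        "kcat_per_min",
        "KM_uM",
        "ic50_imatinib_nM",
        "ic50_ponatinib_nM",
        "ic50_dasatinib_nM",
        "atp_site_mutant",
    ],
    "residence_times": ["drug", "binding_mode", "tR_min", "koffR_per_min"],
    "ddg": [
        "variant",
        "dG_wt_to_mut_active_kcal_mol",
        "dG_wt_to_mut_inactive_kcal_mol",
        "ddG_kcal_mol",
    ],
    "pk_inputs": [
        "drug",
        "ka_per_h",
        "t_half_e_h",
        "ke_per_h",
        "D_mg",
        "M_g_mol",
        "D_umol",
        "Vd_L",
        "tau_h",
        "F",
        "gamma_nM",
        "alpha",
        "epsilon",
    ],
    "resistance_annotations": ["variant", "imatinib", "ponatinib", "dasatinib"],
}


class SchemaError(ValueError):
    """A fixture table is missing a required, unit-annotated column."""


@dataclass(frozen=True)
class DrugPK:
    """Pharmacokinetic data for one drug: raw inputs and printed constants."""

    inputs: pk.PKInputs
    printed: pk.PKConstants


@dataclass(frozen=True)
class FixtureBundle:
    """Validated measured inputs: typed objects plus the raw tables."""

    variants: dict[str, EnzymeVariant]
    drugs: dict[str, DrugSpec]
    annotations: dict[tuple[str, str], str]
    tables: dict[str, pd.DataFrame]
    raw_text: dict[str, str]

    @property
    def variant_names(self) -> list[str]:
        return list(self.variants)

    @property
    def simulated_variant_names(self) -> list[str]:
        """Variants with a conformational free-energy entry (the dynamic set)."""
        return [str(v) for v in self.tables["ddg"]["variant"]]

    @property
    def wild_type(self) -> EnzymeVariant:
        return self.variants["Wild-type"]


def _read_table(path: Path, name: str) -> tuple[pd.DataFrame, str]:
    text = path.read_text()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    missing = [c for c in _SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"fixture table {name!r} ({path.name}) is missing required "
            f"column(s): {', '.join(missing)}"
        )
    return df, text


def load_fixtures(path: Optional[Path] = None) -> FixtureBundle:
    """Load and validate the fixture tables (packaged defaults if no path)."""
    if path is None:
        path = Path(str(resources.files("irpsim").joinpath("data")))
    path = Path(path)

    tables: dict[str, pd.DataFrame] = {}
    raw_text: dict[str, str] = {}
    for name in _SCHEMAS:
        tables[name], raw_text[name] = _read_table(path / f"{name}.tsv", name)

    ddg_by_variant = {
        str(row["variant"]): float(row["ddG_kcal_mol"])
        for _, row in tables["ddg"].iterrows()
    }

    variants: dict[str, EnzymeVariant] = {}
    for _, row in tables["catalytic_params"].iterrows():
        name = str(row["variant"])
        variants[name] = EnzymeVariant(
            name=name,
            kcat=float(row["kcat_per_min"]),
            KM=float(row["KM_uM"]),
            ddG=ddg_by_variant.get(name, 0.0),
            ic50_by_drug={d: float(row[f"ic50_{d}_nM"]) for d in DRUG_NAMES},
            atp_site_mutant=str(row["atp_site_mutant"]).strip().lower() == "true",
        )

    pk_rows = {str(r["drug"]): r for _, r in tables["pk_inputs"].iterrows()}
    drugs: dict[str, DrugSpec] = {}
    for _, row in tables["residence_times"].iterrows():
        name = str(row["drug"])
        p = pk_rows[name]
        inputs = pk.PKInputs(
            F=float(p["F"]),
            D_mass=float(p["D_mg"]),
            M=float(p["M_g_mol"]),
            ka=float(p["ka_per_h"]),
            t_half_e=float(p["t_half_e_h"]),
            Vd=float(p["Vd_L"]),
            tau=float(p["tau_h"]),
        )
        printed = pk.printed_constants(
            Gamma=float(p["gamma_nM"]),
            alpha=float(p["alpha"]),
            epsilon=float(p["epsilon"]),
            tau=float(p["tau_h"]),
        )
        drugs[name] = DrugSpec(
            name=name,
            binding_mode=str(row["binding_mode"]),
            tR=float(row["tR_min"]),
            koffR_printed=float(row["koffR_per_min"]),
            pk=DrugPK(inputs=inputs, printed=printed),
        )

    annotations = {
        (str(row["variant"]), d): str(row[d])
        for _, row in tables["resistance_annotations"].iterrows()
        for d in DRUG_NAMES
    }
    return FixtureBundle(variants, drugs, annotations, tables, raw_text)


def write_fixtures(bundle: FixtureBundle, out_dir: Path) -> None:
    """Write the fixture tables back verbatim (byte-identical round trip)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, text in bundle.raw_text.items():
        (out_dir / f"{name}.tsv").write_text(text)


# ---------------------------------------------------------------------------
# Synthetic variants
# ---------------------------------------------------------------------------

#: Log-uniform sampling ranges spanning the shipped measurements with margin.
DEFAULT_SYNTH_RANGES: dict[str, tuple[float, float]] = {
    "kcat": (3.0, 200.0),  # min^-1
    "KM": (0.5, 25.0),  # uM
    "ic50": (1.0, 11000.0),  # nM
}


def synthesize_variant(
    seed: int,
    ranges: Optional[Mapping[str, tuple[float, float]]] = None,
    drug_names: Sequence[str] = DRUG_NAMES,
) -> EnzymeVariant:
    """A reproducible hypothetical variant with log-uniform parameters."""
    r = dict(DEFAULT_SYNTH_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if not (0 < lo <= hi):
            raise ConfigurationError(f"range for {key!r} must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        lo, hi = r[key]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return EnzymeVariant(
        name=f"synthetic-{seed}",
        kcat=draw("kcat"),
        KM=draw("KM"),
        ddG=float(rng.uniform(-2.5, 0.5)),
        ic50_by_drug={d: draw("ic50") for d in drug_names},
        atp_site_mutant=bool(rng.integers(0, 2)),
    )


# ---------------------------------------------------------------------------
# Batch pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full batch run."""

    variants: Optional[Sequence[str]] = None  # default: the simulated set
    drugs: Sequence[str] = DRUG_NAMES
    convention: str = "effective_unity"
    pk_mode: str = "printed"
    n_days: int = 10
    jitter_width: float = 0.0
    seed: Optional[int] = None
    method: str = "adaptive"
    out_dir: Path = Path("irpsim-out")
    fixtures: Optional[Path] = None


def _log_provenance(params: VariantDrugParameters, pk_mode: str) -> None:
    v, d = params.variant.name, params.drug.name
    log = lambda key, rule, value: logger.info(
        "derived %s x %s: %s = %.6g [%s]", v, d, key, value, rule
    )
    log("konS_uM_min", "michaelis_relation", params.substrate.konS)
    log("koffS_per_min", "catalysis_release_branch", params.substrate.koffS)
    log("RD_nM", "ic50_quasi_equilibrium", params.inhibitor.RD)
    log("konR_nM_min", "dissociation_ratio", params.inhibitor.konR)
    log("koffR_per_min", "residence_or_transfer", params.inhibitor.koffR)
    log("ktransA_per_min", "conformational_exchange", params.ktransA)
    log("ktransI_per_min", "detailed_balance", params.ktransI)
    logger.info("derived %s x %s: pk_mode = %s", v, d, pk_mode)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Derive -> dose -> simulate -> indicators for every combination.

    Writes a deterministic summary ``report.csv`` under ``config.out_dir``
    and returns the summary frame; per-combination trajectories are
    available through the CLI ``simulate`` command.
    """
    bundle = load_fixtures(config.fixtures)
    if not config.drugs:
        raise ConfigurationError("drug list is empty")
    names = (
        list(config.variants)
        if config.variants is not None
        else bundle.simulated_variant_names
    )
    missing = [n for n in names if n not in bundle.variants]
    missing += [d for d in config.drugs if d not in bundle.drugs]
    if missing:
        raise ConfigurationError(f"unknown variant/drug name(s): {missing}")

    thermo = ThermoConfig(convention=config.convention)
    schedule = pk.DoseSchedule(
        n_days=config.n_days, jitter_width=config.jitter_width, seed=config.seed
    )
    sim_config = SimulationConfig(
        method=config.method, duration=config.n_days * 1440.0
    )
    variants = [bundle.variants[n] for n in names]
    drugs = [bundle.drugs[d] for d in config.drugs]

    wt = bundle.wild_type
    for drug in drugs:
        wt_params = build_parameter_set(wt, drug, thermo)
        _log_provenance(wt_params, config.pk_mode)
        for variant in variants:
            if variant.name != wt.name:
                _log_provenance(
                    build_parameter_set(variant, drug, thermo, wt_reference=wt_params),
                    config.pk_mode,
                )

    reports = comparison_report(
        variants,
        drugs,
        bundle.annotations,
        thermo=thermo,
        pk_mode=config.pk_mode,
        sim_config=sim_config,
        schedule=schedule,
        day=config.n_days - 1,
    )
    frame = report_frame(reports)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "report.csv", index=False, float_format="%.10g")
    logger.info("wrote %s (%d combinations)", out_dir / "report.csv", len(frame))
    return frame
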