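"""Rate-constant derivation: published examples and structural invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from irpsim import (
    ConfigurationError,
    DrugSpec,
    EnzymeVariant,
    InhibitorRates,
    ParameterError,
    ThermoConfig,
    build_parameter_set,
    dissociation_constant,
    eta,
    inhibitor_rates_for_variant,
    kon_from_koff,
    mutant_dG,
    residence_to_koff,
    substrate_rates,
    thermo_factor,
    trans_rates,
)
from irpsim.parameters import R_KCAL_PER_MOL_K

positive = st.floats(min_value=1e-3, max_value=1e4)


@pytest.mark.parametrize(
    "tR, expected, rel",
    [(17.0, 0.059, 3e-3), (205.0, 0.00488, 1e-3), (1.0, 1.0, 1e-12)],
)
def test_residence_time_reciprocal(tR, expected, rel):
    assert residence_to_koff(tR) == pytest.approx(expected, rel=rel)


def test_residence_time_must_be_positive():
    with pytest.raises(ParameterError):
        residence_to_koff(0.0)


def test_thermo_factor_conventions():
    unity = ThermoConfig(convention="effective_unity")
    assert thermo_factor(unity, -2.2) == 1.0
    assert thermo_factor(unity, 5.0) == 1.0
    literal = ThermoConfig(convention="per_mole_RT", dG_WT=-1.0)
    assert thermo_factor(literal, 1.0) == pytest.approx(1.0)  # dG_WT + ddG = 0
    expected = math.exp(1.0 / (R_KCAL_PER_MOL_K * 300.0))
    assert thermo_factor(literal, 0.0) == pytest.approx(expected)
    assert thermo_factor(literal, 0.0) == pytest.approx(5.35, rel=2e-3)


@pytest.mark.parametrize(
    "factor, S, KM, expected",
    [(1.0, 10.0, 17.0, 1.0 + 10.0 / 17.0), (1.0, 0.0, 17.0, 1.0), (2.0, 10.0, 10.0, 4.0)],
)
def test_eta(factor, S, KM, expected):
    assert eta(factor, S, KM) == pytest.approx(expected)


def test_eta_rejects_zero_km():
    with pytest.raises(ParameterError):
        eta(1.0, 10.0, 0.0)


def test_dissociation_constant_examples():
    eta_wt = eta(1.0, 10.0, 17.0)
    assert dissociation_constant(527.0, "inactive_binder", eta_wt, 1.0) == pytest.approx(
        203.6, abs=0.05
    )
    assert dissociation_constant(1.8, "active_binder", eta_wt, 1.0) == pytest.approx(
        0.695, abs=5e-4
    )
    for mode in ("inactive_binder", "active_binder"):
        assert dissociation_constant(42.0, mode, 0.0, 1.0) == pytest.approx(42.0)


@given(
    ic50=positive,
    eta_lo=st.floats(min_value=0.0, max_value=50.0),
    delta=st.floats(min_value=1e-3, max_value=10.0),
)
def test_dissociation_constant_monotone(ic50, eta_lo, delta):
    """R_D rises with IC50 and falls as the substrate/conformation weight grows."""
    for mode in ("inactive_binder", "active_binder"):
        base = dissociation_constant(ic50, mode, eta_lo, 1.0)
        assert dissociation_constant(ic50 * (1 + delta), mode, eta_lo, 1.0) > base
        assert dissociation_constant(ic50, mode, eta_lo + delta, 1.0) < base


@pytest.mark.parametrize(
    "koff, RD, expected",
    [(4.88e-3, 0.811, 6.02e-3), (2.33e-3, 0.695, 3.35e-3), (7.0, 7.0, 1.0)],
)
def test_kon_from_koff(koff, RD, expected):
    assert kon_from_koff(koff, RD) == pytest.approx(expected, rel=2e-3)


def test_substrate_rates_wild_type():
    rates = substrate_rates(66.0, 17.0, is_wt=True)
    assert rates.koffS == pytest.approx(33.0)
    assert rates.konS == pytest.approx(5.82, abs=5e-3)


def test_substrate_rates_mutant_branches():
    konS_WT = substrate_rates(66.0, 17.0, is_wt=True).konS
    fast = substrate_rates(175.2, 14.3, konS_WT=konS_WT)  # release-dominated branch
    assert fast.koffS == pytest.approx(2 * 175.2)
    assert fast.konS == pytest.approx(36.8, abs=0.05)
    slow = substrate_rates(6.8, 22.1, konS_WT=konS_WT)  # inherits the WT on-rate
    assert slow.konS == konS_WT
    assert slow.koffS == pytest.approx(122.0, abs=0.5)


@given(kcat=positive, KM=positive, konS_WT=positive)
def test_substrate_rates_satisfy_michaelis_relation(kcat, KM, konS_WT):
    """(kcat+koffS)/konS = K_M exactly, in both branches and for the WT."""
    wt = substrate_rates(kcat, KM, is_wt=True)
    assert (kcat + wt.koffS) / wt.konS == pytest.approx(KM, rel=1e-12)
    mut = substrate_rates(kcat, KM, konS_WT=konS_WT)
    assert (kcat + mut.koffS) / mut.konS == pytest.approx(KM, rel=1e-12)
    if mut.konS == konS_WT:  # fallback branch
        assert mut.koffS == pytest.approx(KM * konS_WT - kcat)
    else:
        assert mut.koffS / kcat == pytest.approx(2.0, rel=1e-12)
        assert mut.konS >= konS_WT


def test_inhibitor_rate_transfer_rules(bundle, params_for):
    # inactive binder: koffR conserved, konR follows from R_D
    g250e = params_for("G250E", "ponatinib")
    assert g250e.inhibitor.koffR == pytest.approx(4.88e-3)
    assert g250e.inhibitor.RD == pytest.approx(4.63, abs=0.005)
    assert g250e.inhibitor.konR == pytest.approx(1.05e-3, rel=5e-3)
    # active binder, ATP-site mutant: konR rescaled by the substrate on-rate ratio
    t315m = params_for("T315M", "dasatinib")
    assert t315m.inhibitor.konR == pytest.approx(7.37e-3, rel=5e-3)
    assert t315m.inhibitor.koffR == pytest.approx(0.779, rel=5e-3)
    # active binder, non-ATP-site mutant: konR inherited unchanged
    e255k = params_for("E255K", "dasatinib")
    assert e255k.inhibitor.konR == params_for("Wild-type", "dasatinib").inhibitor.konR


def test_inhibitor_rates_identity_when_nothing_changes():
    drug = DrugSpec(name="d", binding_mode="inactive_binder", tR=100.0)
    variant = EnzymeVariant(name="v", kcat=10.0, KM=5.0)
    wt = InhibitorRates(RD=2.0, koffR=0.01, konR=0.005)
    out = inhibitor_rates_for_variant(drug, variant, wt, konS_ratio=1.0, RD_mut=2.0)
    assert (out.RD, out.konR, out.koffR) == (wt.RD, wt.konR, wt.koffR)


def test_conformational_exchange_rates(bundle):
    assert trans_rates(bundle.wild_type) == (60.0, 60.0)
    assert trans_rates(bundle.variants["G250E"]) == (55.0, 55.0)
    assert trans_rates(bundle.variants["T315I"]) == (60.0, 60.0)


@pytest.mark.parametrize(
    "dG_WT, ddG, expected", [(-1.0, -2.2, -3.2), (-1.0, 0.0, -1.0), (0.0, 0.4, 0.4)]
)
def test_mutant_free_energy_sum(dG_WT, ddG, expected):
    assert mutant_dG(dG_WT, ddG) == pytest.approx(expected)


def test_build_parameter_set_spot_checks(params_for):
    wt_im = params_for("Wild-type", "imatinib")
    assert wt_im.inhibitor.RD == pytest.approx(203.6, abs=0.05)
    assert wt_im.inhibitor.koffR == pytest.approx(0.059)
    assert wt_im.inhibitor.konR == pytest.approx(2.90e-4, rel=5e-3)
    assert params_for("E255V", "imatinib").inhibitor.RD == pytest.approx(3651, abs=1)
    sub = params_for("Y253H-E255V", "imatinib").substrate
    assert (sub.koffS, sub.konS) == (pytest.approx(26.4, abs=0.05),
                                     pytest.approx(56.6, abs=0.05))


def test_derived_rates_internally_consistent(bundle, params_for):
    """R_D * konR = koffR to machine precision for every combination."""
    for drug in bundle.drugs:
        for name in bundle.simulated_variant_names:
            inh = params_for(name, drug).inhibitor
            assert inh.RD * inh.konR == pytest.approx(inh.koffR, rel=1e-12)


def test_missing_ic50_is_a_configuration_error(bundle):
    variant = EnzymeVariant(name="v", kcat=10.0, KM=5.0, ic50_by_drug={})
    with pytest.raises(ConfigurationError):
        build_parameter_set(variant, bundle.drugs["imatinib"])


def test_detailed_balance_under_literal_convention(bundle):
    thermo = ThermoConfig(convention="per_mole_RT")
    p = build_parameter_set(bundle.wild_type, bundle.drugs["imatinib"], thermo)
    assert p.ktransI / p.ktransA == pytest.approx(p.thermo_factor, rel=1e-12)
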