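"""4-state dynamics: conservation, fixed points, closed-form cross-checks."""

import numpy as np
import pytest

from irpsim import (
    DoseSchedule,
    ParameterError,
    SimulationConfig,
    StabilityError,
    analytic_product_rate,
    build_generator,
    drug_constants,
    initial_state,
    integrate,
    make_profile,
    product_rate_series,
    state_space,
    synthesize_variant,
    build_parameter_set,
    ThermoConfig,
)
from irpsim.kinetics import constant_concentration

from conftest import equilibration_time


def test_state_space_per_binding_mode():
    assert state_space("inactive_binder").labels == ("E_I", "E_A", "E_AS", "E_IR")
    assert state_space("active_binder").labels == ("E_I", "E_A", "E_AS", "E_AR")


@pytest.mark.parametrize("drug_name", ["imatinib", "ponatinib", "dasatinib"])
@pytest.mark.parametrize("R", [0.0, 203.6, 5000.0])
def test_generator_conserves_enzyme(params_for, drug_name, R):
    M = build_generator(params_for("E255K", drug_name), R)
    assert np.allclose(M.sum(axis=0), 0.0, atol=1e-12)


def test_generator_structure(params_for):
    p = params_for("Wild-type", "imatinib")
    M = build_generator(p, 0.0)
    # no binding flux at R=0: the bound state only drains
    assert M[3, 0] == 0.0 and M[3, 1] == 0.0
    assert M[0, 3] == pytest.approx(p.inhibitor.koffR)
    # at R = R_D the binding flux balances unbinding
    M = build_generator(p, p.inhibitor.RD)
    assert M[3, 0] == pytest.approx(p.inhibitor.koffR, rel=1e-12)
    with pytest.raises(ParameterError):
        build_generator(p, -1.0)


def test_initial_state_quasi_equilibrium(params_for):
    state = initial_state(params_for("Wild-type", "imatinib"))
    assert state["E_I"] == pytest.approx(0.3864, abs=5e-5)
    assert state["E_A"] == pytest.approx(0.3864, abs=5e-5)
    assert state["E_AS"] == pytest.approx(0.2273, abs=5e-5)
    assert state["E_IR"] == 0.0
    assert state.total == pytest.approx(1.0, rel=1e-12)


def test_initial_state_without_substrate(bundle):
    thermo = ThermoConfig(S=0.0)
    p = build_parameter_set(bundle.wild_type, bundle.drugs["imatinib"], thermo)
    state = initial_state(p)
    assert state["E_AS"] == 0.0
    assert state["E_I"] == pytest.approx(0.5)
    assert state["E_A"] == pytest.approx(0.5)


def test_untreated_equilibrium_is_a_fixed_point(params_for):
    """With no inhibitor the analytic initial state does not move."""
    p = params_for("G250E", "imatinib")
    traj = integrate(
        initial_state(p), p, constant_concentration(0.0), SimulationConfig(duration=500.0)
    )
    assert np.allclose(traj.states, traj.states[0], rtol=1e-8, atol=1e-12)
    base = analytic_product_rate(p, 0.0)
    assert np.abs(product_rate_series(traj) - base).max() <= 1e-6 * base


@pytest.mark.parametrize(
    "variant, drug", [("E255K", "imatinib"), ("T315I", "dasatinib")]
)
def test_constant_concentration_reaches_closed_form(params_for, variant, drug):
    """Long-time simulated state matches the quasi-equilibrium weights."""
    p = params_for(variant, drug)
    R = 2.5 * p.inhibitor.RD
    t_end = equilibration_time(build_generator(p, R))
    traj = integrate(
        initial_state(p), p, constant_concentration(R), SimulationConfig(duration=t_end)
    )
    expected = analytic_product_rate(p, R)
    assert traj.product_rate[-1] == pytest.approx(expected, rel=1e-6)
    # simulated occupancies match the normalised equilibrium weights
    f = p.thermo_factor
    s_km = p.thermo.S / p.variant.KM
    r_rd = R / p.inhibitor.RD
    if p.drug.binding_mode == "inactive_binder":
        weights = np.array([1.0, f, f * s_km, r_rd])
    else:
        weights = np.array([1.0, f, f * s_km, f * r_rd])
    expected_states = weights / weights.sum() * p.thermo.Etot
    assert np.allclose(traj.states[-1], expected_states, rtol=1e-6)


def test_ic50_concentration_halves_the_rate(params_for):
    p = params_for("E255K", "ponatinib")
    ic50 = p.variant.ic50("ponatinib")
    t_end = equilibration_time(build_generator(p, ic50))
    traj = integrate(
        initial_state(p), p, constant_concentration(ic50), SimulationConfig(duration=t_end)
    )
    assert traj.product_rate[-1] / analytic_product_rate(p, 0.0) == pytest.approx(
        0.5, abs=1e-4
    )


def test_enzyme_conserved_over_ten_days(params_for):
    p = params_for("E255K", "dasatinib")
    constants = drug_constants(p.drug, "printed")
    profile = make_profile(DoseSchedule(n_days=10), constants)
    traj = integrate(initial_state(p), p, profile, SimulationConfig(duration=14400.0))
    totals = traj.states.sum(axis=1)
    assert np.abs(totals - totals[0]).max() <= 1e-6 * totals[0]
    assert np.all(traj.states >= -1e-12)


def test_euler_reference_agrees_with_adaptive(params_for):
    """Adaptive product rates within 0.1% of the 1 ms forward-Euler reference."""
    p = params_for("E255K", "imatinib")
    constants = drug_constants(p.drug, "printed")
    profile = make_profile(DoseSchedule(n_days=1), constants)
    init = initial_state(p)
    window = 120.0  # spans the initial transient and the absorption ramp
    euler = integrate(init, p, profile, SimulationConfig(method="euler_fixed", duration=window))
    adaptive = integrate(init, p, profile, SimulationConfig(duration=window))
    rel = np.abs(adaptive.product_rate - euler.product_rate) / euler.product_rate
    assert rel.max() < 1e-3


def test_unstable_step_raises(params_for):
    p = params_for("G250E", "imatinib")  # stiff: koffS+kcat ~ 525 min^-1
    with pytest.raises(StabilityError, match="step"):
        integrate(
            initial_state(p),
            p,
            constant_concentration(5000.0),
            SimulationConfig(method="euler_fixed", duration=10.0, dt=0.01, output_dt=1.0),
        )


def test_binding_mode_mismatch_rejected(params_for):
    p_im = params_for("T315I", "imatinib")
    p_das = params_for("T315I", "dasatinib")
    with pytest.raises(ParameterError, match="labels"):
        integrate(initial_state(p_das), p_im, constant_concentration(0.0),
                  SimulationConfig(duration=1.0))


@pytest.mark.parametrize("drug", ["imatinib", "dasatinib"])
def test_analytic_rate_equals_ic50_fraction(params_for, drug):
    """rate(R) = rate(0) * IC50/(IC50+R), and halves exactly at R = IC50."""
    p = params_for("E255V", drug)
    ic50 = p.variant.ic50(drug)
    base = analytic_product_rate(p, 0.0)
    assert analytic_product_rate(p, ic50) == pytest.approx(base / 2.0, rel=1e-12)
    for R in (0.0, 10.0, ic50, 20 * ic50):
        assert analytic_product_rate(p, R) == pytest.approx(
            base * ic50 / (ic50 + R), rel=1e-12
        )


def test_synthetic_variants_preserve_total_enzyme():
    """Initial occupancies always sum to Etot, whatever the parameters."""
    drug_proto = dict(name="imatinib", binding_mode="inactive_binder", tR=17.0)
    from irpsim import DrugSpec

    for seed in range(20):
        v = synthesize_variant(seed)
        thermo = ThermoConfig(convention="per_mole_RT")  # exercises f != 1
        p = build_parameter_set(v, DrugSpec(**drug_proto), thermo)
        assert initial_state(p).total == pytest.approx(thermo.Etot, rel=1e-12)
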