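"""CO2 assimilation: limitation structure, C3 reduction, conservation."""

from dataclasses import replace

import numpy as np
import pytest

from photoalloc import (
    Allocation,
    EnergyPartition,
    Environment,
    SimulationContext,
    SpeciesParams,
    net_assimilation,
    simulate,
)

from _oracles import c3_light_limited, farquhar_c3_enzyme, hyperbola


def _c3_like(g_s=0.003, xi=0.0, beta=0.0):
    return SpeciesParams(
        label="c3-like",
        ptype="C3",
        beta=beta,
        k_ccat=2.9,
        xi=xi,
        K_p=80.0,
        g_s=g_s,
        allocation_bounds={"n_C4": (0.0, 0.0)},
    )


def test_min_structure_and_tie_rule():
    r = net_assimilation(10.0, 12.0, 10.0, 8.0)
    assert r.A == 8.0 and r.limiting == "enzyme"
    r = net_assimilation(8.0, 12.0, 8.0, 10.0)
    assert r.A == 8.0 and r.limiting == "ATP"
    r = net_assimilation(12.0, 8.0, 8.0, 10.0)
    assert r.A == 8.0 and r.limiting == "NADPH"
    r = net_assimilation(9.0, 9.5, 9.0, 9.0)  # tie labeled enzyme
    assert r.A == 9.0 and r.limiting == "enzyme"


def test_simulate_invariants(c4, evo_env, c4_alloc, c4_partition):
    r = simulate(c4, evo_env, c4_alloc, c4_partition)
    assert r.A == min(r.A_j, r.A_c)
    assert r.A_j == min(r.A_j_ATP, r.A_j_NADPH)
    assert r.A <= r.A_j + 1e-12 and r.A <= r.A_c + 1e-12


def test_zero_nitrogen_means_zero_assimilation(c4, c4_alloc, c4_partition):
    env = Environment(I=1500.0, T=30.0, C_m=100.0, N_t=0.0)
    r = simulate(c4, env, c4_alloc, c4_partition)
    assert r.A == 0.0


def test_zero_light_means_zero_light_limited(c4, c4_alloc, c4_partition):
    env = Environment(I=0.0, T=30.0, C_m=100.0, N_t=130.0)
    r = simulate(c4, env, c4_alloc, c4_partition)
    assert r.A_j == 0.0 and r.A == 0.0


def test_c3_enzyme_limited_reduces_to_farquhar(c3_alloc, c3_partition):
    """V_pmax = 0, xi = 0, beta = 0: the two-compartment model collapses to
    the single-compartment enzyme-limited C3 rate on a 5x5 grid."""
    sp = _c3_like()
    kin = sp.kinetics
    for c_m in (50.0, 100.0, 150.0, 250.0, 400.0):
        for i in (100.0, 300.0, 600.0, 1000.0, 1800.0):
            env = Environment(I=i, T=25.0, C_m=c_m, O=200.0, N_t=130.0)
            ctx = SimulationContext(sp, env)
            r = ctx.evaluate(c3_alloc, c3_partition)
            caps = r.diagnostics["capacities"]
            expected = farquhar_c3_enzyme(
                caps.E_tot * sp.k_ccat, c_m, 200.0, kin.K_c, kin.K_o, kin.S_co
            )
            assert r.A_c == pytest.approx(expected, rel=1e-10)


def test_c3_light_limited_closed_form_no_photorespiration(c3_alloc):
    """With O2 = 0 (phi = 0) and all energy in the mesophyll pools the
    light-limited components equal atp/3 and J_LET/4."""
    sp = _c3_like()
    part = EnergyPartition(1.0, 0.0, 0.0, 0.0, 0.0)
    env = Environment(I=500.0, T=25.0, C_m=150.0, O=0.0, N_t=130.0)
    ctx = SimulationContext(sp, env)
    r = ctx.evaluate(c3_alloc, part)
    fluxes = r.diagnostics["light"]["fluxes"]
    supply = r.diagnostics["light"]["supply"]
    assert r.A_j_ATP == pytest.approx(supply.atp_rate / 3.0, rel=1e-12)
    assert r.A_j_NADPH == pytest.approx(fluxes.J_LET / 4.0, rel=1e-12)


def test_c3_light_limited_matches_oracle_with_photorespiration(c3_alloc):
    sp = _c3_like()
    part = EnergyPartition(0.75, 0.0, 0.25, 0.0, 0.0)
    kin = sp.kinetics
    env = Environment(I=400.0, T=25.0, C_m=120.0, O=200.0, N_t=130.0)
    ctx = SimulationContext(sp, env)
    r = ctx.evaluate(c3_alloc, part)
    fluxes = r.diagnostics["light"]["fluxes"]
    a_atp, a_nadph = c3_light_limited(
        fluxes.J_LET, fluxes.J_CET, 120.0, 200.0, kin.S_co, (0.75, 0.25)
    )
    assert r.A_j_ATP == pytest.approx(a_atp, rel=1e-10)
    assert r.A_j_NADPH == pytest.approx(a_nadph, rel=1e-10)


def test_light_fluxes_follow_hyperbola(c4, evo_env, c4_alloc):
    ctx = SimulationContext(c4, evo_env)
    r = ctx.evaluate(c4_alloc, EnergyPartition(0.0, 0.5, 0.0, 0.1, 0.4))
    caps = r.diagnostics["capacities"]
    fluxes = r.diagnostics["light"]["fluxes"]
    jmax_let_t = caps.Jmax_LET * ctx.tfac["J_max"]
    assert fluxes.J_LET == pytest.approx(
        hyperbola(fluxes.I_LET, jmax_let_t), rel=1e-12
    )
    assert fluxes.J_t == fluxes.J_LET + fluxes.J_CET


def test_monotone_in_light(c4, c4_alloc, c4_partition):
    """A_j never decreases along a 20-point light ramp."""
    prev = -1.0
    for i in np.linspace(0.0, 2000.0, 20):
        env = Environment(I=float(i), T=30.0, C_m=100.0, N_t=130.0)
        r = simulate(c4, env, c4_alloc, c4_partition)
        assert r.A_j >= prev - 1e-9
        prev = r.A_j


def test_monotone_in_mesophyll_co2_for_c3(c3_alloc, c3_partition):
    sp = _c3_like()
    prev = -1.0
    for c_m in np.linspace(50.0, 150.0, 11):
        env = Environment(I=1000.0, T=25.0, C_m=float(c_m), N_t=130.0)
        r = simulate(sp, env, c3_alloc, c3_partition)
        assert r.A >= prev - 1e-9
        prev = r.A


def test_enzyme_limited_increases_with_rubisco(c4, evo_env, c4_partition):
    """A_c strictly increases with E_tot (via n_Etot) at fixed environment."""
    prev = -1.0
    for n_etot in np.linspace(0.05, 0.5, 10):
        alloc = Allocation(n_etot, 0.08, 1.0 - n_etot - 0.08, 0.6)
        r = simulate(c4, evo_env, alloc, c4_partition)
        assert r.A_c > prev
        prev = r.A_c


def test_c4_saturation_at_high_co2(c4, c4_alloc, c4_partition):
    """As mesophyll CO2 grows the enzyme-limited rate approaches the total
    Rubisco capacity (beta-weighted across compartments)."""
    env = Environment(I=1500.0, T=25.0, C_m=1e7, N_t=130.0)
    ctx = SimulationContext(c4, env)
    r = ctx.evaluate(c4_alloc, c4_partition)
    caps = r.diagnostics["capacities"]
    vcmax = caps.E_tot * ctx.kcat
    assert r.A_c == pytest.approx(vcmax, rel=1e-3)


def test_bundle_sheath_co2_conservation(c4, evo_env, c4_alloc, c4_partition):
    """Pump + shuttle + photorespiratory release balance Rubisco consumption
    and leakage at the solved bundle-sheath CO2 (residual < 1e-9)."""
    r = simulate(c4, evo_env, c4_alloc, c4_partition)
    d = r.diagnostics["enzyme"]
    leak = c4.g_s * (d["C_s"] - SimulationContext(c4, evo_env).Cm)
    residual = d["V_p"] + 0.5 * c4.xi * d["Vo_m"] + 0.5 * d["Vo_s"] - d["Vc_s"] - leak
    assert abs(residual) < 1e-9


def test_perturbing_nonbinding_limitation_leaves_a_unchanged(
    c4, evo_env, c4_alloc, c4_partition
):
    r = simulate(c4, evo_env, c4_alloc, c4_partition)
    if r.limiting == "enzyme":
        # more light cannot matter while enzymes bind
        brighter = replace(evo_env, I=evo_env.I * 1.2)
        r2 = simulate(c4, brighter, c4_alloc, c4_partition)
        assert r2.A == pytest.approx(r.A, rel=1e-9)
    else:
        # a better PEPC affinity only touches the enzyme branch
        easier = replace(c4, K_p=c4.K_p * 0.8)
        r2 = simulate(easier, evo_env, c4_alloc, c4_partition)
        assert r2.A == pytest.approx(r.A, rel=1e-9)


def test_glycine_shuttle_raises_intermediate_assimilation(c3_partition):
    """Shuttling mesophyll photorespiratory CO2 into the bundle sheath
    (xi > 0) benefits a C3-C4 leaf at low CO2."""
    alloc = Allocation(0.4, 0.0, 0.6, 0.9)
    part = EnergyPartition(0.55, 0.2, 0.2, 0.05, 0.0)
    base = dict(label="i", ptype="C3-C4", beta=0.25, k_ccat=3.0, K_p=80.0, g_s=0.003)
    env = Environment(I=1500.0, T=25.0, C_m=60.0, N_t=130.0)
    a_off = simulate(SpeciesParams(xi=0.0, **base), env, alloc, part).A_c
    a_on = simulate(SpeciesParams(xi=0.95, **base), env, alloc, part).A_c
    assert a_on > a_off
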