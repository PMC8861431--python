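import dataclasses

import numpy as np
import pytest

from srpkpd.chamber import (
    ChamberGeometry,
    DiffusionChamberModel,
    TransportParams,
    fit_mcl_diffusivity,
    fit_mcl_thickness,
    fit_metabolic_scaling,
    fit_support_diffusivity,
    flux_from_dataframe,
    flux_to_dataframe,
    slab_equilibration_rate,
    urea_compound,
)
from srpkpd.synth import NoiseModel, gen_flux_dataset


def _stable_root(chain):
    return chain[0].with_(halflife_extracellular_min=float("inf"))


def test_no_cells_equal_reservoirs_equilibrate_to_half(geometry, chain, transport_truth):
    model = DiffusionChamberModel(geometry, [_stable_root(chain)], has_mcl=False)
    sol = model.solve(transport_truth, 20.0, 6000.0,
                      sample_times_min=np.linspace(0, 6000, 11))
    assert sol.donor["CP-506"][-1] == pytest.approx(10.0, rel=0.01)
    assert sol.receiver["CP-506"][-1] == pytest.approx(10.0, rel=0.01)
    assert np.max(np.abs(sol.mass_balance() - 1.0)) <= 1e-5


def test_bare_membrane_matches_analytic_slab_permeation(geometry, chain, transport_truth):
    """Post-lag, donor-receiver difference decays at (DA/L)(1/Vd+1/Vr)."""
    model = DiffusionChamberModel(geometry, [_stable_root(chain)], has_mcl=False)
    ts = np.arange(0.0, 301.0, 5.0)
    sol = model.solve(transport_truth, 20.0, 300.0, sample_times_min=ts)
    rate, lag = slab_equilibration_rate(geometry, transport_truth.d_sup_cm2_s)
    diff = sol.donor["CP-506"] - sol.receiver["CP-506"]
    post = ts > 3.0 * lag
    slope = -np.polyfit(ts[post], np.log(diff[post]), 1)[0]
    assert slope == pytest.approx(rate, rel=0.02)


def test_mass_conserved_in_reactive_anoxic_chamber(geometry, chain):
    params = TransportParams(d_sup_cm2_s=0.717e-6)
    model = DiffusionChamberModel(geometry, chain, condition="anoxic", has_mcl=True)
    sol = model.solve(params, 17.4, 300.0, sample_times_min=np.arange(0.0, 301.0, 30.0))
    assert np.max(np.abs(sol.mass_balance() - 1.0)) <= 1e-5
    # metabolites released into both reservoirs
    assert sol.donor["CP-506M-Cl2"][-1] > 0
    assert sol.receiver["CP-506M-Cl2"][-1] > 0


def test_supraoxic_mcl_flux_is_ordered_and_conservative(geometry, chain, transport_truth):
    model = DiffusionChamberModel(geometry, chain, condition="supraoxic", has_mcl=True)
    sol = model.solve(transport_truth, 17.4, 300.0,
                      sample_times_min=np.arange(0.0, 301.0, 15.0))
    assert np.all(np.diff(sol.receiver["CP-506"]) > 0)
    assert np.all(np.diff(sol.donor["CP-506"]) < 0)
    assert np.max(np.abs(sol.mass_balance() - 1.0)) <= 1e-5


def test_vanishing_mcl_reduces_to_bare_membrane(geometry, transport_truth):
    thin = dataclasses.replace(geometry, mcl_thickness_um=0.5)
    ts = np.arange(0.0, 301.0, 15.0)
    with_mcl = DiffusionChamberModel(thin, [urea_compound()], has_mcl=True).solve(
        transport_truth, 0.0, 300.0, sample_times_min=ts, urea_c0_uM=10.0
    )
    bare = DiffusionChamberModel(geometry, [urea_compound()], has_mcl=False).solve(
        transport_truth, 0.0, 300.0, sample_times_min=ts, urea_c0_uM=10.0
    )
    assert with_mcl.receiver["urea"][-1] == pytest.approx(
        bare.receiver["urea"][-1], rel=0.05
    )


def test_doubling_thickness_doubles_quasi_steady_drop(geometry, transport_truth):
    """Steady-state flux through a slab scales as 1/L, so the concentration
    drop across the MCL scales as L at matched flux."""
    resistance = []
    for L in (101.7, 203.4):
        g = dataclasses.replace(geometry, mcl_thickness_um=L)
        sol = DiffusionChamberModel(g, [urea_compound()], has_mcl=True).solve(
            transport_truth, 0.0, 300.0,
            sample_times_min=np.array([0.0, 290.0, 300.0]), urea_c0_uM=10.0,
        )
        n = g.grid_nodes_per_layer
        ce = sol.ce_fields["urea"][-1]
        # quasi-steady flux from the receiver accumulation rate
        flux = (sol.receiver["urea"][-1] - sol.receiver["urea"][-2]) / 10.0
        resistance.append((ce[0] - ce[n - 1]) / flux)
    # drop per unit flux across the MCL scales with its thickness
    assert resistance[1] / resistance[0] == pytest.approx(2.0, rel=0.15)


def test_receiver_accumulation_monotone_in_d_kin_and_phi(geometry, chain):
    """Receiver build-up rises with D and falls with uptake/consumption."""
    base = TransportParams()
    ts = np.arange(0.0, 301.0, 60.0)

    def receiver_end(params, chain_, condition="supraoxic"):
        m = DiffusionChamberModel(geometry, chain_, condition=condition, has_mcl=True)
        return m.solve(params, 17.4, 300.0, sample_times_min=ts).receiver["CP-506"][-1]

    root = chain[0]
    r_base = receiver_end(base, [root])
    assert receiver_end(dataclasses.replace(base, d_mcl_cm2_s=2 * base.d_mcl_cm2_s), [root]) > r_base
    assert receiver_end(base, [root.with_(k_in=2 * root.k_in)]) < r_base
    # higher phi * k_met0 consumes more prodrug en route (anoxic)
    anx = TransportParams(d_sup_cm2_s=0.717e-6, phi=0.3)
    hi = TransportParams(d_sup_cm2_s=0.717e-6, phi=1.0)
    assert receiver_end(hi, chain, "anoxic") < receiver_end(anx, chain, "anoxic")


def test_phi_monotonicity_of_donor_depletion(geometry, chain):
    ts = np.arange(0.0, 301.0, 30.0)
    donors = {}
    for phi in (1e-3, 0.3, 1.0):
        p = TransportParams(d_sup_cm2_s=0.717e-6, phi=phi)
        m = DiffusionChamberModel(geometry, chain, condition="anoxic", has_mcl=True)
        donors[phi] = m.solve(p, 17.4, 300.0, sample_times_min=ts).donor["CP-506"]
    assert np.all(donors[1.0][1:] < donors[0.3][1:])
    assert np.all(donors[0.3][1:] < donors[1e-3][1:])
    # phi ~ 0: no metabolites produced
    m = DiffusionChamberModel(geometry, chain, condition="anoxic", has_mcl=True)
    sol = m.solve(TransportParams(d_sup_cm2_s=0.717e-6, phi=1e-6), 17.4, 300.0,
                  sample_times_min=ts)
    assert sol.receiver["CP-506H"][-1] < 1e-6


def test_grid_convergence_below_half_percent(geometry, chain, transport_truth):
    ts = np.arange(0.0, 301.0, 60.0)
    sols = {}
    for n in (50, 100):
        g = dataclasses.replace(geometry, grid_nodes_per_layer=n)
        m = DiffusionChamberModel(g, chain, condition="anoxic", has_mcl=True)
        p = TransportParams(d_sup_cm2_s=0.717e-6)
        sols[n] = m.solve(p, 17.4, 300.0, sample_times_min=ts)
    for side in ("donor", "receiver"):
        a = getattr(sols[50], side)["CP-506"][1:]
        b = getattr(sols[100], side)["CP-506"][1:]
        assert np.max(np.abs(a / b - 1.0)) < 0.005


def test_grid_too_coarse_rejected():
    with pytest.raises(ValueError):
        ChamberGeometry(grid_nodes_per_layer=10)


def test_noiseless_stage_fits_are_self_consistent(geometry, chain):
    truth = TransportParams()
    quiet = NoiseModel(cv_proportional=0.0, replicates=1)
    bare, _, _ = gen_flux_dataset(
        geometry, truth, [chain[0]], condition="supraoxic", has_mcl=False,
        include_urea=False, c0_uM=20.0, noise=quiet,
    )
    r = fit_support_diffusivity(bare, geometry, [chain[0]])
    assert r.estimates["d_sup_cm2_s"] == pytest.approx(truth.d_sup_cm2_s, rel=1e-3)

    urea, _, _ = gen_flux_dataset(
        geometry, truth, chain, condition="supraoxic", has_mcl=True,
        include_urea=True, c0_uM=0.0, urea_c0_uM=10.0, noise=quiet,
    )
    r = fit_mcl_thickness(urea, geometry, params=truth)
    assert r.estimates["l_mcl_um"] == pytest.approx(101.7, rel=1e-3)

    sup, _, _ = gen_flux_dataset(
        geometry, truth, chain, condition="supraoxic", has_mcl=True,
        include_urea=False, c0_uM=17.4, noise=quiet,
    )
    r = fit_mcl_diffusivity(sup, geometry, chain, params=truth)
    assert r.estimates["d_mcl_cm2_s"] == pytest.approx(truth.d_mcl_cm2_s, rel=1e-3)


def test_noiseless_phi_fit_is_self_consistent(geometry, chain):
    truth = TransportParams(d_sup_cm2_s=0.717e-6, phi=0.3)
    quiet = NoiseModel(cv_proportional=0.0, replicates=1)
    anx, _, _ = gen_flux_dataset(
        geometry, truth, chain, condition="anoxic", has_mcl=True,
        include_urea=False, c0_uM=17.4, noise=quiet,
    )
    r = fit_metabolic_scaling(anx, geometry, chain, params=truth)
    assert r.estimates["phi"] == pytest.approx(0.3, rel=1e-3)


def test_flux_dataframe_roundtrip(geometry, chain, transport_truth):
    data, df, _ = gen_flux_dataset(
        geometry, transport_truth, chain, condition="supraoxic", has_mcl=True,
        include_urea=True, noise=NoiseModel(cv_proportional=0.0, replicates=2),
    )
    back = flux_from_dataframe(df)
    assert len(back) == len(data)
    for a, b in zip(data, back):
        assert a.condition == b.condition
        for name in a.records:
            assert np.allclose(
                a.donor(name).concentrations_uM, b.donor(name).concentrations_uM
            )
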