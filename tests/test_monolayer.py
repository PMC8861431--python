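import copy

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from srpkpd._fitting import UnderDeterminedError
from srpkpd.monolayer import (
    MonolayerSetup,
    build_rate_matrix,
    fit_aerobic_uptake,
    fit_anoxic_metabolism,
    mass_balance,
    profiles_from_dataframe,
    profiles_to_dataframe,
    simulate_monolayer,
)
from srpkpd.params import CompoundParams
from srpkpd.synth import NoiseModel, gen_monolayer_dataset


def _stable_chain(chain):
    """Published chain with extracellular loss switched off."""
    return tuple(c.with_(halflife_extracellular_min=float("inf")) for c in chain)


def test_no_uptake_leaves_medium_constant(aerobic_setup, chain):
    frozen = tuple(
        c.with_(k_in=0.0, halflife_extracellular_min=float("inf")) for c in chain
    )
    profs = simulate_monolayer(aerobic_setup, frozen, "activator")
    for p in profs:
        if p.compound == "CP-506" and p.compartment == "extracellular":
            assert np.allclose(p.concentrations_uM, aerobic_setup.c0_uM, rtol=1e-12)
        else:
            assert np.allclose(p.concentrations_uM, 0.0, atol=1e-12)


@pytest.mark.parametrize(
    "oxygen, expected_ratio",
    [
        (200.0, 3.7 / 0.06),  # aerobic: k_in/k_out
        (0.0, 3.7 / (0.06 + 0.12)),  # anoxic: k_in/(k_out + k_met0)
    ],
)
def test_steady_state_partitioning_matches_closed_form(chain, oxygen, expected_ratio):
    setup = MonolayerSetup(medium_volume_ul=1e9, sample_times_min=(2000.0,))
    profs = simulate_monolayer(setup, _stable_chain(chain), "activator", oxygen_uM=oxygen)
    d = {(p.compound, p.compartment): p.concentrations_uM[-1] for p in profs}
    ratio = d[("CP-506", "intracellular")] / d[("CP-506", "extracellular")]
    assert ratio == pytest.approx(expected_ratio, rel=1e-3)


def test_matrix_exponential_agrees_with_fine_ode_oracle(anoxic_setup, chain):
    """The exact propagator must match an independent adaptive ODE solve."""
    times = np.linspace(0.0, 240.0, 9)
    A, idx = build_rate_matrix(chain, "activator", anoxic_setup.volume_ratio, 0.0)
    u0 = np.zeros(A.shape[0])
    u0[idx["CP-506"]] = anoxic_setup.c0_uM
    ref = solve_ivp(
        lambda t, u: A @ u, (0, 240.0), u0, t_eval=times, rtol=1e-11, atol=1e-12
    )
    profs = simulate_monolayer(
        anoxic_setup, chain, "activator", oxygen_uM=0.0, times_min=times
    )
    for p in profs:
        col = idx[p.compound] + (0 if p.compartment == "extracellular" else 1)
        assert np.allclose(p.concentrations_uM, np.clip(ref.y[col], 0, None),
                           rtol=1e-6, atol=1e-9)


@pytest.mark.parametrize("alpha", [0.1, 10.0])
def test_first_order_linearity_in_initial_concentration(anoxic_setup, chain, alpha):
    base = simulate_monolayer(anoxic_setup, chain, "activator", oxygen_uM=0.0)
    scaled_setup = MonolayerSetup(oxygen_uM=0.0, c0_uM=anoxic_setup.c0_uM * alpha)
    scaled = simulate_monolayer(scaled_setup, chain, "activator", oxygen_uM=0.0)
    for b, s in zip(base, scaled):
        assert np.allclose(s.concentrations_uM, alpha * b.concentrations_uM,
                           rtol=1e-9, atol=1e-12)


def test_mass_conserved_with_sink_tracking(anoxic_setup, chain):
    times = np.arange(0.0, 241.0, 10.0)
    profs, sink = simulate_monolayer(
        anoxic_setup, chain, "activator", oxygen_uM=0.0,
        times_min=times, return_sink=True,
    )
    balance = mass_balance(profs, anoxic_setup, sink)
    assert np.max(np.abs(balance - 1.0)) <= 1e-6


def test_balance_strictly_decreasing_without_sink(aerobic_setup):
    leaky = (CompoundParams(name="X", k_in=0.5, k_out=0.1,
                            halflife_extracellular_min=60.0),)
    times = np.arange(0.0, 181.0, 15.0)
    profs = simulate_monolayer(aerobic_setup, leaky, "wildtype", times_min=times)
    balance = mass_balance(profs, aerobic_setup)
    assert np.all(np.diff(balance) < 0)


def test_mass_balance_rejects_mismatched_grids(aerobic_setup, chain):
    profs = simulate_monolayer(aerobic_setup, chain, "activator")
    bad = copy.deepcopy(profs)
    bad[0].times_min = bad[0].times_min + 1.0
    with pytest.raises(ValueError):
        mass_balance(bad, aerobic_setup)


def test_noiseless_aerobic_fit_is_self_consistent(aerobic_setup, chain):
    data = [p for p in simulate_monolayer(aerobic_setup, chain, "activator")
            if p.compound == "CP-506"]
    res = fit_aerobic_uptake(data, aerobic_setup, chain)
    assert res.estimates["k_in:CP-506"] == pytest.approx(3.7, rel=1e-3)
    assert res.estimates["k_out:CP-506"] == pytest.approx(0.06, rel=1e-3)
    assert res.r_squared > 0.999999


def test_fully_censored_data_is_underdetermined(aerobic_setup, chain):
    data = [p for p in simulate_monolayer(aerobic_setup, chain, "activator")
            if p.compound == "CP-506"]
    for p in data:
        p.censored[:] = True
    with pytest.raises(UnderDeterminedError):
        fit_aerobic_uptake(data, aerobic_setup, chain)


def test_noisy_recovery_over_seeds(aerobic_setup, anoxic_setup, chain):
    """Generate-with-noise then refit recovers the generating constants."""
    kin, kout, kmet = [], [], []
    for seed in range(5):
        df, _ = gen_monolayer_dataset(
            aerobic_setup, chain, observed_compounds=["CP-506"],
            noise=NoiseModel(seed=seed),
        )
        res_a = fit_aerobic_uptake(profiles_from_dataframe(df), aerobic_setup, chain)
        kin.append(res_a.estimates["k_in:CP-506"])
        kout.append(res_a.estimates["k_out:CP-506"])
        dfx, _ = gen_monolayer_dataset(
            anoxic_setup, chain, oxygen_uM=0.0,
            observed_compounds=["CP-506", "CP-506H", "CP-506M"],
            noise=NoiseModel(seed=100 + seed),
        )
        res_x = fit_anoxic_metabolism(
            profiles_from_dataframe(dfx), anoxic_setup, chain, fixed=res_a
        )
        kmet.append(res_x.estimates["k_met0:CP-506"])
    assert np.median(kin) == pytest.approx(3.7, rel=0.10)
    assert np.median(kout) == pytest.approx(0.06, rel=0.10)
    assert np.median(kmet) == pytest.approx(0.12, rel=0.15)


def test_zero_metabolism_truth_recovers_as_zero(anoxic_setup, chain):
    inert = tuple(
        c.with_(k_met0_by_line={"activator": 0.0, "target": 0.0})
        if c.parent is None else c
        for c in chain
    )
    profs = simulate_monolayer(anoxic_setup, inert, "activator", oxygen_uM=0.0)
    for p in profs:
        if p.compound != "CP-506":
            assert np.allclose(p.concentrations_uM, 0.0, atol=1e-9)
    data = [p for p in profs if p.compound == "CP-506"]
    res = fit_anoxic_metabolism(
        data, anoxic_setup, chain,
        fixed={"k_in:CP-506": 3.7, "k_out:CP-506": 0.06},
        fit_compounds=[],
    )
    assert res.estimates["k_met0:CP-506"] < 1e-4


def test_metabolite_efflux_recovery(anoxic_setup, chain):
    """CP-506H k_out is identifiable from anoxic co-profiles (within 20%)."""
    est = []
    for seed in range(5):
        df, _ = gen_monolayer_dataset(
            anoxic_setup, chain, oxygen_uM=0.0,
            observed_compounds=["CP-506", "CP-506H", "CP-506M"],
            noise=NoiseModel(seed=200 + seed),
        )
        res = fit_anoxic_metabolism(
            profiles_from_dataframe(df), anoxic_setup, chain,
            fixed={"k_in:CP-506": 3.7, "k_out:CP-506": 0.06},
        )
        est.append(res.estimates["k_out:CP-506H"])
    assert np.median(est) == pytest.approx(0.25, rel=0.20)


def test_profile_dataframe_roundtrip(aerobic_setup, chain):
    profs = simulate_monolayer(aerobic_setup, chain, "activator")
    df = profiles_to_dataframe(profs)
    back = profiles_from_dataframe(df)
    orig = {(p.compound, p.compartment): p for p in profs}
    for p in back:
        q = orig[(p.compound, p.compartment)]
        assert np.allclose(p.concentrations_uM, q.concentrations_uM)
        assert np.array_equal(p.times_min, q.times_min)
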