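import numpy as np
import pytest

from srpkpd.monolayer import MonolayerSetup
from srpkpd.params import MEDIA_STABILITY_HALFLIVES_MIN
from srpkpd.synth import (
    NoiseModel,
    ScenarioSpec,
    gen_flux_dataset,
    gen_monolayer_dataset,
    gen_stability_dataset,
    gen_survival_dataset,
    generate_scenario,
    read_provenance,
    write_csv_with_provenance,
)


def test_same_seed_same_bytes(tmp_path, chain):
    paths = []
    for name in ("a.csv", "b.csv"):
        df, truth = gen_monolayer_dataset(noise=NoiseModel(seed=42))
        p = tmp_path / name
        write_csv_with_provenance(df, p, truth)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_noise_off_reproduces_simulator_exactly(aerobic_setup, chain):
    df, _ = gen_monolayer_dataset(
        aerobic_setup, chain, noise=NoiseModel(cv_proportional=0.0, replicates=1)
    )
    from srpkpd.monolayer import profiles_to_dataframe, simulate_monolayer

    ref = profiles_to_dataframe(simulate_monolayer(aerobic_setup, chain, "activator"))
    assert np.allclose(
        df["concentration_uM"].to_numpy(), ref["concentration_uM"].to_numpy()
    )


def test_no_uncensored_value_below_lloq(anoxic_setup, chain):
    df, _ = gen_monolayer_dataset(
        anoxic_setup, chain, oxygen_uM=0.0, noise=NoiseModel(seed=3)
    )
    ok = df.loc[df["censored"] == 0, "concentration_uM"]
    assert (ok >= 0.01).all()
    flagged = df.loc[df["censored"] == 1, "concentration_uM"]
    assert (flagged < 0.01).all()
    # the anoxic experiment produces censored metabolite points early on
    metab_ex = df[
        (df["compound"] == "CP-506M-Cl2") & (df["compartment"] == "extracellular")
    ]
    assert metab_ex["censored"].any()


def test_provenance_roundtrip(tmp_path):
    df, truth = gen_stability_dataset(noise=NoiseModel(seed=1))
    p = tmp_path / "stability.csv"
    write_csv_with_provenance(df, p, truth)
    back = read_provenance(p)
    assert back["kind"] == "media_stability"
    assert back["halflives_min"]["CP-506M"] == pytest.approx(7.6)
    assert back["halflives_min"]["CP-506"] is None  # stable


def test_stability_decay_halves_at_halflife():
    df, _ = gen_stability_dataset(
        times_min=[0.0, 7.6], noise=NoiseModel(cv_proportional=0.0, replicates=1)
    )
    m = df[df["compound"] == "CP-506M"].sort_values("time_min")
    assert m["concentration_uM"].iloc[-1] == pytest.approx(50.0, rel=1e-9)
    stable = df[df["compound"] == "CP-506"]
    assert np.allclose(stable["concentration_uM"], 100.0)


def test_noisy_stability_refit_recovers_halflife():
    """Log-linear refit of the dichloro-amine decay recovers T1/2 ~ 271 min."""
    df, _ = gen_stability_dataset(noise=NoiseModel(seed=5))
    sub = df[(df["compound"] == "CP-506M-Cl2") & (df["censored"] == 0)]
    slope = np.polyfit(sub["time_min"], np.log(sub["concentration_uM"]), 1)[0]
    t_half = -np.log(2.0) / slope
    assert t_half == pytest.approx(MEDIA_STABILITY_HALFLIVES_MIN["CP-506M-Cl2"], rel=0.10)


def test_flux_generator_conserves_before_noise(geometry, chain, transport_truth):
    stable = [chain[0].with_(halflife_extracellular_min=float("inf"))]
    data, _, _ = gen_flux_dataset(
        geometry, transport_truth, stable, condition="supraoxic", has_mcl=False,
        include_urea=False, c0_uM=20.0,
        noise=NoiseModel(cv_proportional=0.0, replicates=1),
    )
    ds = data[0]
    total = ds.donor("CP-506").concentrations_uM + ds.receiver("CP-506").concentrations_uM
    # equal reservoirs: donor + receiver stays within the in-membrane holdup
    assert total[0] == pytest.approx(20.0, rel=1e-6)
    assert np.all(total >= 19.5) and np.all(total <= 20.0 + 1e-9)


def test_anoxic_flux_scenario_shows_metabolites_in_both_reservoirs(geometry, chain):
    from srpkpd.chamber import TransportParams

    data, _, _ = gen_flux_dataset(
        geometry, TransportParams(d_sup_cm2_s=0.717e-6), chain,
        condition="anoxic", has_mcl=True, include_urea=False, c0_uM=17.4,
        noise=NoiseModel(cv_proportional=0.0, replicates=1),
    )
    ds = data[0]
    assert ds.donor("CP-506M-Cl2").concentrations_uM[-1] > 0.01
    assert ds.receiver("CP-506M-Cl2").concentrations_uM[-1] > 0.01


def test_survival_generator_kd_zero_keeps_sf_near_one(lines, chain):
    import dataclasses

    free = {k: dataclasses.replace(v, k_d_monolayer=0.0) for k, v in lines.items()}
    df, _ = gen_survival_dataset(
        [0.1, 1.0], kind="clonogenic", lines=free, compounds=chain,
        noise=NoiseModel(seed=2),
    )
    assert df["surviving_fraction"].mean() == pytest.approx(1.0, abs=0.1)
    assert (df["sf_true"] == 1.0).all()


def test_survival_refit_recovers_kd(lines, chain):
    """Binomial colony noise, then k_d refit: within 20% over seeds."""
    from srpkpd.kill import fit_kill_constant, metabolite_auc_per_uM

    anox = MonolayerSetup(oxygen_uM=0.0)
    auc1 = {k: metabolite_auc_per_uM(anox, chain, v) for k, v in lines.items()}
    est = []
    for seed in range(8):
        df, _ = gen_survival_dataset(
            [0.003, 0.01, 0.03, 0.1, 0.3], kind="clonogenic", lines=lines,
            compounds=chain, noise=NoiseModel(seed=seed),
        )
        aucs = df["concentration_uM"].to_numpy() * df["line"].map(auc1).to_numpy()
        r = fit_kill_constant(df["surviving_fraction"].to_numpy(), aucs)
        est.append(r.estimates["k_d"])
    assert np.median(est) == pytest.approx(0.01, rel=0.20)


def test_spheroid_coculture_generator_shows_bystander_trend(lines, chain):
    df, _ = gen_survival_dataset(
        [0.3], kind="spheroid_coculture", lines=lines, compounds=chain,
        activator_fractions=(0.0, 0.1, 0.5), spheroid_radius_um=40.0,
        noise=NoiseModel(seed=4),
    )
    tgt = (
        df[df["line"] == "target"]
        .groupby("activator_fraction")["sf_true"]
        .first()
        .sort_index()
    )
    assert list(tgt) == sorted(tgt, reverse=True)


def test_scenario_driver_writes_provenance_files(tmp_path):
    spec = ScenarioSpec(kind="media_stability", options={})
    written = generate_scenario(spec, NoiseModel(seed=9), tmp_path)
    assert len(written) == 1
    assert read_provenance(written[0])["kind"] == "media_stability"


def test_unknown_scenario_kind_rejected():
    with pytest.raises(ValueError):
        ScenarioSpec(kind="mystery")
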