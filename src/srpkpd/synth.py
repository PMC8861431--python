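"""Seeded synthetic-data generators for every experimental input.

Each generator runs the corresponding forward model with known
("generating") parameters, applies a multiplicative lognormal measurement
error (LC-MS/MS-like, constant CV), censors values below the lower limit
of quantification, and records full provenance — the generating truth and
the seed — so that any fit can be checked against the parameters that made
its data.

Emulated assays:

- monolayer uptake/metabolism time courses (extracellular and
  intracellular, aerobic and anoxic),
- media-stability decays of the prodrug metabolites,
- diffusion-chamber donor/receiver flux curves with the urea internal
  standard,
- clonogenic survival of monolayers and spheroid co-cultures (binomial
  colony counts given cells plated and plating efficiency).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chamber import (
    ChamberGeometry,
    DiffusionChamberModel,
    FluxDataset,
    TransportParams,
    flux_to_dataframe,
    urea_compound,
)
from .doseresponse import surviving_fraction
from .kill import metabolite_auc_per_uM
from .monolayer import ConcProfile, MonolayerSetup, profiles_to_dataframe, simulate_monolayer
from .params import (
    MEDIA_STABILITY_HALFLIVES_MIN,
    CellLineParams,
    CompoundParams,
    cp506_cell_lines,
    cp506_chain,
)

__all__ = [
    "NoiseModel",
    "ScenarioSpec",
    "gen_monolayer_dataset",
    "gen_stability_dataset",
    "gen_flux_dataset",
    "gen_survival_dataset",
    "write_csv_with_provenance",
    "read_provenance",
    "generate_scenario",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error model shared by all generators.

    Multiplicative lognormal noise with coefficient of variation
    ``cv_proportional`` (mean-preserving), censoring below ``lloq_uM``,
    ``replicates`` independent repeats, and a seed for reproducibility.
    """

    cv_proportional: float = 0.10
    lloq_uM: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_proportional < 0:
            raise ValueError("CV must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv_proportional == 0:
            return np.asarray(values, float).copy()
        sigma = np.sqrt(np.log(1.0 + self.cv_proportional**2))
        factors = rng.lognormal(-0.5 * sigma**2, sigma, np.shape(values))
        return np.asarray(values, float) * factors


@dataclass
class ScenarioSpec:
    """Declarative description of one synthetic experiment (CLI surface)."""

    kind: str  # monolayer_uptake | media_stability | chamber_flux | clonogenic | spheroid_coculture
    options: dict = field(default_factory=dict)

    KINDS = (
        "monolayer_uptake",
        "media_stability",
        "chamber_flux",
        "clonogenic",
        "spheroid_coculture",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")


def _noisy_profiles(
    profiles: Sequence[ConcProfile], noise: NoiseModel, rng: np.random.Generator
) -> list[ConcProfile]:
    out = []
    for rep in range(noise.replicates):
        for p in profiles:
            vals = noise.perturb(p.concentrations_uM, rng)
            cens = vals < noise.lloq_uM
            out.append(
                ConcProfile(
                    p.compound, p.compartment, p.times_min.copy(), vals, cens, replicate=rep
                )
            )
    return out


def gen_monolayer_dataset(
    setup: MonolayerSetup | None = None,
    compounds: Sequence[CompoundParams] | None = None,
    line: str = "activator",
    oxygen_uM: float | None = None,
    observed_compounds: Sequence[str] | None = None,
    noise: NoiseModel = NoiseModel(),
) -> tuple[pd.DataFrame, dict]:
    """Monolayer uptake time courses (both compartments, replicated, censored).

    ``oxygen_uM=0`` gives the anoxic metabolism experiment; the default
    uses the aerobic setup.  Returns (tidy DataFrame, provenance dict).
    """
    setup = setup or MonolayerSetup()
    compounds = tuple(compounds or cp506_chain())
    profiles = simulate_monolayer(setup, compounds, line, oxygen_uM=oxygen_uM)
    if observed_compounds is not None:
        profiles = [p for p in profiles if p.compound in observed_compounds]
    rng = noise.rng()
    noisy = _noisy_profiles(profiles, noise, rng)
    truth = {
        "kind": "monolayer_uptake",
        "line": line,
        "oxygen_uM": setup.oxygen_uM if oxygen_uM is None else oxygen_uM,
        "setup": asdict(setup),
        "noise": asdict(noise),
        "compounds": [_compound_truth(c) for c in compounds],
    }
    return profiles_to_dataframe(noisy), truth


def gen_stability_dataset(
    halflives_min: Mapping[str, float] | None = None,
    c0_uM: float = 100.0,
    times_min: Sequence[float] | None = None,
    noise: NoiseModel = NoiseModel(),
) -> tuple[pd.DataFrame, dict]:
    """Mono-exponential media-stability decays for each compound."""
    hl = dict(halflives_min or MEDIA_STABILITY_HALFLIVES_MIN)
    times = np.asarray(
        times_min if times_min is not None else np.arange(0.0, 361.0, 20.0), float
    )
    rng = noise.rng()
    rows = []
    for name, h in hl.items():
        k = 0.0 if np.isinf(h) else np.log(2.0) / h
        true = c0_uM * np.exp(-k * times)
        for rep in range(noise.replicates):
            vals = noise.perturb(true, rng)
            cens = vals < noise.lloq_uM
            for t, v, c in zip(times, vals, cens):
                rows.append(
                    {
                        "time_min": t,
                        "compound": name,
                        "concentration_uM": v,
                        "replicate": rep,
                        "censored": int(c),
                    }
                )
    truth = {
        "kind": "media_stability",
        "c0_uM": c0_uM,
        "halflives_min": {k: (None if np.isinf(v) else v) for k, v in hl.items()},
        "noise": asdict(noise),
    }
    return pd.DataFrame(rows), truth


def gen_flux_dataset(
    geometry: ChamberGeometry | None = None,
    params: TransportParams | None = None,
    compounds: Sequence[CompoundParams] | None = None,
    condition: str = "supraoxic",
    has_mcl: bool = True,
    include_urea: bool = True,
    c0_uM: float = 17.4,
    urea_c0_uM: float = 10.0,
    duration_min: float = 300.0,
    sample_every_min: float = 15.0,
    n_chambers: int | None = None,
    noise: NoiseModel = NoiseModel(),
) -> tuple[list[FluxDataset], pd.DataFrame, dict]:
    """Diffusion-chamber donor/receiver curves (drug + urea standard).

    One forward solve provides the truth; each chamber replicate applies
    independent measurement noise.  Returns (datasets, tidy DataFrame,
    provenance).
    """
    geometry = geometry or ChamberGeometry()
    params = params or TransportParams()
    compounds = tuple(compounds or cp506_chain())
    n_chambers = noise.replicates if n_chambers is None else n_chambers
    model = DiffusionChamberModel(
        geometry, compounds, condition=condition, has_mcl=has_mcl, include_urea=include_urea
    )
    times = np.arange(0.0, duration_min + sample_every_min / 2.0, sample_every_min)
    sol = model.solve(
        params, c0_uM, duration_min, sample_times_min=times, urea_c0_uM=urea_c0_uM
    )
    rng = noise.rng()
    datasets = []
    for chamber in range(n_chambers):
        ds = sol.to_flux_dataset(condition=condition, chamber_id=chamber)
        for name, (dn, rc) in ds.records.items():
            for prof in (dn, rc):
                prof.concentrations_uM = noise.perturb(prof.concentrations_uM, rng)
                prof.censored = prof.concentrations_uM < noise.lloq_uM
        datasets.append(ds)
    truth = {
        "kind": "chamber_flux",
        "condition": condition,
        "has_mcl": has_mcl,
        "c0_uM": c0_uM,
        "urea_c0_uM": urea_c0_uM,
        "geometry": asdict(geometry),
        "transport": asdict(params),
        "noise": asdict(noise),
        "compounds": [_compound_truth(c) for c in compounds],
    }
    return datasets, flux_to_dataframe(datasets), truth


def gen_survival_dataset(
    c0_values_uM: Sequence[float],
    kind: str = "clonogenic",
    lines: Mapping[str, CellLineParams] | None = None,
    compounds: Sequence[CompoundParams] | None = None,
    setup: MonolayerSetup | None = None,
    activator_fractions: Sequence[float] = (0.0, 0.1, 0.5, 1.0),
    spheroid_radius_um: float = 60.0,
    duration_min: float = 240.0,
    cells_plated: int = 1000,
    plating_efficiency: float = 0.6,
    noise: NoiseModel = NoiseModel(),
) -> tuple[pd.DataFrame, dict]:
    """Clonogenic survival tables with binomial colony-count noise.

    ``kind="clonogenic"`` treats anoxic monolayers of each line;
    ``kind="spheroid_coculture"`` exposes co-culture spheroids at the given
    activator proportions (lattice model, expected-value survival) before
    plating.  Colony counts are Binomial(cells_plated, PE * SF).
    """
    lines = dict(lines or cp506_cell_lines())
    compounds = tuple(compounds or cp506_chain())
    setup = setup or MonolayerSetup(oxygen_uM=0.0)
    rng = noise.rng()
    rows = []
    if kind == "clonogenic":
        for lname, lp in lines.items():
            auc1 = metabolite_auc_per_uM(setup, compounds, lp, duration_min, oxygen_uM=0.0)
            for c0 in c0_values_uM:
                sf_true = float(np.exp(-lp.k_d_monolayer * auc1 * c0))
                rows += _plate(
                    rng, lname, c0, sf_true, cells_plated, plating_efficiency,
                    noise.replicates, extra={"activator_fraction": np.nan},
                )
    elif kind == "spheroid_coculture":
        from .spheroid.config import AbmConfig
        from .spheroid.lattice import clonogenic_survival, make_ball, simulate_exposure

        cfg = AbmConfig(seed=noise.seed)
        for fa in activator_fractions:
            fractions = {}
            if fa > 0:
                fractions["activator"] = fa
            if fa < 1:
                fractions["target"] = 1.0 - fa
            for c0 in c0_values_uM:
                st = make_ball(spheroid_radius_um, fractions, cfg)
                st = simulate_exposure(st, compounds, c0, duration_min, anoxic=True)
                sv = clonogenic_survival(st, lines, compounds, context="spheroid")
                for lname, sf_true in sv.surviving_fraction.items():
                    rows += _plate(
                        rng, lname, c0, sf_true, cells_plated, plating_efficiency,
                        noise.replicates, extra={"activator_fraction": fa},
                    )
    else:
        raise ValueError(f"unknown survival kind {kind!r}")
    truth = {
        "kind": kind,
        "noise": asdict(noise),
        "cells_plated": cells_plated,
        "plating_efficiency": plating_efficiency,
        "lines": {k: asdict(v) for k, v in lines.items()},
        "compounds": [_compound_truth(c) for c in compounds],
    }
    return pd.DataFrame(rows), truth


def _plate(rng, line, c0, sf_true, plated, pe, replicates, extra):
    rows = []
    for rep in range(replicates):
        control = int(rng.binomial(plated, pe))
        treated = int(rng.binomial(plated, min(1.0, pe * sf_true)))
        sf = surviving_fraction(treated, control, plated) if control else np.nan
        rows.append(
            {
                "line": line,
                "concentration_uM": c0,
                "replicate": rep,
                "colonies_treated": treated,
                "colonies_control": control,
                "cells_plated": plated,
                "surviving_fraction": sf,
                "sf_true": sf_true,
                **extra,
            }
        )
    return rows


def _compound_truth(c: CompoundParams) -> dict:
    d = asdict(c)
    d["k_met0_by_line"] = dict(c.k_met0_by_line)
    if np.isinf(d["halflife_extracellular_min"]):
        d["halflife_extracellular_min"] = None
    return d


# -- provenance-carrying CSV I/O -------------------------------------------


def write_csv_with_provenance(df: pd.DataFrame, path, provenance: Mapping) -> None:
    """Write a CSV whose header comment embeds the generating truth."""
    path = Path(path)
    blob = json.dumps(provenance, sort_keys=True, default=_json_default)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {blob}\n")
        df.to_csv(fh, index=False)


def read_provenance(path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# provenance:"):
        raise ValueError(f"{path} carries no provenance header")
    return json.loads(first.split(":", 1)[1])


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, float) and np.isinf(o):
        return None
    raise TypeError(f"not JSON serialisable: {type(o)}")


def generate_scenario(spec: ScenarioSpec, noise: NoiseModel, out_dir) -> list[Path]:
    """Materialise a scenario to provenance-carrying CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if spec.kind == "monolayer_uptake":
        df, truth = gen_monolayer_dataset(noise=noise, **spec.options)
        p = out / "monolayer_uptake.csv"
        write_csv_with_provenance(df, p, truth)
        written.append(p)
    elif spec.kind == "media_stability":
        df, truth = gen_stability_dataset(noise=noise, **spec.options)
        p = out / "media_stability.csv"
        write_csv_with_provenance(df, p, truth)
        written.append(p)
    elif spec.kind == "chamber_flux":
        opts = dict(spec.options)
        if isinstance(opts.get("params"), Mapping):
            opts["params"] = TransportParams(**opts["params"])
        if isinstance(opts.get("geometry"), Mapping):
            opts["geometry"] = ChamberGeometry(**opts["geometry"])
        _, df, truth = gen_flux_dataset(noise=noise, **opts)
        p = out / "chamber_flux.csv"
        write_csv_with_provenance(df, p, truth)
        written.append(p)
    elif spec.kind in ("clonogenic", "spheroid_coculture"):
        opts = dict(spec.options)
        c0 = opts.pop("c0_values_uM", [0.03, 0.1, 0.3, 1.0, 3.0])
        df, truth = gen_survival_dataset(c0, kind=spec.kind, noise=noise, **opts)
        p = out / f"{spec.kind}.csv"
        write_csv_with_provenance(df, p, truth)
        written.append(p)
    return written
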