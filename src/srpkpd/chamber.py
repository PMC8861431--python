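"""One-dimensional reaction-diffusion transport across multicellular layers.

Models the diffusion-chamber flux experiment: a stirred donor reservoir, a
multicellular layer (MCL) grown on a permeable support, the bare support
membrane, and a stirred receiver reservoir.  Within the MCL each compound
obeys Fick's second law with reaction,

    dCe/dt = D d2Ce/dx2 - k_loss Ce - phi (k_in Ce - k_out Ci)
    dCi/dt = k_met_{N-1} Ci_{N-1} + phi (k_in Ce - k_out Ci) - k_met Ci

where ``phi`` is the metabolic scaling factor that maps monolayer-derived
membrane-exchange rates onto tissue-like density.  The support layer has no
cells (diffusion and chemical loss only) and the reservoirs are perfectly
mixed compartments coupled to the layers by boundary flux.

Discretisation is a conservative finite-volume method of lines (uniform
grid per layer, default 50 nodes each) integrated with the trapezoidal
(Crank-Nicolson) rule on a factorised sparse operator; the scheme preserves
total mass to linear-solver precision, with degradation and the terminal
metabolic step routed to an explicit sink.

The staged estimation protocol mirrors the experimental analysis:
``fit_support_diffusivity`` (bare membrane) -> ``fit_mcl_thickness``
(urea internal standard, tissue diffusivity known) -> ``fit_mcl_diffusivity``
(supraoxic, uptake fixed from monolayers) -> ``fit_metabolic_scaling``
(anoxic, everything else frozen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix, identity, lil_matrix
from scipy.sparse.linalg import splu

from ._fitting import FitResult, UnderDeterminedError, fit_least_squares
from .monolayer import ConcProfile
from .params import (
    CM2_S_TO_UM2_MIN,
    UREA_D_MCL_CM2_S,
    CompoundParams,
    validate_chain,
)

__all__ = [
    "ChamberGeometry",
    "TransportParams",
    "FluxDataset",
    "ChamberSolution",
    "DiffusionChamberModel",
    "solve_chamber",
    "fit_support_diffusivity",
    "fit_mcl_thickness",
    "fit_mcl_diffusivity",
    "fit_metabolic_scaling",
    "slab_equilibration_rate",
    "urea_compound",
    "flux_to_dataframe",
    "flux_from_dataframe",
]

ML_TO_UM3 = 1e12
CM2_TO_UM2 = 1e8

#: extracellular (and intracellular) volume fraction inside an MCL
MCL_EXTRACELLULAR_FRACTION = 0.5


@dataclass(frozen=True)
class ChamberGeometry:
    """Diffusion-chamber layout (reservoirs, exposed area, layer thicknesses)."""

    donor_volume_ml: float = 8.5
    receiver_volume_ml: float = 8.5
    exposed_area_cm2: float = 0.6
    support_thickness_um: float = 130.0
    mcl_thickness_um: float = 101.7
    grid_nodes_per_layer: int = 50

    def __post_init__(self) -> None:
        for f in (
            self.donor_volume_ml,
            self.receiver_volume_ml,
            self.exposed_area_cm2,
            self.support_thickness_um,
        ):
            if not (f > 0):
                raise ValueError("all chamber dimensions must be > 0")
        if self.mcl_thickness_um < 0:
            raise ValueError("MCL thickness must be >= 0")
        if self.grid_nodes_per_layer < 20:
            raise ValueError("grid too coarse: need >= 20 nodes per layer")


@dataclass(frozen=True)
class TransportParams:
    """Diffusivities and the metabolic scaling factor for chamber transport."""

    d_sup_cm2_s: float = 1.32e-6
    d_mcl_cm2_s: float = 1.93e-7
    phi: float = 0.3
    d_mcl_urea_cm2_s: float = UREA_D_MCL_CM2_S
    d_sup_urea_cm2_s: float | None = None  # defaults to d_sup_cm2_s

    def __post_init__(self) -> None:
        if self.d_sup_cm2_s <= 0 or self.d_mcl_cm2_s <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if not (0.0 < self.phi <= 1.0):
            raise ValueError("phi must be in (0, 1]")

    @property
    def d_sup_urea(self) -> float:
        return self.d_sup_urea_cm2_s if self.d_sup_urea_cm2_s is not None else self.d_sup_cm2_s


def urea_compound() -> CompoundParams:
    """[14C]-urea internal standard: freely diffusing, no uptake, stable."""
    return CompoundParams(name="urea")


@dataclass
class FluxDataset:
    """Donor/receiver concentration records from one diffusion chamber.

    ``records`` maps compound name -> (donor profile, receiver profile);
    the urea internal standard travels under the key ``"urea"``.
    """

    records: dict[str, tuple[ConcProfile, ConcProfile]]
    condition: str = "supraoxic"  # supraoxic | anoxic
    c0_uM: float = 0.0
    urea_c0_uM: float = 0.0
    chamber_id: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("supraoxic", "anoxic"):
            raise ValueError(f"unknown condition {self.condition!r}")
        for name, (d, r) in self.records.items():
            for p in (d, r):
                if p.times_min.size > 1 and np.any(np.diff(p.times_min) <= 0):
                    raise ValueError(f"{name}: time grid must be increasing")

    @property
    def compounds(self) -> list[str]:
        return [k for k in self.records if k != "urea"]

    def donor(self, name: str) -> ConcProfile:
        return self.records[name][0]

    def receiver(self, name: str) -> ConcProfile:
        return self.records[name][1]


@dataclass
class ChamberSolution:
    """Forward solution: reservoir trajectories, in-layer fields and sink."""

    times_min: np.ndarray
    donor: dict[str, np.ndarray]
    receiver: dict[str, np.ndarray]
    x_um: np.ndarray  # node centres, 0 at the donor face
    ce_fields: dict[str, np.ndarray]  # [ntimes, nnodes]
    ci_fields: dict[str, np.ndarray]  # MCL nodes only (empty when bare)
    sink_amount: np.ndarray  # uM * um^3
    geometry: ChamberGeometry
    node_volumes_um3: np.ndarray
    ci_node_volumes_um3: np.ndarray
    c0_uM: float = 0.0
    urea_c0_uM: float = 0.0

    def total_amount(self, include_urea: bool = False) -> np.ndarray:
        """Total drug amount over time (uM*um^3), including the sink."""
        vd = None
        tot = np.array(self.sink_amount, float)
        for name in self.donor:
            if name == "urea" and not include_urea:
                continue
            gd = self.geometry.donor_volume_ml * ML_TO_UM3
            gr = self.geometry.receiver_volume_ml * ML_TO_UM3
            tot = tot + gd * self.donor[name] + gr * self.receiver[name]
            tot = tot + self.ce_fields[name] @ self.node_volumes_um3
            if name in self.ci_fields and self.ci_fields[name].size:
                tot = tot + self.ci_fields[name] @ self.ci_node_volumes_um3
        return tot

    def mass_balance(self) -> np.ndarray:
        """Chain mass normalised to the initial donor amount."""
        init = self.c0_uM * self.geometry.donor_volume_ml * ML_TO_UM3
        return self.total_amount() / init

    def plot(self, compound: str | None = None, ax=None):
        """Plot donor and receiver concentration-time curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [compound] if compound else list(self.donor)
        for name in names:
            ax.plot(self.times_min, self.donor[name], label=f"{name} donor")
            ax.plot(self.times_min, self.receiver[name], "--", label=f"{name} receiver")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (uM)")
        ax.legend(fontsize=8)
        return ax

    def to_flux_dataset(self, condition: str = "supraoxic", chamber_id: int = 0) -> FluxDataset:
        recs = {}
        for name in self.donor:
            recs[name] = (
                ConcProfile(name, "extracellular", self.times_min, self.donor[name]),
                ConcProfile(name, "extracellular", self.times_min, self.receiver[name]),
            )
        return FluxDataset(
            recs,
            condition=condition,
            c0_uM=self.c0_uM,
            urea_c0_uM=self.urea_c0_uM,
            chamber_id=chamber_id,
        )


def slab_equilibration_rate(
    geometry: ChamberGeometry, d_cm2_s: float, layer: str = "support"
) -> tuple[float, float]:
    """Closed-form two-reservoir slab permeation constants.

    Returns ``(rate_per_min, lag_min)``: after the diffusion lag
    ``L^2/(6D)``, the donor-receiver difference decays exponentially at rate
    ``(D A / L) (1/Vd + 1/Vr)``.
    """
    L = geometry.support_thickness_um if layer == "support" else geometry.mcl_thickness_um
    d = d_cm2_s * CM2_S_TO_UM2_MIN
    area = geometry.exposed_area_cm2 * CM2_TO_UM2
    vd = geometry.donor_volume_ml * ML_TO_UM3
    vr = geometry.receiver_volume_ml * ML_TO_UM3
    rate = (d * area / L) * (1.0 / vd + 1.0 / vr)
    return rate, L * L / (6.0 * d)


class DiffusionChamberModel:
    """Four-compartment reaction-diffusion model of the flux chamber.

    Parameters
    ----------
    geometry
        Chamber layout; ``mcl_thickness_um`` is ignored when ``has_mcl`` is
        False.
    compounds
        Metabolite chain present in the experiment; add
        :func:`urea_compound` (or pass ``include_urea``) to co-transport the
        internal standard.
    line
        Cell line making up the MCL (default the activator line, matching
        the POR-overexpressing MCLs used experimentally).
    condition
        ``"supraoxic"`` closes the oxygen gate on prodrug metabolism,
        ``"anoxic"`` opens it.
    """

    def __init__(
        self,
        geometry: ChamberGeometry,
        compounds: Sequence[CompoundParams],
        line: str = "activator",
        condition: str = "supraoxic",
        has_mcl: bool = True,
        include_urea: bool = False,
        dt_min: float = 0.25,
    ) -> None:
        comps = list(compounds)
        if include_urea and not any(c.name == "urea" for c in comps):
            comps.append(urea_compound())
        self.geometry = geometry
        self.compounds = tuple(comps)
        self.line = line
        if condition not in ("supraoxic", "anoxic"):
            raise ValueError(f"unknown condition {condition!r}")
        self.condition = condition
        self.has_mcl = has_mcl
        self.dt_min = float(dt_min)
        chain = [c for c in comps if c.name != "urea"]
        if chain:
            validate_chain(chain)

    # -- operator assembly -------------------------------------------------

    def _assemble(self, params: TransportParams, geometry: ChamberGeometry):
        g = geometry
        nn = g.grid_nodes_per_layer
        area = g.exposed_area_cm2 * CM2_TO_UM2
        vd = g.donor_volume_ml * ML_TO_UM3
        vr = g.receiver_volume_ml * ML_TO_UM3
        o2 = 0.0 if self.condition == "anoxic" else 200.0

        # layer tables: (name, n, dx, eps, has_cells)
        layers = []
        if self.has_mcl and g.mcl_thickness_um > 0:
            layers.append(("mcl", nn, g.mcl_thickness_um / nn, MCL_EXTRACELLULAR_FRACTION, True))
        layers.append(("sup", nn, g.support_thickness_um / nn, 1.0, False))

        # global state indexing
        comps = self.compounds
        n_nodes = sum(n for _, n, _, _, _ in layers)
        n_ci = sum(n for name, n, _, _, c in layers if c)
        per = 2 + n_nodes + n_ci  # donor, receiver, Ce nodes, Ci nodes
        size = per * len(comps) + 1
        sink = size - 1

        idx_d, idx_r, idx_ce, idx_ci = {}, {}, {}, {}
        pos = 0
        for c in comps:
            idx_d[c.name] = pos
            idx_r[c.name] = pos + 1
            idx_ce[c.name] = pos + 2
            idx_ci[c.name] = pos + 2 + n_nodes
            pos += per

        x_centres = []
        node_eps = []
        node_dx = []
        node_d: dict[str, list[float]] = {c.name: [] for c in comps}
        node_cells = []
        x0 = 0.0
        for lname, n, dx, eps, cells in layers:
            for j in range(n):
                x_centres.append(x0 + (j + 0.5) * dx)
                node_eps.append(eps)
                node_dx.append(dx)
                node_cells.append(cells)
                for c in comps:
                    if c.name == "urea":
                        dval = params.d_mcl_urea_cm2_s if lname == "mcl" else params.d_sup_urea
                    else:
                        dval = params.d_mcl_cm2_s if lname == "mcl" else params.d_sup_cm2_s
                    node_d[c.name].append(dval * CM2_S_TO_UM2_MIN)
            x0 += n * dx
        x_centres = np.array(x_centres)
        node_eps = np.array(node_eps)
        node_dx = np.array(node_dx)
        node_vol = area * node_eps * node_dx
        ci_vol = area * MCL_EXTRACELLULAR_FRACTION * node_dx[np.array(node_cells, bool)]

        terminals = {c.name for c in comps if c.name != "urea"}
        for c in comps:
            if c.parent is not None:
                terminals.discard(c.parent)

        A = lil_matrix((size, size))
        by_name = {c.name: c for c in comps}
        ci_pos = {}  # (compound, node_j) -> state index for cells
        for c in comps:
            k = 0
            for j, has_c in enumerate(node_cells):
                if has_c:
                    ci_pos[(c.name, j)] = idx_ci[c.name] + k
                    k += 1

        for c in comps:
            D = node_d[c.name]
            kloss = c.k_loss
            d_i, r_i, e0 = idx_d[c.name], idx_r[c.name], idx_ce[c.name]

            # conductances between neighbours (amount flux = G * dC)
            def add_pair(i1, v1, i2, v2, G):
                A[i1, i1] -= G / v1
                A[i1, i2] += G / v1
                A[i2, i2] -= G / v2
                A[i2, i1] += G / v2

            # donor <-> first node
            G = node_eps[0] * area * D[0] / (node_dx[0] / 2.0)
            add_pair(d_i, vd, e0, node_vol[0], G)
            # interior pairs
            for j in range(len(x_centres) - 1):
                r1 = node_dx[j] / (2.0 * node_eps[j] * D[j])
                r2 = node_dx[j + 1] / (2.0 * node_eps[j + 1] * D[j + 1])
                G = area / (r1 + r2)
                add_pair(e0 + j, node_vol[j], e0 + j + 1, node_vol[j + 1], G)
            # last node <-> receiver
            jl = len(x_centres) - 1
            G = node_eps[jl] * area * D[jl] / (node_dx[jl] / 2.0)
            add_pair(e0 + jl, node_vol[jl], r_i, vr, G)

            # chemical loss everywhere extracellular -> sink
            if kloss > 0:
                for i, vol in ((d_i, vd), (r_i, vr)):
                    A[i, i] -= kloss
                    A[sink, i] += kloss * vol
                for j in range(len(x_centres)):
                    A[e0 + j, e0 + j] -= kloss
                    A[sink, e0 + j] += kloss * node_vol[j]

            # cellular exchange and metabolism inside the MCL
            if c.name == "urea":
                continue
            kmet = c.k_met(self.line, o2)
            parent = by_name.get(c.parent) if c.parent else None
            kmet_parent = parent.k_met(self.line, o2) if parent else 0.0
            phi = params.phi
            for j, has_c in enumerate(node_cells):
                if not has_c:
                    continue
                ie = e0 + j
                ii = ci_pos[(c.name, j)]
                A[ie, ie] -= phi * c.k_in
                A[ie, ii] += phi * c.k_out
                A[ii, ie] += phi * c.k_in
                A[ii, ii] -= phi * c.k_out + kmet
                if parent is not None:
                    A[ii, ci_pos[(parent.name, j)]] += kmet_parent
                if c.name in terminals and kmet > 0:
                    vol_i = area * MCL_EXTRACELLULAR_FRACTION * node_dx[j]
                    A[sink, ii] += kmet * vol_i

        meta = {
            "idx_d": idx_d,
            "idx_r": idx_r,
            "idx_ce": idx_ce,
            "idx_ci": idx_ci,
            "n_nodes": n_nodes,
            "n_ci": n_ci,
            "x": x_centres,
            "node_vol": node_vol,
            "ci_vol": ci_vol,
            "sink": sink,
            "size": size,
        }
        return csc_matrix(A), meta

    # -- time stepping -----------------------------------------------------

    def solve(
        self,
        params: TransportParams,
        c0_uM: float,
        duration_min: float,
        sample_times_min: Sequence[float] | None = None,
        urea_c0_uM: float = 0.0,
        geometry: ChamberGeometry | None = None,
    ) -> ChamberSolution:
        """Integrate the chamber forward from a drug bolus in the donor."""
        g = geometry or self.geometry
        A, meta = self._assemble(params, g)
        if sample_times_min is None:
            sample_times_min = np.linspace(0.0, duration_min, 21)
        times = np.asarray(sample_times_min, float)

        u = np.zeros(meta["size"])
        root = next((c for c in self.compounds if c.parent is None and c.name != "urea"), None)
        if root is not None:
            u[meta["idx_d"][root.name]] = c0_uM
        if any(c.name == "urea" for c in self.compounds):
            u[meta["idx_d"]["urea"]] = urea_c0_uM

        eye = identity(meta["size"], format="csc")
        out = np.empty((times.size, u.size))
        t_prev = 0.0
        lu_cache: dict[float, tuple] = {}
        for k, t in enumerate(times):
            span = t - t_prev
            if span < 0:
                raise ValueError("sample times must be non-decreasing")
            if span > 0:
                nsub = max(1, int(math.ceil(span / self.dt_min)))
                h = span / nsub
                key = round(h, 12)
                if key not in lu_cache:
                    lu_cache[key] = (
                        splu(csc_matrix(eye - 0.5 * h * A)),
                        eye + 0.5 * h * A,
                    )
                lu, M2 = lu_cache[key]
                for _ in range(nsub):
                    u = lu.solve(M2 @ u)
            out[k] = u
            t_prev = t

        donor, receiver, ce_f, ci_f = {}, {}, {}, {}
        nn = meta["n_nodes"]
        for c in self.compounds:
            donor[c.name] = np.clip(out[:, meta["idx_d"][c.name]], 0.0, None)
            receiver[c.name] = np.clip(out[:, meta["idx_r"][c.name]], 0.0, None)
            e0 = meta["idx_ce"][c.name]
            ce_f[c.name] = out[:, e0 : e0 + nn]
            i0 = meta["idx_ci"][c.name]
            ci_f[c.name] = out[:, i0 : i0 + meta["n_ci"]]
        return ChamberSolution(
            times_min=times,
            donor=donor,
            receiver=receiver,
            x_um=meta["x"],
            ce_fields=ce_f,
            ci_fields=ci_f,
            sink_amount=out[:, meta["sink"]],
            geometry=g,
            node_volumes_um3=meta["node_vol"],
            ci_node_volumes_um3=meta["ci_vol"],
            c0_uM=c0_uM,
            urea_c0_uM=urea_c0_uM,
        )

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        data: FluxDataset | Sequence[FluxDataset],
        free: Sequence[str],
        params: TransportParams | None = None,
        fit_compounds: Sequence[str] | None = None,
        n_starts: int = 1,
        seed: int = 0,
    ) -> FitResult:
        """Least-squares fit of the named transport parameters.

        ``free`` may contain ``"d_sup_cm2_s"``, ``"d_mcl_cm2_s"``, ``"phi"``
        and ``"l_mcl_um"`` (MCL thickness; rebuilds the grid each
        evaluation).  All fits run on log-scale parameters against the
        pooled uncensored donor and receiver points of every chamber.
        """
        datasets = [data] if isinstance(data, FluxDataset) else list(data)
        base = params or TransportParams()
        model_names = {c.name for c in self.compounds}

        def build(v: Mapping[str, float]) -> tuple[TransportParams, ChamberGeometry]:
            pkw = {k: val for k, val in v.items() if k != "l_mcl_um"}
            geom = self.geometry
            if "l_mcl_um" in v:
                geom = replace(geom, mcl_thickness_um=v["l_mcl_um"])
            return (replace(base, **pkw) if pkw else base), geom

        def collect(v: Mapping[str, float]):
            p, geom = build(v)
            obs, pred = [], []
            for ds in datasets:
                grids = [
                    prof.times_min
                    for name, (dn, rc) in ds.records.items()
                    if name in model_names
                    for prof in (dn, rc)
                ]
                grid = np.unique(np.concatenate(grids))
                sol = self.solve(
                    p, ds.c0_uM, float(grid[-1]), sample_times_min=grid,
                    urea_c0_uM=ds.urea_c0_uM, geometry=geom,
                )
                for name, (dn, rc) in ds.records.items():
                    if name not in model_names:
                        continue
                    if fit_compounds is not None and name not in fit_compounds:
                        continue
                    for prof, curve in ((dn, sol.donor[name]), (rc, sol.receiver[name])):
                        m = ~prof.censored
                        if not m.any():
                            continue
                        pi = np.interp(prof.times_min[m], grid, curve)
                        obs.append(prof.concentrations_uM[m])
                        pred.append(pi)
            if not obs:
                raise UnderDeterminedError("no uncensored observations to fit")
            return np.concatenate(obs), np.concatenate(pred)

        floor = 1e-4

        def resid(v):
            o, q = collect(v)
            return np.log(np.maximum(q, floor)) - np.log(np.maximum(o, floor))

        def predict(v):
            return collect(v)[1]

        defaults = {
            "d_sup_cm2_s": base.d_sup_cm2_s,
            "d_mcl_cm2_s": base.d_mcl_cm2_s,
            "phi": base.phi,
            "l_mcl_um": self.geometry.mcl_thickness_um or 100.0,
        }
        bounds = {
            "d_sup_cm2_s": (1e-8, 1e-4),
            "d_mcl_cm2_s": (1e-9, 1e-4),
            "phi": (1e-3, 1.0),
            "l_mcl_um": (1.0, 1000.0),
        }
        p0 = {k: defaults[k] for k in free}
        obs0 = collect(p0)[0]
        if obs0.size < len(free):
            raise UnderDeterminedError(
                f"{obs0.size} usable points for {len(free)} free parameters"
            )
        return fit_least_squares(
            resid,
            p0,
            bounds={k: bounds[k] for k in free},
            n_starts=n_starts,
            seed=seed,
            observed=obs0,
            predict_fn=predict,
            spread=0.3,
        )


def solve_chamber(
    geometry: ChamberGeometry,
    params: TransportParams,
    compounds: Sequence[CompoundParams],
    c0_uM: float,
    duration_min: float,
    condition: str = "supraoxic",
    has_mcl: bool = True,
    **kw,
) -> ChamberSolution:
    """Forward-solve the chamber (functional wrapper over the model class)."""
    model = DiffusionChamberModel(
        geometry, compounds, condition=condition, has_mcl=has_mcl
    )
    return model.solve(params, c0_uM, duration_min, **kw)


def fit_support_diffusivity(
    data: FluxDataset | Sequence[FluxDataset],
    geometry: ChamberGeometry,
    compounds: Sequence[CompoundParams],
    params: TransportParams | None = None,
    **kw,
) -> FitResult:
    """Stage 1: D_sup from bare-membrane (no cells) donor/receiver curves."""
    datasets = [data] if isinstance(data, FluxDataset) else list(data)
    cond = datasets[0].condition
    model = DiffusionChamberModel(
        geometry, compounds, condition=cond, has_mcl=False
    )
    return model.fit(datasets, free=("d_sup_cm2_s",), params=params, **kw)


def fit_mcl_thickness(
    data: FluxDataset | Sequence[FluxDataset],
    geometry: ChamberGeometry,
    params: TransportParams | None = None,
    **kw,
) -> FitResult:
    """Stage 2: MCL thickness from the urea internal standard.

    Urea neither enters cells nor degrades, and its tissue diffusion
    coefficient is known, so the layer thickness is the only unknown.
    """
    model = DiffusionChamberModel(
        geometry, [urea_compound()], condition="supraoxic", has_mcl=True
    )
    return model.fit(data, free=("l_mcl_um",), params=params, fit_compounds=["urea"], **kw)


def fit_mcl_diffusivity(
    data: FluxDataset | Sequence[FluxDataset],
    geometry: ChamberGeometry,
    compounds: Sequence[CompoundParams],
    params: TransportParams | None = None,
    **kw,
) -> FitResult:
    """Stage 3: tissue diffusivity D_MCL from supraoxic MCL flux curves.

    Cellular uptake parameters ride along fixed (from the monolayer fits).
    The oxygen gate is closed, so no metabolites are produced and the fit
    reduces to the prodrug records alone.
    """
    root = validate_chain([c for c in compounds if c.name != "urea"])
    model = DiffusionChamberModel(
        geometry, [root], condition="supraoxic", has_mcl=True
    )
    return model.fit(data, free=("d_mcl_cm2_s",), params=params, **kw)


def fit_metabolic_scaling(
    data: FluxDataset | Sequence[FluxDataset],
    geometry: ChamberGeometry,
    compounds: Sequence[CompoundParams],
    params: TransportParams | None = None,
    **kw,
) -> FitResult:
    """Stage 4: metabolic scaling factor phi from anoxic MCL flux curves."""
    model = DiffusionChamberModel(
        geometry, compounds, condition="anoxic", has_mcl=True
    )
    return model.fit(data, free=("phi",), params=params, **kw)


# -- tabular I/O -----------------------------------------------------------


def flux_to_dataframe(datasets: Sequence[FluxDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for name, (dn, rc) in ds.records.items():
            for prof, side in ((dn, "donor"), (rc, "receiver")):
                for t, c, cen in zip(prof.times_min, prof.concentrations_uM, prof.censored):
                    rows.append(
                        {
                            "time_min": t,
                            "compartment": side,
                            "compound": name,
                            "concentration_uM": c,
                            "chamber_id": ds.chamber_id,
                            "condition": ds.condition,
                            "censored": int(cen),
                        }
                    )
    return pd.DataFrame(rows)


def flux_from_dataframe(df: pd.DataFrame) -> list[FluxDataset]:
    out = []
    for (chamber, cond), g in df.groupby(["chamber_id", "condition"], sort=False):
        recs: dict[str, list] = {}
        for name, gc in g.groupby("compound", sort=False):
            sides = {}
            for side, gs in gc.groupby("compartment", sort=False):
                gs = gs.sort_values("time_min")
                sides[side] = ConcProfile(
                    name,
                    "extracellular",
                    gs["time_min"].to_numpy(float),
                    gs["concentration_uM"].to_numpy(float),
                    gs["censored"].to_numpy(bool) if "censored" in gs else None,
                )
            recs[name] = (sides["donor"], sides["receiver"])
        root = [n for n in recs if n != "urea"]
        c0 = float(recs[root[0]][0].concentrations_uM[0]) if root else 0.0
        u0 = float(recs["urea"][0].concentrations_uM[0]) if "urea" in recs else 0.0
        out.append(
            FluxDataset(recs, condition=cond, c0_uM=c0, urea_c0_uM=u0, chamber_id=int(chamber))
        )
    return out
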