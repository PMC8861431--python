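"""Cellular pharmacokinetics of prodrug uptake and metabolism in monolayers.

A linear (first-order) two-compartment model per compound: extracellular
medium concentration ``Ce`` and intracellular concentration ``Ci`` exchange
via ``k_in``/``k_out``, the prodrug is metabolised intracellularly at an
oxygen-gated rate ``k_met0 * g(O2)`` feeding the next compound in the
metabolite chain, and each compound decays extracellularly with its medium
half-life.  With volume ratio ``vr = Vi/Ve``,

    dCe_N/dt = -k_loss_N Ce_N - vr (k_in_N Ce_N - k_out_N Ci_N)
    dCi_N/dt =  k_met_{N-1} Ci_{N-1} + k_in_N Ce_N - k_out_N Ci_N - k_met_N Ci_N

Degradation and the terminal metabolic step are routed to an explicit sink
so total mass is conserved exactly.  The system is linear time-invariant, so
trajectories are computed with the matrix exponential (exact to machine
precision, no step-size control needed).

The fitting protocol is sequential: aerobic data determine the prodrug
permeabilities ``k_in``/``k_out`` (metabolism closed); these are then frozen
and anoxic data determine the prodrug activation rate ``k_met0`` plus the
permeability and instability constants of each observed metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ._fitting import FitResult, UnderDeterminedError, fit_least_squares
from .params import CellLineParams, CompoundParams, validate_chain

__all__ = [
    "MonolayerSetup",
    "ConcProfile",
    "simulate_monolayer",
    "mass_balance",
    "MonolayerPKModel",
    "fit_aerobic_uptake",
    "fit_anoxic_metabolism",
    "profiles_to_dataframe",
    "profiles_from_dataframe",
]

#: aerobic oxygen concentration in uM (21% O2 at 37 C, air-saturated medium)
AEROBIC_O2_UM = 200.0


@dataclass(frozen=True)
class MonolayerSetup:
    """Geometry and protocol of a monolayer uptake experiment.

    Defaults mirror the cellular uptake assay: 5e5 cells attached in a
    24-well plate, 850 ul total medium after drug addition, 100 uM initial
    prodrug, sampled over 3 h.  ``cell_volume_pl`` sets the intracellular
    volume (not measured directly; 2.5 pl is a typical carcinoma cell and
    the fits are insensitive to it because Vi/Ve is small).
    """

    cell_count: float = 5e5
    cell_volume_pl: float = 2.5
    medium_volume_ul: float = 850.0
    c0_uM: float = 100.0
    duration_min: float = 180.0
    oxygen_uM: float = AEROBIC_O2_UM
    sample_times_min: tuple[float, ...] = (5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180)
    lloq_uM: float = 0.01

    def __post_init__(self) -> None:
        if self.cell_count <= 0 or self.cell_volume_pl <= 0 or self.medium_volume_ul <= 0:
            raise ValueError("volumes and counts must be > 0")
        t = np.asarray(self.sample_times_min, float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.lloq_uM < 0:
            raise ValueError("LLOQ must be >= 0")

    @property
    def volume_ratio(self) -> float:
        """Intracellular/extracellular volume ratio Vi/Ve (dimensionless)."""
        vi_ul = self.cell_count * self.cell_volume_pl * 1e-6  # pl -> ul
        return vi_ul / self.medium_volume_ul


@dataclass
class ConcProfile:
    """Concentration-time record for one compound in one compartment."""

    compound: str
    compartment: str  # "extracellular" | "intracellular"
    times_min: np.ndarray
    concentrations_uM: np.ndarray
    censored: np.ndarray | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, float)
        self.concentrations_uM = np.asarray(self.concentrations_uM, float)
        if self.censored is None:
            self.censored = np.zeros(self.times_min.shape, bool)
        else:
            self.censored = np.asarray(self.censored, bool)
        if self.compartment not in ("extracellular", "intracellular"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not (
            self.times_min.shape
            == self.concentrations_uM.shape
            == self.censored.shape
        ):
            raise ValueError("times, concentrations and censor flags must align")
        if np.any(self.concentrations_uM[~self.censored] < 0):
            raise ValueError("negative uncensored concentration")


def _terminal_names(compounds: Sequence[CompoundParams]) -> set[str]:
    parents = {c.parent for c in compounds if c.parent is not None}
    return {c.name for c in compounds if c.name not in parents}


def build_rate_matrix(
    compounds: Sequence[CompoundParams],
    line: CellLineParams | str | None,
    volume_ratio: float,
    oxygen_uM: float,
) -> tuple[np.ndarray, dict[str, int]]:
    """Assemble the linear ODE generator for the monolayer system.

    State ordering: ``[Ce_0, Ci_0, Ce_1, Ci_1, ..., sink]`` following the
    order of ``compounds``; the sink accumulates extracellular degradation
    and the terminal metabolic step in Ve-referenced uM-equivalents, so the
    weighted sum ``sum(Ce) + vr*sum(Ci) + sink`` is invariant.
    """
    validate_chain(compounds)
    label = line.label if isinstance(line, CellLineParams) else (line or "wildtype")
    n = len(compounds)
    idx = {c.name: 2 * i for i, c in enumerate(compounds)}
    sink = 2 * n
    A = np.zeros((2 * n + 1, 2 * n + 1))
    terminals = _terminal_names(compounds)
    for c in compounds:
        e, i = idx[c.name], idx[c.name] + 1
        kmet = c.k_met(label, oxygen_uM)
        A[e, e] -= c.k_loss + volume_ratio * c.k_in
        A[e, i] += volume_ratio * c.k_out
        A[i, e] += c.k_in
        A[i, i] -= c.k_out + kmet
        A[sink, e] += c.k_loss
        if c.parent is not None:
            A[i, idx[c.parent] + 1] += compounds[
                [cc.name for cc in compounds].index(c.parent)
            ].k_met(label, oxygen_uM)
        if c.name in terminals and kmet > 0:
            A[sink, i] += volume_ratio * kmet
    return A, idx


def simulate_monolayer(
    setup: MonolayerSetup,
    compounds: Sequence[CompoundParams],
    line: CellLineParams | str | None = None,
    oxygen_uM: float | None = None,
    times_min: Sequence[float] | None = None,
    return_sink: bool = False,
):
    """Simulate extracellular/intracellular trajectories for a compound chain.

    Returns a list of :class:`ConcProfile` (Ce and Ci per compound), plus the
    sink trajectory when ``return_sink`` is set.  The prodrug starts at
    ``setup.c0_uM`` extracellularly; everything else at zero.
    """
    o2 = setup.oxygen_uM if oxygen_uM is None else oxygen_uM
    times = np.asarray(
        setup.sample_times_min if times_min is None else times_min, float
    )
    A, idx = build_rate_matrix(compounds, line, setup.volume_ratio, o2)
    root = validate_chain(compounds)
    u = np.zeros(A.shape[0])
    u[idx[root.name]] = setup.c0_uM

    out = np.empty((times.size, u.size))
    t_prev, u_cur = 0.0, u
    props: dict[float, np.ndarray] = {}
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt < 0:
            raise ValueError("simulation times must be non-decreasing")
        if dt > 0:
            P = props.get(dt)
            if P is None:
                P = expm(A * dt)
                props[dt] = P
            u_cur = P @ u_cur
        out[k] = u_cur
        t_prev = t

    profiles = []
    for c in compounds:
        e = idx[c.name]
        profiles.append(ConcProfile(c.name, "extracellular", times, np.clip(out[:, e], 0.0, None)))
        profiles.append(ConcProfile(c.name, "intracellular", times, np.clip(out[:, e + 1], 0.0, None)))
    if return_sink:
        return profiles, out[:, -1]
    return profiles


def mass_balance(
    profiles: Sequence[ConcProfile],
    setup: MonolayerSetup,
    sink: np.ndarray | None = None,
) -> np.ndarray:
    """Total drug mass per time point, normalised to the initial amount.

    Mass is ``sum_N Ce_N + vr * sum_N Ci_N (+ sink)`` in Ve-referenced
    uM-equivalents.  All profiles must share one time grid.
    """
    grids = {tuple(p.times_min) for p in profiles}
    if len(grids) != 1:
        raise ValueError("profiles have mismatched time grids")
    vr = setup.volume_ratio
    total = np.zeros(len(next(iter(grids))))
    for p in profiles:
        w = 1.0 if p.compartment == "extracellular" else vr
        total = total + w * p.concentrations_uM
    if sink is not None:
        total = total + np.asarray(sink, float)
    return total / setup.c0_uM


def _usable_points(data: Sequence[ConcProfile]) -> int:
    return int(sum(np.sum(~p.censored) for p in data))


class MonolayerPKModel:
    """Two-compartment cellular PK model bound to monolayer uptake data.

    Parameters
    ----------
    data
        Observed :class:`ConcProfile` records (any number of replicates).
    setup
        Experimental geometry/protocol the data were collected under.
    compounds
        Template metabolite chain supplying fixed constants (half-lives,
        chain topology) and starting guesses.
    line
        Cell line of the monolayer (sets which ``k_met0`` applies).

    ``fit(stage="aerobic")`` estimates the prodrug permeabilities with
    metabolism closed; ``fit(stage="anoxic", fixed=...)`` freezes those and
    estimates metabolic and metabolite constants.
    """

    def __init__(
        self,
        data: Sequence[ConcProfile],
        setup: MonolayerSetup,
        compounds: Sequence[CompoundParams],
        line: CellLineParams | str = "activator",
    ) -> None:
        self.data = list(data)
        self.setup = setup
        self.compounds = tuple(compounds)
        self.line = line
        self.root = validate_chain(self.compounds)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        setup: MonolayerSetup,
        compounds: Sequence[CompoundParams],
        line: CellLineParams | str = "activator",
    ) -> "MonolayerPKModel":
        return cls(profiles_from_dataframe(df), setup, compounds, line)

    # -- forward model -----------------------------------------------------

    def _predict(
        self, chain: Sequence[CompoundParams], oxygen_uM: float
    ) -> dict[tuple[str, str], ConcProfile]:
        grid = np.unique(np.concatenate([p.times_min for p in self.data]))
        profs = simulate_monolayer(
            self.setup, chain, self.line, oxygen_uM=oxygen_uM, times_min=grid
        )
        return {(p.compound, p.compartment): p for p in profs}

    def _residuals(self, chain, oxygen_uM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Log-scale residuals over all uncensored points (obs, pred, resid)."""
        pred_map = self._predict(chain, oxygen_uM)
        obs, pred = [], []
        for p in self.data:
            key = (p.compound, p.compartment)
            if key not in pred_map:
                continue
            m = ~p.censored
            if not m.any():
                continue
            model = pred_map[key]
            pi = np.interp(p.times_min[m], model.times_min, model.concentrations_uM)
            obs.append(p.concentrations_uM[m])
            pred.append(pi)
        o = np.concatenate(obs) if obs else np.array([])
        q = np.concatenate(pred) if pred else np.array([])
        floor = max(self.setup.lloq_uM, 1e-12)
        resid = np.log(np.maximum(q, floor * 1e-3)) - np.log(np.maximum(o, floor * 1e-3))
        return o, q, resid

    def _chain_with(self, values: Mapping[str, float], oxygen_gate_open: bool) -> tuple[CompoundParams, ...]:
        """Apply 'param:compound'-keyed values onto the template chain."""
        label = self.line.label if isinstance(self.line, CellLineParams) else self.line
        out = []
        for c in self.compounds:
            kw: dict = {}
            for par in ("k_in", "k_out"):
                key = f"{par}:{c.name}"
                if key in values:
                    kw[par] = values[key]
            key = f"k_met0:{c.name}"
            if key in values:
                kw["k_met0_by_line"] = {**dict(c.k_met0_by_line), label: values[key]}
            elif not oxygen_gate_open and c.oxygen_gated:
                kw["k_met0_by_line"] = {label: 0.0}
            out.append(c.with_(**kw) if kw else c)
        return tuple(out)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        stage: str = "aerobic",
        fixed: FitResult | Mapping[str, float] | None = None,
        fit_compounds: Sequence[str] | None = None,
        n_starts: int = 5,
        seed: int = 0,
    ) -> FitResult:
        if stage == "aerobic":
            return self._fit_aerobic(n_starts, seed)
        if stage == "anoxic":
            return self._fit_anoxic(fixed, fit_compounds, n_starts, seed)
        raise ValueError(f"unknown stage {stage!r}")

    def _check_usable(self, free: Sequence[str]) -> None:
        n = _usable_points(self.data)
        if n < len(free):
            raise UnderDeterminedError(
                f"{n} uncensored points for {len(free)} free parameters"
            )

    def _fit_aerobic(self, n_starts: int, seed: int) -> FitResult:
        root = self.root.name
        names = [f"k_in:{root}", f"k_out:{root}"]
        self._check_usable(names)
        o2 = self.setup.oxygen_uM

        def resid(v):
            chain = self._chain_with(v, oxygen_gate_open=False)
            return self._residuals(chain, o2)[2]

        def predict(v):
            chain = self._chain_with(v, oxygen_gate_open=False)
            return self._residuals(chain, o2)[1]

        obs = self._residuals(self._chain_with({}, False), o2)[0]
        p0 = {names[0]: 1.0, names[1]: 0.1}
        res = fit_least_squares(
            resid, p0, n_starts=n_starts, seed=seed, observed=obs, predict_fn=predict
        )
        res.fixed = {f"k_met0:{root}": 0.0}
        return res

    def _fit_anoxic(
        self,
        fixed: FitResult | Mapping[str, float] | None,
        fit_compounds: Sequence[str] | None,
        n_starts: int,
        seed: int,
    ) -> FitResult:
        root = self.root.name
        fixed_map = dict(fixed.estimates) if isinstance(fixed, FitResult) else dict(fixed or {})
        for par in ("k_in", "k_out"):
            key = f"{par}:{root}"
            if key not in fixed_map:
                raise ValueError(f"anoxic stage requires fixed {key} from the aerobic fit")

        observed = {p.compound for p in self.data}
        if fit_compounds is None:
            fit_compounds = [
                c.name for c in self.compounds if c.parent is not None and c.name in observed
            ]
        names = [f"k_met0:{root}"]
        for cname in fit_compounds:
            names += [f"k_in:{cname}", f"k_out:{cname}", f"k_met0:{cname}"]
        self._check_usable(names)

        def full(v):
            return {**fixed_map, **v}

        def resid(v):
            return self._residuals(self._chain_with(full(v), True), 0.0)[2]

        def predict(v):
            return self._residuals(self._chain_with(full(v), True), 0.0)[1]

        obs = self._residuals(self._chain_with(fixed_map, True), 0.0)[0]
        p0 = {n: (0.1 if n.startswith("k_met0") else 0.5) for n in names}
        # permeabilities bounded to a physically plausible range; weakly
        # identified metabolite k_in (tiny extracellular levels) pins to a
        # bound instead of wandering off-scale
        bounds = {
            n: ((1e-4, 1e2) if not n.startswith("k_met0") else (1e-8, 1e1))
            for n in names
        }
        res = fit_least_squares(
            resid,
            p0,
            bounds=bounds,
            fixed=fixed_map,
            n_starts=n_starts,
            seed=seed,
            observed=obs,
            predict_fn=predict,
        )
        return res


def fit_aerobic_uptake(
    data: Sequence[ConcProfile],
    setup: MonolayerSetup,
    compounds: Sequence[CompoundParams],
    line: CellLineParams | str = "activator",
    **kw,
) -> FitResult:
    """Estimate prodrug ``k_in``/``k_out`` from aerobic uptake profiles."""
    return MonolayerPKModel(data, setup, compounds, line).fit("aerobic", **kw)


def fit_anoxic_metabolism(
    data: Sequence[ConcProfile],
    setup: MonolayerSetup,
    compounds: Sequence[CompoundParams],
    fixed: FitResult | Mapping[str, float],
    line: CellLineParams | str = "activator",
    **kw,
) -> FitResult:
    """Estimate metabolic constants from anoxic profiles, permeabilities fixed."""
    return MonolayerPKModel(data, setup, compounds, line).fit("anoxic", fixed=fixed, **kw)


# -- tabular I/O -----------------------------------------------------------


def profiles_to_dataframe(profiles: Sequence[ConcProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for t, c, cen in zip(p.times_min, p.concentrations_uM, p.censored):
            rows.append(
                {
                    "time_min": t,
                    "compound": p.compound,
                    "compartment": p.compartment,
                    "concentration_uM": c,
                    "replicate": p.replicate,
                    "censored": int(cen),
                }
            )
    return pd.DataFrame(rows)


def profiles_from_dataframe(df: pd.DataFrame) -> list[ConcProfile]:
    out = []
    for (comp, compartment, rep), g in df.groupby(
        ["compound", "compartment", "replicate"], sort=False
    ):
        g = g.sort_values("time_min")
        out.append(
            ConcProfile(
                comp,
                compartment,
                g["time_min"].to_numpy(float),
                g["concentration_uM"].to_numpy(float),
                g["censored"].to_numpy(bool) if "censored" in g else None,
                replicate=int(rep),
            )
        )
    return out
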