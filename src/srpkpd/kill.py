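"""Clonogenic kill model linking metabolite exposure to cell survival.

The kill probability is proportional to the intracellular concentration of
the cytotoxic bioreductive metabolites (and zero for the prodrug), so the
integrated hazard over an exposure is ``k_d * sum_N AUC_N`` and

    SF = exp(-k_d * sum_N AUC_N)

with the same ``k_d`` for every cytotoxic metabolite.  For monolayers the
cellular PK model supplies the AUCs; because the kinetics are first order
the AUC scales linearly with the applied concentration, so a single
unit-concentration simulation parameterises a whole dose-response curve.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from ._fitting import FitResult, fit_least_squares
from .monolayer import MonolayerSetup, simulate_monolayer
from .params import CellLineParams, CompoundParams

__all__ = [
    "metabolite_auc_per_uM",
    "monolayer_survival_curve",
    "fit_kill_constant",
]


def metabolite_auc_per_uM(
    setup: MonolayerSetup,
    compounds: Sequence[CompoundParams],
    line: CellLineParams | str,
    duration_min: float = 240.0,
    oxygen_uM: float = 0.0,
    grid_min: float = 1.0,
) -> float:
    """Total cytotoxic-metabolite intracellular AUC per uM of applied prodrug.

    Returns ``sum_N AUC_N / C0`` (minutes) over the cytotoxic compounds for
    the given monolayer protocol; first-order kinetics make this
    independent of ``C0``.
    """
    times = np.arange(0.0, duration_min + grid_min / 2.0, grid_min)
    from dataclasses import replace

    unit = replace(setup, c0_uM=1.0, duration_min=duration_min)
    profiles = simulate_monolayer(unit, compounds, line, oxygen_uM=oxygen_uM, times_min=times)
    cyto = {c.name for c in compounds if c.is_cytotoxic}
    total = 0.0
    for p in profiles:
        if p.compartment == "intracellular" and p.compound in cyto:
            total += float(np.trapezoid(p.concentrations_uM, p.times_min))
    return total


def monolayer_survival_curve(
    c0_values_uM: Sequence[float],
    setup: MonolayerSetup,
    compounds: Sequence[CompoundParams],
    line: CellLineParams,
    duration_min: float = 240.0,
    oxygen_uM: float = 0.0,
) -> np.ndarray:
    """Predicted clonogenic SF of a monolayer over a concentration series."""
    auc1 = metabolite_auc_per_uM(setup, compounds, line, duration_min, oxygen_uM)
    c0 = np.asarray(c0_values_uM, float)
    return np.exp(-line.k_d_monolayer * auc1 * c0)


def fit_kill_constant(
    sf_observed: Sequence[float],
    auc_totals: Sequence[float],
) -> FitResult:
    """Estimate ``k_d`` from observed surviving fractions and model AUCs.

    The log-linear structure (``-log SF = k_d * AUC``) is fitted by least
    squares on log-survival, which weights the informative intermediate
    doses and is exact for noiseless data.
    """
    sf = np.asarray(sf_observed, float)
    auc = np.asarray(auc_totals, float)
    keep = (sf > 0) & np.isfinite(sf)
    sf, auc = sf[keep], auc[keep]

    def resid(v):
        return -v["k_d"] * auc - np.log(sf)

    return fit_least_squares(
        resid,
        {"k_d": 1e-2},
        bounds={"k_d": (1e-10, 1e3)},
        n_starts=3,
        observed=np.log(sf),
        predict_fn=lambda v: -v["k_d"] * auc,
    )
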