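"""Kinetic and transport parameters for a hypoxia-activated prodrug and its metabolites.

The central objects are :class:`CompoundParams` (per-compound first-order rate
constants and diffusion coefficients, linked into a metabolite chain via
``parent``) and :class:`CellLineParams` (doubling time and kill-probability
constants for the metabolically competent "activator" and metabolically
defective "target" cell lines).

:func:`cp506_chain` returns the published parameter set for the nitrogen
mustard prodrug CP-506 and its three major reduced metabolites
(hydroxylamine CP-506H, amine CP-506M and dichloro-amine CP-506M-Cl2),
which is the default generating truth for every synthetic experiment in
this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "CompoundParams",
    "CellLineParams",
    "halflife_to_rate",
    "oxygen_gate",
    "cp506_chain",
    "cp506_cell_lines",
    "validate_chain",
    "CM2_S_TO_UM2_MIN",
    "UREA_D_MCL_CM2_S",
    "MEDIA_STABILITY_HALFLIVES_MIN",
]

#: conversion factor for diffusion coefficients, cm^2/s -> um^2/min
CM2_S_TO_UM2_MIN = 1e8 * 60.0

#: tissue diffusion coefficient of the [14C]-urea internal standard (cm^2/s)
UREA_D_MCL_CM2_S = 3.67e-7

#: measured half-lives of the prodrug metabolites in stirred culture medium at
#: 37 C (minutes); the prodrug itself shows no loss over the assay window.
MEDIA_STABILITY_HALFLIVES_MIN: Mapping[str, float] = {
    "CP-506": math.inf,
    "CP-506H-(OH)2": 2.5,
    "CP-506H": 10.5,
    "CP-506M": 7.6,
    "CP-506H-Cl2": 141.3,
    "CP-506M-Cl2": 271.1,
    "CP-506M-(OH)2": 393.9,
}


def halflife_to_rate(halflife_min: float) -> float:
    """Convert a first-order half-life (minutes) to a rate constant (1/min).

    An infinite half-life denotes a chemically stable compound and maps to a
    rate of exactly zero.

    Raises
    ------
    ValueError
        If ``halflife_min`` is finite and not strictly positive, or NaN.
    """
    if math.isnan(halflife_min):
        raise ValueError("half-life must not be NaN")
    if math.isinf(halflife_min) and halflife_min > 0:
        return 0.0
    if halflife_min <= 0:
        raise ValueError(f"half-life must be positive, got {halflife_min}")
    return math.log(2.0) / halflife_min


def oxygen_gate(o2_uM: float, k_o2: float = 0.1, hill: float = 2.0) -> float:
    """Fractional activity of the bioreductive pathway at oxygen level ``o2_uM``.

    Hyperbolic inhibition ``1 / (1 + (O2/K)^h)`` with defaults chosen so the
    gate is fully open at anoxia (g(0) = 1) and essentially closed above
    1 uM O2 (g(1 uM) < 0.01), matching the strict oxygen dependence of
    prodrug activation.  Metabolite instability is chemical, not enzymatic,
    and is never gated.
    """
    if o2_uM < 0:
        raise ValueError("oxygen concentration must be >= 0")
    return 1.0 / (1.0 + (o2_uM / k_o2) ** hill)


@dataclass(frozen=True)
class CompoundParams:
    """First-order kinetic and transport constants for one compound.

    Attributes
    ----------
    name : str
        Compound identifier.
    parent : str | None
        Compound from which this one is produced by intracellular metabolism
        (``None`` for the prodrug at the root of the chain).
    k_in, k_out : float
        Transmembrane transfer rate constants (1/min), extracellular ->
        intracellular and back.
    k_met0_by_line : mapping
        Maximum (anoxic) intracellular metabolism/instability rate constant
        (1/min) per cell-line label.  For the prodrug this is the
        reductase-dependent activation rate and differs strongly between
        activator and target lines; for metabolites it is chemical
        instability and line-independent.
    halflife_extracellular_min : float
        First-order loss half-life in cell-free medium (minutes); ``inf``
        means stable.
    oxygen_gated : bool
        True only for the prodrug: intracellular metabolism is suppressed by
        oxygen via :func:`oxygen_gate`.
    is_cytotoxic : bool
        Whether the compound contributes to the kill-probability exposure
        integral (the prodrug itself does not).
    d_tissue_cm2_s, d_medium_cm2_s : float
        Diffusion coefficients through tissue-density extracellular space and
        free culture medium (cm^2/s).
    """

    name: str
    parent: str | None = None
    k_in: float = 0.0
    k_out: float = 0.0
    k_met0_by_line: Mapping[str, float] = field(default_factory=dict)
    halflife_extracellular_min: float = math.inf
    oxygen_gated: bool = False
    is_cytotoxic: bool = False
    d_tissue_cm2_s: float = 1.93e-7
    d_medium_cm2_s: float = 1.32e-6

    def __post_init__(self) -> None:
        if self.k_in < 0 or self.k_out < 0:
            raise ValueError(f"{self.name}: rate constants must be >= 0")
        if any(v < 0 for v in self.k_met0_by_line.values()):
            raise ValueError(f"{self.name}: k_met0 must be >= 0")
        if not (self.halflife_extracellular_min > 0):
            raise ValueError(f"{self.name}: half-life must be > 0")
        if self.oxygen_gated and self.parent is not None:
            raise ValueError(f"{self.name}: only the root prodrug may be oxygen-gated")

    @property
    def k_loss(self) -> float:
        """Extracellular first-order loss rate constant (1/min)."""
        return halflife_to_rate(self.halflife_extracellular_min)

    def k_met0(self, line: str) -> float:
        """Maximum anoxic intracellular metabolism rate for ``line`` (1/min)."""
        return self.k_met0_by_line.get(line, 0.0)

    def k_met(self, line: str, o2_uM: float) -> float:
        """Oxygen-dependent intracellular metabolism rate (1/min)."""
        g = oxygen_gate(o2_uM) if self.oxygen_gated else 1.0
        return self.k_met0(line) * g

    def with_(self, **changes) -> "CompoundParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class CellLineParams:
    """Growth and drug-sensitivity parameters of one cell line."""

    name: str
    doubling_time_h: float
    k_d_monolayer: float = 0.0  # 1/(uM min), kill probability per unit exposure
    k_d_spheroid: float = 0.0
    label: str = "wildtype"  # activator | target | wildtype

    def __post_init__(self) -> None:
        if not (self.doubling_time_h > 0):
            raise ValueError("doubling time must be > 0")
        if self.k_d_monolayer < 0 or self.k_d_spheroid < 0:
            raise ValueError("k_d must be >= 0")
        if self.label not in ("activator", "target", "wildtype"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def growth_rate_per_min(self) -> float:
        """Exponential volume growth rate ln2 / Td (1/min)."""
        return math.log(2.0) / (self.doubling_time_h * 60.0)


def validate_chain(compounds: Sequence[CompoundParams]) -> CompoundParams:
    """Validate a metabolite chain and return its root (the prodrug).

    The ``parent`` links must form an acyclic chain over the given compounds
    with exactly one root, and only the root may be oxygen-gated.
    """
    by_name = {c.name: c for c in compounds}
    if len(by_name) != len(compounds):
        raise ValueError("duplicate compound names")
    roots = [c for c in compounds if c.parent is None]
    if len(roots) != 1:
        raise ValueError(f"chain must have exactly one root, found {len(roots)}")
    for c in compounds:
        if c.parent is not None and c.parent not in by_name:
            raise ValueError(f"{c.name}: unknown parent {c.parent!r}")
    # walk up from every compound; a cycle would loop forever past len(compounds)
    for c in compounds:
        seen = {c.name}
        cur = c
        while cur.parent is not None:
            cur = by_name[cur.parent]
            if cur.name in seen:
                raise ValueError("cycle in metabolite chain")
            seen.add(cur.name)
    return roots[0]


def cp506_chain() -> tuple[CompoundParams, ...]:
    """Published PK parameter set for CP-506 and its major metabolites.

    Linear chain CP-506 -> CP-506H -> CP-506M -> CP-506M-Cl2 -> (terminal
    sink).  The terminal k_met0 of CP-506M-Cl2 routes further reduction
    products (inactive diols etc.) to an explicit sink so that mass is
    conserved.  Units: rate constants 1/min, half-lives stored in minutes,
    diffusion coefficients cm^2/s.
    """
    met = {"activator": 0.12, "target": 0.0019}
    return (
        CompoundParams(
            name="CP-506",
            k_in=3.7,
            k_out=0.06,
            k_met0_by_line=met,
            halflife_extracellular_min=30.0 * 60.0,
            oxygen_gated=True,
            is_cytotoxic=False,
        ),
        CompoundParams(
            name="CP-506H",
            parent="CP-506",
            k_in=0.9,
            k_out=0.25,
            k_met0_by_line={"activator": 0.09, "target": 0.09},
            halflife_extracellular_min=0.18 * 60.0,
            is_cytotoxic=True,
        ),
        CompoundParams(
            name="CP-506M",
            parent="CP-506H",
            k_in=0.9,
            k_out=0.4,
            k_met0_by_line={"activator": 0.1, "target": 0.1},
            halflife_extracellular_min=0.13 * 60.0,
            is_cytotoxic=True,
        ),
        CompoundParams(
            name="CP-506M-Cl2",
            parent="CP-506M",
            k_in=0.9,
            k_out=0.3,
            k_met0_by_line={"activator": 0.1, "target": 0.1},
            halflife_extracellular_min=4.52 * 60.0,
            is_cytotoxic=True,
        ),
    )


def cp506_cell_lines() -> dict[str, CellLineParams]:
    """Activator (POR-overexpressing) and target (POR-null) HCT-116 lines."""
    return {
        "activator": CellLineParams(
            name="POR-R",
            doubling_time_h=21.7,
            k_d_monolayer=0.01,
            k_d_spheroid=0.0256,
            label="activator",
        ),
        "target": CellLineParams(
            name="PORko-G",
            doubling_time_h=22.95,
            k_d_monolayer=0.01,
            k_d_spheroid=0.0256,
            label="target",
        ),
    }
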