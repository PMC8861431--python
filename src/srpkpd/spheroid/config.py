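"""Configuration for the lattice spheroid agent-based model."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AbmConfig"]


@dataclass(frozen=True)
class AbmConfig:
    """Lattice, physiology and numerics knobs for spheroid simulations.

    Cells sit on a cubic lattice with ``lattice_spacing_um`` pitch and
    divide on reaching ``v_div_um3`` (twice the post-division volume).
    Oxygen enters from the boundary at ``boundary_o2_uM`` and is consumed
    at up to ``o2_consumption_fmol_per_cell_min`` per cell
    (Michaelis-limited below ``k_o2_consumption_uM``); cells falling below
    ``necrosis_o2_threshold_uM`` are tagged to die and lyse
    ``lysis_delay_h`` later, vacating their site.  ``cell_volume_fraction``
    is the fraction of an occupied site taken up by cell (the rest is
    intercellular space through which drug and oxygen diffuse).

    The default oxygen consumption is set so that an untreated spheroid a
    few hundred micrometres in radius develops a hypoxic (<0.15 uM) core —
    an effective, tunable value, not a measured one.
    """

    lattice_spacing_um: float = 10.0
    v_div_um3: float = 1000.0
    cell_volume_fraction: float = 0.5
    necrosis_o2_threshold_uM: float = 0.15
    lysis_delay_h: float = 24.0
    boundary_o2_uM: float = 200.0
    o2_consumption_fmol_per_cell_min: float = 3.6
    k_o2_consumption_uM: float = 1.0
    k_grow_o2_uM: float = 1.0
    medium_margin_sites: int = 4
    time_step_min: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_spacing_um <= 0 or self.v_div_um3 <= 0:
            raise ValueError("lattice spacing and division volume must be > 0")
        # a site must be able to hold one cell near division
        ratio = self.v_div_um3 / self.lattice_spacing_um**3
        if not (0.25 <= ratio <= 4.0):
            raise ValueError(
                "lattice_spacing^3 should approximate the division volume "
                f"(ratio {ratio:.2f})"
            )
        if self.necrosis_o2_threshold_uM <= 0:
            raise ValueError("necrosis threshold must be > 0")
        if not (0.0 < self.cell_volume_fraction < 1.0):
            raise ValueError("cell volume fraction must be in (0, 1)")
        if self.time_step_min <= 0 or self.lysis_delay_h < 0:
            raise ValueError("invalid timing parameters")
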