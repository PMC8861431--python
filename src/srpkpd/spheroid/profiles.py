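"""Radial intracellular concentration profiles and penetration metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RadialProfile"]


@dataclass
class RadialProfile:
    """Mean intracellular concentration binned by depth from the surface.

    ``depths_um`` are bin centres ordered surface -> centre; ``mean_ci_uM``
    maps compound -> per-bin mean intracellular concentration.
    """

    depths_um: np.ndarray
    mean_ci_uM: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, float)
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("depths must be strictly increasing")
        for k, v in self.mean_ci_uM.items():
            v = np.asarray(v, float)
            if v.shape != self.depths_um.shape:
                raise ValueError(f"{k}: bin count mismatch")
            self.mean_ci_uM[k] = v

    def fold_range(self, compound: str) -> float:
        """Ratio of the outermost (peripheral) to innermost (central) bin."""
        c = self.mean_ci_uM[compound]
        if c[-1] <= 0:
            return float("inf")
        return float(c[0] / c[-1])

    def penetration_depth(self, compound: str, fraction: float = 0.01) -> float:
        """Depth at which the profile first drops below ``fraction`` of the
        peripheral (outermost-bin) value, linearly interpolated between bin
        centres.  Returns the maximum depth if the profile never drops that
        far (i.e. the compound penetrates the full radius)."""
        c = self.mean_ci_uM[compound]
        thresh = fraction * c[0]
        below = np.nonzero(c < thresh)[0]
        if below.size == 0:
            return float(self.depths_um[-1])
        j = below[0]
        if j == 0:
            return float(self.depths_um[0])
        # interpolate on log-concentration (profiles decay ~exponentially)
        d0, d1 = self.depths_um[j - 1], self.depths_um[j]
        c0, c1 = max(c[j - 1], 1e-300), max(c[j], 1e-300)
        f = (np.log(thresh) - np.log(c0)) / (np.log(c1) - np.log(c0))
        return float(d0 + f * (d1 - d0))

    def plot(self, ax=None, logy: bool = True):
        """Plot the radial profiles (depth on x, mean Ci on y) per compound."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, c in self.mean_ci_uM.items():
            ax.plot(self.depths_um, c, marker="o", ms=3, label=name)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("depth from spheroid surface (um)")
        ax.set_ylabel("mean intracellular concentration (uM)")
        ax.legend(fontsize=8)
        return ax

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, c in self.mean_ci_uM.items():
            for d, v in zip(self.depths_um, c):
                rows.append({"depth_um": d, "compound": name, "mean_Ci_uM": v})
        return pd.DataFrame(rows)
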