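"""Dose-response utilities: 4PL fitting, IC50 interpolation, surviving fractions.

The IC50 convention here is the assay one: the concentration at which the
fitted curve crosses 50% of the untreated control, obtained by
interpolation on a fitted four-parameter logistic (4PL).  This coincides
with the 4PL midpoint ``ec50`` only when ``bottom = 0`` and ``top`` equals
the control level.  Curves that never reach 50% of control return a
greater-than-range sentinel instead of a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._fitting import FitResult, fit_least_squares

__all__ = [
    "DoseResponse",
    "Curve4PL",
    "FourParamLogisticModel",
    "fit_4pl",
    "interpolate_ic50",
    "surviving_fraction",
    "fold_ratio",
    "GREATER_THAN_RANGE",
]

#: sentinel returned when the fitted curve never crosses 50% of control
GREATER_THAN_RANGE = float("inf")


@dataclass
class DoseResponse:
    """Concentration vs fraction-of-control records for one assay."""

    concentrations_uM: np.ndarray
    responses: np.ndarray  # fraction of untreated control
    line: str = ""
    condition: str = "aerobic"  # aerobic | anoxic
    endpoint: str = "clonogenic"  # antiproliferative | clonogenic | growth

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations_uM.shape != self.responses.shape:
            raise ValueError("concentration/response length mismatch")
        if np.any(self.concentrations_uM < 0) or np.any(self.responses < 0):
            raise ValueError("concentrations and responses must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DoseResponse":
        return cls(
            df["concentration_uM"].to_numpy(float),
            df["response_fraction"].to_numpy(float),
            line=str(df["line"].iloc[0]) if "line" in df else "",
            condition=str(df["condition"].iloc[0]) if "condition" in df else "aerobic",
            **kw,
        )


@dataclass(frozen=True)
class Curve4PL:
    """Four-parameter logistic y = bottom + (top-bottom)/(1+(x/ec50)^hill)."""

    bottom: float
    top: float
    ec50: float
    hill: float

    def __post_init__(self) -> None:
        if not (self.top > self.bottom):
            raise ValueError("top must exceed bottom")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, x / self.ec50, 0.0)
            y = self.bottom + (self.top - self.bottom) / (1.0 + ratio**self.hill)
        return np.where(x > 0, y, self.top)


class FourParamLogisticModel:
    """4PL regression model for a dose-response record.

    Fitting runs on the log-concentration axis (zero-concentration controls
    normalise the response but are excluded from the regression) and
    returns a :class:`FitResult` whose ``curve`` attribute is the fitted
    :class:`Curve4PL`.
    """

    def __init__(self, data: DoseResponse) -> None:
        self.data = data
        mask = data.concentrations_uM > 0
        self.x = data.concentrations_uM[mask]
        self.y = data.responses[mask]
        if np.unique(self.x).size < 4:
            raise ValueError("need at least 4 distinct positive concentrations")

    def fit(self, n_starts: int = 5, seed: int = 0) -> FitResult:
        x, y = self.x, self.y
        ymax, ymin = float(np.max(y)), float(np.min(y))
        span = max(ymax - ymin, 1e-6)

        def curve_of(v) -> Curve4PL:
            return Curve4PL(
                bottom=v["bottom"] - 1.0,  # shifted +1 to keep log-scale positive
                top=v["bottom"] - 1.0 + v["span"],
                ec50=v["ec50"],
                hill=v["hill"],
            )

        def resid(v):
            return curve_of(v)(x) - y

        p0 = {
            "bottom": max(ymin, 0.0) + 1.0,
            "span": span,
            "ec50": float(np.exp(np.mean(np.log(x)))),
            "hill": 1.0,
        }
        bounds = {
            "bottom": (1e-6, 2.0 + 1.0),
            "span": (1e-6, 10.0),
            "ec50": (np.min(x) * 1e-3, np.max(x) * 1e3),
            "hill": (0.1, 10.0),
        }
        res = fit_least_squares(
            resid,
            p0,
            bounds=bounds,
            n_starts=n_starts,
            seed=seed,
            observed=y,
            predict_fn=lambda v: curve_of(v)(x),
            spread=0.3,
        )
        curve = curve_of(res.estimates)
        if curve.ec50 <= np.min(x) / 30.0 or curve.ec50 >= np.max(x) * 30.0:
            raise RuntimeError(
                "4PL fit did not converge to a transition inside the tested "
                f"concentration range (ec50={curve.ec50:.3g} uM)"
            )
        if curve.top - curve.bottom < 0.05:
            raise RuntimeError(
                "no dose-response transition in range: fitted span "
                f"{curve.top - curve.bottom:.3g} is negligible"
            )
        res.estimates = {
            "bottom": curve.bottom,
            "top": curve.top,
            "ec50": curve.ec50,
            "hill": curve.hill,
        }
        res.stderr = {
            "bottom": res.stderr.get("bottom", math.nan),
            "top": math.nan,
            "ec50": res.stderr.get("ec50", math.nan),
            "hill": res.stderr.get("hill", math.nan),
        }
        res.curve = curve  # type: ignore[attr-defined]
        return res


def fit_4pl(data: DoseResponse, **kw) -> Curve4PL:
    """Fit a 4-parameter logistic and return the fitted curve."""
    return FourParamLogisticModel(data).fit(**kw).curve  # type: ignore[attr-defined]


def interpolate_ic50(curve: Curve4PL, control_level: float = 1.0) -> float:
    """Concentration at which the curve crosses 50% of the control level.

    Solves ``curve(x) = control_level / 2`` analytically on the fitted 4PL.
    Returns :data:`GREATER_THAN_RANGE` (infinity) when the curve plateaus
    above that level, mirroring ">range" reporting of non-crossing assays.
    """
    target = 0.5 * control_level
    if target <= curve.bottom:
        return GREATER_THAN_RANGE
    if target >= curve.top:
        return 0.0
    frac = (curve.top - curve.bottom) / (target - curve.bottom) - 1.0
    return float(curve.ec50 * frac ** (1.0 / curve.hill))


def surviving_fraction(
    treated_colonies: float,
    control_colonies: float,
    treated_plated: float,
    control_plated: float | None = None,
) -> float:
    """Clonogenic surviving fraction: treated over control plating efficiency."""
    if control_plated is None:
        control_plated = treated_plated
    if treated_plated <= 0 or control_plated <= 0:
        raise ValueError("cells plated must be > 0")
    if treated_colonies < 0 or control_colonies < 0:
        raise ValueError("colony counts must be >= 0")
    if control_colonies == 0:
        raise ZeroDivisionError("control plating efficiency is zero; SF undefined")
    return (treated_colonies / treated_plated) / (control_colonies / control_plated)


def fold_ratio(a_uM: float, b_uM: float) -> float:
    """Fold change a/b, rounded to 3 significant figures."""
    if b_uM <= 0:
        raise ValueError("denominator must be > 0")
    r = a_uM / b_uM
    if r == 0:
        return 0.0
    return float(round(r, -int(math.floor(math.log10(abs(r)))) + 2))
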