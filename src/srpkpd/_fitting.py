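"""Shared nonlinear least-squares machinery.

All fits in the package go through :func:`fit_least_squares`: bounded
least squares on log10-transformed parameters (every fitted quantity is a
positive rate, diffusivity, length or scaling factor), with seeded
multi-starts to avoid local minima, and standard errors propagated from the
Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "fit_least_squares", "UnderDeterminedError"]


class UnderDeterminedError(ValueError):
    """Fewer usable (non-censored) data points than free parameters."""


@dataclass
class FitResult:
    """Estimated parameters with uncertainties and goodness of fit.

    Attributes
    ----------
    estimates : dict
        Free-parameter estimates on their natural scale.
    stderr : dict
        Approximate standard errors (delta method from the Jacobian of the
        residual vector at the optimum).
    fixed : dict
        Parameters held constant during the fit.
    residuals : ndarray
        Residual vector at the optimum (on the objective scale).
    r_squared : float
        1 - SSR/SST computed on the untransformed observations.
    """

    estimates: dict[str, float]
    stderr: dict[str, float]
    fixed: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    r_squared: float = float("nan")
    n_obs: int = 0
    cost: float = float("nan")
    message: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.estimates) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")

    def summary(self) -> str:
        """Plain-text parameter table in the style of a regression summary."""
        lines = [
            "Least-squares fit results",
            "=" * 58,
            f"{'parameter':<22}{'estimate':>14}{'std err':>14}",
            "-" * 58,
        ]
        for name, val in self.estimates.items():
            se = self.stderr.get(name, float("nan"))
            lines.append(f"{name:<22}{val:>14.5g}{se:>14.3g}")
        for name, val in self.fixed.items():
            lines.append(f"{name:<22}{val:>14.5g}{'(fixed)':>14}")
        lines.append("-" * 58)
        lines.append(f"n_obs = {self.n_obs}    R^2 = {self.r_squared:.4f}")
        return "\n".join(lines)


def _rsquared(observed: np.ndarray, predicted: np.ndarray) -> float:
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    ssr = float(np.sum((observed - predicted) ** 2))
    if sst == 0.0:
        return 1.0 if ssr == 0.0 else float("-inf")
    return 1.0 - ssr / sst


def fit_least_squares(
    residual_fn: Callable[[Mapping[str, float]], np.ndarray],
    p0: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    fixed: Mapping[str, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    observed: np.ndarray | None = None,
    predict_fn: Callable[[Mapping[str, float]], np.ndarray] | None = None,
    log_scale: bool = True,
    spread: float = 0.5,
) -> FitResult:
    """Bounded least squares with seeded multi-starts.

    Parameters
    ----------
    residual_fn
        Maps a parameter dict to a residual vector.
    p0
        Initial guesses for the free parameters (natural scale, > 0 when
        ``log_scale``).
    bounds
        Optional (lo, hi) bounds per parameter on the natural scale.
    n_starts
        Number of optimiser starts; the first uses ``p0`` exactly, the rest
        perturb it by lognormal factors of width ``spread`` decades.
    observed, predict_fn
        When given, R^2 is computed from ``predict_fn`` at the optimum
        against ``observed`` (both on the natural data scale).
    """
    names = list(p0)
    x0 = np.array([p0[k] for k in names], float)
    if log_scale and np.any(x0 <= 0):
        raise ValueError("log-scale fitting requires positive initial guesses")

    lo = np.full(len(names), 1e-12)
    hi = np.full(len(names), 1e12)
    if bounds:
        for i, k in enumerate(names):
            if k in bounds:
                lo[i], hi[i] = bounds[k]

    def to_dict(x: np.ndarray) -> dict[str, float]:
        vals = 10.0**x if log_scale else x
        return dict(zip(names, vals))

    def fun(x: np.ndarray) -> np.ndarray:
        return np.asarray(residual_fn(to_dict(x)), float)

    r0 = fun(np.log10(x0) if log_scale else x0)
    if r0.size < len(names):
        raise UnderDeterminedError(
            f"{r0.size} usable residuals for {len(names)} free parameters"
        )

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 * 10.0 ** rng.normal(0.0, spread, len(names))
        xs = np.clip(xs, lo, hi)
        if log_scale:
            xs, lo_t, hi_t = np.log10(xs), np.log10(lo), np.log10(hi)
        else:
            lo_t, hi_t = lo, hi
        try:
            sol = least_squares(fun, xs, bounds=(lo_t, hi_t), method="trf", x_scale="jac")
        except Exception:  # a bad start may push the solver into failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimiser starts failed")

    est = to_dict(best.x)
    # delta-method standard errors: cov_log = s^2 (J^T J)^-1 on the log scale
    stderr: dict[str, float] = {}
    J = best.jac
    dof = max(best.fun.size - len(names), 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        diag = np.clip(np.diag(cov), 0.0, np.inf)
        for i, k in enumerate(names):
            se_t = float(np.sqrt(diag[i]))
            stderr[k] = est[k] * np.log(10.0) * se_t if log_scale else se_t
    except np.linalg.LinAlgError:
        stderr = {k: float("nan") for k in names}

    r2 = float("nan")
    if observed is not None and predict_fn is not None:
        r2 = _rsquared(observed, predict_fn(est))

    return FitResult(
        estimates=est,
        stderr=stderr,
        fixed=dict(fixed or {}),
        residuals=best.fun,
        r_squared=r2,
        n_obs=int(best.fun.size),
        cost=float(best.cost),
        message=best.message,
    )
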