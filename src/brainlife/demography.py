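"""Survival, fecundity, and the lifetime-reproduction objective R0.

Mortality is age-independent, so survivorship is ``l(t) = exp(-mu*t)``.
Fecundity comes in two modes:

* **approximate** (default): effective fecundity proportional to the mass of
  reproductive tissue, ``m(t) = C * f0 * x_r(t)`` — valid when offspring
  maintenance by the reproductive tissue is negligible and reproductive
  tissue is far costlier to maintain than to build;
* **exact**: offspring accounting by the same energy-conservation logic used
  for skills, integrating ``dx_o/dt = (s_o*B_rest_r - x_o*B_o)/E_o`` with
  ``B_rest_r = x_r*B_r + dx_r/dt * E_r`` and fecundity ``f(t) = dx_o/dt``.

The objective of the allocation problem is the basic reproductive number

    R0 = ∫_0^T l(t) * m(t) dt,

the expected lifetime number of offspring.  ``C`` and ``f0`` rescale R0 but
never move its argmax, so they only matter for interpreting reported values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson, solve_ivp

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet
    from .trajectory import StateTrajectory

__all__ = [
    "OffspringAccounting",
    "survival",
    "fecundity_approx",
    "fecundity_exact",
    "lifetime_reproduction",
]


@dataclass(frozen=True)
class OffspringAccounting:
    """Exact-fecundity parameters: fraction ``s_o`` of reproductive metabolic
    rate devoted to offspring, production heat ``E_o`` (MJ·offspring⁻¹) and
    maintenance rate ``B_o`` (MJ·year⁻¹·offspring⁻¹)."""

    s_o: float
    E_o: float
    B_o: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_o <= 1.0:
            raise ValueError(f"s_o must lie in [0, 1], got {self.s_o!r}")
        if self.E_o <= 0:
            raise ValueError(f"E_o must be > 0, got {self.E_o!r}")
        if self.B_o < 0:
            raise ValueError(f"B_o must be >= 0, got {self.B_o!r}")


def survival(t, mu: float):
    """Survivorship l(t) = exp(-mu*t) under age-independent mortality."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    out = np.exp(-mu * t)
    return out if out.ndim else float(out)


def fecundity_approx(x_r, p: "ParameterSet"):
    """Effective fecundity m(t) = C * f0 * x_r (offspring·year⁻¹)."""
    x_r = np.asarray(x_r, dtype=float)
    out = p.C * p.f0 * x_r
    return out if out.ndim else float(out)


def fecundity_exact(traj: "StateTrajectory", o: OffspringAccounting,
                    p: "ParameterSet") -> tuple[np.ndarray, np.ndarray]:
    """Exact fecundity series f(t) and offspring count x_o(t) on the
    trajectory's reporting grid.

    Integrates the offspring energy balance against the trajectory's
    reproductive metabolic rate ``B_rest_r(t)`` (interpolated linearly
    between grid points) from ``x_o(0) = 0``.
    """
    t = np.asarray(traj.t)
    B_rest_r = np.asarray(traj.B_rest_r)

    def rhs(ti, y):
        br = np.interp(ti, t, B_rest_r)
        return [(o.s_o * br - y[0] * o.B_o) / o.E_o]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, rtol=1e-10, atol=1e-12,
                    method="LSODA", dense_output=False)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"offspring integration failed: {sol.message}")
    x_o = sol.y[0]
    f = (o.s_o * B_rest_r - x_o * o.B_o) / o.E_o
    return f, x_o


def lifetime_reproduction(traj: "StateTrajectory", p: "ParameterSet",
                          m: np.ndarray | None = None) -> float:
    """Basic reproductive number R0 = ∫ l(t)·m(t) dt over the trajectory.

    By default the approximate effective fecundity ``C*f0*x_r(t)`` is used;
    an explicit effective-fecundity series ``m`` on the trajectory grid may
    be supplied instead (e.g. from :func:`fecundity_exact` scaled by ``C``).
    Quadrature is composite Simpson on the reporting grid, consistent with
    the integrator's accuracy on the (smooth-within-segment) integrand.
    """
    t = np.asarray(traj.t)
    if t[-1] < p.T - 1e-9:
        raise ValueError(f"trajectory ends at t={t[-1]} but T={p.T}; it must span [0, T]")
    if m is None:
        m = fecundity_approx(np.asarray(traj.x_r), p)
    m = np.asarray(m, dtype=float)
    integrand = survival(t, p.mu) * m
    return float(simpson(integrand, x=t))


def cumulative_reproduction(t: np.ndarray, m: np.ndarray, mu: float) -> np.ndarray:
    """Running integral of l(s)·m(s) up to each grid age (trapezoid rule)."""
    integrand = survival(t, mu) * m
    return cumulative_trapezoid(integrand, t, initial=0.0)
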