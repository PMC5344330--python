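"""Allocation controls and forward integration of the ontogenetic dynamics.

A :class:`ControlStrategy` is an age mesh on ``[0, T]`` with one allocation
triple ``(u_b, u_r, u_s)`` per interval (piecewise-constant, the default and
the representation used by the optimizer) or one triple per node
(piecewise-linear, for mesh-refinement studies).  :func:`integrate` runs the
state dynamics forward from the newborn state with an adaptive solver,
restarting at every control node so discontinuities are never smoothed over,
and augments the system with the running integral of ``l(t)·m(t)`` so the
trajectory carries its own R0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .demography import OffspringAccounting
from .environment import extraction_efficiency
from .physiology import NegativeGrowthWarning, effective_allocation

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet

__all__ = [
    "ControlStrategy",
    "StateTrajectory",
    "IntegrationOptions",
    "evaluate_control",
    "integrate",
    "StateFlooredWarning",
]


class StateFlooredWarning(UserWarning):
    """A state variable went (slightly) negative and was floored at zero."""


@dataclass(frozen=True)
class ControlStrategy:
    """Age mesh plus per-interval (or per-node) allocation triples.

    ``mesh`` is strictly increasing from 0 to the terminal age ``T``.  With
    ``interpolation="constant"`` (default), ``values`` has one row per
    interval and the control is right-continuous: at an interior node the
    succeeding interval's triple applies.  With ``interpolation="linear"``,
    ``values`` has one row per node and the control is interpolated linearly
    in between.  Every triple must lie on the unit simplex to 1e-9.
    """

    mesh: np.ndarray
    values: np.ndarray
    interpolation: str = "constant"

    def __post_init__(self) -> None:
        mesh = np.asarray(self.mesh, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "mesh", mesh)
        object.__setattr__(self, "values", values)
        if mesh.ndim != 1 or mesh.size < 2:
            raise ValueError("mesh must contain at least two ages (0 and T)")
        if mesh[0] != 0.0:
            raise ValueError(f"mesh must start at 0, got {mesh[0]!r}")
        if np.any(np.diff(mesh) <= 0):
            raise ValueError("mesh ages must be strictly increasing")
        if self.interpolation not in ("constant", "linear"):
            raise ValueError(f"interpolation must be 'constant' or 'linear', got {self.interpolation!r}")
        n_expected = mesh.size - 1 if self.interpolation == "constant" else mesh.size
        if values.shape != (n_expected, 3):
            raise ValueError(
                f"values must have shape ({n_expected}, 3) for {self.interpolation!r} "
                f"interpolation on a {mesh.size}-node mesh, got {values.shape}"
            )
        if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
            raise ValueError("allocation components must lie in [0, 1]")
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"allocation triples must sum to 1 within 1e-9; row {bad} sums to {sums[bad]!r}")

    # -- evaluation --------------------------------------------------------
    @property
    def T(self) -> float:
        return float(self.mesh[-1])

    @property
    def n_intervals(self) -> int:
        return self.mesh.size - 1

    def __call__(self, t: float) -> np.ndarray:
        """Allocation triple at age ``t`` (right-continuous at nodes)."""
        if t < -1e-12 or t > self.T + 1e-12:
            raise ValueError(f"age {t!r} outside [0, {self.T}]")
        t = min(max(t, 0.0), self.T)
        if self.interpolation == "constant":
            idx = int(np.searchsorted(self.mesh, t, side="right")) - 1
            idx = min(max(idx, 0), self.n_intervals - 1)
            return self.values[idx].copy()
        u = np.array([np.interp(t, self.mesh, self.values[:, j]) for j in range(3)])
        return u / u.sum()

    def constant_values(self) -> np.ndarray:
        """Per-interval triples; for linear interpolation, interval midpoints."""
        if self.interpolation == "constant":
            return self.values.copy()
        mid = 0.5 * (self.mesh[:-1] + self.mesh[1:])
        return np.vstack([self(t) for t in mid])

    # -- serialization -----------------------------------------------------
    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "mesh": self.mesh.tolist(),
            "values": self.values.tolist(),
            "interpolation": self.interpolation,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ControlStrategy":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            mesh=np.asarray(payload["mesh"], dtype=float),
            values=np.asarray(payload["values"], dtype=float),
            interpolation=payload.get("interpolation", "constant"),
        )

    @classmethod
    def constant(cls, u: tuple[float, float, float], T: float) -> "ControlStrategy":
        """Single-interval strategy holding one triple for all ages."""
        return cls(mesh=np.array([0.0, float(T)]), values=np.array([u], dtype=float))

    @classmethod
    def uniform_mesh(cls, values: np.ndarray, T: float) -> "ControlStrategy":
        values = np.atleast_2d(values)
        return cls(mesh=np.linspace(0.0, float(T), values.shape[0] + 1), values=values)


def evaluate_control(c: ControlStrategy, t: float) -> np.ndarray:
    """Allocation triple of strategy ``c`` at age ``t`` (right-continuous)."""
    return c(t)


@dataclass(frozen=True)
class IntegrationOptions:
    """Integrator settings: tolerances, reporting-grid size, fecundity mode."""

    rtol: float = 1e-8
    atol: float = 1e-10
    n_report: int = 1000
    # RK45 by default: LSODA's stiffness switching can stall on the
    # discontinuous shrink-to-zero corner; the dynamics here are at most
    # mildly stiff.  Any solve_ivp method name is accepted.
    method: str = "RK45"
    exact_fecundity: Optional[OffspringAccounting] = None
    #: states below -negativity_tol trigger a warning before flooring
    negativity_tol: float = 1e-9


@dataclass
class StateTrajectory:
    """State and derived metabolic series on a reporting grid, plus R0.

    All series share the age grid ``t``; units are kg, skill units, and
    MJ·year⁻¹.  ``x_o`` is present only when the trajectory was integrated
    with exact offspring accounting.
    """

    t: np.ndarray
    x_b: np.ndarray
    x_r: np.ndarray
    x_s: np.ndarray
    x_k: np.ndarray
    e: np.ndarray
    B_rest: np.ndarray
    B_maint: np.ndarray
    B_syn: np.ndarray
    B_rest_b: np.ndarray
    B_rest_r: np.ndarray
    u: np.ndarray  # (n, 3) control evaluated on the grid
    R0: float
    control: ControlStrategy
    x_o: Optional[np.ndarray] = None
    warnings_: list = field(default_factory=list)

    @property
    def body_mass(self) -> np.ndarray:
        return self.x_b + self.x_r + self.x_s

    def final_state(self) -> tuple[float, float, float, float]:
        return (float(self.x_b[-1]), float(self.x_r[-1]), float(self.x_s[-1]), float(self.x_k[-1]))

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        header = (
            "# brainlife trajectory: age [y]; x_b, x_r, x_s [kg]; x_k [skill]; "
            "e [-]; B_rest, B_maint, B_syn [MJ/y]\n"
            "age,x_b,x_r,x_s,x_k,e,B_rest,B_maint,B_syn\n"
        )
        data = np.column_stack([
            self.t, self.x_b, self.x_r, self.x_s, self.x_k,
            self.e, self.B_rest, self.B_maint, self.B_syn,
        ])
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, delimiter=",", fmt="%.10g")
        return path


def _rhs_factory(p: "ParameterSet", u: np.ndarray, o: Optional[OffspringAccounting]):
    """Scalar RHS for one constant-control segment: states + cumulative R0 (+ x_o)."""
    u_b, u_r, u_s = float(u[0]), float(u[1]), float(u[2])

    def rhs(t, y):
        x_b = max(y[0], 0.0)
        x_r = max(y[1], 0.0)
        x_s = max(y[2], 0.0)
        x_k = max(y[3], 0.0)
        x_B = x_b + x_r + x_s
        e = float(extraction_efficiency(x_k, t, p))
        B_rest = p.K * e * x_B**p.beta
        B_maint = x_b * p.B_b + x_r * p.B_r + x_s * p.B_s
        B_syn = B_rest - B_maint
        ub, ur, us = u_b, u_r, u_s
        if B_syn < 0.0 and ((x_b <= 0.0 and ub > 0.0) or (x_r <= 0.0 and ur > 0.0)
                            or (x_s <= 0.0 and us > 0.0)):
            ub, ur, us = effective_allocation(
                np.array([ub, ur, us]), (x_b, x_r, x_s), (p.E_b, p.E_r, p.E_s), B_syn)
        dx_b = ub * B_syn / p.E_b
        dx_r = ur * B_syn / p.E_r
        dx_s = us * B_syn / p.E_s
        dx_k = (p.s_k * (x_b * p.B_b + ub * B_syn) - x_k * p.B_k) / p.E_k
        dR0 = math.exp(-p.mu * t) * p.C * p.f0 * x_r
        out = [dx_b, dx_r, dx_s, dx_k, dR0]
        if o is not None:
            x_o = max(y[5], 0.0)
            B_rest_r = x_r * p.B_r + dx_r * p.E_r
            out.append((o.s_o * B_rest_r - x_o * o.B_o) / o.E_o)
        return out

    return rhs


def _segment_controls(c: ControlStrategy) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoint ages and the constant triple applied on each segment."""
    if c.interpolation == "constant":
        return c.mesh.copy(), c.values.copy()
    # linear interpolation: subdivide each interval so a constant-per-segment
    # approximation of the linear control is accurate to the mesh scale
    sub = 8
    nodes = [np.linspace(c.mesh[i], c.mesh[i + 1], sub + 1)[:-1] for i in range(c.n_intervals)]
    breaks = np.append(np.concatenate(nodes), c.mesh[-1])
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    vals = np.vstack([c(t) for t in mids])
    return breaks, vals


def integrate(p: "ParameterSet", c: ControlStrategy,
              options: Optional[IntegrationOptions] = None) -> StateTrajectory:
    """Integrate the ontogenetic dynamics under strategy ``c`` over [0, T].

    Adaptive integration restarts at every control breakpoint; the cumulative
    reproductive output is carried as an extra state so ``R0`` is computed to
    the same accuracy as the trajectory itself.  States that drift below zero
    beyond ``options.negativity_tol`` are floored at zero with a
    :class:`StateFlooredWarning` (tissue shrinkage to zero is a legitimate
    corner of the model, not an error).
    """
    opts = options or IntegrationOptions()
    if abs(c.T - p.T) > 1e-9:
        raise ValueError(f"control mesh ends at {c.T} but parameters have T = {p.T}")
    o = opts.exact_fecundity
    y = [p.x_b0, p.x_r0, p.x_s0, p.x_k0, 0.0] + ([0.0] if o is not None else [])
    breaks, seg_u = _segment_controls(c)

    t_report = np.linspace(0.0, p.T, opts.n_report)
    ys = np.empty((len(y), t_report.size))
    collected: list[str] = []
    floored = False

    for i in range(len(breaks) - 1):
        t0, t1 = float(breaks[i]), float(breaks[i + 1])
        rhs = _rhs_factory(p, seg_u[i], o)
        sol = solve_ivp(rhs, (t0, t1), y, method=opts.method,
                        rtol=opts.rtol, atol=opts.atol, dense_output=True)
        if not sol.success:
            raise RuntimeError(
                f"integration failed on segment [{t0:.4g}, {t1:.4g}]: {sol.message}"
            )
        # sample the reporting grid points inside (t0, t1]
        mask = (t_report > t0) & (t_report <= t1) if i > 0 else (t_report >= t0) & (t_report <= t1)
        if np.any(mask):
            ys[:, mask] = sol.sol(t_report[mask])
        y = sol.y[:, -1].copy()
        if np.any(y[:4] < -opts.negativity_tol):
            floored = True
        y[:4] = np.maximum(y[:4], 0.0)

    if floored:
        msg = "state variable(s) went negative during integration and were floored at 0"
        collected.append(msg)
        warnings.warn(msg, StateFlooredWarning, stacklevel=2)

    neg_mask = ys[:4] < 0
    if np.any(ys[:4] < -opts.negativity_tol) and not floored:
        msg = "reported state series dipped below zero and were floored at 0"
        collected.append(msg)
        warnings.warn(msg, StateFlooredWarning, stacklevel=2)
    ys[:4][neg_mask] = 0.0

    x_b, x_r, x_s, x_k = ys[0], ys[1], ys[2], ys[3]
    u_grid = np.vstack([c(t) for t in t_report])
    e = np.asarray(extraction_efficiency(x_k, t_report, p), dtype=float)
    x_B = x_b + x_r + x_s
    B_rest = p.K * e * x_B**p.beta
    B_maint = x_b * p.B_b + x_r * p.B_r + x_s * p.B_s
    B_syn = B_rest - B_maint
    if np.any(B_syn < -1e-12):
        msg = "growth metabolic rate is negative on part of the trajectory (tissue shrinkage)"
        collected.append(msg)
        warnings.warn(msg, NegativeGrowthWarning, stacklevel=2)
    B_rest_b = x_b * p.B_b + u_grid[:, 0] * B_syn
    B_rest_r = x_r * p.B_r + u_grid[:, 1] * B_syn

    return StateTrajectory(
        t=t_report, x_b=x_b, x_r=x_r, x_s=x_s, x_k=x_k,
        e=e, B_rest=B_rest, B_maint=B_maint, B_syn=B_syn,
        B_rest_b=B_rest_b, B_rest_r=B_rest_r, u=u_grid,
        R0=float(ys[4, -1]), control=c,
        x_o=(ys[5] if o is not None else None),
        warnings_=collected,
    )
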