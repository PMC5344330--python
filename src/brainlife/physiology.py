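"""Metabolic bookkeeping and the ontogenetic state dynamics.

The body is partitioned into brain, reproductive, and somatic tissue with
masses ``x_b, x_r, x_s`` (kg); ``x_k`` is the skill level.  Resting metabolic
rate follows a power law of body mass scaled by extraction efficiency,

    B_rest = K * e(x_k, t) * x_B**beta,      x_B = x_b + x_r + x_s,

and splits exactly into maintenance ``B_maint = sum_i x_i * B_i`` and growth
(synthesis) ``B_syn = B_rest - B_maint``.  The allocation strategy
``u = (u_b, u_r, u_s)`` on the unit simplex divides ``B_syn`` among the
tissues, giving the growth rates

    dx_i/dt = u_i * B_syn / E_i,

while a fixed fraction ``s_k`` of the brain metabolic rate drives skill
learning against a per-skill memory cost:

    dx_k/dt = (s_k * [x_b*B_b + u_b*B_syn] - x_k*B_k) / E_k.

Energy conservation — ``sum_i dx_i/dt * E_i == B_syn`` — holds identically
for any simplex allocation, and is exercised by the test suite along whole
trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .environment import extraction_efficiency

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet

__all__ = [
    "BodyState",
    "MetabolicBreakdown",
    "maintenance_rate",
    "resting_rate",
    "metabolic_breakdown",
    "dynamics_rhs",
    "effective_allocation",
    "brain_metabolic_rate",
    "asymptotic_skill",
    "encephalization_quotient",
    "NegativeGrowthWarning",
    "SIMPLEX_TOL",
]

#: tolerance on |u_b + u_r + u_s - 1| for allocation triples
SIMPLEX_TOL = 1e-8

# Encephalization quotient: observed brain mass over the expected brain mass
# for the body mass, using the primate allometry EQ = x_b / (0.01122 * x_B**0.76)
# with both masses in kg.
_EQ_COEF = 11.22e-3
_EQ_EXP = 0.76


class NegativeGrowthWarning(UserWarning):
    """Growth metabolic rate is negative: maintenance exceeds resting rate
    and allocated tissues shrink."""


@dataclass(frozen=True)
class BodyState:
    """Tissue masses (kg), skill level (skill units), and age (years)."""

    x_b: float
    x_r: float
    x_s: float
    x_k: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x_b", "x_r", "x_s", "x_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.body_mass <= 0:
            raise ValueError("total body mass x_b + x_r + x_s must be > 0")

    @property
    def body_mass(self) -> float:
        return self.x_b + self.x_r + self.x_s


@dataclass(frozen=True)
class MetabolicBreakdown:
    """Partition of resting metabolic rate at one instant (MJ·year⁻¹)."""

    B_maint: float
    B_syn: float
    B_rest: float
    B_rest_b: float  # brain metabolic rate
    B_rest_r: float  # reproductive-tissue metabolic rate
    e_t: float


def maintenance_rate(s: BodyState, p: "ParameterSet") -> float:
    """Maintenance metabolic rate x_b*B_b + x_r*B_r + x_s*B_s (MJ·year⁻¹)."""
    return s.x_b * p.B_b + s.x_r * p.B_r + s.x_s * p.B_s


def resting_rate(s: BodyState, e_t: float, p: "ParameterSet") -> float:
    """Resting metabolic rate K * e * x_B**beta (MJ·year⁻¹)."""
    if not 0.0 <= e_t <= 1.0:
        raise ValueError(f"extraction efficiency must lie in [0, 1], got {e_t!r}")
    x_B = s.body_mass
    if x_B <= 0:
        raise ValueError("body mass must be > 0")
    return p.K * e_t * x_B**p.beta


def _check_simplex(u: Sequence[float]) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ValueError("allocation must be a triple (u_b, u_r, u_s)")
    if np.any(u < -SIMPLEX_TOL) or np.any(u > 1 + SIMPLEX_TOL):
        raise ValueError(f"allocation components must lie in [0, 1], got {u}")
    if abs(float(u.sum()) - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"allocation must sum to 1 (tolerance {SIMPLEX_TOL}), got sum {u.sum()!r}")
    return u


def metabolic_breakdown(s: BodyState, u: Sequence[float], p: "ParameterSet",
                        warn_negative: bool = True) -> MetabolicBreakdown:
    """Evaluate the instantaneous metabolic partition at state ``s``.

    Extraction efficiency is evaluated from the current skill and age, then
    ``B_rest``, ``B_maint`` and their difference ``B_syn`` follow.  A negative
    ``B_syn`` (maintenance exceeding intake) is returned as-is — allocated
    tissues shrink — with a :class:`NegativeGrowthWarning`.
    """
    u = _check_simplex(u)
    e_t = float(extraction_efficiency(s.x_k, s.t, p))
    B_rest = resting_rate(s, e_t, p)
    B_maint = maintenance_rate(s, p)
    B_syn = B_rest - B_maint
    if B_syn < 0 and warn_negative:
        warnings.warn(
            f"growth metabolic rate negative at t={s.t:.3f} (B_rest={B_rest:.4g} "
            f"< B_maint={B_maint:.4g}); tissues shrink",
            NegativeGrowthWarning,
            stacklevel=2,
        )
    xdot_b = u[0] * B_syn / p.E_b
    B_rest_b = s.x_b * p.B_b + xdot_b * p.E_b
    xdot_r = u[1] * B_syn / p.E_r
    B_rest_r = s.x_r * p.B_r + xdot_r * p.E_r
    return MetabolicBreakdown(
        B_maint=B_maint, B_syn=B_syn, B_rest=B_rest,
        B_rest_b=B_rest_b, B_rest_r=B_rest_r, e_t=e_t,
    )


def effective_allocation(u: np.ndarray, masses: Sequence[float], E: Sequence[float],
                         B_syn: float) -> np.ndarray:
    """Allocation actually applied, correcting the empty-tissue boundary.

    Equal to ``u`` whenever all tissue masses are positive or the growth
    metabolic rate is non-negative — i.e. everywhere the literal dynamics
    are well defined.  When ``B_syn < 0`` and a tissue with positive
    allocation is already exhausted, that tissue cannot shrink further to pay
    the maintenance deficit; its share is redistributed to the remaining
    tissues in proportion to their stored synthesis energy ``x_i * E_i``, so
    the deficit is always paid by existing biomass and the energy-conservation
    identity is preserved.  Without this correction a floored state would let
    maintenance go unpaid — a free energy source that corrupts the
    optimization landscape.
    """
    u = np.asarray(u, dtype=float)
    if B_syn >= 0:
        return u
    masses = np.asarray(masses, dtype=float)
    dead = (masses <= 0.0) & (u > 0.0)
    if not np.any(dead):
        return u
    u_eff = np.where(masses <= 0.0, 0.0, u)
    excess = 1.0 - float(u_eff.sum())
    weights = np.where(masses > 0.0, masses * np.asarray(E, dtype=float), 0.0)
    wsum = float(weights.sum())
    if wsum <= 0.0:
        return u_eff  # nothing left to shrink; dynamics vanish with the body
    return u_eff + excess * weights / wsum


def dynamics_rhs(s: BodyState, u: Sequence[float], p: "ParameterSet",
                 warn_negative: bool = True) -> tuple[float, float, float, float]:
    """Time derivatives (dx_b, dx_r, dx_s, dx_k) of the ontogenetic state.

    ``u`` must be an allocation triple on the unit simplex (checked to
    :data:`SIMPLEX_TOL`).  The identity
    ``dx_b*E_b + dx_r*E_r + dx_s*E_s == B_rest - B_maint`` holds exactly.
    A negative growth metabolic rate shrinks the allocated tissues as-is
    (with a warning); only at the ill-defined empty-tissue boundary is the
    allocation corrected by :func:`effective_allocation`.
    """
    u = _check_simplex(u)
    mb = metabolic_breakdown(s, u, p, warn_negative=warn_negative)
    u = effective_allocation(u, (s.x_b, s.x_r, s.x_s), (p.E_b, p.E_r, p.E_s), mb.B_syn)
    xdot_b = u[0] * mb.B_syn / p.E_b
    xdot_r = u[1] * mb.B_syn / p.E_r
    xdot_s = u[2] * mb.B_syn / p.E_s
    xdot_k = (p.s_k * (s.x_b * p.B_b + u[0] * mb.B_syn) - s.x_k * p.B_k) / p.E_k
    return (xdot_b, xdot_r, xdot_s, xdot_k)


def brain_metabolic_rate(x_b: float, xdot_b: float, p: "ParameterSet") -> float:
    """Brain metabolic rate x_b*B_b + dx_b*E_b (MJ·year⁻¹).

    In the adult limit (``dx_b = 0``) this reduces to ``x_b * B_b``: adult
    brain metabolic rate is proportional to brain mass.
    """
    if x_b < 0:
        raise ValueError("brain mass must be >= 0")
    return x_b * p.B_b + xdot_b * p.E_b


def asymptotic_skill(adult_brain_mass: float, p: "ParameterSet") -> float:
    """Asymptotic (determinate) skill level s_k * B_b * x_b / B_k.

    This is the fixed point of the skill dynamics once brain growth has
    stopped: memory costs saturate the brain metabolic rate allocated to
    skills, making adult skill proportional to adult brain mass.  With
    ``B_k = 0`` there is no saturation (skill grows throughout life) and no
    finite asymptote exists.
    """
    if adult_brain_mass < 0:
        raise ValueError("brain mass must be >= 0")
    if p.B_k <= 0:
        raise ValueError("asymptotic skill is undefined for B_k <= 0 (indeterminate skill growth)")
    return p.s_k * p.B_b * adult_brain_mass / p.B_k


def encephalization_quotient(adult_brain_mass: float, adult_body_mass: float) -> float:
    """Encephalization quotient x_b / (11.22e-3 * x_B**0.76), masses in kg."""
    if adult_brain_mass <= 0 or adult_body_mass <= 0:
        raise ValueError("brain and body mass must be > 0")
    return adult_brain_mass / (_EQ_COEF * adult_body_mass**_EQ_EXP)
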