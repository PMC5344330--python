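"""Energy-extraction environment for the me-vs-nature setting.

An individual of age ``t`` with skill level ``x_k`` faces an environmental
challenge of difficulty ``d(t) = alpha * (1 - phi(t))``, where maternal
facilitation ``phi(t) = phi0 * exp(-phi_r * t)`` eases the challenge early in
life.  The individual's competence is either a power (``c = x_k**gamma``) or
an exponential (``c = exp(gamma * x_k)``) function of skill, and the fraction
of the maximal energy flow actually extracted is the contest success ratio

    e = c / (d + c),

a dimensionless efficiency in [0, 1].  Because the challenge is posed by
nature and met alone (with maternal help at most), ``e`` does not depend on
the resident population's strategy; alternative social settings can be
plugged in by supplying any callable ``e(x_k, t)`` to the integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet

__all__ = [
    "ChallengeState",
    "maternal_facilitation",
    "difficulty",
    "competence",
    "extraction_efficiency",
    "challenge_state",
    "DegenerateContestWarning",
]


class DegenerateContestWarning(UserWarning):
    """Raised when both competence and difficulty are zero (0/0 contest)."""


@dataclass(frozen=True)
class ChallengeState:
    """Snapshot of the challenge at one age: facilitation, difficulty,
    competence, and the resulting extraction efficiency."""

    t: float
    phi_t: float
    d_t: float
    c_t: float
    e_t: float


def maternal_facilitation(t, phi0: float, phi_r: float):
    """Maternal facilitation phi(t) = phi0 * exp(-phi_r * t).

    Dimensionless, non-increasing in age; ``phi(0) = phi0``.
    Accepts scalars or numpy arrays of ages.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    out = phi0 * np.exp(-phi_r * t)
    return out if out.ndim else float(out)


def difficulty(t, alpha: float, phi0: float, phi_r: float):
    """Challenge difficulty d(t) = alpha * (1 - phi(t)), in competence units.

    Non-decreasing in age, rising from ``alpha*(1 - phi0)`` at birth toward
    ``alpha`` as maternal facilitation wanes.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    phi = maternal_facilitation(t, phi0, phi_r)
    out = alpha * (1.0 - np.asarray(phi))
    return out if out.ndim else float(out)


def competence(x_k, gamma: float, form: str = "power"):
    """Competence c(x_k): ``x_k**gamma`` (power) or ``exp(gamma*x_k)`` (exponential).

    With ``gamma = 0`` skills are ineffective and competence is 1 for all
    skill levels under either form (``0**0`` is taken as 1).
    """
    x_k = np.asarray(x_k, dtype=float)
    if np.any(x_k < 0):
        raise ValueError("skill level x_k must be >= 0")
    if form == "power":
        if gamma == 0:
            out = np.ones_like(x_k)
        else:
            out = np.power(x_k, gamma)
    elif form == "exponential":
        out = np.exp(gamma * x_k)
    else:
        raise ValueError(f"unknown competence form {form!r}")
    return out if out.ndim else float(out)


def extraction_efficiency(x_k, t, p: "ParameterSet"):
    """Contest-success energy-extraction efficiency e = c / (d + c) in [0, 1].

    ``e`` increases with skill, decreases with environmental difficulty, and
    equals 1 whenever the (facilitated) challenge has zero difficulty while
    competence is positive.  A contest with ``c = 0`` against ``d > 0`` is
    lost with certainty (``e = 0``).  The degenerate 0/0 corner (zero
    competence against a fully facilitated challenge) is resolved as ``e = 1``
    with a :class:`DegenerateContestWarning`: zero difficulty means nothing
    stands between the individual and the energy.
    """
    c = np.asarray(competence(x_k, p.gamma, p.competence_form), dtype=float)
    d = np.asarray(difficulty(t, p.alpha, p.phi0, p.phi_r), dtype=float)
    c, d = np.broadcast_arrays(c, d)
    denom = c + d
    degenerate = denom == 0.0
    if np.any(degenerate):
        warnings.warn(
            "degenerate contest (competence = difficulty = 0) resolved as e = 1",
            DegenerateContestWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(degenerate, 1.0, c / np.where(degenerate, 1.0, denom))
    return e if e.ndim else float(e)


def challenge_state(x_k: float, t: float, p: "ParameterSet") -> ChallengeState:
    """Assemble the full :class:`ChallengeState` at one age."""
    phi = maternal_facilitation(t, p.phi0, p.phi_r)
    d = difficulty(t, p.alpha, p.phi0, p.phi_r)
    c = competence(x_k, p.gamma, p.competence_form)
    e = extraction_efficiency(x_k, t, p)
    return ChallengeState(t=float(t), phi_t=float(phi), d_t=float(d), c_t=float(c), e_t=float(e))
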