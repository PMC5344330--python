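"""Vectorized fixed-step evaluation of R0 for batches of allocation strategies.

The optimizer, the brute-force oracle, and the needle-variation certificate
all need thousands of R0 evaluations.  This module integrates the ontogenetic
dynamics for a whole *batch* of piecewise-constant controls at once with a
classical RK4 scheme whose steps are aligned with the control mesh, so every
candidate in a batch sees exactly the same discretization and R0 differences
between candidates are free of differential integration error.  (Quantities
that must be compared at certificate precision are therefore always evaluated
inside one batch.)

Steps are capped absolutely (0.1 year by default) and refined per interval
against the fastest linear relaxation rate the batch's controls can excite
(``u_i * B_i / E_i`` per tissue, plus the skill turnover ``B_k / E_k``),
which keeps explicit RK4 stable without paying the stiff-rate price on
intervals that do not allocate to the stiff tissue.

A numba-compiled kernel (:mod:`brainlife._engine_numba`) carries the inner
loops when numba is importable; a pure-numpy fallback with identical
semantics is used otherwise.  The adaptive reference integrator in
:mod:`brainlife.trajectory` remains the authority for reported trajectories;
agreement between the two is part of the test suite.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from ._engine_numba import HAVE_NUMBA, rk4_batch

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ParameterSet

__all__ = ["BatchEvaluator"]

#: absolute RK4 step cap, years
DT_CAP = 0.1
#: stability factor: dt <= _STAB / (fastest relaxation rate)
_STAB = 2.0


class BatchEvaluator:
    """Evaluate R0 (and final states) for batches of per-interval controls.

    Parameters
    ----------
    p : ParameterSet
    mesh : array of breakpoint ages from 0 to T (one control triple applies
        on each interval).
    dt_max : absolute step cap in years (default :data:`DT_CAP`); steps are
        further refined per interval by the stability rule.
    """

    def __init__(self, p: "ParameterSet", mesh: np.ndarray, dt_max: float | None = None):
        self.p = p
        self.mesh = np.asarray(mesh, dtype=float)
        if self.mesh[0] != 0.0 or np.any(np.diff(self.mesh) <= 0):
            raise ValueError("mesh must be strictly increasing from 0")
        self.dt_cap = float(dt_max) if dt_max is not None else DT_CAP
        self._param_tuple = np.array([
            p.K, p.beta, p.B_b, p.B_r, p.B_s, p.E_b, p.E_r, p.E_s,
            p.s_k, p.B_k, p.E_k, p.mu, p.C, p.f0, p.alpha, p.gamma,
            p.phi0, p.phi_r, 0.0 if p.competence_form == "power" else 1.0,
        ])

    # -- step schedule -----------------------------------------------------
    def _substeps(self, U: np.ndarray) -> np.ndarray:
        """Per-interval substep counts for a batch (shared by all rows)."""
        p = self.p
        rates = np.array([p.B_b / p.E_b, p.B_r / p.E_r, p.B_s / p.E_s])
        u_max = U.max(axis=0)  # (n_int, 3): worst case over the batch
        lam = np.maximum((u_max * rates).max(axis=1), p.B_k / p.E_k)
        with np.errstate(divide="ignore"):
            dt = np.minimum(self.dt_cap, np.where(lam > 0, _STAB / lam, self.dt_cap))
        lengths = np.diff(self.mesh)
        return np.maximum(1, np.ceil(lengths / dt).astype(np.int64))

    # -- vectorized physics (numpy fallback path) --------------------------
    def _efficiency(self, x_k: np.ndarray, t: float) -> np.ndarray:
        p = self.p
        if p.competence_form == "power":
            c = np.ones_like(x_k) if p.gamma == 0 else np.power(x_k, p.gamma)
        else:
            c = np.exp(p.gamma * x_k)
        d = p.alpha * (1.0 - p.phi0 * np.exp(-p.phi_r * t))
        denom = c + d
        return np.where(denom == 0.0, 1.0, c / np.where(denom == 0.0, 1.0, denom))

    def _rhs(self, t: float, Y: np.ndarray, U: np.ndarray) -> np.ndarray:
        p = self.p
        # clamp state reads at zero so intermediate RK stages never take
        # fractional powers of negative masses
        x_b = np.maximum(Y[:, 0], 0.0)
        x_r = np.maximum(Y[:, 1], 0.0)
        x_s = np.maximum(Y[:, 2], 0.0)
        x_k = np.maximum(Y[:, 3], 0.0)
        x_B = x_b + x_r + x_s
        e = self._efficiency(x_k, t)
        B_rest = p.K * e * np.power(x_B, p.beta)
        B_syn = B_rest - (x_b * p.B_b + x_r * p.B_r + x_s * p.B_s)
        U = self._effective_allocation(U, x_b, x_r, x_s, B_syn)
        out = np.empty_like(Y)
        out[:, 0] = U[:, 0] * B_syn / p.E_b
        out[:, 1] = U[:, 1] * B_syn / p.E_r
        out[:, 2] = U[:, 2] * B_syn / p.E_s
        out[:, 3] = (p.s_k * (x_b * p.B_b + U[:, 0] * B_syn) - x_k * p.B_k) / p.E_k
        out[:, 4] = np.exp(-p.mu * t) * p.C * p.f0 * x_r
        return out

    def _effective_allocation(self, U, x_b, x_r, x_s, B_syn):
        """Vectorized empty-tissue boundary correction (see
        :func:`brainlife.physiology.effective_allocation`)."""
        p = self.p
        masses = np.stack([x_b, x_r, x_s], axis=1)
        deficit = B_syn < 0.0
        dead = (masses <= 0.0) & (U > 0.0) & deficit[:, None]
        rows = np.any(dead, axis=1)
        if not np.any(rows):
            return U
        U = U.copy()
        E = np.array([p.E_b, p.E_r, p.E_s])
        sub = masses[rows]
        u_eff = np.where(sub <= 0.0, 0.0, U[rows])
        excess = 1.0 - u_eff.sum(axis=1)
        w = np.where(sub > 0.0, sub * E, 0.0)
        wsum = w.sum(axis=1)
        safe = wsum > 0.0
        scale = np.where(safe, excess / np.where(safe, wsum, 1.0), 0.0)
        U[rows] = u_eff + scale[:, None] * w
        return U

    def _evaluate_numpy(self, U: np.ndarray, substeps: np.ndarray, Y: np.ndarray) -> np.ndarray:
        t = 0.0
        for j in range(self.mesh.size - 1):
            u = U[:, j, :]
            dt = (self.mesh[j + 1] - self.mesh[j]) / substeps[j]
            for _ in range(substeps[j]):
                k1 = self._rhs(t, Y, u)
                k2 = self._rhs(t + 0.5 * dt, Y + 0.5 * dt * k1, u)
                k3 = self._rhs(t + 0.5 * dt, Y + 0.5 * dt * k2, u)
                k4 = self._rhs(t + dt, Y + dt * k3, u)
                Y += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                np.maximum(Y[:, :4], 0.0, out=Y[:, :4])
                t += dt
            t = float(self.mesh[j + 1])
        return Y

    # -- public API --------------------------------------------------------
    def evaluate(self, U: np.ndarray, return_states: bool = False):
        """Integrate a batch of controls ``U`` of shape (B, n_intervals, 3).

        Returns the R0 array of shape (B,), plus the final states (B, 4)
        when ``return_states`` is true.  States are floored at zero after
        every step (shrinkage to zero is a valid corner, not an error).
        """
        U = np.ascontiguousarray(np.asarray(U, dtype=float))
        if U.ndim == 2:
            U = U[None]
        n_int = self.mesh.size - 1
        if U.shape[1:] != (n_int, 3):
            raise ValueError(f"controls must have shape (B, {n_int}, 3), got {U.shape}")
        p = self.p
        Y = np.zeros((U.shape[0], 5))
        Y[:, 0] = p.x_b0
        Y[:, 1] = p.x_r0
        Y[:, 2] = p.x_s0
        Y[:, 3] = p.x_k0
        substeps = self._substeps(U)
        if HAVE_NUMBA:
            Y = rk4_batch(Y, U, self.mesh, substeps, self._param_tuple)
        else:  # pragma: no cover - numba present in the supported environment
            Y = self._evaluate_numpy(U, substeps, Y)
        r0 = Y[:, 4].copy()
        if return_states:
            return r0, Y[:, :4].copy()
        return r0
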