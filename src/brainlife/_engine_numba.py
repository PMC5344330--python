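"""Numba-compiled core of the batched RK4 engine.

Semantics are identical to the pure-numpy path in :mod:`brainlife._engine`:
classical RK4 with steps aligned to the control mesh, state reads clamped at
zero inside stages, states floored at zero after each step, and the
empty-tissue allocation correction applied when the growth metabolic rate is
negative.  The batch dimension is the outer loop so candidates share one
step schedule exactly.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=False, fastmath=False)
def _rhs_fill(Y, U, t, P, dY):  # pragma: no cover - compiled
    (K, beta, B_b, B_r, B_s, E_b, E_r, E_s, s_k, B_k, E_k,
     mu, C, f0, alpha, gamma, phi0, phi_r, form) = P
    B = Y.shape[0]
    phi = phi0 * np.exp(-phi_r * t)
    d = alpha * (1.0 - phi)
    lm = np.exp(-mu * t) * C * f0
    for i in range(B):
        x_b = Y[i, 0] if Y[i, 0] > 0.0 else 0.0
        x_r = Y[i, 1] if Y[i, 1] > 0.0 else 0.0
        x_s = Y[i, 2] if Y[i, 2] > 0.0 else 0.0
        x_k = Y[i, 3] if Y[i, 3] > 0.0 else 0.0
        x_B = x_b + x_r + x_s
        if form == 0:
            c = 1.0 if gamma == 0.0 else x_k**gamma
        else:
            c = np.exp(gamma * x_k)
        denom = c + d
        e = 1.0 if denom == 0.0 else c / denom
        B_rest = K * e * x_B**beta if x_B > 0.0 else 0.0
        B_syn = B_rest - (x_b * B_b + x_r * B_r + x_s * B_s)
        u_b = U[i, 0]
        u_r = U[i, 1]
        u_s = U[i, 2]
        if B_syn < 0.0:
            # redistribute shrinkage shares of exhausted tissues
            dead_b = x_b <= 0.0 and u_b > 0.0
            dead_r = x_r <= 0.0 and u_r > 0.0
            dead_s = x_s <= 0.0 and u_s > 0.0
            if dead_b or dead_r or dead_s:
                ub = 0.0 if x_b <= 0.0 else u_b
                ur = 0.0 if x_r <= 0.0 else u_r
                us = 0.0 if x_s <= 0.0 else u_s
                excess = 1.0 - ub - ur - us
                w_b = x_b * E_b
                w_r = x_r * E_r
                w_s = x_s * E_s
                wsum = w_b + w_r + w_s
                if wsum > 0.0:
                    ub += excess * w_b / wsum
                    ur += excess * w_r / wsum
                    us += excess * w_s / wsum
                u_b, u_r, u_s = ub, ur, us
        dY[i, 0] = u_b * B_syn / E_b
        dY[i, 1] = u_r * B_syn / E_r
        dY[i, 2] = u_s * B_syn / E_s
        dY[i, 3] = (s_k * (x_b * B_b + u_b * B_syn) - x_k * B_k) / E_k
        dY[i, 4] = lm * x_r


@njit(cache=False, fastmath=False)
def rk4_batch(Y, U, mesh, substeps, P):  # pragma: no cover - compiled
    """Integrate all candidates; Y is modified in place and returned."""
    B = Y.shape[0]
    n_int = mesh.shape[0] - 1
    k1 = np.empty((B, 5))
    k2 = np.empty((B, 5))
    k3 = np.empty((B, 5))
    k4 = np.empty((B, 5))
    Ytmp = np.empty((B, 5))
    for j in range(n_int):
        t = mesh[j]
        m = substeps[j]
        dt = (mesh[j + 1] - mesh[j]) / m
        Uj = U[:, j, :]
        for _ in range(m):
            _rhs_fill(Y, Uj, t, P, k1)
            for i in range(B):
                for q in range(5):
                    Ytmp[i, q] = Y[i, q] + 0.5 * dt * k1[i, q]
            _rhs_fill(Ytmp, Uj, t + 0.5 * dt, P, k2)
            for i in range(B):
                for q in range(5):
                    Ytmp[i, q] = Y[i, q] + 0.5 * dt * k2[i, q]
            _rhs_fill(Ytmp, Uj, t + 0.5 * dt, P, k3)
            for i in range(B):
                for q in range(5):
                    Ytmp[i, q] = Y[i, q] + dt * k3[i, q]
            _rhs_fill(Ytmp, Uj, t + dt, P, k4)
            for i in range(B):
                for q in range(5):
                    Y[i, q] += (dt / 6.0) * (k1[i, q] + 2.0 * k2[i, q]
                                             + 2.0 * k3[i, q] + k4[i, q])
                for q in range(4):
                    if Y[i, q] < 0.0:
                        Y[i, q] = 0.0
            t += dt
    return Y
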