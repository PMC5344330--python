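"""Shared fixtures: small analytic parameter sets and the packaged benchmarks.

The "flatline" set is constructed so the newborn sits exactly at metabolic
equilibrium (resting rate equals maintenance, skill at its fixed point),
giving constant states under any allocation — handy for exact assertions.
The "toy" set is a mild, fast-to-integrate configuration used by solver
tests; it is not calibrated to any organism.
"""

import numpy as np
import pytest

from brainlife import ParameterSet, benchmark_parameters


@pytest.fixture(scope="session")
def toy_params() -> ParameterSet:
    """Small, non-stiff configuration for solver and property tests."""
    return ParameterSet(
        x_b0=0.1, x_r0=0.01, x_s0=1.0,
        K=30.0, beta=0.75,
        B_b=40.0, B_r=30.0, B_s=8.0,
        E_b=20.0, E_r=10.0, E_s=6.0,
        f0=1.0, mu=0.05, T=20.0,
        x_k0=1.0, s_k=0.5, B_k=20.0, E_k=40.0,
        phi0=0.6, phi_r=0.3,
        alpha=0.05, gamma=1.0,
        competence_form="power",
    )


@pytest.fixture(scope="session")
def flatline_params() -> ParameterSet:
    """Newborn exactly at metabolic equilibrium: B_rest == B_maint and the
    skill level at its maintenance fixed point, so every state is constant
    in time under any allocation.

    alpha = 0 makes extraction efficiency identically 1; with beta = 1 and
    K equal to the mass-weighted mean maintenance cost, B_syn = 0.
    """
    x_b0, x_r0, x_s0 = 1.0, 1.0, 1.0
    B_b = B_r = B_s = 2.0
    K = 2.0  # B_maint / x_B = 6 / 3
    s_k, B_k = 0.5, 4.0
    x_k0 = s_k * x_b0 * B_b / B_k  # skill fixed point with u_b = 0
    return ParameterSet(
        x_b0=x_b0, x_r0=x_r0, x_s0=x_s0,
        K=K, beta=1.0,
        B_b=B_b, B_r=B_r, B_s=B_s,
        E_b=5.0, E_r=5.0, E_s=5.0,
        f0=1.0, mu=0.1, T=10.0,
        x_k0=x_k0, s_k=s_k, B_k=B_k, E_k=8.0,
        phi0=0.0, phi_r=1.0,
        alpha=0.0, gamma=1.0,
        competence_form="power",
    )


@pytest.fixture(scope="session")
def power_benchmark() -> ParameterSet:
    return benchmark_parameters("power")


@pytest.fixture(scope="session")
def exponential_benchmark() -> ParameterSet:
    return benchmark_parameters("exponential")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170309)
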