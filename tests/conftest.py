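"""Shared fixtures and random-draw helpers."""

from __future__ import annotations

import numpy as np
import pytest

from essoil import (
    CompetitionKernel,
    ModelParameters,
    ThermalScenario,
    apply_temperature,
    default_config,
    phi_star,
    solve_equilibrium,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def params(config) -> ModelParameters:
    return config.parameters


@pytest.fixture(scope="session")
def kernel(config) -> CompetitionKernel:
    return config.kernel


@pytest.fixture(scope="session")
def scenario() -> ThermalScenario:
    return ThermalScenario()


@pytest.fixture(scope="session")
def tp20(params, scenario):
    return apply_temperature(params, 20.0, scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def draw_feasible_setup(rng, base: ModelParameters, *, require_stable: bool = True, max_tries: int = 200):
    """Random jittered parameter set with an existing, feasible (stable) ESS.

    Returns ``(params, tp, kernel, phi_star_value, equilibrium)``.
    """
    for _ in range(max_tries):
        jitter = lambda lo, hi: float(rng.uniform(lo, hi))  # noqa: E731
        p = ModelParameters(
            I=base.I * jitter(0.5, 2.0),
            eC=base.eC * jitter(0.5, 2.0),
            eD=base.eD * jitter(0.5, 2.0),
            v0D=base.v0D * jitter(0.5, 2.0),
            EvD=base.EvD * jitter(0.9, 1.1),
            K0D=base.K0D * jitter(0.5, 2.0),
            EKD=base.EKD * jitter(0.9, 1.1),
            v0U=base.v0U * jitter(0.5, 2.0),
            EvU=base.EvU * jitter(0.9, 1.1),
            K0U=base.K0U * jitter(0.5, 2.0),
            EKU=base.EKU * jitter(0.9, 1.1),
            dM=base.dM * jitter(0.5, 1.5),
            dZ=base.dZ * jitter(0.5, 2.0),
            gM=jitter(0.3, 0.7),
            gZ=jitter(0.3, 0.7),
            Rgas=base.Rgas,
        )
        T = jitter(5.0, 30.0)
        tp = apply_temperature(p, T)
        ratio = tp.dM_T / (tp.gM_T * tp.vmaxU)
        if ratio >= 0.9:
            continue
        kern = CompetitionKernel(c0=1.0 / (1.0 - ratio) + jitter(0.15, 1.5))
        opt = phi_star(tp, p, kern)
        if not opt.exists:
            continue
        eq = solve_equilibrium(tp, p, opt.phi_star)
        if not eq.feasible:
            continue
        if require_stable and not eq.stable:
            continue
        return p, tp, kern, opt.phi_star, eq
    raise RuntimeError("could not draw a feasible random configuration")


def random_positive_state(rng, scale=(100.0, 1.0, 10.0, 1.0)):
    from essoil import PoolState

    return PoolState(*(rng.uniform(1e-6, s) for s in scale))
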