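"""Four-pool microbe-enzyme decomposition model.

State variables are soil organic carbon (C), dissolved organic carbon (D),
microbial biomass carbon (M), and exoenzyme carbon (Z).  Decomposition of C
and microbial uptake of D both follow Michaelis-Menten kinetics; a fraction
``phi`` of assimilated carbon is allocated to exoenzyme production instead of
growth.  All rates are unit-agnostic provided the parameter set is
self-consistent (the shipped defaults use mg C per cm^3 of soil and hours).

The nontrivial steady state is obtained semi-analytically: D* in closed form
from the biomass equation, M* from whole-system mass balance, Z* from the
enzyme equation, and C* by bracketed root finding on the remaining scalar
equation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParameters",
    "TemperatureLocalParameters",
    "PoolState",
    "Equilibrium",
    "InfeasibleEquilibrium",
    "EquilibriumSolverError",
    "rhs",
    "respiration_flux",
    "equilibrium_doc",
    "solve_equilibrium",
    "jacobian",
    "jacobian_stability",
    "feasible_trait_range",
]

#: residual tolerance (model units) below which a candidate root is accepted
RESIDUAL_TOL = 1e-9
#: eigenvalue real part must be below this to count as stable
STABILITY_EIG_TOL = -1e-12


class InfeasibleEquilibrium(Exception):
    """No positive steady state exists for the requested trait/temperature."""


class EquilibriumSolverError(RuntimeError):
    """Numerical failure distinct from analytic infeasibility."""


@dataclass(frozen=True)
class ModelParameters:
    """Temperature-independent parameters of the four-pool system.

    Arrhenius pre-exponentials (``v0D``, ``K0D``, ``v0U``, ``K0U``) and
    activation energies (``EvD``, ``EKD``, ``EvU``, ``EKU``) define the
    kinetic parameters at any temperature; ``Rgas`` must be in units matching
    the activation energies (kJ mol^-1 K^-1 for the defaults).
    """

    I: float  # litter input to SOC, mass C volume^-1 time^-1
    eC: float  # SOC leaching rate, time^-1
    eD: float  # DOC leaching rate, time^-1
    v0D: float  # decomposition vmax pre-exponential
    EvD: float  # decomposition vmax activation energy
    K0D: float  # decomposition Km pre-exponential
    EKD: float  # decomposition Km activation energy
    v0U: float  # uptake vmax pre-exponential
    EvU: float  # uptake vmax activation energy
    K0U: float  # uptake Km pre-exponential
    EKU: float  # uptake Km activation energy
    dM: float  # microbial turnover rate, time^-1
    dZ: float  # enzyme deactivation rate, time^-1
    gM: float  # growth efficiency gamma_M, in (0, 1]
    gZ: float  # enzyme production efficiency gamma_Z, in (0, 1]
    Rgas: float = 0.008314

    def __post_init__(self) -> None:
        for name in ("v0D", "K0D", "v0U", "K0U", "dM", "dZ", "eD", "Rgas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.I <= 0:
            raise ValueError(f"I must be > 0, got {self.I}")
        if self.eC <= 0:
            # eC > 0 bounds SOC even when the enzyme pool collapses
            raise ValueError(f"eC must be > 0, got {self.eC}")
        for name in ("gM", "gZ"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def with_litter(self, I: float) -> "ModelParameters":
        """Copy of this parameter set with a different litter input."""
        return replace(self, I=I)


@dataclass(frozen=True)
class TemperatureLocalParameters:
    """Kinetic and physiological parameters evaluated at one temperature."""

    vmaxD: float
    KmD: float
    vmaxU: float
    KmU: float
    dM_T: float
    gM_T: float
    T: float  # degrees C, for provenance

    def __post_init__(self) -> None:
        for name in ("vmaxD", "KmD", "vmaxU", "KmU"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.gM_T <= 1.0:
            raise ValueError(f"gM_T must be in (0, 1], got {self.gM_T}")


class PoolState(NamedTuple):
    """Carbon pools (mass C per volume)."""

    C: float
    D: float
    M: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


#: stability classes assigned by :func:`jacobian_stability`
STABILITY_CLASSES = (
    "stable",
    "unstable",
    "oscillatory-stable",
    "oscillatory-unstable",
)


@dataclass(frozen=True)
class Equilibrium:
    """A solved steady state of the four-pool system."""

    state: PoolState
    phi: float
    T: float
    shr: float  # soil heterotrophic respiration flux at the steady state
    decay_rate: float  # decomposition flux divided by C*
    stability: str
    feasible: bool
    residual: float = field(default=np.nan, compare=False)

    @property
    def stable(self) -> bool:
        return self.stability in ("stable", "oscillatory-stable")


def _check_inputs(state: PoolState, phi: float) -> None:
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    arr = np.asarray(state, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"all pools must be >= 0, got {tuple(arr)}")


def _uptake(state: PoolState, tp: TemperatureLocalParameters) -> float:
    return tp.vmaxU * state.D / (tp.KmU + state.D) * state.M


def _decomposition(state: PoolState, tp: TemperatureLocalParameters) -> float:
    return tp.vmaxD * state.C / (tp.KmD + state.C) * state.Z


def rhs(
    state: PoolState,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
) -> np.ndarray:
    """Time derivatives ``(dC/dt, dD/dt, dM/dt, dZ/dt)``.

    The sum of the four components satisfies the mass-balance identity
    ``I - eC*C - eD*D - respiration_flux`` exactly (algebraic identity, see
    tests).
    """
    _check_inputs(state, phi)
    state = PoolState(*state)
    dec = _decomposition(state, tp)
    upt = _uptake(state, tp)
    dC = params.I - params.eC * state.C - dec
    dD = dec + tp.dM_T * state.M + params.dZ * state.Z - params.eD * state.D - upt
    dMdt = (1.0 - phi) * tp.gM_T * upt - tp.dM_T * state.M
    dZdt = phi * params.gZ * upt - params.dZ * state.Z
    return np.array([dC, dD, dMdt, dZdt])


def respiration_flux(
    state: PoolState,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
) -> float:
    """Carbon leaving the D pool that is assimilated neither to M nor to Z.

    Equals ``uptake * (1 - phi*gZ - (1-phi)*gM_T)``, i.e. the inefficiency
    losses of growth and enzyme production combined.
    """
    _check_inputs(state, phi)
    state = PoolState(*state)
    upt = _uptake(state, tp)
    return upt * (1.0 - phi * params.gZ - (1.0 - phi) * tp.gM_T)


def equilibrium_doc(
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
) -> float | None:
    """Closed-form steady-state DOC, or ``None`` when no positive D* exists.

    From the biomass equation: ``(1-phi)*gM_T*vmaxU*D/(KmU+D) = dM_T`` has a
    positive solution iff ``(1-phi)*gM_T*vmaxU > dM_T``.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    denom = (1.0 - phi) * tp.gM_T * tp.vmaxU - tp.dM_T
    if denom <= 0.0:
        return None
    return tp.KmU * tp.dM_T / denom


def _infeasible(phi: float, T: float) -> Equilibrium:
    return Equilibrium(
        state=PoolState(np.nan, np.nan, np.nan, np.nan),
        phi=phi,
        T=T,
        shr=np.nan,
        decay_rate=np.nan,
        stability="unstable",
        feasible=False,
    )


def _per_biomass_respiration(
    tp: TemperatureLocalParameters, params: ModelParameters, phi: float
) -> float:
    """Respiration per unit biomass at the steady-state uptake rate."""
    loss = 1.0 - phi * params.gZ - (1.0 - phi) * tp.gM_T
    return tp.dM_T * loss / ((1.0 - phi) * tp.gM_T)


def solve_equilibrium(
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
    *,
    n_scan: int = 512,
    classify: bool = True,
) -> Equilibrium:
    """Solve the nontrivial steady state at one temperature and trait value.

    Reduction: D* in closed form; M* = (I - eC*C - eD*D*)/r_u with r_u the
    per-biomass respiration; Z* proportional to M*; the SOC equation then
    becomes a scalar equation in C solved by bracketed root finding on
    ``(0, (I - eD*D*)/eC)``.  Returns ``feasible=False`` when no root exists
    (temperatures/traits too low to support microbial activity).  When
    several roots exist, the stable one is returned; with several stable
    roots, the smallest C* (with a logged warning).
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    D = equilibrium_doc(tp, params, phi)
    if D is None:
        return _infeasible(phi, tp.T)
    r_u = _per_biomass_respiration(tp, params, phi)
    if r_u <= 0.0 or phi == 0.0:
        # perfect efficiency cannot balance the SOC equation with M > 0;
        # phi = 0 leaves no enzymes, so DOC cannot sustain biomass
        return _infeasible(phi, tp.T)
    a = phi * params.gZ * tp.dM_T / ((1.0 - phi) * tp.gM_T * params.dZ)
    c_upper = (params.I - params.eD * D) / params.eC
    if c_upper <= 0.0:
        return _infeasible(phi, tp.T)

    def g(C: float) -> float:
        L = params.I - params.eC * C - params.eD * D  # = r_u * M
        return params.I - params.eC * C - tp.vmaxD * C / (tp.KmD + C) * a * L / r_u

    eps = 1e-12 * c_upper
    grid = np.linspace(eps, c_upper - eps, n_scan)
    L = params.I - params.eC * grid - params.eD * D
    gv = params.I - params.eC * grid - tp.vmaxD * grid / (tp.KmD + grid) * a * L / r_u
    sign = np.sign(gv)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots: list[float] = []
    for i in crossings:
        try:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15, maxiter=200))
        except Exception as exc:  # pragma: no cover - brentq with a bracket rarely fails
            raise EquilibriumSolverError(f"root refinement failed near C={grid[i]}") from exc
    roots.extend(grid[np.nonzero(gv == 0.0)[0]])
    if not roots:
        return _infeasible(phi, tp.T)

    candidates = []
    for C in sorted(roots):
        Lc = params.I - params.eC * C - params.eD * D
        M = Lc / r_u
        if M <= 0.0:
            continue
        Z = a * M
        state = PoolState(C, D, M, Z)
        res = float(np.max(np.abs(rhs(state, tp, params, phi))))
        if res > RESIDUAL_TOL * max(1.0, params.I / min(params.eC, tp.dM_T)):
            raise EquilibriumSolverError(
                f"equilibrium residual {res:.3e} exceeds tolerance at C={C}"
            )
        shr = respiration_flux(state, tp, params, phi)
        eq = Equilibrium(
            state=state,
            phi=phi,
            T=tp.T,
            shr=shr,
            decay_rate=(params.I - params.eC * C) / C,
            stability="stable",
            feasible=True,
            residual=res,
        )
        if classify:
            eq = replace(eq, stability=jacobian_stability(eq, tp, params, phi))
        candidates.append(eq)
    if not candidates:
        return _infeasible(phi, tp.T)
    stable = [eq for eq in candidates if eq.stable]
    if len(stable) > 1:
        logger.warning(
            "multiple stable equilibria at T=%.3g, phi=%.3g; returning smallest C*",
            tp.T,
            phi,
        )
    chosen = stable[0] if stable else candidates[0]
    return chosen


def jacobian(
    state: PoolState,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
    *,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`rhs` at ``state``."""
    x0 = np.asarray(state, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        h = rel_step * max(abs(x0[j]), 1e-8)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (rhs(PoolState(*xp), tp, params, phi) - rhs(PoolState(*xm), tp, params, phi)) / (
            xp[j] - xm[j]
        )
    return J


def jacobian_stability(
    eq: Equilibrium,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    phi: float,
    *,
    rel_step: float = 1e-6,
) -> str:
    """Classify a feasible equilibrium by the eigenvalues of its Jacobian."""
    if not eq.feasible:
        raise ValueError("stability classification requires a feasible equilibrium")
    J = jacobian(eq.state, tp, params, phi, rel_step=rel_step)
    if not np.all(np.isfinite(J)):
        raise EquilibriumSolverError("non-finite Jacobian entries")
    eigvals = np.linalg.eigvals(J)
    scale = float(np.max(np.abs(eigvals)))
    oscillatory = bool(np.any(np.abs(eigvals.imag) > 1e-9 * max(scale, 1e-30)))
    is_stable = bool(np.all(eigvals.real < STABILITY_EIG_TOL))
    if oscillatory:
        return "oscillatory-stable" if is_stable else "oscillatory-unstable"
    return "stable" if is_stable else "unstable"


def feasible_trait_range(
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    *,
    tol: float = 1e-6,
    n_scan: int = 64,
) -> tuple[float, float] | None:
    """Trait interval supporting a feasible, stable equilibrium.

    ``phi_max = 1 - dM_T/(gM_T*vmaxU)`` is the closed-form positivity bound
    on D*; ``phi_min`` is located by bisection on the feasibility predicate.
    Returns ``None`` when the range is empty.
    """
    phi_max = 1.0 - tp.dM_T / (tp.gM_T * tp.vmaxU)
    if phi_max <= 0.0:
        return None

    def ok(phi: float) -> bool:
        if not 0.0 < phi < 1.0:
            return False
        eq = solve_equilibrium(tp, params, phi)
        return eq.feasible and eq.stable

    probes = np.linspace(phi_max / n_scan, phi_max * (1 - 1e-9), n_scan)
    feas = [p for p in probes if ok(p)]
    if not feas:
        return None
    hi = feas[0]
    lo = 0.0
    while hi - lo > tol * max(phi_max, 1e-3):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return (hi, phi_max)
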