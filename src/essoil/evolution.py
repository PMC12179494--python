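"""Adaptive dynamics of the exoenzyme allocation trait.

A rare mutant with allocation ``phi_mut`` grows in the environment set by a
resident ``phi_res`` at its ecological equilibrium.  Local competition gives
stronger producers private access to extra DOC through a kernel ``c`` of the
trait difference, with ``c(0) = 0``, the sign of its argument, and slope
``c0 = c'(0) > 0``.  The selection gradient has a closed form whose unique
zero,

    ``phi* = 1 - dM_T/(gM_T * vmaxU) - 1/c0``,

is convergent whenever it exists and uninvadable when ``c''(0) < 2*c0**2``.
A pairwise-invasibility matrix is provided as a brute-force check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, TemperatureLocalParameters, equilibrium_doc

__all__ = [
    "CompetitionKernel",
    "TraitOptimum",
    "competition_kernel_value",
    "invasion_fitness",
    "selection_gradient",
    "phi_star",
    "pairwise_invasibility",
    "classify_singularity",
]

KERNEL_SHAPES = ("arctan", "linear")


@dataclass(frozen=True)
class CompetitionKernel:
    """Competitive-advantage function of the mutant-resident trait difference.

    Shapes:

    ``arctan`` (default)
        ``c(z) = (2/pi) * arctan(c0 * (pi/2) * z)`` -- smooth, odd, bounded
        in (-1, 1) so mutant DOC access stays positive, with ``c'(0) = c0``
        and ``c''(0) = 0`` (hence always satisfying the uninvadability
        condition ``c''(0) < 2*c0**2``).
    ``linear``
        ``c(z) = c0 * z``; valid only while ``1 + c > 0``.
    """

    c0: float
    shape: str = "arctan"

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")
        if self.shape not in KERNEL_SHAPES:
            raise ValueError(f"unknown kernel shape {self.shape!r}; expected one of {KERNEL_SHAPES}")

    @property
    def curvature0(self) -> float:
        """``c''(0)``; zero for both shipped shapes."""
        return 0.0

    @property
    def uninvadable(self) -> bool:
        return self.curvature0 < 2.0 * self.c0**2

    def __call__(self, dphi):
        z = np.asarray(dphi, dtype=float)
        if self.shape == "arctan":
            out = (2.0 / math.pi) * np.arctan(self.c0 * (math.pi / 2.0) * z)
        else:
            out = self.c0 * z
        return out if out.ndim else float(out)


def competition_kernel_value(dphi, kernel: CompetitionKernel):
    """Kernel value ``c(dphi)``; rejects arguments with ``1 + c <= 0``."""
    val = kernel(dphi)
    if np.any(np.asarray(val) <= -1.0):
        raise ValueError("kernel value <= -1 would give the mutant nonpositive DOC access")
    return val


@dataclass(frozen=True)
class TraitOptimum:
    """Existence and value of the evolutionarily stable allocation."""

    phi_star: float | None
    exists: bool
    reason: str  # one of: ok, growth_infeasible, c0_too_small
    uninvadable: bool
    convergent: bool


def _resident_doc(
    phi_res: float, tp: TemperatureLocalParameters, params: ModelParameters
) -> float:
    D = equilibrium_doc(tp, params, phi_res)
    if D is None:
        raise ValueError(
            f"resident trait phi_res={phi_res} has no feasible equilibrium DOC "
            f"at T={tp.T} C"
        )
    return D


def invasion_fitness(
    phi_mut,
    phi_res: float,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    kernel: CompetitionKernel,
):
    """Per-capita growth rate of a rare mutant against an equilibrium resident.

    ``s = (1-phi_mut)*gM_T*vmaxU*Dt/(KmU+Dt) - dM_T`` with
    ``Dt = (1 + c(phi_mut - phi_res)) * D*_res``; identically zero on the
    diagonal ``phi_mut == phi_res``.
    """
    D = _resident_doc(phi_res, tp, params)
    phi_mut = np.asarray(phi_mut, dtype=float)
    if np.any(phi_mut < 0) or np.any(phi_mut >= 1):
        raise ValueError("phi_mut must be in [0, 1)")
    Dt = (1.0 + competition_kernel_value(phi_mut - phi_res, kernel)) * D
    s = (1.0 - phi_mut) * tp.gM_T * tp.vmaxU * Dt / (tp.KmU + Dt) - tp.dM_T
    return s if s.ndim else float(s)


def selection_gradient(
    phi: float,
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    kernel: CompetitionKernel,
) -> float:
    """Derivative of invasion fitness in the mutant trait at the resident.

    Closed form:
    ``dM_T * ( c0 * (1 - dM_T/((1-phi)*gM_T*vmaxU)) - 1/(1-phi) )``.
    """
    _resident_doc(phi, tp, params)  # validates feasibility
    u = tp.dM_T / ((1.0 - phi) * tp.gM_T * tp.vmaxU)
    return tp.dM_T * (kernel.c0 * (1.0 - u) - 1.0 / (1.0 - phi))


def phi_star(
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    kernel: CompetitionKernel,
) -> TraitOptimum:
    """Unique evolutionary singularity ``1 - dM_T/(gM_T*vmaxU) - 1/c0``.

    Exists (strictly positive) iff ``dM_T/(gM_T*vmaxU) < 1`` and
    ``c0 > 1/(1 - dM_T/(gM_T*vmaxU))``; convergent whenever it exists.
    """
    ratio = tp.dM_T / (tp.gM_T * tp.vmaxU)
    if ratio >= 1.0:
        return TraitOptimum(None, False, "growth_infeasible", kernel.uninvadable, False)
    if kernel.c0 <= 1.0 / (1.0 - ratio):
        return TraitOptimum(None, False, "c0_too_small", kernel.uninvadable, False)
    value = 1.0 - ratio - 1.0 / kernel.c0
    return TraitOptimum(value, True, "ok", kernel.uninvadable, True)


def pairwise_invasibility(
    tp: TemperatureLocalParameters,
    params: ModelParameters,
    kernel: CompetitionKernel,
    grid_n: int = 101,
    phi_range: tuple[float, float] | None = None,
    snap_to: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sign matrix of invasion fitness over a (resident, mutant) trait grid.

    Returns ``(phi_grid, S)`` where ``S[i, j] = sign(s(phi_mut=grid[j],
    phi_res=grid[i]))``; rows index the resident.  The grid spans the
    closed-form trait range with positive resident DOC unless ``phi_range``
    is given.  ``snap_to`` moves the nearest grid node onto an exact trait
    value (typically the singularity, so its row/column are evaluated at the
    singularity itself rather than a neighbouring node).
    """
    if grid_n < 20:
        raise ValueError(f"grid_n must be >= 20, got {grid_n}")
    if phi_range is None:
        phi_max = 1.0 - tp.dM_T / (tp.gM_T * tp.vmaxU)
        if phi_max <= 0:
            raise ValueError("no resident trait has a feasible equilibrium DOC")
        lo, hi = 1e-6 * phi_max, phi_max * (1.0 - 1e-6)
    else:
        lo, hi = phi_range
    grid = np.linspace(lo, hi, grid_n)
    if snap_to is not None:
        if not lo <= snap_to <= hi:
            raise ValueError(f"snap_to={snap_to} outside grid range ({lo}, {hi})")
        grid[int(np.argmin(np.abs(grid - snap_to)))] = snap_to
    S = np.empty((grid_n, grid_n))
    for i, pr in enumerate(grid):
        S[i, :] = np.sign(invasion_fitness(grid, pr, tp, params, kernel))
        S[i, i] = 0.0  # diagonal is analytically zero
    return grid, S


def classify_singularity(grid: np.ndarray, S: np.ndarray, phi_s: float) -> dict[str, bool]:
    """Sign-structure classification of a singularity from a PIP matrix.

    Uninvadable: no mutant invades the resident at the singularity (the
    resident row is nonpositive).  Convergent: for residents below the
    singularity the mutant one node closer invades, and symmetrically above.
    """
    j = int(np.argmin(np.abs(grid - phi_s)))
    mutants_vs_singularity = S[j, :]
    ess = bool(np.all(mutants_vs_singularity[np.arange(len(grid)) != j] <= 0))
    below = np.nonzero(grid < phi_s)[0]
    above = np.nonzero(grid > phi_s)[0]
    conv_below = bool(
        np.all([S[i, i + 1] > 0 for i in below if i + 1 < len(grid) and grid[i + 1] < phi_s])
    )
    conv_above = bool(np.all([S[i, i - 1] > 0 for i in above if i - 1 >= 0 and grid[i - 1] > phi_s]))
    return {"ess": ess, "convergent": conv_below and conv_above}
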