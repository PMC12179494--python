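"""Gridded decadal steady-state projections with and without trait optimization.

Every cell is initialized at its 2010 equilibrium with the allocation trait
optimized to the local 2010 temperature.  Each subsequent decade is solved at
that decade's temperature (and litter input, when supplied) either with the
trait frozen at its 2010 value (``fixed`` mode) or re-optimized to the
decade's temperature (``evolving`` mode).  Cells whose optimum does not exist
or whose equilibrium is infeasible in 2010 are inactive and excluded from
aggregates; cells that fail in a later decade are dropped from that run's
aggregates (with a logged count) so the global series stays comparable
across decades.

Stocks are per-volume densities (SOC + microbial biomass); global aggregates
multiply by the cell area weight and a reference soil depth, so absolute
totals depend on those conventions while ratios between runs do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolution import CompetitionKernel, phi_star
from .model import ModelParameters, solve_equilibrium
from .thermal import BiomeKineticsTable, ThermalScenario, apply_temperature

logger = logging.getLogger(__name__)

__all__ = [
    "ForcingGrid",
    "ProjectionResult",
    "initialize_cells",
    "run_projection",
    "optimization_effect",
    "MODES",
]

MODES = ("fixed", "evolving")

#: warming below this (degrees C) masks the per-unit-warming effect
WARMING_MASK_THRESHOLD = 0.1


@dataclass(frozen=True)
class ForcingGrid:
    """Per-cell, per-decade forcing.

    ``cells`` must have columns ``cell, lat, lon, weight`` (and optionally
    ``biome``); ``T`` is ``(n_cells, n_decades)`` in degrees C; ``litter``
    optionally overrides the litter input with the same shape.
    """

    cells: pd.DataFrame
    decades: np.ndarray
    T: np.ndarray
    litter: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"cell", "lat", "lon", "weight"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table is missing columns {sorted(missing)}")
        object.__setattr__(self, "decades", np.asarray(self.decades, dtype=int))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        if len(self.decades) < 1:
            raise ValueError("at least one decade is required")
        if np.any(np.diff(self.decades) <= 0):
            raise ValueError("decades must be strictly increasing")
        n_cells, n_dec = self.T.shape
        if n_cells != len(self.cells) or n_dec != len(self.decades):
            raise ValueError(
                f"T has shape {self.T.shape}, expected ({len(self.cells)}, {len(self.decades)})"
            )
        if np.any(~np.isfinite(self.T)):
            raise ValueError("temperature field contains missing values")
        if np.any(self.cells["weight"].to_numpy() <= 0):
            raise ValueError("area weights must be > 0")
        if self.cells["cell"].duplicated().any():
            raise ValueError("duplicate cell ids")
        if self.litter is not None:
            litter = np.asarray(self.litter, dtype=float)
            object.__setattr__(self, "litter", litter)
            if litter.shape != self.T.shape:
                raise ValueError(f"litter has shape {litter.shape}, expected {self.T.shape}")
            if np.any(~(litter > 0)):
                raise ValueError("litter inputs must be > 0")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class ProjectionResult:
    """Per-cell and global outcome of one projection run."""

    cell_table: pd.DataFrame  # cell, decade, T, phi, C, D, M, stock, shr, active
    global_series: pd.DataFrame  # decade, total_stock, total_shr, n_active
    metadata: dict = field(default_factory=dict)

    @property
    def mode(self) -> str:
        return self.metadata["mode"]

    def cumulative_stock_change(self) -> float:
        """Global stock change from the first to the last decade."""
        s = self.global_series.sort_values("decade")["total_stock"].to_numpy()
        return float(s[-1] - s[0])


def _cell_params(
    params: ModelParameters,
    row: pd.Series,
    table: BiomeKineticsTable | None,
) -> ModelParameters:
    if table is not None and "biome" in row.index and not pd.isna(row["biome"]):
        return table.apply(params, int(row["biome"]))
    return params


def initialize_cells(
    forcing: ForcingGrid,
    params: ModelParameters,
    kernel: CompetitionKernel,
    scenario: ThermalScenario | None = None,
    table: BiomeKineticsTable | None = None,
) -> pd.DataFrame:
    """Per-cell first-decade optimum and equilibrium.

    Returns one row per cell with ``phi0``, ``active`` and the first-decade
    pools; both projection modes share this initialization, so first-decade
    stocks are identical between them.
    """
    if forcing.n_cells == 0:
        raise ValueError("empty forcing grid")
    rows = []
    for i, (_, cell) in enumerate(forcing.cells.iterrows()):
        p = _cell_params(params, cell, table)
        if forcing.litter is not None:
            p = p.with_litter(forcing.litter[i, 0])
        T0 = forcing.T[i, 0]
        tp = apply_temperature(p, T0, scenario)
        opt = phi_star(tp, p, kernel)
        row = {
            "cell": cell["cell"],
            "lat": cell["lat"],
            "lon": cell["lon"],
            "weight": cell["weight"],
            "T0": T0,
            "phi0": np.nan,
            "active": False,
            "C0": np.nan,
            "D0": np.nan,
            "M0": np.nan,
            "stock0": np.nan,
            "shr0": np.nan,
        }
        if opt.exists:
            eq = solve_equilibrium(tp, p, opt.phi_star)
            if eq.feasible:
                row.update(
                    phi0=opt.phi_star,
                    active=True,
                    C0=eq.state.C,
                    D0=eq.state.D,
                    M0=eq.state.M,
                    stock0=eq.state.C + eq.state.M,
                    shr0=eq.shr,
                )
        rows.append(row)
    init = pd.DataFrame(rows)
    logger.info(
        "initialized %d cells: %d active, %d inactive",
        len(init),
        int(init["active"].sum()),
        int((~init["active"]).sum()),
    )
    return init


def run_projection(
    forcing: ForcingGrid,
    params: ModelParameters,
    kernel: CompetitionKernel,
    scenario: ThermalScenario | None = None,
    mode: str = "evolving",
    *,
    depth: float = 1.0,
    table: BiomeKineticsTable | None = None,
    init: pd.DataFrame | None = None,
) -> ProjectionResult:
    """Run one projection mode over all decades of the forcing.

    ``depth`` is the reference soil depth factor applied to per-volume stock
    densities when aggregating (default 1, i.e. totals per unit depth).
    ``init`` may carry a shared initialization from :func:`initialize_cells`
    to avoid recomputing it for paired runs.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if init is None:
        init = initialize_cells(forcing, params, kernel, scenario, table)
    records = []
    failed_cells: set = set()
    for i, (_, cell) in enumerate(init.iterrows()):
        if not cell["active"]:
            continue
        base = _cell_params(params, forcing.cells.iloc[i], table)
        for j, decade in enumerate(forcing.decades):
            p = base.with_litter(forcing.litter[i, j]) if forcing.litter is not None else base
            T = forcing.T[i, j]
            tp = apply_temperature(p, T, scenario)
            if j == 0:
                # shared initialization: reuse the first-decade equilibrium
                records.append(
                    {
                        "cell": cell["cell"],
                        "decade": int(decade),
                        "T": T,
                        "phi": cell["phi0"],
                        "C": cell["C0"],
                        "D": cell["D0"],
                        "M": cell["M0"],
                        "stock": cell["stock0"],
                        "shr": cell["shr0"],
                        "active": True,
                    }
                )
                continue
            if mode == "fixed":
                phi = cell["phi0"]
            else:
                opt = phi_star(tp, p, kernel)
                if not opt.exists:
                    failed_cells.add(cell["cell"])
                    records.append(
                        {
                            "cell": cell["cell"],
                            "decade": int(decade),
                            "T": T,
                            "phi": np.nan,
                            "C": np.nan,
                            "D": np.nan,
                            "M": np.nan,
                            "stock": np.nan,
                            "shr": np.nan,
                            "active": False,
                        }
                    )
                    continue
                phi = min(opt.phi_star, 1.0 - 1e-12)
            eq = solve_equilibrium(tp, p, phi)
            ok = eq.feasible
            if not ok:
                failed_cells.add(cell["cell"])
            records.append(
                {
                    "cell": cell["cell"],
                    "decade": int(decade),
                    "T": T,
                    "phi": phi if ok else np.nan,
                    "C": eq.state.C if ok else np.nan,
                    "D": eq.state.D if ok else np.nan,
                    "M": eq.state.M if ok else np.nan,
                    "stock": eq.state.C + eq.state.M if ok else np.nan,
                    "shr": eq.shr if ok else np.nan,
                    "active": ok,
                }
            )
    cell_table = pd.DataFrame(
        records,
        columns=["cell", "decade", "T", "phi", "C", "D", "M", "stock", "shr", "active"],
    )
    if failed_cells:
        logger.warning(
            "%d cells failed after initialization and are excluded from aggregates",
            len(failed_cells),
        )
    included = set(init.loc[init["active"], "cell"]) - failed_cells
    weights = init.set_index("cell")["weight"]
    agg_rows = []
    for decade in forcing.decades:
        sub = cell_table[(cell_table["decade"] == decade) & cell_table["cell"].isin(included)]
        w = weights.loc[sub["cell"]].to_numpy()
        agg_rows.append(
            {
                "decade": int(decade),
                "total_stock": float(np.sum(sub["stock"].to_numpy() * w)) * depth,
                "total_shr": float(np.sum(sub["shr"].to_numpy() * w)) * depth,
                "n_active": int(len(sub)),
            }
        )
        logger.info(
            "decade %d: %d aggregated cells (%d active at init, %d failed later)",
            decade,
            len(sub),
            int(init["active"].sum()),
            len(failed_cells),
        )
    metadata = {
        "mode": mode,
        "scenario": (scenario or ThermalScenario()).kind,
        "c0": kernel.c0,
        "depth": depth,
        "n_cells": forcing.n_cells,
        "n_included": len(included),
        "failed_cells": sorted(failed_cells),
    }
    return ProjectionResult(cell_table=cell_table, global_series=pd.DataFrame(agg_rows), metadata=metadata)


def optimization_effect(
    evo: ProjectionResult,
    fixed: ProjectionResult,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell and global stock differences between paired runs.

    Returns ``(cell_deltas, summary)``: per cell and decade the stock
    difference (evolving minus fixed) and its per-unit-local-warming variant
    (masked where warming since the first decade is below 0.1 C); the
    summary holds the difference of cumulative first-to-last-decade global
    stock changes.  Cells inactive in either run are absent.
    """
    for key in ("scenario", "c0", "depth"):
        if evo.metadata.get(key) != fixed.metadata.get(key):
            raise ValueError(
                f"runs differ in {key}: {evo.metadata.get(key)!r} vs {fixed.metadata.get(key)!r}"
            )
    a = evo.cell_table[evo.cell_table["active"]]
    b = fixed.cell_table[fixed.cell_table["active"]]
    if set(a["decade"]) != set(b["decade"]):
        raise ValueError("runs cover different decades")
    merged = a.merge(b, on=["cell", "decade"], suffixes=("_evo", "_fixed"))
    # keep only cells present (active) in both runs across all decades
    n_dec = merged["decade"].nunique()
    full = merged.groupby("cell")["decade"].transform("count") == n_dec
    merged = merged[full].copy()
    if not np.allclose(merged["T_evo"], merged["T_fixed"]):
        raise ValueError("runs were driven by different temperature forcing")
    first = merged["decade"].min()
    t0 = merged[merged["decade"] == first].set_index("cell")["T_evo"]
    merged["warming"] = merged["T_evo"].to_numpy() - t0.loc[merged["cell"]].to_numpy()
    merged["d_stock"] = merged["stock_evo"] - merged["stock_fixed"]
    merged["d_shr"] = merged["shr_evo"] - merged["shr_fixed"]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_warm = merged["d_stock"] / merged["warming"]
    per_warm[merged["warming"] < WARMING_MASK_THRESHOLD] = np.nan
    merged["d_stock_per_warming"] = per_warm
    cell_deltas = merged[
        ["cell", "decade", "T_evo", "warming", "d_stock", "d_shr", "d_stock_per_warming"]
    ].rename(columns={"T_evo": "T"})
    summary = {
        "cumulative_effect": evo.cumulative_stock_change() - fixed.cumulative_stock_change(),
        "evo_change": evo.cumulative_stock_change(),
        "fixed_change": fixed.cumulative_stock_change(),
        "n_cells": int(merged["cell"].nunique()),
    }
    return cell_deltas, summary
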