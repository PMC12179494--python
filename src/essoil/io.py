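"""Readers and writers for forcing grids and projection results.

Forcing grids round-trip through NetCDF (classic format via the scipy
backend, dimensions ``cell`` and ``decade``) and through a long-format CSV
(one row per cell and decade).  Projection results are written as a tidy
per-cell CSV, a global time-series CSV, a NetCDF mirror, and a JSON metadata
sidecar carrying the package version, the configuration hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .projection import ForcingGrid, ProjectionResult

__all__ = [
    "write_forcing",
    "read_forcing",
    "write_results",
    "read_global_series",
    "config_hash",
]

_NC_ENGINE = "scipy"  # classic NetCDF3; no compiled netCDF4 dependency


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _forcing_to_dataset(grid: ForcingGrid) -> xr.Dataset:
    data = {
        "T": (("cell", "decade"), grid.T),
    }
    if grid.litter is not None:
        data["litter"] = (("cell", "decade"), grid.litter)
    coords = {
        "cell": grid.cells["cell"].to_numpy(),
        "decade": grid.decades,
        "lat": ("cell", grid.cells["lat"].to_numpy()),
        "lon": ("cell", grid.cells["lon"].to_numpy()),
        "weight": ("cell", grid.cells["weight"].to_numpy()),
    }
    if "biome" in grid.cells.columns:
        coords["biome"] = ("cell", grid.cells["biome"].to_numpy())
    return xr.Dataset(data, coords=coords)


def write_forcing(grid: ForcingGrid, path: str | Path) -> Path:
    """Write a forcing grid; the format follows the file extension (.nc/.csv)."""
    path = Path(path)
    if path.suffix == ".nc":
        _forcing_to_dataset(grid).to_netcdf(path, engine=_NC_ENGINE)
    elif path.suffix == ".csv":
        rows = []
        for j, decade in enumerate(grid.decades):
            frame = grid.cells.copy()
            frame["decade"] = int(decade)
            frame["T"] = grid.T[:, j]
            if grid.litter is not None:
                frame["litter"] = grid.litter[:, j]
            rows.append(frame)
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported forcing format {path.suffix!r} (use .nc or .csv)")
    return path


def read_forcing(path: str | Path) -> ForcingGrid:
    """Read a forcing grid written by :func:`write_forcing`."""
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
            ds = ds.load()
        cells = pd.DataFrame(
            {
                "cell": ds["cell"].values,
                "lat": ds["lat"].values,
                "lon": ds["lon"].values,
                "weight": ds["weight"].values,
            }
        )
        if "biome" in ds.coords:
            cells["biome"] = ds["biome"].values
        litter = ds["litter"].values if "litter" in ds else None
        return ForcingGrid(cells=cells, decades=ds["decade"].values, T=ds["T"].values, litter=litter)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"cell", "lat", "lon", "weight", "decade", "T"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"forcing CSV is missing columns {sorted(missing)}")
        decades = np.sort(df["decade"].unique())
        pivot = df.pivot(index="cell", columns="decade", values="T").sort_index()
        cell_cols = ["cell", "lat", "lon", "weight"] + (["biome"] if "biome" in df.columns else [])
        cells = df[cell_cols].drop_duplicates("cell").sort_values("cell").reset_index(drop=True)
        litter = None
        if "litter" in df.columns and df["litter"].notna().all():
            litter = df.pivot(index="cell", columns="decade", values="litter").sort_index().to_numpy()
        return ForcingGrid(cells=cells, decades=decades, T=pivot.to_numpy(), litter=litter)
    raise ValueError(f"unsupported forcing format {path.suffix!r} (use .nc or .csv)")


def write_results(
    result: ProjectionResult | pd.DataFrame,
    out_dir: str | Path,
    *,
    basename: str | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a projection result (or a plain comparison table) to ``out_dir``.

    Returns the mapping of artifact names to paths.  CSV column order is
    stable across runs; the metadata sidecar carries the configuration hash,
    package version, seed, and the run metadata (including the ``c0``
    actually used).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "package_version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    if isinstance(result, pd.DataFrame):
        name = basename or "table"
        table_path = out_dir / f"{name}.csv"
        result.to_csv(table_path, index=False)
        meta_path = out_dir / f"{name}.meta.json"
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        return {"table": table_path, "metadata": meta_path}

    name = basename or f"projection_{result.mode}"
    meta["run"] = result.metadata
    paths = {
        "cells": out_dir / f"{name}_cells.csv",
        "global": out_dir / f"{name}_global.csv",
        "netcdf": out_dir / f"{name}.nc",
        "metadata": out_dir / f"{name}.meta.json",
    }
    result.cell_table.to_csv(paths["cells"], index=False)
    result.global_series.to_csv(paths["global"], index=False)
    active = result.cell_table[result.cell_table["active"]]
    ds = xr.Dataset.from_dataframe(active.set_index(["cell", "decade"]).drop(columns=["active"]))
    # note: the scipy NetCDF backend reserves the global attribute name
    # "mode" for the file handle, so the run mode is stored as "run_mode"
    ds.attrs.update({k: str(v) for k, v in meta.items() if k != "run"})
    ds.attrs["run_mode"] = result.metadata["mode"]
    ds.attrs["c0"] = result.metadata["c0"]
    ds.to_netcdf(paths["netcdf"], engine=_NC_ENGINE)
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return paths


def read_global_series(path: str | Path) -> pd.DataFrame:
    """Read a global time-series CSV written by :func:`write_results`."""
    return pd.read_csv(path, float_precision="round_trip")
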