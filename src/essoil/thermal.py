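"""Temperature dependence of kinetic and physiological parameters.

All four Michaelis-Menten parameters follow an Arrhenius law with a 273 K
offset.  Three scenarios control the remaining physiology:

``kinetics_only``
    turnover and growth efficiency are temperature-independent (baseline);
``mortality_arrhenius``
    microbial turnover follows its own Arrhenius law with activation energy
    ``EdM`` (anchored so that it matches the base turnover at ``Tref``);
``cue_linear``
    growth efficiency declines linearly with temperature at slope ``m`` per
    degree C, clipped below at ``gM_floor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .model import ModelParameters, TemperatureLocalParameters

__all__ = [
    "ThermalScenario",
    "BiomeKineticsTable",
    "arrhenius",
    "apply_temperature",
    "load_biome_kinetics",
    "assign_biome",
    "SCENARIO_KINDS",
]

SCENARIO_KINDS = ("kinetics_only", "mortality_arrhenius", "cue_linear")


@dataclass(frozen=True)
class ThermalScenario:
    """Temperature-sensitivity scenario for turnover and growth efficiency.

    ``d0M`` may be left ``None`` under ``mortality_arrhenius``, in which case
    it is anchored so the temperature-dependent turnover equals the base
    turnover at ``Tref``.
    """

    kind: str = "kinetics_only"
    EdM: float | None = None  # turnover activation energy (mortality_arrhenius)
    d0M: float | None = None  # turnover pre-exponential (mortality_arrhenius)
    m: float | None = None  # CUE slope per degree C (cue_linear)
    Tref: float = 20.0  # reference temperature, degrees C
    gM_floor: float = 0.01  # lower clip for gM under cue_linear

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}")
        if not 0.0 < self.gM_floor < 1.0:
            raise ValueError(f"gM_floor must be in (0, 1), got {self.gM_floor}")
        if self.kind == "mortality_arrhenius" and self.EdM is None:
            raise ValueError("mortality_arrhenius scenario requires EdM")
        if self.kind == "cue_linear" and self.m is None:
            raise ValueError("cue_linear scenario requires slope m")


def arrhenius(v0: float, E: float, T: float, Rgas: float) -> float:
    """``v0 * exp(-E / (Rgas * (T + 273)))``; increasing in T for E > 0."""
    if v0 < 0:
        raise ValueError(f"pre-exponential must be >= 0, got {v0}")
    TK = T + 273.0
    if TK <= 0:
        raise ValueError(f"temperature {T} C is at or below absolute zero")
    return v0 * math.exp(-E / (Rgas * TK))


class BiomeKineticsTable:
    """Per-biome decomposition kinetics (biome ids 1-5)."""

    REQUIRED = ("v0D", "EvD", "K0D", "EKD")
    OPTIONAL = ("v0U", "EvU", "K0U", "EKU")

    def __init__(self, entries: dict[int, dict[str, float]]):
        if sorted(entries) != [1, 2, 3, 4, 5]:
            raise ValueError(f"biome table must have exactly biomes 1-5, got {sorted(entries)}")
        for biome, row in entries.items():
            for key in self.REQUIRED:
                if key not in row:
                    raise ValueError(f"biome {biome} is missing {key}")
            for key, val in row.items():
                if key not in self.REQUIRED + self.OPTIONAL:
                    raise ValueError(f"biome {biome} has unknown column {key}")
                if val <= 0:
                    raise ValueError(f"biome {biome} has nonpositive {key} = {val}")
        self._entries = {int(b): dict(row) for b, row in entries.items()}

    def __getitem__(self, biome: int) -> dict[str, float]:
        return self._entries[int(biome)]

    def apply(self, params: ModelParameters, biome: int) -> ModelParameters:
        """Parameter set with this biome's kinetics substituted in."""
        from dataclasses import replace

        return replace(params, **self[biome])

    @property
    def entries(self) -> dict[int, dict[str, float]]:
        return {b: dict(r) for b, r in self._entries.items()}


def load_biome_kinetics(path=None) -> BiomeKineticsTable:
    """Read a biome kinetics CSV (columns: biome, v0D, EvD, K0D, EKD, ...).

    Without a path, the table shipped with the package is used.
    """
    if path is None:
        with resources.files("essoil.data").joinpath("biome_kinetics.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if "biome" not in df.columns:
        raise ValueError("biome kinetics table needs a 'biome' column")
    entries = {
        int(row["biome"]): {k: float(row[k]) for k in df.columns if k != "biome"}
        for _, row in df.iterrows()
    }
    return BiomeKineticsTable(entries)


#: mean-annual-temperature upper bounds (degrees C) mapping MAT to biomes 5..1
#: (tundra/boreal, cold conifer, temperate deciduous, temperate grassland,
#: tropical).  A documented convenience only; real biome maps should be
#: supplied via forcing metadata.
_BIOME_MAT_BOUNDS = ((-2.0, 5), (5.0, 4), (12.0, 3), (19.0, 2), (float("inf"), 1))


def assign_biome(mat: float) -> int:
    """Map a mean annual temperature to a biome id 1-5 by fixed thresholds."""
    for bound, biome in _BIOME_MAT_BOUNDS:
        if mat <= bound:
            return biome
    raise AssertionError("unreachable")


def apply_temperature(
    params: ModelParameters,
    T: float,
    scenario: ThermalScenario | None = None,
    biome: int | None = None,
    table: BiomeKineticsTable | None = None,
) -> TemperatureLocalParameters:
    """Evaluate the temperature-local parameter set at ``T`` degrees C."""
    if scenario is None:
        scenario = ThermalScenario()
    if biome is not None:
        if table is None:
            raise ValueError(f"biome id {biome} given without a kinetics table")
        params = table.apply(params, biome)
    R = params.Rgas
    vmaxD = arrhenius(params.v0D, params.EvD, T, R)
    KmD = arrhenius(params.K0D, params.EKD, T, R)
    vmaxU = arrhenius(params.v0U, params.EvU, T, R)
    KmU = arrhenius(params.K0U, params.EKU, T, R)

    dM_T = params.dM
    gM_T = params.gM
    if scenario.kind == "mortality_arrhenius":
        d0M = scenario.d0M
        if d0M is None:
            # anchor so that dM_T(Tref) == params.dM
            d0M = params.dM * math.exp(scenario.EdM / (R * (scenario.Tref + 273.0)))
        dM_T = arrhenius(d0M, scenario.EdM, T, R)
    elif scenario.kind == "cue_linear":
        gM_T = min(max(params.gM + scenario.m * (T - scenario.Tref), scenario.gM_floor), 1.0)

    return TemperatureLocalParameters(
        vmaxD=vmaxD, KmD=KmD, vmaxU=vmaxU, KmU=KmU, dM_T=dM_T, gM_T=gM_T, T=T
    )
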