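# essoil

Microbe-enzyme soil carbon dynamics with an **e**volutionarily **s**table
**s**trategy for exoenzyme allocation, a Q10 reference model, and gridded
decadal warming projections.

## What it does

The core is a four-pool decomposition system — soil organic carbon (C),
dissolved organic carbon (D), microbial biomass (M), and exoenzyme carbon
(Z). Decomposition and uptake follow Michaelis–Menten kinetics whose
parameters obey Arrhenius temperature laws; a trait `phi` sets the fraction
of assimilated carbon that microbes divert from growth into exoenzyme
production. On top of the ecological model, an adaptive-dynamics layer
computes invasion fitness, the selection gradient, and the evolutionarily
stable allocation

```
phi* = 1 - dM/(gM * vmaxU(T)) - 1/c0
```

where `c0` is the local competitive advantage accruing to stronger enzyme
producers. Because `vmaxU` rises with temperature, `phi*` rises with
warming — optimized microbial communities decompose faster in a warmer
world, amplifying soil carbon loss relative to a model with a frozen trait.

Modules:

- `essoil.model` — the ODE right-hand side, respiration flux, semi-analytic
  steady-state solver, Jacobian stability classification, feasible trait
  range.
- `essoil.thermal` — Arrhenius kinetics; baseline and alternative
  temperature-sensitivity scenarios (temperature-dependent mortality, linear
  CUE decline); per-biome kinetics tables.
- `essoil.evolution` — competition kernel, invasion fitness, selection
  gradient, closed-form ESS with existence conditions, brute-force
  pairwise-invasibility matrices.
- `essoil.q10` — first-order Q10 decay benchmark calibrated to the
  mechanistic equilibrium decay rate at 10 °C.
- `essoil.projection` — gridded decadal steady-state projections in `fixed`
  and `evolving` trait modes, plus the per-cell and global optimization
  effect.
- `essoil.forcing` — synthetic decadal forcing grids with a latitudinal MAT
  gradient and polar-amplified warming (no climate-data download needed).
- `essoil.io` / `essoil.config` / `essoil.cli` — NetCDF/CSV readers and
  writers, validated YAML configuration, command-line entry points.

## CLI

All subcommands accept `--config cfg.yaml` (defaults ship with the package)
and `--set key=value` overrides, and are bit-reproducible for a given
configuration and seed.

```bash
essoil steady-state --temp 20                       # solve one equilibrium (at the ESS)
essoil ess --tmin 0 --tmax 30 --steps 31            # ESS allocation vs temperature
essoil pip --temp 20 --grid-n 101 --out pip.csv     # pairwise-invasibility sign matrix
essoil compare-q10 --tmin 2 --tmax 30 --out q10.csv # mechanistic vs Q10 benchmark
essoil synth-forcing --n-lat 18 --n-lon 10 --seed 1 --out forcing.nc
essoil project --forcing forcing.nc --mode both --c0 1.17 --out results/
```

`project` writes per-cell and global CSV time series, a NetCDF mirror, a
JSON metadata sidecar (config hash, seed, c0), and — when both modes are
run — the per-cell optimization effect (stock difference evolving minus
fixed, also per unit of local warming).

## Conventions and caveats

- Default units are mg C per cm³ of soil and hours; all computations are
  unit-agnostic given a self-consistent configuration.
- Arrhenius laws use a 273 K offset and `Rgas = 0.008314` kJ mol⁻¹ K⁻¹.
- Global aggregates multiply per-volume stock densities by cos-latitude
  area weights and a configurable reference depth (`projection.depth`,
  default 1), so absolute totals depend on those conventions; ratios
  between paired runs do not.
- Cells whose ESS does not exist (too cold) or whose equilibrium is
  infeasible are flagged inactive and excluded from aggregates — this
  reproduces the masked high-latitude regions seen in optimized-trait
  projections.
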