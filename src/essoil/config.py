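"""Run configuration: a single YAML document validated before any computation.

Unknown keys are hard errors (fail loud), every value passes its domain
type's invariants at load time, and ``load -> write -> load`` is the
identity.  Dotted ``--set`` overrides (``parameters.dM=2e-4``) support
parameter sweeps without file proliferation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .evolution import CompetitionKernel
from .model import ModelParameters
from .thermal import ThermalScenario

__all__ = ["RunConfig", "ProjectionOptions", "ConfigError", "load_config", "write_config", "default_config"]


class ConfigError(ValueError):
    """Invalid, missing, or unknown configuration key."""


@dataclass(frozen=True)
class ProjectionOptions:
    mode: str = "both"  # fixed | evolving | both
    depth: float = 1.0  # reference soil depth factor for aggregation

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "evolving", "both"):
            raise ConfigError(f"projection.mode must be fixed|evolving|both, got {self.mode!r}")
        if self.depth <= 0:
            raise ConfigError(f"projection.depth must be > 0, got {self.depth}")


@dataclass(frozen=True)
class RunConfig:
    parameters: ModelParameters
    scenario: ThermalScenario
    kernel: CompetitionKernel
    c0_alternatives: tuple[float, ...] = ()
    projection: ProjectionOptions = field(default_factory=ProjectionOptions)
    seed: int = 0
    log_level: str = "INFO"

    def kernels(self) -> list[CompetitionKernel]:
        """The main kernel plus one per alternative c0 value."""
        out = [self.kernel]
        out.extend(CompetitionKernel(c0=c, shape=self.kernel.shape) for c in self.c0_alternatives)
        return out


_BLOCKS = ("parameters", "scenario", "kernel", "projection", "seed", "log_level")


def _build_block(cls, block: dict, name: str):
    import dataclasses

    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(block)
    if missing:
        raise ConfigError(f"missing required key(s) in {name!r}: {sorted(missing)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} block: {exc}") from exc


def _from_mapping(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    unknown = set(doc) - set(_BLOCKS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "parameters" not in doc:
        raise ConfigError("missing required key(s): ['parameters']")
    kernel_block = dict(doc.get("kernel", {"c0": 1.17}))
    c0_alt = tuple(kernel_block.pop("c0_alternatives", ()))
    return RunConfig(
        parameters=_build_block(ModelParameters, dict(doc["parameters"]), "parameters"),
        scenario=_build_block(ThermalScenario, dict(doc.get("scenario", {})), "scenario"),
        kernel=_build_block(CompetitionKernel, kernel_block, "kernel"),
        c0_alternatives=c0_alt,
        projection=_build_block(ProjectionOptions, dict(doc.get("projection", {})), "projection"),
        seed=int(doc.get("seed", 0)),
        log_level=str(doc.get("log_level", "INFO")),
    )


def _apply_overrides(doc: dict, overrides: dict[str, object]) -> dict:
    for dotted, value in overrides.items():
        parts = dotted.split(".")
        node = doc
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot override through non-mapping key {part!r} in {dotted!r}")
        node[parts[-1]] = value
    return doc


def load_config(path: str | Path | None = None, overrides: dict[str, object] | None = None) -> RunConfig:
    """Load and validate a YAML configuration (package defaults when no path)."""
    if path is None:
        text = resources.files("essoil.data").joinpath("default_config.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
    doc = yaml.safe_load(text) or {}
    if overrides:
        doc = _apply_overrides(doc, dict(overrides))
    return _from_mapping(doc)


def to_mapping(cfg: RunConfig) -> dict:
    doc = {
        "parameters": asdict(cfg.parameters),
        "scenario": {k: v for k, v in asdict(cfg.scenario).items() if v is not None},
        "kernel": {"c0": cfg.kernel.c0, "shape": cfg.kernel.shape},
        "projection": asdict(cfg.projection),
        "seed": cfg.seed,
        "log_level": cfg.log_level,
    }
    if cfg.c0_alternatives:
        doc["kernel"]["c0_alternatives"] = list(cfg.c0_alternatives)
    return doc


def write_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(to_mapping(cfg), sort_keys=True))
    return path


def default_config() -> RunConfig:
    """The configuration shipped with the package."""
    return load_config(None)
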