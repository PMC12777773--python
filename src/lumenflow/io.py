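"""Run configuration, serialisation, and field output.

A single YAML document describes a run (one case or a sweep): units are
fixed — lengths cm, times s, volumes mL, concentrations mM, viscosities
mPa*s — with no unit inference.  Configurations are validated with pydantic
(schema violations are reported with their field paths) and round-trip
losslessly; every output directory receives the resolved configuration and
a version stamp.

Field snapshots are written as legacy-ASCII VTK structured grids (text
format readable by ParaView and friends); tabular outputs as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .flow import RESOLUTIONS, SolverConfig
from .kinematics import MotilityCase

__all__ = [
    "CaseConfig",
    "GridConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_vtk_structured",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


class CaseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    motility: Literal["segmentation", "peristalsis"]
    intensity: Literal["light", "moderate", "vigorous"] = "moderate"
    fluid: str = "nutridrink_default"
    pocket_volume: float = Field(2.0, gt=0, description="mL")
    occlusion_ratio: float = Field(0.3, gt=0, lt=1)
    release: Literal["most_occluded", "least_occluded"] = "most_occluded"
    species: list[str] = Field(default_factory=lambda: ["insulin", "C10"])
    n_periods: int = Field(30, ge=1)
    wavelength: Optional[float] = Field(None, gt=0, description="cm override")
    n_pockets: Optional[int] = Field(None, ge=1)

    def to_case(self) -> MotilityCase:
        return MotilityCase(
            motility=self.motility,
            intensity=self.intensity,
            fluid_id=self.fluid,
            pocket_volume=self.pocket_volume,
            occlusion_ratio=self.occlusion_ratio,
            release_position=self.release,
            species=tuple(self.species),
            n_periods=self.n_periods,
            wavelength=self.wavelength,
            n_pockets=self.n_pockets,
        )


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    motility: list[str] = Field(default_factory=lambda: ["segmentation"])
    intensity: list[str] = Field(default_factory=lambda: ["light", "moderate", "vigorous"])
    fluid: list[str] = Field(default_factory=lambda: ["water_37C", "nutridrink_default"])
    pocket_volume: list[float] = Field(default_factory=lambda: [2.0, 10.0])
    occlusion_ratio: list[float] = Field(default_factory=lambda: [0.3, 0.5, 0.7])
    release: list[str] = Field(default_factory=lambda: ["most_occluded", "least_occluded"])
    n_periods: int = 30


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["case", "sweep"] = "case"
    case: Optional[CaseConfig] = None
    grid: Optional[GridConfig] = None
    resolution: str = "coarse"
    seed: int = 0
    output_dir: str = "lumenflow_out"
    snapshot_every_periods: Optional[float] = None
    analysis_k: int = 4

    def solver_config(self) -> SolverConfig:
        try:
            return RESOLUTIONS[self.resolution]
        except KeyError:
            raise ConfigError(
                f"resolution: unknown preset {self.resolution!r}; "
                f"choose from {sorted(RESOLUTIONS)}"
            ) from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as e:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigError(f"{path}: invalid configuration\n" + "\n".join(lines)) from None
    if cfg.kind == "case" and cfg.case is None:
        raise ConfigError(f"{path}: kind=case requires a 'case' section")
    if cfg.kind == "sweep" and cfg.grid is None:
        raise ConfigError(f"{path}: kind=sweep requires a 'grid' section")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def stamp_output_dir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")
    (out / "version.json").write_text(
        json.dumps({"lumenflow": __version__}, indent=2)
    )
    return out


def write_vtk_structured(
    path: str | Path,
    z2d: np.ndarray,
    r2d: np.ndarray,
    fields: dict,
    title: str = "lumenflow fields",
) -> None:
    """Write an axisymmetric (z, r) slab as a legacy-ASCII VTK structured grid.

    ``z2d``/``r2d`` are (nz, nr) node coordinates; each entry of ``fields``
    is a matching (nz, nr) scalar array.
    """
    nz, nr = z2d.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET STRUCTURED_GRID\n")
        f.write(f"DIMENSIONS {nr} {nz} 1\n")
        f.write(f"POINTS {nz * nr} float\n")
        for i in range(nz):
            for j in range(nr):
                f.write(f"{z2d[i, j]:.6g} {r2d[i, j]:.6g} 0\n")
        f.write(f"POINT_DATA {nz * nr}\n")
        for name, arr in fields.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for i in range(nz):
                for j in range(nr):
                    f.write(f"{arr[i, j]:.6g}\n")
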