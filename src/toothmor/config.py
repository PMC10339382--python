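"""Pipeline configuration: strict YAML/JSON parsing and config digests.

Unknown keys are rejected (fail-fast on typos) and every output artifact is
stamped with a digest of the exact configuration that produced it, so the
provenance of any file can be checked against the config that claims it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .fe import SolverOptions
from .geometry import GeometrySpec
from .materials import MaterialSet, default_materials

__all__ = ["GridSpec", "HopgdOptions", "EvaluationOptions", "PipelineConfig"]


@dataclass(frozen=True)
class GridSpec:
    """Uniform force grid bounds (N) and point counts per axis."""

    min: float = 50.0
    max: float = 200.0
    n_fy: int = 4
    n_fz: int = 4

    def validate(self):
        if not self.min < self.max:
            raise ConfigError("grid requires min < max")
        if self.n_fy < 2 or self.n_fz < 2:
            raise ConfigError("grid needs at least 2 points per axis")


@dataclass(frozen=True)
class HopgdOptions:
    tol_modes: float = 1e-4
    max_modes: int = 50
    tol_fp: float = 1e-8
    max_sweeps: int = 200
    interp_scheme: str = "linear"
    init: str = "svd"

    def validate(self):
        if not (self.tol_modes > 0 and self.tol_fp > 0):
            raise ConfigError("hopgd tolerances must be positive")
        if self.interp_scheme not in ("linear", "cubic"):
            raise ConfigError(f"unknown interp_scheme {self.interp_scheme!r}")


@dataclass(frozen=True)
class EvaluationOptions:
    mask: str = "all"
    reference: str = "fe"

    def validate(self):
        if self.reference not in ("fe", "analytic"):
            raise ConfigError(f"unknown reference source {self.reference!r}")


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as err:
        raise ConfigError(f"bad {context}: {err}") from err


@dataclass
class PipelineConfig:
    """Everything needed to run the offline/online workflow end to end."""

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    materials: MaterialSet = field(default_factory=default_materials)
    grid: GridSpec = field(default_factory=GridSpec)
    solver: SolverOptions = field(default_factory=SolverOptions)
    hopgd: HopgdOptions = field(default_factory=HopgdOptions)
    evaluation: EvaluationOptions = field(default_factory=EvaluationOptions)
    output_dir: str = "toothmor_out"
    seed: int = 0

    def validate(self):
        self.geometry.validate()
        self.grid.validate()
        self.hopgd.validate()
        self.evaluation.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "materials": self.materials.to_dict(),
            "grid": dataclasses.asdict(self.grid),
            "solver": dataclasses.asdict(self.solver),
            "hopgd": dataclasses.asdict(self.hopgd),
            "evaluation": dataclasses.asdict(self.evaluation),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def digest(self) -> str:
        """Short content digest of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {
            "geometry", "materials", "grid", "solver", "hopgd",
            "evaluation", "output_dir", "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        cfg = cls(
            geometry=_from_mapping(GeometrySpec, data.get("geometry", {}), "geometry"),
            materials=(
                MaterialSet.from_dict(data["materials"])
                if "materials" in data
                else default_materials()
            ),
            grid=_from_mapping(GridSpec, data.get("grid", {}), "grid"),
            solver=_from_mapping(SolverOptions, data.get("solver", {}), "solver"),
            hopgd=_from_mapping(HopgdOptions, data.get("hopgd", {}), "hopgd"),
            evaluation=_from_mapping(
                EvaluationOptions, data.get("evaluation", {}), "evaluation"
            ),
            output_dir=str(data.get("output_dir", "toothmor_out")),
            seed=int(data.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML (JSON is a YAML subset and therefore accepted)."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as err:
            raise ConfigError(f"{path}: cannot parse: {err}") from err
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
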