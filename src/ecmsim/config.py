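"""Run configuration, YAML loading and run manifests.

A :class:`RunConfig` resolves every simulation parameter explicitly: lattice
geometry, fiber count (directly or via a concentration preset), fiber length
range, phenotype, probability-model shapes, seed, schedule and the
quantification settings.  ``write_manifest`` serialises the fully resolved
configuration plus the seed so that any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .params import (
    MATRIX_PRESETS,
    PHENOTYPE_PRESETS,
    Phenotype,
    ProbabilityModel,
    phenotype_from_dict,
)
from .state import LatticeSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "write_manifest", "config_from_dict"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass(frozen=True)
class RunConfig:
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    n_fibers: int = 2000
    matrix_preset: str | None = None
    fiber_length_min: float = 4.5
    fiber_length_max: float = 45.0
    orientation_mode: str = "sphere"
    phenotype: Phenotype = field(default_factory=Phenotype)
    n_cells: int | None = None  # None -> phenotype.initial_cells; 0 -> acellular
    model: ProbabilityModel = field(default_factory=ProbabilityModel)
    seed: int = 0
    n_steps: int = 336
    record_every: int = 48
    step_hours: float = 0.5
    # quantification / rendering
    pixel_size: float = 0.45
    render_radius: float = 0.9
    z_thickness: float | None = None
    n_slices: int = 15

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ConfigError("n_fibers must be non-negative")
        if not (0 < self.fiber_length_min <= self.fiber_length_max):
            raise ConfigError("fiber length range must satisfy 0 < min <= max")
        if self.n_steps < 0 or self.record_every < 1:
            raise ConfigError("n_steps must be >= 0 and record_every >= 1")

    def resolved_n_cells(self) -> int:
        return self.phenotype.initial_cells if self.n_cells is None else self.n_cells

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "lattice": self.lattice.to_dict(),
            "matrix": {
                "preset": self.matrix_preset,
                "n_fibers": self.n_fibers,
                "fiber_length_min": self.fiber_length_min,
                "fiber_length_max": self.fiber_length_max,
                "orientation_mode": self.orientation_mode,
            },
            "phenotype": self.phenotype.to_dict(),
            "model": self.model.to_dict(),
            "run": {
                "seed": self.seed,
                "n_steps": self.n_steps,
                "record_every": self.record_every,
                "step_hours": self.step_hours,
                "n_cells": self.resolved_n_cells(),
            },
            "quantify": {
                "pixel_size": self.pixel_size,
                "render_radius": self.render_radius,
                "z_thickness": self.z_thickness,
                "n_slices": self.n_slices,
            },
        }


_LATTICE_KEYS = {"cell_lattice_size", "ecm_lattice_size", "spacing"}
_MATRIX_KEYS = {"preset", "n_fibers", "fiber_length_min", "fiber_length_max",
                "orientation_mode"}
_RUN_KEYS = {"seed", "n_steps", "record_every", "step_hours", "n_cells"}
_QUANT_KEYS = {"pixel_size", "render_radius", "z_thickness", "n_slices"}
_PHENOTYPE_KEYS = {"name", "p_dep_max", "p_deg_max", "p_nothing", "deposit_threshold",
                   "motility_threshold", "initial_cells", "min_cells"}
_MODEL_KEYS = set(ProbabilityModel().to_dict().keys())


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )


def config_from_dict(raw: dict | None) -> RunConfig:
    """Build a RunConfig from a (possibly partial) nested mapping."""
    raw = dict(raw or {})
    _check_keys("<top>", raw, {"lattice", "matrix", "phenotype", "model", "run",
                               "quantify"})

    lat = dict(raw.get("lattice") or {})
    _check_keys("lattice", lat, _LATTICE_KEYS)
    lattice = LatticeSpec(**lat)

    mat = dict(raw.get("matrix") or {})
    _check_keys("matrix", mat, _MATRIX_KEYS)
    preset = mat.pop("preset", None)
    n_fibers = mat.pop("n_fibers", None)
    if preset is not None:
        if preset not in MATRIX_PRESETS:
            raise ConfigError(
                f"unknown matrix preset {preset!r}; choose from {sorted(MATRIX_PRESETS)}"
            )
        if n_fibers is None:
            n_fibers = MATRIX_PRESETS[preset]
    if n_fibers is None:
        n_fibers = 2000

    phen_raw = raw.get("phenotype")
    if phen_raw is None:
        phenotype = Phenotype()
    elif isinstance(phen_raw, str):
        if phen_raw not in PHENOTYPE_PRESETS:
            raise ConfigError(
                f"unknown phenotype preset {phen_raw!r}; choose from "
                f"{sorted(PHENOTYPE_PRESETS)}"
            )
        phenotype = PHENOTYPE_PRESETS[phen_raw]
    else:
        _check_keys("phenotype", phen_raw, _PHENOTYPE_KEYS)
        try:
            phenotype = phenotype_from_dict(phen_raw)
        except ValueError as exc:
            raise ConfigError(f"invalid phenotype: {exc}") from exc

    model_raw = dict(raw.get("model") or {})
    _check_keys("model", model_raw, _MODEL_KEYS)
    try:
        model = ProbabilityModel(**model_raw)
    except ValueError as exc:
        raise ConfigError(f"invalid probability model: {exc}") from exc

    run = dict(raw.get("run") or {})
    _check_keys("run", run, _RUN_KEYS)
    quant = dict(raw.get("quantify") or {})
    _check_keys("quantify", quant, _QUANT_KEYS)

    return RunConfig(
        lattice=lattice,
        n_fibers=int(n_fibers),
        matrix_preset=preset,
        fiber_length_min=float(mat.get("fiber_length_min", 4.5)),
        fiber_length_max=float(mat.get("fiber_length_max", 45.0)),
        orientation_mode=mat.get("orientation_mode", "sphere"),
        phenotype=phenotype,
        model=model,
        **{k: run[k] for k in run},
        **{k: quant[k] for k in quant},
    )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; absent keys get defaults, unknown keys fail."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    return config_from_dict(raw)


def write_manifest(config: RunConfig, seed: int, out_dir) -> Path:
    """Write the fully resolved run manifest (config + seed + versions)."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.with_overrides(seed=seed).to_dict(),
        "seed": seed,
        "versions": {
            "ecmsim": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def config_from_manifest(path) -> RunConfig:
    """Rebuild the RunConfig recorded in a manifest file."""
    data = json.loads(Path(path).read_text())
    cfg = data["config"]
    mat = dict(cfg["matrix"])
    mat.pop("preset", None)
    raw = {
        "lattice": cfg["lattice"],
        "matrix": mat,
        "phenotype": cfg["phenotype"],
        "model": cfg["model"],
        "run": cfg["run"],
        "quantify": cfg["quantify"],
    }
    return config_from_dict(raw)
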