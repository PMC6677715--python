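"""Experiment configuration: a single human-editable YAML mapping that
fully determines a run (all pathway, geometry, growth and seed values),
validated against the domain-type invariants.

Presets reproduce the package's reference experiments:

``static-isotropic``
    pattern formation on a static hexagonal grid, isotropic protrusions
    of length 3.5 cell radii, uniform signal weights;
``growth``
    nutrient-limited growth of a population from a single cell;
``coupled-isotropic``
    the growth log replayed under the full single-cell model with the
    static-pattern signaling parameters;
``coupled-spots``
    differential weighting ``[w_a, q_a, w_b, q_b] = [1, 0.001, 0.06,
    0.06]`` producing sparse spots;
``coupled-polarized``
    polarized horizontal protrusions (directions 0 and pi, angular width
    pi/20, length 5) with weights ``[1, 0.001, 0.2, 0.15]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .contacts import ProtrusionSpec
from .dlcm import GrowthParams
from .params import PathwayParams

__all__ = ["ExperimentConfig", "load_config", "PRESETS"]

_MODES = ("wellmixed", "growth", "coupled")


@dataclass
class ExperimentConfig:
    """Fully validated configuration of one experiment."""

    mode: str = "wellmixed"
    pathway: PathwayParams = field(default_factory=PathwayParams)
    protrusion: ProtrusionSpec = field(default_factory=ProtrusionSpec)
    lattice_nx: int = 10
    lattice_ny: int = 10
    periodic: bool = False
    growth: GrowthParams = field(default_factory=GrowthParams)
    mesh_voxels: int = 1
    seed: int = 0
    t_end: float = 200.0
    output_times: tuple[float, ...] = (4.0, 20.0, 40.0, 200.0)
    split_reporter: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.lattice_nx < 1 or self.lattice_ny < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.mesh_voxels < 1:
            raise ValueError("mesh_voxels must be >= 1")
        if self.t_end < 0:
            raise ValueError("t_end must be non-negative")
        ot = np.asarray(self.output_times, dtype=float)
        if len(ot) and (np.any(np.diff(ot) < 0) or np.any(ot < 0)):
            raise ValueError("output_times must be sorted and non-negative")

    def to_mapping(self) -> dict:
        d = {
            "mode": self.mode,
            "lattice_nx": self.lattice_nx,
            "lattice_ny": self.lattice_ny,
            "periodic": self.periodic,
            "mesh_voxels": self.mesh_voxels,
            "seed": self.seed,
            "t_end": self.t_end,
            "output_times": list(self.output_times),
            "split_reporter": self.split_reporter,
            "pathway": asdict(self.pathway),
            "growth": asdict(self.growth),
            "protrusion": {
                "length": self.protrusion.length,
                "directions": list(self.protrusion.directions),
                "width": self.protrusion.width,
            },
        }
        return d

    def echo(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)


def _build_section(cls, mapping: dict, section: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown keys in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {section} configuration: {exc}") from exc


def load_config(source: str | Path | dict | None = None,
                preset: str | None = None) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig`.

    ``source`` is a YAML file path or an inline mapping; omitted values
    take the documented defaults (the static-pattern reference
    parameters).  Unknown keys raise a named :class:`ValueError`.  A
    ``preset`` mapping is applied first and then overridden by
    ``source``.
    """
    mapping: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        mapping.update(_deep_copy(PRESETS[preset]))
    if source is not None:
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                loaded = yaml.safe_load(fh) or {}
        else:
            loaded = dict(source)
        if not isinstance(loaded, dict):
            raise ValueError("configuration must be a mapping")
        _deep_update(mapping, loaded)

    top_known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(mapping) - top_known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    sub = {}
    if "pathway" in mapping:
        sub["pathway"] = _build_section(PathwayParams,
                                        mapping.pop("pathway"), "pathway")
    if "growth" in mapping:
        sub["growth"] = _build_section(GrowthParams,
                                       mapping.pop("growth"), "growth")
    if "protrusion" in mapping:
        pm = dict(mapping.pop("protrusion"))
        unknown = set(pm) - {"length", "directions", "width"}
        if unknown:
            raise ValueError(f"unknown keys in section 'protrusion': "
                             f"{sorted(unknown)}")
        if "directions" in pm:
            pm["directions"] = tuple(float(x) for x in pm["directions"])
        sub["protrusion"] = ProtrusionSpec(**pm)
    if "output_times" in mapping:
        mapping["output_times"] = tuple(float(x)
                                        for x in mapping["output_times"])
    return ExperimentConfig(**mapping, **sub)


def _deep_copy(d: dict) -> dict:
    return {k: (_deep_copy(v) if isinstance(v, dict) else v)
            for k, v in d.items()}


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


PRESETS: dict[str, dict] = {
    "static-isotropic": {
        "mode": "wellmixed",
        "lattice_nx": 10,
        "lattice_ny": 10,
        "t_end": 200.0,
        "output_times": [4.0, 20.0, 40.0, 200.0],
    },
    "growth": {
        "mode": "growth",
        "lattice_nx": 60,
        "lattice_ny": 60,
        "t_end": float("inf"),
        "output_times": [],
    },
    "coupled-isotropic": {
        "mode": "coupled",
        "lattice_nx": 60,
        "lattice_ny": 60,
        "mesh_voxels": 40,
        "t_end": 200.0,
        "output_times": [50.0, 100.0, 200.0],
    },
    "coupled-spots": {
        "mode": "coupled",
        "lattice_nx": 60,
        "lattice_ny": 60,
        "mesh_voxels": 40,
        "t_end": 200.0,
        "output_times": [50.0, 100.0, 200.0],
        "pathway": {"w_a": 1.0, "q_a": 0.001, "w_b": 0.06, "q_b": 0.06},
    },
    "coupled-polarized": {
        "mode": "coupled",
        "lattice_nx": 60,
        "lattice_ny": 60,
        "mesh_voxels": 40,
        "t_end": 200.0,
        "output_times": [50.0, 100.0, 200.0],
        "pathway": {"w_a": 1.0, "q_a": 0.001, "w_b": 0.2, "q_b": 0.15},
        "protrusion": {"length": 5.0, "directions": [0.0, float(np.pi)],
                       "width": float(np.pi) / 20.0},
    },
}
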