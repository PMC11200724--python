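"""YAML configuration round-tripping.

A run configuration is a nested mapping mirroring :class:`RunConfig`:
``geometry``, ``passive``, ``active``, ``circulation`` sections plus the
top-level solver/coupling scalars.  The packaged default
(``data/default_config.yaml``) is the calibrated baseline configuration;
material sections default to the ventricle/atrium parameter fixtures in
``data/materials.yaml``.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from importlib import resources
from pathlib import Path

import yaml

from .circulation import CirculationParams
from .constitutive import ActiveMaterialParams, PassiveMaterialParams
from .geometry import LVGeometryConfig
from .simulator import RunConfig

__all__ = [
    "load_config",
    "save_config",
    "default_config",
    "load_materials",
    "config_to_dict",
    "config_from_dict",
]


def _build(cls, d: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def config_to_dict(cfg: RunConfig) -> dict:
    d = {
        "geometry": asdict(cfg.geometry),
        "passive": cfg.passive.to_dict(),
        "active": cfg.active.to_dict(),
        "circulation": asdict(cfg.circulation),
    }
    d["circulation"]["la_active"] = cfg.circulation.la_active.to_dict()
    for name in ("edp_reference", "fiber_prestretch", "blend_width",
                 "solver_tol", "root_rest_position"):
        d[name] = getattr(cfg, name)
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    geo = _build(LVGeometryConfig, d.pop("geometry", {}))
    passive = _build(PassiveMaterialParams, d.pop("passive", {})) \
        if "passive" in d else PassiveMaterialParams.ventricle()
    active = _build(ActiveMaterialParams, d.pop("active", {})) \
        if "active" in d else ActiveMaterialParams.ventricle()
    circ_d = dict(d.pop("circulation", {}))
    if "la_active" in circ_d:
        circ_d["la_active"] = _build(ActiveMaterialParams, circ_d["la_active"])
    circulation = _build(CirculationParams, circ_d)
    return _build(RunConfig, {
        "geometry": geo, "passive": passive, "active": active,
        "circulation": circulation, **d})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a run configuration; with no path, the packaged calibrated
    default."""
    if path is None:
        return default_config()
    return config_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def default_config() -> RunConfig:
    ref = resources.files("cardioloop.data") / "default_config.yaml"
    return config_from_dict(yaml.safe_load(ref.read_text()))


def load_materials(tissue: str = "ventricle") -> tuple[PassiveMaterialParams,
                                                       ActiveMaterialParams]:
    """Passive/active parameter fixtures for ``ventricle`` or ``atrium``."""
    ref = resources.files("cardioloop.data") / "materials.yaml"
    d = yaml.safe_load(ref.read_text())
    if tissue not in d:
        raise KeyError(f"unknown tissue {tissue!r}")
    return (_build(PassiveMaterialParams, d[tissue]["passive"]),
            _build(ActiveMaterialParams, d[tissue]["active"]))
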