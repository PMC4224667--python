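"""YAML configuration: serialising and loading the full parameter bundle.

The config file groups parameters under the keys ``thermal``, ``quality``,
``architecture``, ``management`` and ``weather``; any key or sub-key may be
omitted, in which case defaults apply.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from typing import Any

import yaml

from .architecture import ArchitectureParams, ManagementParams
from .fibre_quality import LogisticParams, QualityParams
from .thermal import ThermalParams
from .weather import SyntheticWeatherSpec

__all__ = ["SimulationConfig", "load_config", "dump_config", "default_config"]


@dataclass
class SimulationConfig:
    thermal: ThermalParams = field(default_factory=ThermalParams)
    quality: QualityParams = field(default_factory=QualityParams)
    architecture: ArchitectureParams = field(default_factory=ArchitectureParams)
    management: ManagementParams | None = None
    weather: SyntheticWeatherSpec | None = None


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _parse_date(value: Any) -> dt.date | None:
    if value is None or isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _build(cls, data: dict[str, Any], converters: dict[str, Any] | None = None):
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in valid:
            raise KeyError(f"unknown key {key!r} for {cls.__name__}")
        if converters and key in converters:
            value = converters[key](value)
        kwargs[key] = value
    return cls(**kwargs)


def _build_quality(data: dict[str, Any]) -> QualityParams:
    conv = {
        name: (lambda v: LogisticParams(**v) if isinstance(v, dict) else LogisticParams(*v))
        for name in ("length", "strength", "micronaire")
    }
    for name in ("length_mean_coeffs", "strength_mean_coeffs",
                 "strength_td_coeffs", "micronaire_tmin_coeffs"):
        conv[name] = tuple
    return _build(QualityParams, data, conv)


def _build_architecture(data: dict[str, Any]) -> ArchitectureParams:
    conv = {
        "abscission_table": lambda rows: tuple(
            (float("inf") if u in (None, "inf", ".inf") else float(u), float(p))
            for u, p in rows
        )
    }
    return _build(ArchitectureParams, data, conv)


def _build_management(data: dict[str, Any]) -> ManagementParams:
    conv = {k: _parse_date for k in ("sowing_date", "main_topping_date", "branch_topping_date")}
    return _build(ManagementParams, data, conv)


def load_config(path) -> SimulationConfig:
    """Load a YAML config file into a SimulationConfig (missing keys → defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimulationConfig()
    if "thermal" in raw:
        cfg.thermal = _build(ThermalParams, raw["thermal"])
    if "quality" in raw:
        cfg.quality = _build_quality(raw["quality"])
    if "architecture" in raw:
        cfg.architecture = _build_architecture(raw["architecture"])
    if "management" in raw:
        cfg.management = _build_management(raw["management"])
    if "weather" in raw:
        cfg.weather = _build(SyntheticWeatherSpec, raw["weather"])
    return cfg


def dump_config(cfg: SimulationConfig, path=None) -> str:
    """Serialise a SimulationConfig to YAML; write to ``path`` if given."""
    doc = {
        "thermal": _to_plain(cfg.thermal),
        "quality": _to_plain(cfg.quality),
        "architecture": _to_plain(cfg.architecture),
    }
    if cfg.management is not None:
        doc["management"] = _to_plain(cfg.management)
    if cfg.weather is not None:
        doc["weather"] = _to_plain(cfg.weather)
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def default_config() -> SimulationConfig:
    return SimulationConfig()
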