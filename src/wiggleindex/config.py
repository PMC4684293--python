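"""Run configuration: one YAML file that reproduces a whole run.

The config gathers everything a run depends on — paths, WI parameters,
plate layout, the file-naming template, the time grid, analysis options
and the master seed — so that re-running with the same file and inputs is
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import WIParams
from .io import DataError, PlateLayout, WellBox
from .synthetic import TIME_GRID

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(Exception):
    """Malformed or inconsistent run configuration."""


@dataclass
class RunConfig:
    params: WIParams = field(default_factory=WIParams)
    layout: PlateLayout | None = None
    naming_template: str = "{genotype}_{insecticide}_{dose_ppm}ppm_t{time_min}_{well_id}"
    time_grid: tuple[float, ...] = TIME_GRID
    transform: str = "auto"
    beta_convention: str = "negate"
    conf_level: float = 0.95
    control_group: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "params": asdict(self.params),
            "naming_template": self.naming_template,
            "time_grid": list(self.time_grid),
            "transform": self.transform,
            "beta_convention": self.beta_convention,
            "conf_level": self.conf_level,
            "control_group": self.control_group,
            "seed": self.seed,
        }
        if self.layout is not None:
            d["layout"] = {
                "grid_shape": list(self.layout.grid_shape),
                "wells": [
                    {
                        "well_id": w.well_id,
                        "rows": [w.row_start, w.row_stop],
                        "cols": [w.col_start, w.col_stop],
                    }
                    for w in self.layout.wells
                ],
            }
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def _layout_from_dict(d: dict) -> PlateLayout:
    try:
        wells = [
            WellBox(w["well_id"], w["rows"][0], w["rows"][1], w["cols"][0], w["cols"][1])
            for w in d["wells"]
        ]
        return PlateLayout(wells=wells, grid_shape=tuple(d.get("grid_shape", (2, 2))))
    except (KeyError, TypeError, DataError) as exc:
        raise ConfigError(f"bad layout section: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    cfg = RunConfig()
    try:
        if "params" in raw:
            cfg.params = WIParams(**raw["params"])
        if "layout" in raw:
            cfg.layout = _layout_from_dict(raw["layout"])
        for key in (
            "naming_template",
            "transform",
            "beta_convention",
            "conf_level",
            "control_group",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "time_grid" in raw:
            cfg.time_grid = tuple(float(t) for t in raw["time_grid"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad config value: {exc}") from exc
    return cfg
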