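"""Run configuration: every analysis constant in one place.

The defaults are the study-design constants of the pipeline (site grid
size, replicate length, screening thresholds, the used:available ratio,
and so on).  Configs round-trip through a flat ``key = value`` text
file; overrides are logged by the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class RunConfig:
    seed: int = 0
    crs: str = "local-projected-meters"
    # landscape / survey geometry
    site_grid_m: float = 8_000.0
    replicate_m: float = 2_000.0
    replicate_step_m: float = 2_000.0
    replicate_max_m: float = 20_000.0
    kernel_radius_m: float = 10_000.0
    line_spacing_m: float = 100.0
    # model selection
    corr_threshold: float = 0.70
    vif_threshold: float = 3.0
    delta_aicc: float = 2.0
    alpha: float = 0.05
    n_boot: int = 1000
    # home ranges and RSF
    isopleth_level: float = 0.95
    ratio: int = 4
    subadult_max_age_y: float = 4.0
    min_days: int = 60
    season_start: str = "04-01"
    season_end: str = "10-31"
    max_speed_m_per_h: float = 10_000.0
    residency_window_days: int = 14
    residency_multiple: float = 3.0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                raw[key.strip()] = value.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = _convert(f.type, raw[f.name])
        return cls(**kwargs)


def _convert(typ, value: str):
    if typ in (int, "int"):
        return int(value)
    if typ in (float, "float"):
        return float(value)
    return value
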