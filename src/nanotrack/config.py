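"""Run configuration: every numeric default of the pipeline in one place.

The on-disk format is plain text ``key = value`` lines (``#`` comments
allowed), written in a fixed field order so that write -> read -> write
round-trips to identical file content.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

from .errors import InvalidParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # calibration
    pixel_size_um: float = 0.1
    frame_interval_s: float = 0.1
    # detection
    psf_sigma_px: float = 1.3
    snr_min: float = 5.0
    # linking
    max_disp_px: float = 3.5
    max_gap: int = 1
    # dynamics
    msd_n_lags: int = 4
    max_lag_fraction: float = 1.0
    peak_n_bins: int = 30
    dwell_bin_width_s: float = 0.1
    dwell_fit_floor_s: float = 0.0
    exclude_censored_dwells: bool = True
    # colocalization
    match_radius_px: float = 2.0
    # FCS
    beam_waist_um: float = 0.25
    fcs_segments: int = 4
    # units for densities: "um2" or "px2"
    density_unit: str = "um2"
    # randomness (mixture restarts etc.)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "psf_sigma_px",
                     "snr_min", "max_disp_px", "match_radius_px",
                     "beam_waist_um", "dwell_bin_width_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.density_unit not in ("um2", "px2"):
            raise InvalidParameterError("density_unit must be 'um2' or 'px2'")

    def to_file(self, path) -> None:
        lines = ["# nanotrack run configuration"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise InvalidParameterError(f"unknown config key: {key}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.lower() in ("true", "1", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)
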