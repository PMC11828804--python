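"""Config parsing/validation and shared file readers/writers.

Config files are YAML with the documented sections below; unknown keys are
rejected. Lengths in files are SI metres; flow rates in the ``flow``
section use the bench unit µL/min and are converted centrally. Every run
writes a provenance block (config hash, package version, timestamp) so an
output directory is self-describing.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .device import DeviceGeometry, TransportParams
from .errors import ConfigurationError, FormatError
from .sensing import ROI_TABLE_COLUMNS, RGBStack

SUPPORTED_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # CLI default renders at 20 µm/px (the library default is the 3.45 µm/px
    # optical scale, which allocates full-resolution chamber images)
    phantom: dict = {"pixel_scale": 20e-6}
    flow_rate_ul_min: float = 0.5
    gas_high_percent: float = 19.0
    gas_low_percent: float = 0.0
    zone2_mode: str = "stripes"
    oxygen_advection: bool = False
    nx: int = 100
    nz: int = 50
    t_end_s: float = 7200.0
    dt_s: float = 10.0
    out_every_s: float = 600.0
    with_cells: bool = True


class RunConfig(BaseModel):
    """Validated top-level run configuration."""

    model_config = ConfigDict(extra="forbid")

    geometry: dict = {}
    transport: dict = {}
    scenario: ScenarioConfig = ScenarioConfig()
    seed: int = 0
    outdir: str = "zonechip_out"
    log_level: str = "INFO"

    def device_geometry(self) -> DeviceGeometry:
        try:
            return DeviceGeometry(**self.geometry)
        except ValidationError as e:
            raise ConfigurationError(f"invalid geometry section: {e}") from e

    def transport_params(self) -> TransportParams:
        geo = self.device_geometry()
        try:
            return TransportParams.for_geometry(geo, **self.transport)
        except ValidationError as e:
            raise ConfigurationError(f"invalid transport section: {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        cfg = RunConfig(**raw)
        cfg.device_geometry()      # eager validation: unknown keys, invariants
        cfg.transport_params()
        return cfg
    except (ValidationError, ConfigurationError) as e:
        raise ConfigurationError(f"invalid configuration {path}: {e}") from e


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))


def provenance(config: RunConfig) -> dict:
    """Config hash + package version + timestamp for output sidecars."""
    from . import __version__

    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return {"config_sha256": hashlib.sha256(blob).hexdigest(),
            "package_version": __version__,
            "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat()}


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image_any(path: str | Path) -> np.ndarray:
    """Read a TIFF (possibly multi-frame) or PNG image.

    Returns the pixel array with its native dtype; multi-frame TIFFs come
    back as (T, H, W[, C]).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return iio.imread(path)
    raise FormatError(
        f"unsupported image format {path.suffix!r}; supported: "
        f"{', '.join(SUPPORTED_IMAGE_SUFFIXES)}")


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Write a TIFF stack or a PNG frame, chosen by suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, array)
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, array)
        return
    raise FormatError(
        f"unsupported image format {path.suffix!r}; supported: "
        f"{', '.join(SUPPORTED_IMAGE_SUFFIXES)}")


def write_stack(stack: RGBStack, directory: str | Path, stem: str = "stack") -> dict:
    """Write an RGBStack as multi-frame TIFF + ROI CSV + timestamps CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff = directory / f"{stem}.tif"
    write_image(tiff, stack.frames)
    roi_csv = directory / f"{stem}_rois.csv"
    stack.roi_table.to_csv(roi_csv, index=False)
    times_csv = directory / f"{stem}_times.csv"
    pd.DataFrame({"frame": np.arange(stack.timestamps.size),
                  "time_s": stack.timestamps}).to_csv(times_csv, index=False)
    return {"tiff": str(tiff), "rois": str(roi_csv), "times": str(times_csv)}


def read_stack(directory: str | Path, stem: str = "stack") -> RGBStack:
    """Read back a stack written by :func:`write_stack`."""
    directory = Path(directory)
    frames = read_image_any(directory / f"{stem}.tif")
    if frames.ndim == 3:       # single frame collapsed by the writer
        frames = frames[None]
    roi = read_roi_table(directory / f"{stem}_rois.csv")
    times = pd.read_csv(directory / f"{stem}_times.csv")["time_s"].to_numpy(float)
    return RGBStack(frames=frames, timestamps=times, roi_table=roi)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_roi_table(path: str | Path) -> pd.DataFrame:
    """Read a ROI table CSV (roi_id, x_px, y_px, radius_px, zone)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    cols = [c.strip() for c in header.split(",")]
    missing = [c for c in ROI_TABLE_COLUMNS if c not in cols]
    if missing:
        raise FormatError(
            f"{path}: line 1: ROI table header is missing columns {missing} "
            f"(found {cols})")
    return pd.read_csv(path)


def write_table(rows, path: str | Path) -> None:
    """Write a list of dicts (or DataFrame) as UTF-8 CSV with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
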