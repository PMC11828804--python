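"""Synthetic-data generator: oxygen phantoms, sensor stacks, staining sets.

Every pipeline input can be generated with known ground truth: plan-view
oxygen fields over the chamber footprint (phantoms), RGB sensor image
stacks whose red/green ratio follows the two-site Stern–Volmer model over
the phantom field with multiplicative per-channel Gaussian noise
(photon-like, default 1%), and multichannel staining image sets with
zone-graded albumin intensity. Outputs are fully deterministic under a
fixed seed, and ground truth is available alongside every product so
parameter-recovery tests never re-derive it.

Default acquisition settings mirror the study: 10-min frame cadence,
1.5-mm sensor disks, 19%/0% gas levels with the cell-free measured zone
plateaus (≈19/13/7 %O2) as the step-switch targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .device import DeviceGeometry, zone_of
from .errors import ConfigurationError, PlacementError, RenderingError
from .quantify import ChannelImageSet
from .sensing import ROI_TABLE_COLUMNS, RGBStack, SVCalibration, sv_forward

__all__ = ["PhantomSpec", "OxygenPhantom", "make_oxygen_phantom",
           "render_sensor_stack", "render_staining_set", "roi_table_pixels"]


class PhantomSpec(BaseModel):
    """Scenario and acquisition settings for the synthetic generators."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    scenario: str = "step_switch"     # uniform | step_switch | three_zone_steady
    seed: int = 0
    frame_interval: float = 600.0     # s, imaging cadence
    duration: float = 7200.0          # s
    noise_sigma_red: float = 0.01     # multiplicative Gaussian sigma
    noise_sigma_green: float = 0.01
    # ground-truth sensor model
    f1: float = 0.8
    Ksv: float = 0.05                 # per %O2
    R0: float = 1.5
    green_gain: float = 20000.0       # counts at 16-bit
    background: float = 400.0         # counts outside sensor disks
    bit_depth: int = 16               # 8 or 16
    pixel_scale: float = 3.45e-6      # m/px
    # step_switch / three_zone_steady shape
    zone_targets: tuple[float, float, float] = (19.0, 13.0, 7.0)   # %O2 plateaus
    time_constants: tuple[float, float, float] = (600.0, 600.0, 600.0)  # s
    start_percent: float = 19.0
    transition_width: float = 2.0e-3  # m, zone blending for steady profiles

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if self.scenario not in ("uniform", "step_switch", "three_zone_steady"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.noise_sigma_red < 0 or self.noise_sigma_green < 0:
            raise ConfigurationError("noise sigmas must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if self.pixel_scale <= 0 or self.frame_interval <= 0 or self.duration <= 0:
            raise ConfigurationError("pixel_scale, frame_interval, duration must be > 0")
        return self

    def calibration(self) -> SVCalibration:
        """The generator's true Stern–Volmer parameters."""
        return SVCalibration(f1=self.f1, Ksv=self.Ksv, R0=self.R0,
                             scope="truth")

    def truth(self) -> dict:
        """Ground-truth sidecar content (JSON-serializable)."""
        return self.model_dump()


@dataclass
class OxygenPhantom:
    """Known plan-view oxygen field: %O2 per x pixel column per frame."""

    times: np.ndarray        # (T,)
    x_profile: np.ndarray    # (T, W) %O2 along the chamber length
    pixel_scale: float
    geometry: DeviceGeometry

    @property
    def width_px(self) -> int:
        return self.x_profile.shape[1]

    @property
    def height_px(self) -> int:
        return int(round(self.geometry.chamber_width / self.pixel_scale))

    def o2_at(self, t_index: int, x_px) -> np.ndarray:
        return self.x_profile[t_index, np.asarray(x_px, dtype=int)]

    def roi_means(self, roi_table: pd.DataFrame) -> np.ndarray:
        """Disk-pixel means of the phantom field, shape (T, n_roi).

        Uses the same inclusive pixel-centre disk membership as the
        sensing pipeline, so a noiseless rendered stack round-trips to
        these values exactly (up to quantization).
        """
        ys = np.arange(self.height_px)
        out = np.empty((self.times.size, len(roi_table)))
        for k, row in enumerate(roi_table.itertuples()):
            xs = np.arange(self.width_px)
            r2 = row.radius_px ** 2 - (xs - row.x_px) ** 2
            counts = np.array([np.sum((ys - row.y_px) ** 2 <= rem) if rem >= 0 else 0
                               for rem in r2], dtype=float)
            inside = counts > 0
            out[:, k] = self.x_profile[:, inside] @ counts[inside] / counts.sum()
        return out


def _zone_of_x(x_m: np.ndarray, geometry: DeviceGeometry) -> np.ndarray:
    b1, b2 = geometry.zone_boundaries
    frac = x_m / geometry.chamber_length
    return np.where(frac <= b1, 1, np.where(frac <= b2, 2, 3))


def make_oxygen_phantom(spec: PhantomSpec, geometry: DeviceGeometry) -> OxygenPhantom:
    """Generate the ground-truth oxygen field for a scenario.

    ``uniform``: constant ``start_percent`` everywhere. ``step_switch``:
    per-zone exponential relaxation from ``start_percent`` toward the zone
    targets with the given time constants. ``three_zone_steady``: static
    piecewise-smooth x-profile blending the zone targets over
    ``transition_width``.
    """
    W = int(round(geometry.chamber_length / spec.pixel_scale))
    times = np.arange(0.0, spec.duration + 1e-9, spec.frame_interval)
    x_m = (np.arange(W) + 0.5) * spec.pixel_scale

    if spec.scenario == "uniform":
        prof = np.full((times.size, W), spec.start_percent)
    elif spec.scenario == "step_switch":
        zones = _zone_of_x(x_m, geometry)
        targets = np.asarray(spec.zone_targets)[zones - 1]
        taus = np.asarray(spec.time_constants)[zones - 1]
        decay = np.exp(-times[:, None] / taus[None, :])
        prof = targets[None, :] + (spec.start_percent - targets[None, :]) * decay
    else:  # three_zone_steady
        b1, b2 = geometry.zone_boundaries
        L = geometry.chamber_length
        w = spec.transition_width

        def blend(level_a, level_b, edge):
            return level_a + (level_b - level_a) / (1.0 + np.exp(-(x_m - edge * L) / (w / 4.0)))

        p = blend(spec.zone_targets[0], spec.zone_targets[1], b1)
        p = p + blend(0.0, spec.zone_targets[2] - spec.zone_targets[1], b2)
        prof = np.tile(p, (times.size, 1))
    return OxygenPhantom(times=times, x_profile=prof,
                         pixel_scale=spec.pixel_scale, geometry=geometry)


def roi_table_pixels(geometry: DeviceGeometry, pixel_scale: float) -> pd.DataFrame:
    """ROI table (pixel coordinates) for the geometry's sensor sections."""
    rows = []
    for i, (cx, cy) in enumerate(geometry.roi_centers, start=1):
        rows.append({"roi_id": i,
                     "x_px": cx / pixel_scale,
                     "y_px": cy / pixel_scale,
                     "radius_px": geometry.roi_diameter / 2.0 / pixel_scale,
                     "zone": zone_of((cx, cy), geometry)})
    return pd.DataFrame(rows, columns=list(ROI_TABLE_COLUMNS))


def render_sensor_stack(phantom: OxygenPhantom, spec: PhantomSpec,
                        roi_table: pd.DataFrame | None = None) -> RGBStack:
    """Render an RGB sensor stack from a phantom field.

    Inside each sensor disk the green (reference) channel is a constant
    gain and the red channel green_gain · R0 · [f1/(1+Ksv·O2) + f2], each
    with independent multiplicative Gaussian noise; outside the disks both
    channels sit at the background level. Pixel values are quantized to
    the declared bit depth; gains that would clip raise a rendering error.
    """
    if roi_table is None:
        roi_table = roi_table_pixels(phantom.geometry, spec.pixel_scale)
    H, W = phantom.height_px, phantom.width_px
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    vmax = np.iinfo(dtype).max
    cal = spec.calibration()

    r_max = spec.green_gain * spec.R0 * 1.0   # R/R0 <= 1
    headroom = 1.0 + 6.0 * max(spec.noise_sigma_red, spec.noise_sigma_green)
    if max(r_max, spec.green_gain) * headroom > vmax:
        raise RenderingError(
            f"channel gains exceed the {spec.bit_depth}-bit range (max signal "
            f"{max(r_max, spec.green_gain) * headroom:.0f} > {vmax})")

    rng = np.random.default_rng(spec.seed)
    T = phantom.times.size
    frames = np.empty((T, H, W, 3), dtype=dtype)
    yy, xx = np.mgrid[0:H, 0:W]
    disk = np.zeros((H, W), dtype=bool)
    for row in roi_table.itertuples():
        disk |= (xx - row.x_px) ** 2 + (yy - row.y_px) ** 2 <= row.radius_px ** 2

    for ti in range(T):
        o2_cols = phantom.x_profile[ti]          # (W,)
        rr0 = np.asarray(sv_forward(np.clip(o2_cols, 0.0, None), cal))
        red = np.where(disk, spec.green_gain * spec.R0 * rr0[None, :], spec.background)
        green = np.where(disk, spec.green_gain, spec.background)
        if spec.noise_sigma_red > 0:
            red = red * (1.0 + spec.noise_sigma_red * rng.standard_normal((H, W)))
        if spec.noise_sigma_green > 0:
            green = green * (1.0 + spec.noise_sigma_green * rng.standard_normal((H, W)))
        frames[ti, :, :, 0] = np.clip(np.round(red), 0, vmax).astype(dtype)
        frames[ti, :, :, 1] = np.clip(np.round(green), 0, vmax).astype(dtype)
        frames[ti, :, :, 2] = 0
    return RGBStack(frames=frames, timestamps=phantom.times.copy(),
                    roi_table=roi_table, pixel_scale=spec.pixel_scale)


def render_staining_set(zone_gains=(3.0, 2.0, 1.0), n_sites: int = 36,
                        cells_per_site: int = 60, viability: float = 0.95,
                        seed: int = 0, image_size: tuple[int, int] = (256, 256),
                        red_role: str = "albumin", nucleus_radius: int = 5,
                        lognormal_sigma: float = 0.3,
                        max_tries: int = 200) -> list[ChannelImageSet]:
    """Generate zone-graded staining image sets with known ground truth.

    Nuclei are non-overlapping disks in the blue channel; each cell is
    live with probability ``viability`` (green marker on live cells). The
    red channel carries either the dead-cell stain (``red_role='dead'``)
    or albumin with per-cell intensity zone_gain × lognormal factor
    (``red_role='albumin'``), so mean RFU across zones follows the gains.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    H, W = image_size
    yy, xx = np.mgrid[0:H, 0:W]
    sites: list[ChannelImageSet] = []
    for zone in (1, 2, 3):
        gain = zone_gains[zone - 1]
        for s in range(n_sites):
            blue = np.zeros((H, W), dtype=np.uint8)
            green = np.zeros((H, W), dtype=np.uint8)
            red = np.zeros((H, W), dtype=np.uint8)
            centers: list[tuple[int, int]] = []
            for _ in range(cells_per_site):
                for attempt in range(max_tries):
                    cy = rng.integers(nucleus_radius, H - nucleus_radius)
                    cx = rng.integers(nucleus_radius, W - nucleus_radius)
                    if all((cy - py) ** 2 + (cx - px) ** 2 > (2 * nucleus_radius) ** 2
                           for py, px in centers):
                        centers.append((cy, cx))
                        break
                else:
                    raise PlacementError(
                        f"could not place {cells_per_site} non-overlapping nuclei "
                        f"in a {H}x{W} image after {max_tries} tries each")
            alive = rng.random(len(centers)) < viability
            albumin_factor = gain * rng.lognormal(mean=0.0, sigma=lognormal_sigma,
                                                  size=len(centers))
            for ci, (cy, cx) in enumerate(centers):
                m = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius ** 2
                blue[m] = 200
                if alive[ci]:
                    green[m] = 180
                if red_role == "dead":
                    if not alive[ci]:
                        red[m] = 180
                else:
                    red[m] = np.uint8(np.clip(40.0 * albumin_factor[ci], 0, 255))
            sites.append(ChannelImageSet(blue=blue, green=green, red=red,
                                         red_role=red_role, zone=zone,
                                         site_index=s))
    return sites
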