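"""Ratiometric oxygen sensing: two-site Stern–Volmer model and pipeline.

The sensor sections combine an oxygen-quenched dye (PtTFPP, red emission)
with an oxygen-insensitive reference dye (MFY, green emission), imaged with
an RGB camera. Per region of interest (ROI) the ratiometric readout is
R = mean(red) / mean(green), and the quenching follows the simplified
two-site Stern–Volmer model

    R / R0 = f1 / (1 + Ksv·[O2]) + f2,       f2 = 1 − f1,

where R0 is the ratio at zero oxygen, f1 the quenchable dye fraction and
Ksv the quenching constant (per %O2 here). The model is strictly
decreasing in [O2], so it inverts in closed form on the physical band
f2 < R/R0 ≤ 1.

A two-point calibration (19% and 0%) cannot identify f1 and Ksv jointly;
``calibrate`` therefore offers a two-point mode with f1 fixed (default
0.8) and a multi-point least-squares mode for ≥ 3 oxygen levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.optimize import least_squares

from .errors import CalibrationError, ConfigurationError, DataError, DomainError

__all__ = [
    "SVCalibration", "RGBStack", "RatioSeries", "QCFlag",
    "sv_forward", "sv_invert", "calibrate", "extract_ratios",
    "ratios_to_oxygen", "flag_bleached", "response_time",
]

ROI_TABLE_COLUMNS = ("roi_id", "x_px", "y_px", "radius_px", "zone")


class QCFlag:
    """Bit flags attached to individual (frame, ROI) ratio entries."""

    OK = 0
    ZERO_REFERENCE = 1   # green mean was zero; no ratio
    BELOW_BAND = 2       # R/R0 ≤ f2: outside the model band (possible bleaching)
    CLAMPED_HIGH = 4     # R/R0 > 1: clamped to 0% O2
    BLEACHED_ROI = 8     # ROI excluded by the persistence rule


class SVCalibration(BaseModel):
    """Fitted two-site Stern–Volmer parameters for one ROI (or globally)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    f1: float
    Ksv: float            # per %O2
    R0: float
    scope: str = "global"     # "global" or "roi:<id>"
    residual_norm: float = 0.0
    n_points: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SVCalibration":
        if not (0.0 < self.f1 <= 1.0):
            raise CalibrationError(f"f1 must be in (0, 1], got {self.f1}")
        if self.Ksv <= 0:
            raise CalibrationError("Ksv must be positive")
        if self.R0 <= 0:
            raise CalibrationError("R0 must be positive")
        return self

    @property
    def f2(self) -> float:
        """Unquenchable dye fraction; f1 + f2 = 1 exactly by construction."""
        return 1.0 - self.f1


def sv_forward(O2, calib: SVCalibration):
    """R/R0 at oxygen level ``O2`` (%): f1/(1 + Ksv·O2) + f2."""
    O2 = np.asarray(O2, dtype=float)
    if np.any(O2 < 0):
        raise DomainError("oxygen percentage must be non-negative")
    out = calib.f1 / (1.0 + calib.Ksv * O2) + calib.f2
    return out if out.shape else float(out)


def sv_invert(R_over_R0, calib: SVCalibration):
    """Closed-form inverse of :func:`sv_forward` on the physical band.

    Returns O2 in %. Entries with R/R0 ≤ f2 (below the saturation floor,
    e.g. a bleached sensor) come back NaN; entries with R/R0 > 1 are
    clamped to 0% O2. Use :func:`ratios_to_oxygen` to keep the QC flags.
    """
    r = np.asarray(R_over_R0, dtype=float)
    out = np.empty_like(r)
    low = r <= calib.f2
    high = r > 1.0
    ok = ~low & ~high
    out[low] = np.nan
    out[high] = 0.0
    out[ok] = (calib.f1 / (r[ok] - calib.f2) - 1.0) / calib.Ksv
    return out if out.shape else float(out)


def calibrate(points, mode: str = "two_point", f1_fixed: float | None = 0.8,
              scope: str = "global") -> SVCalibration:
    """Fit Stern–Volmer parameters from (O2 %, R) calibration points.

    At least one point must be at 0% O2 — its (mean) R defines R0.
    ``two_point`` fixes f1 at ``f1_fixed`` and solves Ksv exactly from the
    highest-oxygen point; ``multi_point`` least-squares fits (f1, Ksv)
    jointly under the constraint f2 = 1 − f1 and needs ≥ 3 distinct levels.
    Replicate R values at the same level are averaged.
    """
    pts = [(float(o), float(r)) for o, r in points]
    if any(o < 0 for o, _ in pts):
        raise DomainError("calibration oxygen levels must be non-negative")
    zero_rs = [r for o, r in pts if o == 0.0]
    if not zero_rs:
        raise CalibrationError("calibration requires a 0% oxygen point (defines R0)")
    R0 = float(np.mean(zero_rs))
    levels: dict[float, list[float]] = {}
    for o, r in pts:
        levels.setdefault(o, []).append(r)
    o2 = np.array(sorted(levels))
    rr0 = np.array([np.mean(levels[o]) for o in o2]) / R0

    if mode == "two_point":
        if f1_fixed is None:
            raise CalibrationError(
                "two_point mode cannot identify f1 and Ksv from two levels; "
                "pass f1_fixed or use multi_point with >= 3 levels")
        nz = o2[o2 > 0]
        if nz.size == 0:
            raise CalibrationError("two_point mode needs a non-zero oxygen point")
        o_hi = float(nz[-1])
        r_hi = float(rr0[o2 == o_hi][0])
        f2 = 1.0 - f1_fixed
        if r_hi <= f2:
            raise CalibrationError(
                f"R/R0 at {o_hi}% lies at or below f2={f2}; incompatible with f1={f1_fixed}")
        Ksv = (f1_fixed / (r_hi - f2) - 1.0) / o_hi
        return SVCalibration(f1=f1_fixed, Ksv=Ksv, R0=R0, scope=scope,
                             residual_norm=0.0, n_points=len(pts))
    if mode == "multi_point":
        if o2.size < 3:
            raise CalibrationError("multi_point mode requires >= 3 distinct oxygen levels")

        def resid(theta):
            f1, ksv = theta
            return f1 / (1.0 + ksv * o2) + (1.0 - f1) - rr0

        fit = least_squares(resid, x0=[0.8, 0.05],
                            bounds=([1e-6, 1e-9], [1.0, np.inf]))
        f1, Ksv = fit.x
        return SVCalibration(f1=float(f1), Ksv=float(Ksv), R0=R0, scope=scope,
                             residual_norm=float(np.linalg.norm(fit.fun)),
                             n_points=len(pts))
    raise ConfigurationError(f"unknown calibration mode {mode!r}")


@dataclass
class RGBStack:
    """Time-indexed RGB image stack plus the sensor-section ROI table.

    ``frames`` is (T, H, W, 3) with channel order (red = oxygen-sensitive,
    green = reference, blue unused); ``roi_table`` is a DataFrame with
    columns (roi_id, x_px, y_px, radius_px, zone).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    roi_table: pd.DataFrame
    pixel_scale: float | None = None   # m/px, metadata

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise DataError(f"frames must be (T, H, W, 3), got {f.shape}")
        t = np.asarray(self.timestamps, dtype=float)
        if t.size != f.shape[0]:
            raise DataError("one timestamp per frame required")
        if np.any(np.diff(t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        missing = [c for c in ROI_TABLE_COLUMNS if c not in self.roi_table.columns]
        if missing:
            raise DataError(f"ROI table is missing columns {missing}")
        H, W = f.shape[1:3]
        tab = self.roi_table
        if np.any((tab.x_px - tab.radius_px < -0.5) | (tab.x_px + tab.radius_px > W - 0.5)
                  | (tab.y_px - tab.radius_px < -0.5) | (tab.y_px + tab.radius_px > H - 0.5)):
            raise DataError("ROI disks must lie within the image bounds")
        self.frames = f
        self.timestamps = t

    def roi_masks(self) -> dict[int, np.ndarray]:
        """Disk membership masks (pixel centre within radius, inclusive)."""
        H, W = self.frames.shape[1:3]
        yy, xx = np.mgrid[0:H, 0:W]
        masks = {}
        for row in self.roi_table.itertuples():
            masks[int(row.roi_id)] = ((xx - row.x_px) ** 2 + (yy - row.y_px) ** 2
                                      <= row.radius_px ** 2)
        return masks


@dataclass
class RatioSeries:
    """Per-ROI ratio R(t) and (after inversion) O2(t) with QC flags."""

    times: np.ndarray            # (T,)
    roi_ids: np.ndarray          # (n,)
    zones: np.ndarray            # (n,)
    R: np.ndarray                # (T, n)
    o2_percent: np.ndarray | None = None
    flags: np.ndarray = field(default=None)  # (T, n) int bit flags
    excluded_rois: frozenset = frozenset()

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(self.R.shape, dtype=int)

    def good(self) -> np.ndarray:
        """Boolean mask of entries usable for downstream zone statistics."""
        excl = np.isin(self.roi_ids, list(self.excluded_rois))
        return (self.flags == QCFlag.OK) & ~excl[None, :]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ti, t in enumerate(self.times):
            for k, rid in enumerate(self.roi_ids):
                rows.append({"time_s": t, "roi_id": int(rid),
                             "zone": int(self.zones[k]),
                             "R": self.R[ti, k],
                             "O2_percent": (np.nan if self.o2_percent is None
                                            else self.o2_percent[ti, k]),
                             "qc_flag": int(self.flags[ti, k])})
        return pd.DataFrame(rows)


def extract_ratios(stack: RGBStack) -> RatioSeries:
    """Per-frame, per-ROI ratio R = mean(red)/mean(green) over the disk.

    Channel means are taken before the ratio (not pixelwise ratios). A ROI
    frame whose green mean is zero is flagged, not fatal.
    """
    if len(stack.roi_table) == 0:
        raise DataError("ROI table is empty")
    masks = stack.roi_masks()
    roi_ids = np.array([int(r) for r in stack.roi_table.roi_id])
    zones = np.array([int(z) for z in stack.roi_table.zone])
    T = stack.frames.shape[0]
    R = np.full((T, roi_ids.size), np.nan)
    flags = np.zeros((T, roi_ids.size), dtype=int)
    red = stack.frames[..., 0].astype(float)
    green = stack.frames[..., 1].astype(float)
    for k, rid in enumerate(roi_ids):
        m = masks[rid]
        red_mean = red[:, m].mean(axis=1)
        green_mean = green[:, m].mean(axis=1)
        zero = green_mean == 0
        flags[zero, k] |= QCFlag.ZERO_REFERENCE
        with np.errstate(divide="ignore", invalid="ignore"):
            R[:, k] = np.where(zero, np.nan, red_mean / green_mean)
    return RatioSeries(times=stack.timestamps.copy(), roi_ids=roi_ids,
                       zones=zones, R=R, flags=flags)


def ratios_to_oxygen(ratios: RatioSeries,
                     calibs: dict[int, SVCalibration] | SVCalibration) -> RatioSeries:
    """Invert per-entry ratios to %O2, propagating QC flags.

    ``calibs`` is either one global calibration or a per-ROI mapping; ROIs
    missing from the mapping fall back to the ``'global'``-scoped entry
    with a warning.
    """
    import warnings as _warnings

    o2 = np.full_like(ratios.R, np.nan)
    flags = ratios.flags.copy()
    for k, rid in enumerate(ratios.roi_ids):
        if isinstance(calibs, SVCalibration):
            cal = calibs
        else:
            cal = calibs.get(int(rid))
            if cal is None:
                cal = calibs.get("global")
                if cal is None:
                    raise CalibrationError(
                        f"no calibration for ROI {rid} and no global fallback")
                _warnings.warn(f"ROI {rid}: falling back to global calibration",
                               stacklevel=2)
        rr0 = ratios.R[:, k] / cal.R0
        valid = ~np.isnan(rr0)
        low = valid & (rr0 <= cal.f2)
        high = valid & (rr0 > 1.0)
        flags[low, k] |= QCFlag.BELOW_BAND
        flags[high, k] |= QCFlag.CLAMPED_HIGH
        with np.errstate(invalid="ignore"):
            o2[valid, k] = sv_invert(rr0[valid], cal)
    return RatioSeries(times=ratios.times, roi_ids=ratios.roi_ids,
                       zones=ratios.zones, R=ratios.R, o2_percent=o2,
                       flags=flags, excluded_rois=ratios.excluded_rois)


def flag_bleached(series: RatioSeries, max_physical_O2: float = 19.0,
                  margin: float = 2.0, persistence: int = 3) -> RatioSeries:
    """Exclude ROIs reading supra-physical oxygen persistently.

    A ROI whose O2 exceeds ``max_physical_O2 + margin`` for at least
    ``persistence`` consecutive frames is excluded from downstream zone
    statistics (photobleached sensor signature); single-frame spikes are
    kept.
    """
    if series.o2_percent is None:
        raise DataError("flag_bleached requires O2 values; run ratios_to_oxygen first")
    over = series.o2_percent > (max_physical_O2 + margin)
    excluded = set(series.excluded_rois)
    flags = series.flags.copy()
    for k, rid in enumerate(series.roi_ids):
        run = best = 0
        for v in over[:, k]:
            run = run + 1 if v else 0
            best = max(best, run)
        if best >= persistence:
            excluded.add(int(rid))
            flags[:, k] |= QCFlag.BLEACHED_ROI
    return RatioSeries(times=series.times, roi_ids=series.roi_ids,
                       zones=series.zones, R=series.R,
                       o2_percent=series.o2_percent, flags=flags,
                       excluded_rois=frozenset(excluded))


def response_time(times_s: np.ndarray, values: np.ndarray,
                  fraction: float = 0.9, step_time: float | None = None,
                  plateau_frames: int = 3,
                  min_excursion: float = 0.0) -> float | None:
    """Step-response completion time in minutes.

    The start plateau is the mean of the first ``plateau_frames`` samples
    and the end plateau the mean of the last ``plateau_frames``; the
    response time is the interval from ``step_time`` (default: the first
    sample) until the signal first completes ``fraction`` of the
    plateau-to-plateau excursion, with linear interpolation between
    frames. Returns ``None`` when no step is detectable (excursion not
    larger than ``min_excursion``).
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise DataError("times and values must be equal-length, size >= 2")
    k = min(plateau_frames, max(1, t.size // 4))
    start = float(np.mean(v[:k]))
    end = float(np.mean(v[-k:]))
    excursion = end - start
    if abs(excursion) <= min_excursion or excursion == 0.0:
        return None
    target = start + fraction * excursion
    t0 = t[0] if step_time is None else step_time
    crossed = (v - target) * np.sign(excursion) >= 0
    idx = np.nonzero(crossed)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        t_cross = t[0]
    else:
        frac = (target - v[i - 1]) / (v[i] - v[i - 1])
        t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    return float((t_cross - t0) / 60.0)
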