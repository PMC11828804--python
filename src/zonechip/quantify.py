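"""Downstream biological quantification: viability, albumin RFU, zone stats.

Live/dead staining gives per-site counts of total nuclei (Hoechst, blue)
and dead cells (ethidium homodimer, red); viability is
(total − dead)/total × 100. Albumin immunostaining is quantified as
relative fluorescent units (RFU): the mean 8-bit grey value of the albumin
(red) channel divided by the mean of the nuclei (blue) channel per image,
which cancels common exposure scaling. Sites aggregate per zone as
mean ± sample SD, with a one-way ANOVA across zones (significance at
p < 0.05 in the study design).

Object counting thresholds are Otsu by default (the choice is documented
because counts are threshold-sensitive) with a fixed-value override.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import DataError, DomainError

__all__ = ["ChannelImageSet", "ZoneStats", "count_objects", "viability",
           "albumin_rfu", "zone_statistics", "as_8bit"]


@dataclass
class ChannelImageSet:
    """Registered single-channel images from one imaging site.

    ``red_role`` records whether the red channel carries the dead-cell
    stain or the albumin stain for this experiment.
    """

    blue: np.ndarray     # nuclei (Hoechst)
    green: np.ndarray    # live cells (calcein-AM)
    red: np.ndarray      # dead cells OR albumin, see red_role
    red_role: str        # "dead" | "albumin"
    zone: int
    site_index: int = 0

    def __post_init__(self):
        if self.red_role not in ("dead", "albumin"):
            raise DataError(f"red_role must be 'dead' or 'albumin', got {self.red_role!r}")
        if not (self.blue.shape == self.green.shape == self.red.shape):
            raise DataError("all channels must share one shape")


@dataclass
class ZoneStats:
    """Per-zone summary of a metric plus the across-zone ANOVA."""

    table: pd.DataFrame          # index zone, columns mean/sd/n
    anova_F: float | None
    anova_p: float | None
    note: str = ""

    def to_dict(self) -> dict:
        per_zone = {str(z): {"mean": float(r["mean"]), "sd": float(r["sd"]),
                             "n": int(r["n"])}
                    for z, r in self.table.iterrows()}
        return {"zones": per_zone, "anova_F": self.anova_F,
                "anova_p": self.anova_p, "note": self.note}


def as_8bit(img: np.ndarray) -> np.ndarray:
    """Convert a channel image to its 8-bit greyscale equivalent.

    uint8 passes through; other integer dtypes are scaled by the dtype
    range; floats are assumed already on a 0–255 scale.
    """
    if img.dtype == np.uint8:
        return img
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return (img.astype(float) * (255.0 / info.max)).astype(np.uint8)
    return np.clip(img, 0, 255).astype(np.uint8)


def count_objects(channel: np.ndarray, threshold: float | None = None,
                  min_area: int = 1) -> int:
    """Count connected bright objects in a single channel.

    Binary threshold (Otsu when ``threshold`` is None) → 8-connected
    component labelling → components of at least ``min_area`` pixels.
    A blank image counts zero.
    """
    img = np.asarray(channel)
    if img.size == 0:
        return 0
    if threshold is None:
        if np.all(img == img.flat[0]):
            return 0
        threshold = threshold_otsu(img)
    else:
        lo, hi = (np.iinfo(img.dtype).min, np.iinfo(img.dtype).max) \
            if np.issubdtype(img.dtype, np.integer) else (-np.inf, np.inf)
        if not (lo <= threshold <= hi):
            raise DomainError(f"threshold {threshold} outside dtype range [{lo}, {hi}]")
    binary = img > threshold
    if not np.any(binary):
        return 0
    labels = label(binary, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]
    return int(np.sum(areas >= min_area))


def viability(total_cells: int, dead_cells: int) -> float:
    """Viability (%) = (total − dead)/total × 100.

    Returns NaN for total = 0 (undefined); dead > total is a data error.
    """
    if total_cells < 0 or dead_cells < 0:
        raise DataError("cell counts must be non-negative")
    if dead_cells > total_cells:
        raise DataError(f"dead cells ({dead_cells}) exceed total ({total_cells})")
    if total_cells == 0:
        return float("nan")
    return (total_cells - dead_cells) / total_cells * 100.0


def albumin_rfu(site: ChannelImageSet) -> float:
    """Albumin RFU: mean 8-bit red (albumin) / mean 8-bit blue (nuclei).

    Returns NaN when the nuclei channel is empty (zero mean).
    """
    if site.red_role != "albumin":
        raise DataError("albumin_rfu requires a site whose red channel is albumin")
    red = as_8bit(site.red).astype(float)
    blue = as_8bit(site.blue).astype(float)
    blue_mean = blue.mean()
    if blue_mean == 0:
        return float("nan")
    return float(red.mean() / blue_mean)


def zone_statistics(values, zones) -> ZoneStats:
    """Per-zone mean ± SD (n−1 denominator) and one-way ANOVA across zones.

    With a single zone only the descriptive statistics are returned and the
    ANOVA is skipped with a notice.
    """
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    if values.size != zones.size or values.size == 0:
        raise DataError("values and zones must be non-empty and equal-length")
    df = pd.DataFrame({"zone": zones, "value": values})
    table = df.groupby("zone")["value"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    groups = [g.values for _, g in df.groupby("zone")["value"]]
    if len(groups) < 2:
        return ZoneStats(table=table, anova_F=None, anova_p=None,
                         note="single zone: ANOVA skipped")
    if any(len(g) < 2 for g in groups):
        raise DataError("ANOVA requires at least 2 values per zone")
    F, p = stats.f_oneway(*groups)
    return ZoneStats(table=table, anova_F=float(F), anova_p=float(p))
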