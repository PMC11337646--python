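"""ROI trait extraction: 33 vegetation-index medians over the whole ROI and
over the Otsu-masked canopy (66 spectral traits) plus 9 geometric traits
from the canopy height model.

Masking follows the OSAVI-Otsu recipe: compute OSAVI over the ROI, threshold
it with Otsu's method (256-bin histogram, maximizing between-class
variance), and call a pixel canopy when OSAVI exceeds the threshold.
Geometric traits are height percentiles (p50/p75/p95/p98), the ground area
below the p25/p50/p75 height percentiles, canopy volume (sum of pixel
heights x pixel area / ROI area) and the masked coverage fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu

from .indices import compute_vi, vi_names
from .scene import PlotScene, roi_pixel_mask

__all__ = [
    "GEOMETRIC_TRAITS",
    "trait_columns",
    "CanopyMask",
    "otsu_threshold",
    "canopy_mask",
    "spectral_traits",
    "geometric_traits",
    "TraitRecord",
    "extract_traits",
]

GEOMETRIC_TRAITS = (
    "height_p50",
    "height_p75",
    "height_p95",
    "height_p98",
    "area_below_p25",
    "area_below_p50",
    "area_below_p75",
    "canopy_volume",
    "coverage",
)

#: minimum masked pixels for a stable median; fewer is flagged low-support
LOW_SUPPORT_PIXELS = 10


def trait_columns(include_height_sd: bool = False) -> list[str]:
    """Fixed column order: 9 geometric, then 33 unmasked, then 33 masked."""
    cols = list(GEOMETRIC_TRAITS)
    if include_height_sd:
        cols.append("height_sd")
    cols += [f"{v}_median" for v in vi_names()]
    cols += [f"{v}_masked_median" for v in vi_names()]
    return cols


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu cut point of the ROI's OSAVI values (between-class variance
    maximized over a 256-bin histogram)."""
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < 2:
        raise ValueError("Otsu threshold undefined for a constant raster")
    return float(threshold_otsu(vals, nbins=nbins))


@dataclass
class CanopyMask:
    """Canopy/soil mask for one ROI: True where OSAVI > threshold."""

    mask: np.ndarray  # boolean, full raster shape; False outside the ROI
    otsu_threshold: float
    coverage: float  # masked pixels / ROI pixels

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


#: Otsu separability (between-class / total variance) below which the ROI
#: histogram is effectively unimodal.  A single Gaussian mode yields ~0.64
#: however it is split; genuine soil/plant mixtures on these scenes exceed
#: 0.90 even at 3% canopy cover or heavy senescence.
OTSU_SEPARABILITY_MIN = 0.8


def canopy_mask(scene: PlotScene, roi: Polygon) -> CanopyMask:
    """OSAVI -> Otsu -> mask for the ROI.

    A constant or effectively unimodal OSAVI field means there is nothing to
    separate (Otsu would bisect sensor noise): the ROI is treated as a
    single class — all-soil (coverage 0) when its OSAVI level sits below the
    soil/plant midpoint, all-canopy otherwise.
    """
    from .scene import soil_plant_osavi_midpoint

    in_roi = roi_pixel_mask(roi, scene.shape, scene.gsd)
    if not in_roi.any():
        raise ValueError("ROI does not intersect the scene")
    osavi = compute_vi(scene.bands, "OSAVI")
    vals = osavi[in_roi]
    vals = vals[np.isfinite(vals)]

    def single_class() -> CanopyMask:
        level = float(np.nanmedian(vals)) if vals.size else -np.inf
        if level > soil_plant_osavi_midpoint():
            return CanopyMask(in_roi.copy(), level, 1.0)
        return CanopyMask(np.zeros_like(in_roi), level, 0.0)

    try:
        thr = otsu_threshold(vals)
    except ValueError:
        return single_class()
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if lo.size and hi.size and vals.var() > 0:
        w0 = lo.size / vals.size
        eta = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2 / vals.var()
        if eta < OTSU_SEPARABILITY_MIN:
            return single_class()
    mask = in_roi & (osavi > thr)
    return CanopyMask(mask, thr, float(mask.sum() / in_roi.sum()))


def spectral_traits(scene: PlotScene, roi: Polygon, mask: CanopyMask) -> dict[str, float]:
    """Median of each of the 33 indices over all ROI pixels and over masked
    pixels only: 66 named values.  Masked medians are NaN at coverage 0."""
    in_roi = roi_pixel_mask(roi, scene.shape, scene.gsd)
    if not in_roi.any():
        raise ValueError("ROI does not intersect the scene")
    masked = mask.mask & in_roi
    out: dict[str, float] = {}
    for name in vi_names():
        vi = compute_vi(scene.bands, name)
        out[f"{name}_median"] = float(np.nanmedian(vi[in_roi]))
        if masked.any():
            out[f"{name}_masked_median"] = float(np.nanmedian(vi[masked]))
        else:
            out[f"{name}_masked_median"] = math.nan
    return out


def geometric_traits(chm: np.ndarray, roi: Polygon, mask: CanopyMask, gsd: float,
                     include_height_sd: bool = False) -> dict[str, float]:
    """The 9 geometric traits of one ROI.

    Percentiles use linear interpolation between order statistics.  The
    area-below traits count pixels strictly below the same-ROI percentile
    (so a constant canopy has area 0) times the pixel area.  Volume divides
    the summed pixel heights x pixel area by the ROI polygon area, so it
    equals mean pixel height when the ROI is pixel-aligned.
    """
    if gsd <= 0:
        raise ValueError("gsd must be > 0")
    in_roi = roi_pixel_mask(roi, chm.shape, gsd)
    if not in_roi.any():
        raise ValueError("ROI does not intersect the CHM")
    h = chm[in_roi].astype(float)
    p25, p50, p75, p95, p98 = np.percentile(h, [25, 50, 75, 95, 98])
    px_area = gsd * gsd
    out = {
        "height_p50": float(p50),
        "height_p75": float(p75),
        "height_p95": float(p95),
        "height_p98": float(p98),
        "area_below_p25": float(np.count_nonzero(h < p25) * px_area),
        "area_below_p50": float(np.count_nonzero(h < p50) * px_area),
        "area_below_p75": float(np.count_nonzero(h < p75) * px_area),
        "canopy_volume": float(h.sum() * px_area / roi.area),
        "coverage": mask.coverage,
    }
    if include_height_sd:
        out["height_sd"] = float(h.std(ddof=0))
    return out


@dataclass
class TraitRecord:
    """75 named trait values for one plot x date x ROI type."""

    plot_id: str
    date: date
    roi_type: str
    cut_number: int | None
    values: dict[str, float]
    otsu_threshold: float
    low_support: bool = False

    def __post_init__(self) -> None:
        expected = set(trait_columns()) | set(trait_columns(include_height_sd=True))
        extra = set(self.values) - expected
        if extra:
            raise ValueError(f"unexpected trait fields: {sorted(extra)}")

    def to_dict(self) -> dict:
        cols = trait_columns(include_height_sd="height_sd" in self.values)
        row = {
            "plot_id": self.plot_id,
            "date": self.date,
            "roi_type": self.roi_type,
            "cut_number": self.cut_number,
        }
        row.update({c: self.values[c] for c in cols})
        row["low_support"] = self.low_support
        return row


def extract_traits(scene: PlotScene, roi_type: str, cut_number: int | None = None,
                   include_height_sd: bool = False) -> TraitRecord:
    """OSAVI -> Otsu -> mask -> 66 spectral + 9 geometric traits for one ROI."""
    roi = scene.roi(roi_type, cut_number)
    mask = canopy_mask(scene, roi)
    values = geometric_traits(scene.chm, roi, mask, scene.gsd,
                              include_height_sd=include_height_sd)
    values.update(spectral_traits(scene, roi, mask))
    n_masked = int((mask.mask & roi_pixel_mask(roi, scene.shape, scene.gsd)).sum())
    return TraitRecord(
        plot_id=scene.plot_id,
        date=scene.date,
        roi_type=roi_type,
        cut_number=cut_number,
        values=values,
        otsu_threshold=mask.otsu_threshold,
        low_support=0 < n_masked < LOW_SUPPORT_PIXELS,
    )
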