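"""Plot-scene rendering: five-band reflectance rasters plus a canopy height
model (CHM) with known ground truth, and the two ROI types.

A scene is a two-component pixel mixture.  Each pixel is plant with
probability equal to the local green ground-cover fraction, otherwise soil.
Plant pixels get Gaussian-jittered heights around the plot's mean canopy
height and a plant reflectance spectrum that interpolates green -> senesced
with the senescence index; soil pixels sit at height ~0 with a fixed soil
spectrum.  Scene coordinates are metres, x along the plot length, pixel
centres at (col + 0.5) * gsd.

Two ROI rectangles per plot mirror field practice: ``roi_permanent`` is a
fixed, never-disturbed area at the plot end measured at every date, while
``roi_precise`` for cut k sits exactly over the k-th destructive quadrat.
They never overlap.  A heterogeneity knob imposes a smooth biomass gradient
along the plot so the two ROI types can be made to disagree by a controlled
amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import shapely
from shapely.geometry import Polygon, box

__all__ = ["PlotState", "PlotScene", "render_scene", "roi_pixel_mask"]

# reflectance spectra (blue, green, red, red_edge, nir)
SOIL_SPECTRUM = {"blue": 0.06, "green": 0.08, "red": 0.12, "red_edge": 0.16, "nir": 0.17}
GREEN_PLANT_SPECTRUM = {"blue": 0.03, "green": 0.09, "red": 0.04, "red_edge": 0.30, "nir": 0.48}
SENESCED_PLANT_SPECTRUM = {"blue": 0.10, "green": 0.16, "red": 0.22, "red_edge": 0.28, "nir": 0.33}

def soil_plant_ndvi_midpoint() -> float:
    """NDVI midpoint between the soil and green-plant spectra; pre-emergence
    scenes must stay below this for soil/plant separability."""
    nd = lambda s: (s["nir"] - s["red"]) / (s["nir"] + s["red"])
    return 0.5 * (nd(SOIL_SPECTRUM) + nd(GREEN_PLANT_SPECTRUM))


def soil_plant_osavi_midpoint() -> float:
    """Same midpoint on the OSAVI scale, used to resolve degenerate
    (constant-OSAVI) masking cases."""
    os = lambda s: 1.16 * (s["nir"] - s["red"]) / (s["nir"] + s["red"] + 0.16)
    return 0.5 * (os(SOIL_SPECTRUM) + os(GREEN_PLANT_SPECTRUM))


@dataclass
class PlotState:
    """Canopy state of one plot on one date (from :func:`simulate_growth`)."""

    plot_id: str
    date: date
    mean_height: float  # m
    green_fraction: float  # in [0, 1]
    senescence: float = 0.0  # 0 = fully green, 1 = fully senesced

    def __post_init__(self) -> None:
        if not 0.0 <= self.green_fraction <= 1.0:
            raise ValueError("green_fraction must lie in [0, 1]")
        if self.mean_height < 0:
            raise ValueError("mean_height must be >= 0")
        if not 0.0 <= self.senescence <= 1.0:
            raise ValueError("senescence must lie in [0, 1]")


@dataclass
class PlotScene:
    plot_id: str
    date: date
    gsd: float  # m / pixel
    bands: dict[str, np.ndarray]
    chm: np.ndarray
    roi_permanent: Polygon
    roi_precise: dict[int, Polygon]  # cut number -> polygon

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.bands.values()} | {self.chm.shape}
        if len(shapes) != 1:
            raise ValueError("all rasters must share one shape")
        if np.any(self.chm < 0):
            raise ValueError("canopy heights must be >= 0")
        footprint = box(0, 0, self.chm.shape[1] * self.gsd, self.chm.shape[0] * self.gsd)
        rois = [self.roi_permanent, *self.roi_precise.values()]
        for roi in rois:
            if not footprint.buffer(1e-9).contains(roi):
                raise ValueError("ROI outside plot footprint")
        for cut, roi in self.roi_precise.items():
            if roi.intersection(self.roi_permanent).area > 1e-12:
                raise ValueError(f"precise ROI for cut {cut} overlaps the permanent ROI")

    @property
    def shape(self) -> tuple[int, int]:
        return self.chm.shape

    def roi(self, roi_type: str, cut_number: int | None = None) -> Polygon:
        if roi_type == "permanent":
            return self.roi_permanent
        if roi_type == "precise":
            if cut_number is None:
                raise ValueError("precise ROI requires a cut number")
            if cut_number not in self.roi_precise:
                raise KeyError(f"no precise ROI for cut {cut_number}")
            return self.roi_precise[cut_number]
        raise ValueError("roi_type must be 'permanent' or 'precise'")


def roi_pixel_mask(poly: Polygon, shape: tuple[int, int], gsd: float) -> np.ndarray:
    """Boolean raster of pixels whose centres fall inside the polygon."""
    ny, nx = shape
    xs = (np.arange(nx) + 0.5) * gsd
    ys = (np.arange(ny) + 0.5) * gsd
    xx, yy = np.meshgrid(xs, ys)
    return shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(shape)


def _default_rois(plot_length: float, plot_width: float, n_cuts: int,
                  roi_size: float) -> tuple[Polygon, dict[int, Polygon]]:
    margin = 0.25 * roi_size
    y0 = (plot_width - roi_size) / 2
    permanent = box(margin, y0, margin + roi_size, y0 + roi_size)
    start = 2 * margin + roi_size
    slot = (plot_length - start - margin) / max(n_cuts, 1)
    if slot < roi_size:
        raise ValueError("plot too short for the requested number of precise ROIs")
    precise = {}
    for k in range(1, n_cuts + 1):
        x0 = start + (k - 1) * slot + (slot - roi_size) / 2
        precise[k] = box(x0, y0, x0 + roi_size, y0 + roi_size)
    return permanent, precise


def heterogeneity_profile(x: np.ndarray, plot_length: float, amount: float,
                          phase: float = 0.0) -> np.ndarray:
    """Smooth within-plot biomass multiplier along x, mean ~1, range ~1 +/- amount."""
    return 1.0 + amount * np.sin(2 * np.pi * x / plot_length + phase)


def render_scene(state: PlotState, gsd: float, seed: int, *,
                 plot_length: float = 8.0, plot_width: float = 2.0,
                 n_cuts: int = 5, roi_size: float = 1.0,
                 height_noise_sd: float = 0.05,
                 reflectance_noise_cv: float = 0.03,
                 heterogeneity: float = 0.0,
                 heterogeneity_phase: float = 0.0) -> PlotScene:
    """Render one plot x date into a :class:`PlotScene`.

    With default ``gsd = 1/64`` m the 1 m ROI squares are 64 x 64 pixels.
    Deterministic given ``seed``.
    """
    if gsd <= 0:
        raise ValueError("gsd must be > 0")
    rng = np.random.default_rng(seed)
    ny = int(round(plot_width / gsd))
    nx = int(round(plot_length / gsd))
    xs = (np.arange(nx) + 0.5) * gsd
    profile = heterogeneity_profile(xs, plot_length, heterogeneity, heterogeneity_phase)

    local_gf = np.clip(state.green_fraction * profile, 0.0, 1.0)  # per column
    local_h = np.maximum(state.mean_height * profile, 0.0)
    gf_map = np.broadcast_to(local_gf, (ny, nx))
    h_map = np.broadcast_to(local_h, (ny, nx))

    plant = rng.random((ny, nx)) < gf_map
    chm = np.where(
        plant,
        np.maximum(h_map + rng.normal(0.0, height_noise_sd, (ny, nx)), 0.0)
        if height_noise_sd > 0
        else h_map,
        0.0,
    )

    s = state.senescence
    plant_spec = {
        b: (1 - s) * GREEN_PLANT_SPECTRUM[b] + s * SENESCED_PLANT_SPECTRUM[b]
        for b in SOIL_SPECTRUM
    }
    bands = {}
    for b in SOIL_SPECTRUM:
        base = np.where(plant, plant_spec[b], SOIL_SPECTRUM[b])
        if reflectance_noise_cv > 0:
            base = base * (1.0 + rng.normal(0.0, reflectance_noise_cv, (ny, nx)))
        bands[b] = np.clip(base, 0.0, 1.0)

    roi_perm, roi_prec = _default_rois(plot_length, plot_width, n_cuts, roi_size)
    return PlotScene(
        plot_id=state.plot_id,
        date=state.date,
        gsd=gsd,
        bands=bands,
        chm=chm,
        roi_permanent=roi_perm,
        roi_precise=roi_prec,
    )
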