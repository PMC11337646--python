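"""File formats: multi-band TIFF scenes, GeoJSON ROIs, CSV tables.

Scenes are written as plain (ungeoreferenced) TIFFs in scene coordinates —
five reflectance bands in the order blue, green, red, red_edge, nir, the CHM
as a separate single-band file — with the ground sample distance and band
order stored as JSON in the image description tag.  ROIs are GeoJSON
polygons in the same metre coordinate system.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .design import TrialDesign
from .growth import BiomassCut, WeatherSeries
from .indices import BANDS
from .scene import PlotScene

__all__ = [
    "write_scene",
    "read_scene",
    "write_rois",
    "read_rois",
    "write_weather_csv",
    "read_weather_csv",
    "write_cuts_csv",
    "read_cuts_csv",
    "write_design_csv",
    "read_design_csv",
]


def write_scene(scene: PlotScene, directory: str | Path) -> dict[str, Path]:
    """Write bands.tif (5 bands), chm.tif and rois.geojson; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "plot_id": scene.plot_id,
        "date": scene.date.isoformat(),
        "gsd": scene.gsd,
        "bands": list(BANDS),
    }
    bands_path = directory / "bands.tif"
    stack = np.stack([scene.bands[b] for b in BANDS]).astype(np.float32)
    tifffile.imwrite(bands_path, stack, description=json.dumps(meta))
    chm_path = directory / "chm.tif"
    tifffile.imwrite(chm_path, scene.chm.astype(np.float32),
                     description=json.dumps({**meta, "layer": "chm"}))
    roi_path = directory / "rois.geojson"
    write_rois(scene.roi_permanent, scene.roi_precise, roi_path)
    return {"bands": bands_path, "chm": chm_path, "rois": roi_path}


def read_scene(directory: str | Path) -> PlotScene:
    directory = Path(directory)
    with tifffile.TiffFile(directory / "bands.tif") as tf:
        meta = json.loads(tf.pages[0].description)
        stack = tf.asarray()
    chm = tifffile.imread(directory / "chm.tif")
    permanent, precise = read_rois(directory / "rois.geojson")
    return PlotScene(
        plot_id=meta["plot_id"],
        date=date.fromisoformat(meta["date"]),
        gsd=float(meta["gsd"]),
        bands={b: stack[i].astype(float) for i, b in enumerate(meta["bands"])},
        chm=chm.astype(float),
        roi_permanent=permanent,
        roi_precise=precise,
    )


def write_rois(permanent: Polygon, precise: dict[int, Polygon], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"roi_type": "permanent"},
            "geometry": mapping(permanent),
        }
    ]
    for cut, poly in sorted(precise.items()):
        features.append(
            {
                "type": "Feature",
                "properties": {"roi_type": "precise", "cut_number": cut},
                "geometry": mapping(poly),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_rois(path: str | Path) -> tuple[Polygon, dict[int, Polygon]]:
    fc = json.loads(Path(path).read_text())
    permanent = None
    precise: dict[int, Polygon] = {}
    for feat in fc["features"]:
        poly = shape(feat["geometry"])
        props = feat.get("properties", {})
        if props.get("roi_type") == "permanent":
            permanent = poly
        elif props.get("roi_type") == "precise":
            precise[int(props["cut_number"])] = poly
    if permanent is None:
        raise ValueError(f"no permanent ROI in {path}")
    return permanent, precise


def write_weather_csv(weather: WeatherSeries, path: str | Path) -> None:
    weather.frame.to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> WeatherSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return WeatherSeries(df)


def write_cuts_csv(cuts: list[BiomassCut], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plot_id": c.plot_id,
                "date": c.date.isoformat(),
                "cut_number": c.cut_number,
                "fw_quad": c.fw_quad,
                "fw_sub": c.fw_sub,
                "dw_sub": c.dw_sub,
                "quad_area": c.quad_area,
            }
            for c in cuts
        ]
    ).to_csv(path, index=False)


def read_cuts_csv(path: str | Path) -> list[BiomassCut]:
    df = pd.read_csv(path, parse_dates=["date"])
    return [
        BiomassCut(
            plot_id=str(r.plot_id),
            date=r.date.date(),
            cut_number=int(r.cut_number),
            fw_quad=float(r.fw_quad),
            fw_sub=float(r.fw_sub),
            dw_sub=float(r.dw_sub),
            quad_area=float(r.quad_area),
        )
        for r in df.itertuples()
    ]


def write_design_csv(design: TrialDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design_csv(path: str | Path) -> TrialDesign:
    return TrialDesign.from_frame(pd.read_csv(path))
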