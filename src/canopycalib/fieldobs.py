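"""Ground-truth processing: quadrat dry-weight arithmetic, cumulative
thermal time, and broad growth-stage classification."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .growth import BiomassCut, WeatherSeries

__all__ = [
    "compute_dw_agb",
    "cumulative_thermal_time",
    "StageBoundaries",
    "classify_stage",
]

STAGES = ("vegetative", "flowering", "grain_fill")


def compute_dw_agb(cut: BiomassCut) -> float:
    """Dry weight of aboveground biomass, g/m^2.

    DW_AGB = FW_quad * (DW_sub / FW_sub) / Quad_area.  An empty quadrat
    (FW_quad = 0) is 0 g/m^2; FW_sub = 0 with material in the quadrat leaves
    the dry:fresh ratio undefined.
    """
    if cut.fw_quad == 0:
        return 0.0
    if cut.fw_sub == 0:
        raise ZeroDivisionError("FW_sub = 0 with FW_quad > 0: dry:fresh ratio undefined")
    return cut.fw_quad * (cut.dw_sub / cut.fw_sub) / cut.quad_area


def cumulative_thermal_time(weather: WeatherSeries, sowing_date: date,
                            base_temp: float = 0.0) -> pd.DataFrame:
    """Running sum from sowing of max(0, (tmin+tmax)/2 - base_temp), degC day.

    The base temperature defaults to the standard wheat convention of 0 degC
    and is configurable.  Returns columns ``date, tt`` for every day from
    sowing to the end of weather coverage.
    """
    df = weather.frame
    if sowing_date < weather.start or sowing_date > weather.end:
        raise ValueError("sowing_date outside weather coverage")
    sel = df[df["date"] >= sowing_date].reset_index(drop=True)
    daily = np.maximum(0.0, (sel["tmin"].to_numpy() + sel["tmax"].to_numpy()) / 2 - base_temp)
    return pd.DataFrame({"date": sel["date"], "tt": np.cumsum(daily)})


@dataclass(frozen=True)
class StageBoundaries:
    """Thermal-time cut points between broad stages (degC day).

    ``tt_veg_flower`` is where the fitted phenology curve reaches Zadoks 50
    (head emergence), ``tt_flower_grainfill`` where it reaches 70 (start of
    grain development).
    """

    tt_veg_flower: float
    tt_flower_grainfill: float

    def __post_init__(self) -> None:
        if not (0 < self.tt_veg_flower < self.tt_flower_grainfill):
            raise ValueError("need 0 < tt_veg_flower < tt_flower_grainfill")


def classify_stage(tt, boundaries: StageBoundaries):
    """Broad stage for thermal time ``tt`` (scalar or array).

    Boundaries are inclusive on the earlier stage: tt <= tt_veg_flower is
    vegetative, tt <= tt_flower_grainfill is flowering, else grain_fill.
    """
    tt_arr = np.asarray(tt, dtype=float)
    if np.any(tt_arr < 0):
        raise ValueError("thermal time must be >= 0")
    out = np.where(
        tt_arr <= boundaries.tt_veg_flower,
        "vegetative",
        np.where(tt_arr <= boundaries.tt_flower_grainfill, "flowering", "grain_fill"),
    )
    return out.item() if np.isscalar(tt) or np.ndim(tt) == 0 else out
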