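"""Growth dynamics: weather, thermal-time driven biomass trajectories and
destructive quadrat sampling.

Plot biomass follows a logistic curve in cumulative thermal time (TT),

    DW(tt) = A_g * d * [1 + a * f(row, col)] / (1 + exp(-r (tt - t_i))) * eps,

with genotype asymptote ``A_g`` (g/m^2), a density multiplier ``d``, a smooth
spatial field ``f`` over the trial grid scaled by the relative trend
amplitude ``a``, inflection ``t_i`` (degC day), rate ``r`` (1/degC day) and a
lognormal plot-level residual ``eps`` with coefficient of variation
``residual_cv``.  Canopy state (mean height, green ground-cover fraction and
a senescence index) is derived monotonically from biomass, with greenness
declining after ``senescence_onset_tt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .design import TrialDesign

__all__ = [
    "WeatherSeries",
    "synthetic_weather",
    "GrowthParams",
    "simulate_growth",
    "BiomassCut",
    "sample_biomass",
]


@dataclass
class WeatherSeries:
    """Daily weather; dates contiguous, tmax >= tmin."""

    frame: pd.DataFrame  # columns: date, tmin, tmax, rain, irrigation

    def __post_init__(self) -> None:
        df = self.frame
        required = {"date", "tmin", "tmax"}
        if not required.issubset(df.columns):
            raise ValueError(f"weather needs columns {sorted(required)}")
        if (df["tmax"] < df["tmin"]).any():
            raise ValueError("tmax < tmin in weather series")
        d = pd.to_datetime(df["date"])
        if len(d) > 1 and not (d.diff().dropna() == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates must be contiguous daily")
        self.frame = df.assign(date=d.dt.date).reset_index(drop=True)

    @property
    def start(self) -> date:
        return self.frame["date"].iloc[0]

    @property
    def end(self) -> date:
        return self.frame["date"].iloc[-1]


def synthetic_weather(start: date, n_days: int, seed: int,
                      tmean_start: float = 12.0, tmean_end: float = 22.0,
                      diurnal_range: float = 10.0, noise_sd: float = 1.5) -> WeatherSeries:
    """Winter-to-spring season: mean temperature ramps up over the season
    with day-to-day Gaussian variation."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_days)
    tmean = tmean_start + (tmean_end - tmean_start) * t + rng.normal(0, noise_sd, n_days)
    tmin = tmean - diurnal_range / 2
    tmax = tmean + diurnal_range / 2
    rain = np.where(rng.random(n_days) < 0.15, rng.gamma(2.0, 4.0, n_days), 0.0)
    frame = pd.DataFrame(
        {
            "date": [start + timedelta(days=int(i)) for i in range(n_days)],
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
            "rain": np.round(rain, 2),
            "irrigation": 0.0,
        }
    )
    return WeatherSeries(frame)


@dataclass
class GrowthParams:
    """Parameters of the logistic biomass model.

    ``biomass_asymptote`` maps genotype -> final biomass (g/m^2); genotypes
    missing from the map fall back to ``default_asymptote``.
    ``density_effect`` maps sowing density (plants/m) -> multiplier on
    attained biomass; unseen densities interpolate linearly between the
    mapped ones.  ``spatial_trend_amplitude`` is in g/m^2 and is applied
    relative to the mean asymptote so the trend scales with crop size.
    """

    biomass_asymptote: dict[str, float] = field(default_factory=dict)
    default_asymptote: float = 1400.0
    tt_inflection: float = 1100.0
    growth_rate: float = 0.004
    density_effect: dict[float, float] = field(
        default_factory=lambda: {75.0: 0.85, 150.0: 1.0, 225.0: 1.1, 300.0: 1.15}
    )
    spatial_trend_amplitude: float = 0.0
    residual_cv: float = 0.0
    senescence_onset_tt: float = 1600.0
    senescence_ramp_tt: float = 600.0
    max_height: float = 1.0  # m, canopy height at the asymptote
    height_half_dw: float = 250.0  # g/m^2 at which height reaches half max
    cover_scale_dw: float = 300.0  # g/m^2 e-folding scale of ground cover
    within_plot_heterogeneity: float = 0.0  # relative biomass gradient inside a plot

    def __post_init__(self) -> None:
        if self.default_asymptote <= 0 or any(v <= 0 for v in self.biomass_asymptote.values()):
            raise ValueError("biomass asymptote must be > 0")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")

    def asymptote(self, genotype: str) -> float:
        return self.biomass_asymptote.get(genotype, self.default_asymptote)

    def density_multiplier(self, density: float) -> float:
        if not self.density_effect:
            return 1.0
        keys = np.array(sorted(self.density_effect))
        vals = np.array([self.density_effect[k] for k in keys])
        return float(np.interp(density, keys, vals))


def default_genotype_asymptotes(genotypes: list[str], seed: int,
                                mean: float = 1400.0, cv: float = 0.10) -> dict[str, float]:
    """Draw per-genotype asymptotes (lognormal around ``mean``); the spread
    is the genetic signal the repeatability stage recovers."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    draws = mean * np.exp(rng.normal(-sigma**2 / 2, sigma, len(genotypes)))
    return {g: float(a) for g, a in zip(sorted(genotypes), draws)}


def _spatial_field(row: np.ndarray, col: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    """Smooth low-order field over the grid, range roughly [-1, 1]."""
    r = (row - 1) / max(n_rows - 1, 1)
    c = (col - 1) / max(n_cols - 1, 1)
    return 0.6 * np.sin(np.pi * c) * np.cos(0.5 * np.pi * r) + 0.4 * (r - 0.5) * (c - 0.5) * 4


def _logistic(tt: np.ndarray, t_i: float, r: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-r * (np.asarray(tt, dtype=float) - t_i)))


def green_fraction_curve(dw: np.ndarray, tt: np.ndarray, params: GrowthParams) -> np.ndarray:
    cover = 1.0 - np.exp(-np.asarray(dw, dtype=float) / params.cover_scale_dw)
    sen = np.clip(
        (np.asarray(tt, dtype=float) - params.senescence_onset_tt) / params.senescence_ramp_tt,
        0.0,
        1.0,
    )
    return np.clip(cover * (1.0 - sen), 0.0, 1.0)


def simulate_growth(design: TrialDesign, weather: WeatherSeries, params: GrowthParams,
                    seed: int, sowing_date: date, dates: list[date],
                    base_temp: float = 0.0) -> pd.DataFrame:
    """Per plot x date canopy state with known ground truth.

    Returns a frame with columns ``experiment, plot_id, row, column, genotype,
    density, date, tt, dw_agb, mean_height, green_fraction, senescence``.
    ``dw_agb`` carries the spatial trend and the lognormal residual;
    ``mean_height`` and ``green_fraction`` are monotone functions of the
    residual-free biomass so canopy geometry tracks the true signal.
    """
    from .fieldobs import cumulative_thermal_time

    for d in dates:
        if d < weather.start or d > weather.end:
            raise ValueError(f"date {d} outside weather coverage")
        if d < sowing_date:
            raise ValueError(f"date {d} before sowing {sowing_date}")

    tt_series = cumulative_thermal_time(weather, sowing_date, base_temp=base_temp)
    tt_map = dict(zip(tt_series["date"], tt_series["tt"]))

    rng = np.random.default_rng(seed)
    n_rows = max(p.row for p in design.plots)
    n_cols = max(p.column for p in design.plots)
    rows = np.array([p.row for p in design.plots], dtype=float)
    cols = np.array([p.column for p in design.plots], dtype=float)
    trend = _spatial_field(rows, cols, n_rows, n_cols)
    mean_asym = float(np.mean([params.asymptote(p.genotype) for p in design.plots]))
    rel_amp = params.spatial_trend_amplitude / mean_asym

    sigma = np.sqrt(np.log1p(params.residual_cv**2))
    # one residual per plot x date, drawn up-front for determinism
    resid = np.exp(rng.normal(-sigma**2 / 2, sigma, (len(design.plots), len(dates))))
    if params.residual_cv == 0:
        resid[:] = 1.0

    records = []
    for i, p in enumerate(design.plots):
        a = params.asymptote(p.genotype) * params.density_multiplier(p.density)
        a_plot = a * (1.0 + rel_amp * trend[i])
        for j, d in enumerate(dates):
            tt = float(tt_map[d])
            dw_clean = a_plot * float(_logistic(tt, params.tt_inflection, params.growth_rate))
            dw = dw_clean * resid[i, j]
            height = params.max_height * dw_clean / (dw_clean + params.height_half_dw)
            gf = float(green_fraction_curve(np.array(dw_clean), np.array(tt), params))
            sen = float(
                np.clip((tt - params.senescence_onset_tt) / params.senescence_ramp_tt, 0.0, 1.0)
            )
            records.append(
                {
                    "experiment": design.experiment_id,
                    "plot_id": p.plot_id,
                    "row": p.row,
                    "column": p.column,
                    "genotype": p.genotype,
                    "density": p.density,
                    "date": d,
                    "tt": tt,
                    "dw_agb": dw,
                    "mean_height": height,
                    "green_fraction": gf,
                    "senescence": sen,
                }
            )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class BiomassCut:
    """Quadrat cut record: fresh weight of the whole quadrat, fresh and dry
    weights of a subsample, and the quadrat area."""

    plot_id: str
    date: date
    cut_number: int
    fw_quad: float  # g
    fw_sub: float  # g
    dw_sub: float  # g
    quad_area: float  # m^2

    def __post_init__(self) -> None:
        if self.quad_area <= 0:
            raise ValueError("quad_area must be > 0")
        if not (0 <= self.dw_sub <= self.fw_sub or (self.fw_sub == 0 and self.dw_sub == 0)):
            raise ValueError("need 0 <= dw_sub <= fw_sub")
        if self.fw_quad < 0:
            raise ValueError("fw_quad must be >= 0")


def sample_biomass(true_dw_agb: float, quad_area: float, noise_cv: float, seed: int,
                   plot_id: str = "plot", when: date | None = None,
                   cut_number: int = 1) -> BiomassCut:
    """Emit a quadrat record whose dry-weight arithmetic recovers
    ``true_dw_agb`` up to a mean-one lognormal measurement factor."""
    if quad_area <= 0:
        raise ValueError("quad_area must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factor = float(np.exp(rng.normal(-sigma**2 / 2, sigma)))
    else:
        factor = 1.0
    ratio = float(rng.uniform(0.15, 0.40))  # dry:fresh ratio of wheat herbage
    dw_area = true_dw_agb * factor  # g/m^2 measured
    fw_quad = dw_area * quad_area / ratio
    fw_sub = min(fw_quad, 120.0) if fw_quad > 0 else 0.0  # ~20-stem subsample
    dw_sub = ratio * fw_sub
    when = when or date(2020, 1, 1)
    return BiomassCut(plot_id, when, cut_number, fw_quad, fw_sub, dw_sub, quad_area)
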