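"""Registry of the 33 vegetation indices used as spectral traits.

Each index is a pixel-wise function of the five reflectance bands (blue,
green, red, red_edge, nir; reflectance in [0, 1]).  The registry is data:
one auditable table mapping the field abbreviation to its canonical
literature formula.  Every formula here is finite on strictly positive
reflectances (denominators are positive sums, positive constants, or plain
ratios of positive bands).

OSAVI doubles as the masking channel for canopy/soil separation and GSAVI,
NDVI, NDRE etc. are the usual greenness / red-edge chlorophyll proxies.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping

import numpy as np

__all__ = ["BANDS", "VI_REGISTRY", "compute_vi", "vi_names"]

BANDS = ("blue", "green", "red", "red_edge", "nir")

Arr = np.ndarray
VIFunc = Callable[[Arr, Arr, Arr, Arr, Arr], Arr]


def _nd(a: Arr, b: Arr) -> Arr:
    return (a - b) / (a + b)


# name -> (function(blue, green, red, red_edge, nir), long name)
VI_REGISTRY: Mapping[str, tuple[VIFunc, str]] = {
    "NDVI": (lambda b, g, r, re, n: _nd(n, r), "Normalized difference vegetation index"),
    "GNDVI": (lambda b, g, r, re, n: _nd(n, g), "Green NDVI"),
    "NDRE": (lambda b, g, r, re, n: _nd(n, re), "Normalized difference red edge"),
    "BNDVI": (lambda b, g, r, re, n: _nd(n, b), "Blue NDVI"),
    "OSAVI": (
        lambda b, g, r, re, n: 1.16 * (n - r) / (n + r + 0.16),
        "Optimized soil-adjusted vegetation index",
    ),
    "GOSAVI": (
        lambda b, g, r, re, n: (n - g) / (n + g + 0.16),
        "Green optimized soil-adjusted vegetation index",
    ),
    "SAVI": (
        lambda b, g, r, re, n: 1.5 * (n - r) / (n + r + 0.5),
        "Soil-adjusted vegetation index",
    ),
    "GSAVI": (
        lambda b, g, r, re, n: 1.5 * (n - g) / (n + g + 0.5),
        "Green soil-adjusted vegetation index",
    ),
    "MSAVI": (
        lambda b, g, r, re, n: 0.5 * (2 * n + 1 - np.sqrt((2 * n + 1) ** 2 - 8 * (n - r))),
        "Modified soil-adjusted vegetation index",
    ),
    "EVI2": (
        lambda b, g, r, re, n: 2.5 * (n - r) / (n + 2.4 * r + 1),
        "Two-band enhanced vegetation index",
    ),
    "WDRVI": (
        lambda b, g, r, re, n: (0.12 * n - r) / (0.12 * n + r),
        "Wide dynamic range vegetation index",
    ),
    "SR": (lambda b, g, r, re, n: n / r, "Simple ratio (NIR/red)"),
    "GRVI": (lambda b, g, r, re, n: n / g, "Green ratio vegetation index (NIR/green)"),
    "RERVI": (lambda b, g, r, re, n: n / re, "Red-edge ratio vegetation index"),
    "CIgreen": (lambda b, g, r, re, n: n / g - 1.0, "Green chlorophyll index"),
    "CIrededge": (lambda b, g, r, re, n: n / re - 1.0, "Red-edge chlorophyll index"),
    "DVI": (lambda b, g, r, re, n: n - r, "Difference vegetation index"),
    "GDVI": (lambda b, g, r, re, n: n - g, "Green difference vegetation index"),
    "REDVI": (lambda b, g, r, re, n: n - re, "Red-edge difference vegetation index"),
    "RDVI": (
        lambda b, g, r, re, n: (n - r) / np.sqrt(n + r),
        "Renormalized difference vegetation index",
    ),
    "MSR": (
        lambda b, g, r, re, n: (n / r - 1.0) / np.sqrt(n / r + 1.0),
        "Modified simple ratio",
    ),
    "NLI": (
        lambda b, g, r, re, n: (n**2 - r) / (n**2 + r),
        "Non-linear vegetation index",
    ),
    "TVI": (
        lambda b, g, r, re, n: 0.5 * (120 * (n - g) - 200 * (r - g)),
        "Triangular vegetation index",
    ),
    "MCARI": (
        lambda b, g, r, re, n: ((re - r) - 0.2 * (re - g)) * (re / r),
        "Modified chlorophyll absorption ratio index",
    ),
    "TCARI": (
        lambda b, g, r, re, n: 3 * ((re - r) - 0.2 * (re - g) * (re / r)),
        "Transformed chlorophyll absorption ratio index",
    ),
    "NGRDI": (lambda b, g, r, re, n: _nd(g, r), "Normalized green-red difference index"),
    "MGRVI": (
        lambda b, g, r, re, n: (g**2 - r**2) / (g**2 + r**2),
        "Modified green-red vegetation index",
    ),
    "NGBDI": (lambda b, g, r, re, n: _nd(g, b), "Normalized green-blue difference index"),
    "RGBVI": (
        lambda b, g, r, re, n: (g**2 - b * r) / (g**2 + b * r),
        "Red-green-blue vegetation index",
    ),
    "GLI": (
        lambda b, g, r, re, n: (2 * g - r - b) / (2 * g + r + b),
        "Green leaf index",
    ),
    "ExG": (lambda b, g, r, re, n: 2 * g - r - b, "Excess green index"),
    "ExGR": (
        lambda b, g, r, re, n: (2 * g - r - b) - (1.4 * r - g),
        "Excess green minus excess red",
    ),
    "GRRI": (lambda b, g, r, re, n: g / r, "Green-red ratio index"),
}

assert len(VI_REGISTRY) == 33, "registry must hold exactly 33 indices"
assert "OSAVI" in VI_REGISTRY


def vi_names() -> list[str]:
    """Registry order, fixed for reproducible column layouts."""
    return list(VI_REGISTRY)


def compute_vi(bands: Mapping[str, Arr], name: str) -> Arr:
    """Pixel-wise index raster from co-registered band rasters.

    Non-finite pixels (e.g. zero-reflectance soil artefacts) are returned as
    NaN and excluded from medians downstream.
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}; known: {sorted(VI_REGISTRY)}")
    missing = [b for b in BANDS if b not in bands]
    if missing:
        raise ValueError(f"missing bands {missing}")
    arrs = [np.asarray(bands[b], dtype=float) for b in BANDS]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"bands not co-registered: shapes {shapes}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = VI_REGISTRY[name][0](*arrs)
    return np.where(np.isfinite(out), out, np.nan)
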