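"""Phenology model: trial-mean Zadoks score as a penalized cubic spline in
cumulative thermal time.

The model is Y = beta0 + f(TT) + eps with f a cubic B-spline smooth on 10
equally spaced knots and a second-order difference penalty on the basis
coefficients; the penalty strength is chosen by generalized cross-validation
(GCV).  Follows the Model/fit()/Results convention: build a
:class:`PhenologyModel` from observations, call :meth:`~PhenologyModel.fit`,
and query the returned :class:`PhenologyResults` for predictions, stage
boundaries and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq

from .fieldobs import StageBoundaries

__all__ = [
    "PhenologyModel",
    "PhenologyResults",
    "zadoks_curve",
    "simulate_zadoks_observations",
]

ZADOKS_MIN, ZADOKS_MAX = 0.0, 99.0


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int = 3):
    """Open (clamped) knot vector on the given interior knot sequence."""
    t = np.concatenate(
        [np.repeat(knots[0], degree), knots, np.repeat(knots[-1], degree)]
    )
    x = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(x, t, degree).toarray(), t


class PhenologyModel:
    """Penalized-spline regression of trial-mean Zadoks score on thermal time.

    Parameters
    ----------
    tt : array
        Cumulative thermal time of each observation (degC day).
    zadoks : array
        Trial-mean Zadoks score (0-99) at each thermal time.
    n_knots : int
        Number of equally spaced knots spanning the observed TT range.
    """

    def __init__(self, tt, zadoks, n_knots: int = 10, degree: int = 3):
        tt = np.asarray(tt, dtype=float)
        z = np.asarray(zadoks, dtype=float)
        if tt.shape != z.shape or tt.ndim != 1:
            raise ValueError("tt and zadoks must be 1-D arrays of equal length")
        if np.unique(tt).size <= n_knots:
            raise ValueError(
                f"need more than {n_knots} distinct thermal-time values, "
                f"got {np.unique(tt).size}"
            )
        order = np.argsort(tt)
        self.tt = tt[order]
        self.zadoks = z[order]
        self.n_knots = n_knots
        self.degree = degree
        self.knots = np.linspace(self.tt[0], self.tt[-1], n_knots)

    def fit(self, lam: float | None = None,
            lam_grid: np.ndarray | None = None) -> "PhenologyResults":
        """Fit by penalized least squares; ``lam=None`` selects the penalty
        by GCV over a log-spaced grid."""
        B, t = _bspline_design(self.tt, self.knots, self.degree)
        n, k = B.shape
        D = np.diff(np.eye(k), n=2, axis=0)
        P = D.T @ D
        BtB = B.T @ B
        Btz = B.T @ self.zadoks

        def solve(l: float):
            coef = np.linalg.solve(BtB + l * P, Btz)
            fitted = B @ coef
            # effective dof: trace of the smoother matrix
            edof = np.trace(np.linalg.solve(BtB + l * P, BtB))
            return coef, fitted, edof

        if lam is None:
            if lam_grid is None:
                lam_grid = np.logspace(-4, 6, 41)
            best = (np.inf, None)
            for l in lam_grid:
                _, fitted, edof = solve(l)
                rss = float(np.sum((self.zadoks - fitted) ** 2))
                denom = max(n - edof, 1e-8)
                gcv = n * rss / denom**2
                if gcv < best[0]:
                    best = (gcv, l)
            lam = float(best[1])
        coef, fitted, edof = solve(lam)
        rss = float(np.sum((self.zadoks - fitted) ** 2))
        scale = np.sqrt(rss / max(n - edof, 1.0))
        return PhenologyResults(self, coef, t, float(lam), float(edof), float(scale))


@dataclass
class PhenologyResults:
    model: PhenologyModel
    coef: np.ndarray
    knot_vector: np.ndarray
    lam: float
    edof: float
    scale: float

    @property
    def spline(self) -> BSpline:
        return BSpline(self.knot_vector, self.coef, self.model.degree, extrapolate=False)

    def predict(self, tt) -> np.ndarray:
        """Predicted Zadoks score, clamped to the 0-99 scale and to the
        observed TT range."""
        tt = np.asarray(tt, dtype=float)
        x = np.clip(tt, self.model.knots[0], self.model.knots[-1])
        return np.clip(self.spline(x), ZADOKS_MIN, ZADOKS_MAX)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.tt)

    def solve_crossing(self, score: float, tol: float = 0.5) -> float:
        """Smallest TT in the observed range where the fitted curve reaches
        ``score``; bisection to ``tol`` degC day."""
        lo, hi = self.model.knots[0], self.model.knots[-1]
        grid = np.linspace(lo, hi, 2048)
        vals = self.predict(grid) - score
        if vals[0] >= 0:
            return float(lo)
        idx = np.nonzero(vals >= 0)[0]
        if idx.size == 0:
            raise ValueError(f"fitted curve never reaches Zadoks {score}")
        i = idx[0]
        f = lambda x: float(self.predict(x) - score)
        return float(brentq(f, grid[i - 1], grid[i], xtol=tol))

    def solve_stage_boundaries(self, tol: float = 0.5) -> StageBoundaries:
        """Thermal time at the Zadoks 50 and 70 crossings."""
        return StageBoundaries(
            tt_veg_flower=self.solve_crossing(50.0, tol),
            tt_flower_grainfill=self.solve_crossing(70.0, tol),
        )

    def plot(self, ax=None):
        """Observations, fitted curve and solved stage boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.tt, self.model.zadoks, s=14, color="0.4",
                   label="trial-mean Zadoks")
        grid = np.linspace(self.model.knots[0], self.model.knots[-1], 400)
        ax.plot(grid, self.predict(grid), color="C2", label="spline fit")
        try:
            b = self.solve_stage_boundaries()
            for x, lbl in ((b.tt_veg_flower, "Zadoks 50"),
                           (b.tt_flower_grainfill, "Zadoks 70")):
                ax.axvline(x, ls="--", color="C3", lw=1)
                ax.annotate(lbl, (x, 5), rotation=90, fontsize=8)
        except ValueError:
            pass
        ax.set_xlabel("cumulative thermal time (degC day)")
        ax.set_ylabel("Zadoks score")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        lines = [
            "Phenology spline (Zadoks ~ s(TT))",
            "=" * 40,
            f"n obs            {self.model.tt.size:>10d}",
            f"knots            {self.model.n_knots:>10d}",
            f"penalty (GCV)    {self.lam:>10.4g}",
            f"effective dof    {self.edof:>10.2f}",
            f"residual scale   {self.scale:>10.2f}",
        ]
        try:
            b = self.solve_stage_boundaries()
            lines += [
                f"Zadoks 50 at TT  {b.tt_veg_flower:>10.1f} degC day",
                f"Zadoks 70 at TT  {b.tt_flower_grainfill:>10.1f} degC day",
            ]
        except ValueError:
            lines += ["stage boundaries not reached in observed range"]
        return "\n".join(lines)


def zadoks_curve(tt50: float = 1189.0, tt70: float = 1523.0, zmax: float = ZADOKS_MAX):
    """Logistic development curve calibrated to cross Zadoks 50 at ``tt50``
    and 70 at ``tt70``.  Returns a vectorized callable."""
    if not 0 < tt50 < tt70:
        raise ValueError("need 0 < tt50 < tt70")
    a50 = np.log(zmax / 50.0 - 1.0)
    a70 = np.log(zmax / 70.0 - 1.0)
    s = (tt70 - tt50) / (a50 - a70)
    t0 = tt50 + a50 * s

    def curve(tt):
        return zmax / (1.0 + np.exp(-(np.asarray(tt, dtype=float) - t0) / s))

    return curve


def simulate_zadoks_observations(tt50: float, tt70: float, n: int, sigma: float,
                                 seed: int, tt_max: float = 2200.0):
    """Noisy trial-mean Zadoks observations along the season.

    Returns (tt, zadoks) arrays of length ``n``; observation times are
    equally spaced over [0, tt_max] and scores carry Gaussian noise with
    standard deviation ``sigma``, clipped to the Zadoks scale.
    """
    rng = np.random.default_rng(seed)
    tt = np.linspace(0.0, tt_max, n)
    z = zadoks_curve(tt50, tt70)(tt) + rng.normal(0.0, sigma, n)
    return tt, np.clip(z, ZADOKS_MIN, ZADOKS_MAX)
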