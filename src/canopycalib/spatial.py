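"""Row-column spatial mixed model for within-season repeatability.

The model for a plot value y (typically predicted biomass at one cut) is

    y = f(row, col) + Z_g u_g + Z_r u_r + Z_c u_c + e,

with genotype, row and column effects random (u_k ~ N(0, sigma2 * gamma_k I)),
a two-dimensional penalized tensor-product of marginal cubic B-spline bases
f(row, col) with anisotropic second-order difference penalties (one
smoothing parameter per axis), and iid residuals.  The penalty null space
(the bilinear surface 1, r, c, r*c) is moved into the fixed effects so the
penalized part is proper.  Variance components are estimated by REML on a
dense representation; effective dimensions (ED) come from the mixed-model
equations, ED_k = q_k - trace(G_k^{-1} C^{-1}_{kk}), i.e. the trace of the
component's block of the hat matrix.

Within-season repeatability is w^2 = ED_g / (n_genotypes - 1), clamped to
[0, 1]; the alternative printed normalization (total observation count in
the denominator) is available for audit via ``as_printed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phenology import _bspline_design

__all__ = [
    "SpatialModel",
    "SpatialResults",
    "fit_spatial_model",
    "effective_dimension",
    "compute_w2",
    "repeatability_trajectory",
    "plot_repeatability",
    "RepeatabilityResult",
]


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels))
    Z = np.zeros((len(labels), len(levels)))
    index = {l: i for i, l in enumerate(levels)}
    for i, l in enumerate(labels):
        Z[i, index[l]] = 1.0
    return Z, levels


def _marginal_basis(coords: np.ndarray, max_knots: int) -> np.ndarray:
    lo, hi = coords.min(), coords.max()
    k = max(min(max_knots, int(hi - lo) + 1), 2)
    knots = np.linspace(lo, hi, k)
    B, _ = _bspline_design(coords, knots, degree=3)
    return B


class SpatialModel:
    """Spatial mixed model over a row-column trial grid.

    Parameters
    ----------
    data : DataFrame
        One row per plot with columns for the response value, genotype, and
        integer grid coordinates.
    knots : (int, int)
        Maximum marginal knots along (row, column); capped at the grid
        dimension.
    """

    def __init__(self, data: pd.DataFrame, value_col: str = "value",
                 genotype_col: str = "genotype", row_col: str = "row",
                 column_col: str = "column", knots: tuple[int, int] = (10, 10),
                 include_spline: bool = True):
        df = data.reset_index(drop=True)
        self.y = df[value_col].to_numpy(dtype=float)
        rows = df[row_col].to_numpy(dtype=float)
        cols = df[column_col].to_numpy(dtype=float)
        genos = df[genotype_col].to_numpy()

        counts = pd.Series(genos).value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 genotypes")
        if (counts <= 1).all():
            raise ValueError(
                "genotypic variance inestimable: every genotype has a single plot"
            )

        self.Z_g, self.genotypes = _indicator(genos)
        self.Z_r, _ = _indicator(rows)
        self.Z_c, _ = _indicator(cols)

        self.include_spline = include_spline
        Br = _marginal_basis(rows, knots[0])
        Bc = _marginal_basis(cols, knots[1])
        br, bc = Br.shape[1], Bc.shape[1]
        # row-wise tensor product: B[i] = Br[i] (x) Bc[i]
        B = (Br[:, :, None] * Bc[:, None, :]).reshape(len(rows), br * bc)

        def second_diff_penalty(k: int) -> np.ndarray:
            if k < 3:
                return np.zeros((k, k))
            D = np.diff(np.eye(k), n=2, axis=0)
            return D.T @ D

        K_r = np.kron(second_diff_penalty(br), np.eye(bc))
        K_c = np.kron(np.eye(br), second_diff_penalty(bc))
        evals, evecs = np.linalg.eigh(K_r + K_c)
        null = evals < 1e-8 * max(evals.max(), 1.0)
        U_null, U_pen = evecs[:, null], evecs[:, ~null]
        if include_spline:
            self.X = B @ U_null  # bilinear fixed surface (includes the intercept)
            self.Z_s = B @ U_pen
            self.K_r = U_pen.T @ K_r @ U_pen
            self.K_c = U_pen.T @ K_c @ U_pen
        else:
            self.X = np.ones((len(rows), 1))
            self.Z_s = np.zeros((len(rows), 0))
            self.K_r = np.zeros((0, 0))
            self.K_c = np.zeros((0, 0))
        self.block_sizes = {
            "genotype": self.Z_g.shape[1],
            "row": self.Z_r.shape[1],
            "column": self.Z_c.shape[1],
        }
        if include_spline:
            self.block_sizes["spline"] = self.Z_s.shape[1]
        self.n_theta = 5 if include_spline else 3

    # -- REML -------------------------------------------------------------
    def _prec_blocks(self, theta: np.ndarray) -> list[np.ndarray]:
        """Prior precision (relative to sigma^2) of each random block."""
        g_g, g_r, g_c = np.exp(theta[:3])
        blocks = [
            np.eye(self.Z_g.shape[1]) / g_g,
            np.eye(self.Z_r.shape[1]) / g_r,
            np.eye(self.Z_c.shape[1]) / g_c,
        ]
        if self.include_spline:
            l_r, l_c = np.exp(theta[3:5])
            blocks.append(l_r * self.K_r + l_c * self.K_c)
        return blocks

    def _reml_neg_loglik(self, theta: np.ndarray) -> float:
        # centred response: translation only moves the intercept, exactly
        y, X = self.y - self.y.mean(), self.X
        n, p = len(y), X.shape[1]
        Z = self._Z()
        prec = self._prec_blocks(theta)
        # V* = I + Z G* Z' with G* = blockdiag(prec)^{-1}
        G = np.linalg.inv(_blockdiag(prec))
        V = np.eye(n) + Z @ G @ Z.T
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        quad = float(y @ Py)
        if quad <= 0:
            return 1e12
        sigma2 = quad / (n - p)
        return 0.5 * (logdet_V + logdet_XtViX + (n - p) * np.log(sigma2))

    def fit(self, theta0: np.ndarray | None = None, maxiter: int = 200,
            tol: float = 1e-6) -> "SpatialResults":
        """REML estimation; optimizer works on log variance ratios and log
        smoothing parameters."""
        if theta0 is None:
            theta0 = np.zeros(self.n_theta)
        bounds = [(-16.0, 16.0)] * self.n_theta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                self._reml_neg_loglik,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
            )
        return self._results(res.x, converged=bool(res.success), n_iter=res.nit)

    def results_at(self, theta: np.ndarray) -> "SpatialResults":
        """Results at a fixed variance-parameter vector (no optimization);
        used for limit checks and dense-oracle comparisons."""
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_theta:
            raise ValueError(f"theta must have length {self.n_theta}")
        return self._results(theta, converged=True, n_iter=0)

    def _Z(self) -> np.ndarray:
        return np.hstack([self.Z_g, self.Z_r, self.Z_c, self.Z_s])

    def _results(self, theta: np.ndarray, converged: bool, n_iter: int) -> "SpatialResults":
        y_mean = self.y.mean()
        y, X = self.y - y_mean, self.X
        n, p = len(y), X.shape[1]
        Z = self._Z()
        prec = self._prec_blocks(theta)
        W = np.hstack([X, Z])
        Pmat = _blockdiag([np.zeros((p, p))] + prec)
        C = W.T @ W + Pmat
        Cinv = np.linalg.inv(C)
        a = Cinv @ (W.T @ y)
        fitted = W @ a + y_mean
        resid = self.y - fitted

        # sigma^2 from the REML profile
        G = np.linalg.inv(_blockdiag(prec))
        V = np.eye(n) + Z @ G @ Z.T
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
        sigma2 = float(y @ (Vi_y - Vi_X @ beta)) / (n - p)

        q = list(self.block_sizes.values())
        offs = np.cumsum([p] + q)
        eds = {}
        for k, name in enumerate(self.block_sizes):
            sl = slice(offs[k], offs[k + 1])
            eds[name] = float(q[k] - np.trace(prec[k] @ Cinv[sl, sl]))
        g_g = float(np.exp(theta[0]))
        coeffs = {"fixed": a[:p]}
        for k, name in enumerate(self.block_sizes):
            coeffs[name] = a[offs[k]:offs[k + 1]]
        return SpatialResults(
            model=self,
            theta=theta,
            v_g=g_g * sigma2,
            v_r=sigma2,
            effective_dims=eds,
            n_fixed=p,
            coefficients=coeffs,
            fitted=fitted,
            residuals=resid,
            converged=converged,
            n_iter=n_iter,
        )


def _blockdiag(mats: list[np.ndarray]) -> np.ndarray:
    sizes = [m.shape[0] for m in mats]
    out = np.zeros((sum(sizes), sum(sizes)))
    o = 0
    for m, s in zip(mats, sizes):
        out[o:o + s, o:o + s] = m
        o += s
    return out


@dataclass
class SpatialResults:
    model: SpatialModel
    theta: np.ndarray
    v_g: float  # genotypic variance
    v_r: float  # residual variance
    effective_dims: dict[str, float]
    n_fixed: int
    coefficients: dict[str, np.ndarray]
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def ed_genotype(self) -> float:
        return self.effective_dims["genotype"]

    @property
    def ed_residual(self) -> float:
        n = len(self.model.y)
        return n - self.n_fixed - sum(self.effective_dims.values())

    def w2(self, as_printed: bool = False) -> float:
        """Within-season repeatability from the genetic effective dimension.

        Default denominator is n_genotypes - 1 (the free dimensions of the
        genotype component); ``as_printed`` divides by n_observations - 1
        instead, reproducing the study's printed normalization.
        """
        n_geno = len(self.model.genotypes)
        if n_geno < 2:
            raise ValueError("w2 undefined for fewer than 2 genotypes")
        denom = (len(self.model.y) - 1) if as_printed else (n_geno - 1)
        return float(np.clip(self.ed_genotype / denom, 0.0, 1.0))

    def genotype_blups(self) -> pd.Series:
        return pd.Series(self.coefficients["genotype"], index=self.model.genotypes)

    def summary(self) -> str:
        lines = [
            "Spatial mixed model (row-column + 2-D P-spline)",
            "=" * 48,
            f"n obs         {len(self.model.y):>10d}",
            f"n genotypes   {len(self.model.genotypes):>10d}",
            f"converged     {str(self.converged):>10s}  ({self.n_iter} iter)",
            f"V_G           {self.v_g:>10.3f}",
            f"V_R           {self.v_r:>10.3f}",
        ]
        for name, ed in self.effective_dims.items():
            lines.append(f"ED[{name:<9s}] {ed:>9.2f}")
        lines.append(f"ED[residual ] {self.ed_residual:>9.2f}")
        lines.append(f"w2            {self.w2():>10.3f}")
        return "\n".join(lines)


def fit_spatial_model(plot_values: pd.DataFrame, knots: tuple[int, int] = (10, 10),
                      value_col: str = "value") -> SpatialResults:
    """Convenience wrapper: build and REML-fit the spatial model from a
    (row, column, genotype, value) table."""
    return SpatialModel(plot_values, value_col=value_col, knots=knots).fit()


def effective_dimension(fit: SpatialResults, component: str) -> float:
    """ED of one model component (trace of its hat-matrix block)."""
    if component == "residual":
        return fit.ed_residual
    if component not in fit.effective_dims:
        raise KeyError(
            f"unknown component {component!r}; known: "
            f"{list(fit.effective_dims) + ['residual']}"
        )
    return fit.effective_dims[component]


def compute_w2(fit: SpatialResults, as_printed: bool = False) -> float:
    return fit.w2(as_printed=as_printed)


@dataclass(frozen=True)
class RepeatabilityResult:
    experiment_id: str
    cut_number: int
    v_g: float
    v_r: float
    ed_g: float
    w2: float
    converged: bool


def repeatability_trajectory(predictions: pd.DataFrame, value_col: str = "pred",
                             knots: tuple[int, int] = (10, 10)) -> pd.DataFrame:
    """One repeatability estimate per experiment x cut.

    ``predictions`` needs columns experiment, cut_number, row, column,
    genotype plus the value column.  Cells where the model cannot be fitted
    (single genotype, no replication) are skipped with a warning.
    """
    rows = []
    for (exp, cut), sub in predictions.groupby(["experiment", "cut_number"], sort=True):
        try:
            fit = fit_spatial_model(sub, knots=knots, value_col=value_col)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"skipping {exp} cut {cut}: {err}")
            continue
        rows.append(
            RepeatabilityResult(
                experiment_id=str(exp),
                cut_number=int(cut),
                v_g=fit.v_g,
                v_r=fit.v_r,
                ed_g=fit.ed_genotype,
                w2=fit.w2(),
                converged=fit.converged,
            )
        )
    table = pd.DataFrame(
        [
            {
                "experiment": r.experiment_id,
                "cut_number": r.cut_number,
                "v_g": r.v_g,
                "v_r": r.v_r,
                "ed_g": r.ed_g,
                "w2": r.w2,
                "converged": r.converged,
            }
            for r in rows
        ]
    )
    return table


def plot_repeatability(table: pd.DataFrame, ax=None):
    """w2 per cut, one line per experiment (the repeatability trajectory)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for exp, sub in table.groupby("experiment"):
        sub = sub.sort_values("cut_number")
        ax.plot(sub["cut_number"], sub["w2"], "-o", ms=4, label=str(exp))
    ax.set_xlabel("biomass cut")
    ax.set_ylabel("within-season repeatability w2")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    return ax
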