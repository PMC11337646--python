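"""Feature selection: pairwise-correlation filtering, then recursive feature
elimination (RFE) with a partial-least-squares base learner under resampled
validation, and the 1-standard-error subset rule.

The PLS1 regressor here is a NIPALS partial-least-squares fit for a single
response that exposes the full per-component coefficient path: one fit at
``A`` components yields predictions for every component count ``1..A`` and
the per-component coefficient contributions needed by the importance score
(weighted sums of absolute coefficients, weights proportional to the
response sum of squares captured by each component).  That path is what
makes the nested resampling affordable: each inner cross-validation fold is
a single fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PLS1",
    "correlation_filter",
    "plsr_importance",
    "RFEProfile",
    "rfe",
    "select_subset_1se",
]


class PLS1:
    """Univariate-response partial least squares (NIPALS), with the
    cumulative coefficient path over components.

    Predictors are centred and unit-scaled on the fitting data; the response
    is centred.  ``coef_path_[:, k-1]`` are the standardized-scale
    coefficients of the k-component model.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y) -> "PLS1":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        A = min(self.n_components, p, n - 1)
        if A < 1:
            raise ValueError("need at least one component and two samples")
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_ = y.mean()
        Xc = (X - self.x_mean_) / self.x_std_
        yc = y - self.y_mean_
        if np.allclose(yc, 0):
            raise ValueError("degenerate response: zero variance")

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        ss = np.zeros(A)  # response sum of squares captured per component
        Xr, yr = Xc.copy(), yc.copy()
        for h in range(A):
            w = Xr.T @ yr
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                A = h
                break
            w /= norm
            t = Xr @ w
            tt = float(t @ t)
            if tt < 1e-12:
                A = h
                break
            ph = Xr.T @ t / tt
            qh = float(yr @ t) / tt
            Xr = Xr - np.outer(t, ph)
            yr = yr - qh * t
            W[:, h], P[:, h], q[h] = w, ph, qh
            ss[h] = qh**2 * tt
        if A < 1:
            raise ValueError("no usable PLS component (constant predictors?)")
        W, P, q, ss = W[:, :A], P[:, :A], q[:A], ss[:A]
        # R maps X (standardized) to scores: T = Xc R
        R = W @ np.linalg.inv(P.T @ W)
        self.n_components_ = A
        self.x_rotations_ = R
        self.y_loadings_ = q
        self.ss_comp_ = ss
        # cumulative coefficient path: B_k = sum_{h<=k} R[:, h] q[h]
        self.coef_path_ = np.cumsum(R * q, axis=1)
        self.coef_ = self.coef_path_[:, -1]
        return self

    def predict(self, X, ncomp: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        k = self.n_components_ if ncomp is None else min(ncomp, self.n_components_)
        b = self.coef_path_[:, k - 1]
        return self.y_mean_ + ((X - self.x_mean_) / self.x_std_) @ b

    def predict_all(self, X) -> np.ndarray:
        """Predictions for every component count: shape (n, A)."""
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + ((X - self.x_mean_) / self.x_std_) @ self.coef_path_

    # sklearn-compatible plumbing so the learner drops into the training grid
    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "PLS1":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=float).ravel()
        pred = self.predict(X)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot


def plsr_importance(model: PLS1, feature_names: list[str] | None = None):
    """Nonnegative importance per predictor: sum over components of the
    absolute coefficient contribution |R_jh q_h|, weighted by the share of
    response sum of squares the component captured."""
    if not hasattr(model, "coef_path_"):
        raise ValueError("model must be fitted before computing importance")
    contrib = np.abs(model.x_rotations_ * model.y_loadings_)  # (p, A)
    w = model.ss_comp_ / model.ss_comp_.sum()
    scores = contrib @ w
    if feature_names is None:
        return scores
    return dict(zip(feature_names, scores))


def correlation_filter(X: pd.DataFrame, cutoff: float = 0.95) -> list[str]:
    """Retain columns so that no pairwise |r| exceeds ``cutoff``.

    Zero-variance columns are removed first (their correlation is
    undefined).  Then, while the worst pair exceeds the cutoff, the member
    with the larger mean absolute correlation to all other retained columns
    is dropped.  Returns retained column names in original order.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    keep = [c for c in X.columns if X[c].nunique() > 1]
    corr = X[keep].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    active = list(range(len(keep)))
    while True:
        sub = corr[np.ix_(active, active)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= cutoff:
            break
        mean_i = sub[i].sum() / (len(active) - 1)
        mean_j = sub[j].sum() / (len(active) - 1)
        drop = i if mean_i >= mean_j else j
        active.pop(drop)
        if len(active) < 2:
            break
    return [keep[a] for a in active]


@dataclass
class RFEProfile:
    """RMSE-vs-subset-size profile and aggregated importance ranking."""

    feature_names: list[str]
    sizes: np.ndarray  # 1..p
    rmse: np.ndarray  # (n_resamples, p); column s-1 is subset size s
    mean_ranks: dict[str, float]  # mean elimination rank, 1 = best
    chosen_size: int = 0
    chosen_features: list[str] = field(default_factory=list)

    @property
    def mean_rmse(self) -> np.ndarray:
        return self.rmse.mean(axis=0)

    @property
    def se_rmse(self) -> np.ndarray:
        return self.rmse.std(axis=0, ddof=1) / np.sqrt(self.rmse.shape[0])

    @property
    def ranking(self) -> list[str]:
        """Features from most to least important (ties alphabetical)."""
        return sorted(self.mean_ranks, key=lambda f: (self.mean_ranks[f], f))

    def plot(self, ax=None):
        """RMSE vs subset size with the +/- SE band and the 1-SE choice."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m, s = self.mean_rmse, self.se_rmse
        ok = np.isfinite(m)
        ax.plot(self.sizes[ok], m[ok], "-o", ms=3, color="C0")
        ax.fill_between(self.sizes[ok], (m - s)[ok], (m + s)[ok],
                        alpha=0.25, color="C0")
        if self.chosen_size:
            ax.axvline(self.chosen_size, ls="--", color="C3", lw=1,
                       label=f"1-SE choice: {self.chosen_size}")
            ax.legend(frameon=False)
        ax.set_xlabel("subset size")
        ax.set_ylabel("validation RMSE (g/m2)")
        return ax

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "sizes": self.sizes.tolist(),
            "mean_rmse": self.mean_rmse.tolist(),
            "se_rmse": self.se_rmse.tolist(),
            "mean_ranks": self.mean_ranks,
            "ranking": self.ranking,
            "chosen_size": int(self.chosen_size),
            "chosen_features": self.chosen_features,
        }


def _stratified_split(n: int, frac: float, strata, rng) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    if strata is None:
        perm = rng.permutation(idx)
        k = int(round(frac * n))
        return np.sort(perm[:k]), np.sort(perm[k:])
    strata = np.asarray(strata)
    train, test = [], []
    for s in np.unique(strata):
        sub = idx[strata == s]
        perm = rng.permutation(sub)
        k = int(round(frac * sub.size))
        train.append(perm[:k])
        test.append(perm[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _tune_ncomp_cv(X: np.ndarray, y: np.ndarray, folds: int, rng,
                   max_comp: int | None = None) -> int:
    """Component count minimizing k-fold CV RMSE; one fit per fold covers
    the whole 1..A grid via the coefficient path."""
    n, p = X.shape
    A = min(p, n - 1 - int(np.ceil(n / folds))) if max_comp is None else max_comp
    A = max(min(A, p), 1)
    assign = rng.permutation(n) % folds
    sq_err = np.zeros(A)
    counts = 0
    for f in range(folds):
        tr, va = assign != f, assign == f
        if va.sum() == 0 or tr.sum() < 2:
            continue
        model = PLS1(n_components=A).fit(X[tr], y[tr])
        preds = model.predict_all(X[va])  # (n_va, A_fit)
        err = (preds - y[va][:, None]) ** 2
        a_fit = preds.shape[1]
        sq_err[:a_fit] += err.sum(axis=0)
        if a_fit < A:  # short fit: extend the last column
            sq_err[a_fit:] += err[:, -1].sum()
        counts += va.sum()
    rmse = np.sqrt(sq_err / counts)
    return int(np.argmin(rmse) + 1)


def rfe(X: pd.DataFrame, y, n_resamples: int = 30, split: float = 0.8,
        seed: int = 0, strata=None, inner_folds: int = 10,
        step_fraction: float = 0.0) -> RFEProfile:
    """Recursive feature elimination with a PLS base learner.

    For each of ``n_resamples`` 80:20 resamples (stratified when ``strata``
    is given): tune the component count by ``inner_folds``-fold CV on the
    80%, fit, record validation RMSE, drop the lowest-importance feature,
    and repeat down to a single feature.  Importance and standardization are
    recomputed inside every resample, never on pooled data.  The profile
    aggregates RMSE mean and standard error per subset size and mean
    elimination ranks across resamples, then applies the 1-SE subset rule.

    ``step_fraction > 0`` drops that fraction of features per iteration (a
    speed option for very wide matrices; off by default).
    """
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("degenerate response: zero variance")
    names = list(X.columns)
    p = len(names)
    Xv = X.to_numpy(dtype=float)

    rmse = np.full((n_resamples, p), np.nan)
    ranks = np.zeros((n_resamples, p))
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_resamples)):
        rng = np.random.default_rng(child)
        tr, va = _stratified_split(len(y), split, strata, rng)
        feats = list(range(p))
        n_dropped = 0
        while feats:
            s = len(feats)
            Xtr, Xva = Xv[np.ix_(tr, feats)], Xv[np.ix_(va, feats)]
            ncomp = _tune_ncomp_cv(Xtr, y[tr], inner_folds, rng) if s > 1 else 1
            model = PLS1(n_components=ncomp).fit(Xtr, y[tr])
            pred = model.predict(Xva)
            rmse[i, s - 1] = float(np.sqrt(np.mean((pred - y[va]) ** 2)))
            if s == 1:
                ranks[i, feats[0]] = 1
                break
            imp = plsr_importance(model)
            k_drop = 1 if step_fraction <= 0 else max(1, int(step_fraction * s))
            order = np.argsort(imp, kind="stable")  # ascending importance
            for j in order[:k_drop]:
                ranks[i, feats[j]] = p - n_dropped
                n_dropped += 1
            feats = [f for k, f in enumerate(feats) if k not in set(order[:k_drop])]

    # with fractional steps some sizes are never visited; keep visited ones
    mean_ranks = {names[j]: float(ranks[:, j].mean()) for j in range(p)}
    profile = RFEProfile(
        feature_names=names,
        sizes=np.arange(1, p + 1),
        rmse=rmse,
        mean_ranks=mean_ranks,
    )
    chosen = select_subset_1se(profile)
    profile.chosen_features = chosen
    return profile


def select_subset_1se(profile: RFEProfile) -> list[str]:
    """Smallest subset whose mean RMSE is within one standard error of the
    best subset's mean RMSE; sets ``chosen_size`` and returns the top
    features by aggregated rank."""
    mean = profile.mean_rmse
    se = profile.se_rmse
    valid = np.isfinite(mean)
    sizes = profile.sizes[valid]
    m, s = mean[valid], se[valid]
    best = int(np.argmin(m))
    threshold = m[best] + s[best]
    chosen_size = int(sizes[np.nonzero(m <= threshold)[0][0]])
    profile.chosen_size = chosen_size
    return profile.ranking[:chosen_size]
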