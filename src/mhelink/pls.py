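"""PLS2 regression linking gene expression to serum compound modules.

One model per compound module: the FDR-significant genes form the
predictor block X (samples x genes), the module's metabolites/cytokines
the joint response block Y.  Components are extracted by NIPALS,
maximizing X-Y covariance; fit quality is summarized by cumulative R2 and
leave-one-out Q2 (1 - PRESS/TSS with strict per-fold re-centering and
re-scaling), and first-component gene loadings provide the ranking used
by downstream enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix


@dataclass
class PLSModelFit:
    predictor_ids: list[str]
    response_ids: list[str]
    n_components: int
    x_weights: np.ndarray      # p x A, unit-norm columns
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # q x A
    x_scores: np.ndarray       # n x A, mutually orthogonal
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    scaling: str = "autoscale"

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients B (p x q) on the scaled blocks."""
        a = n_components or self.n_components
        W, P, Q = (self.x_weights[:, :a], self.x_loadings[:, :a],
                   self.y_loadings[:, :a])
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: pd.DataFrame | np.ndarray,
                n_components: int | None = None) -> np.ndarray:
        """Predict responses on the original scale."""
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_ids].to_numpy(float)
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_scale
        Ys = Xs @ self.coefficients(n_components)
        return Ys * self.y_scale + self.y_mean


@dataclass
class FitStats:
    r2_per_component: list[float]      # cumulative
    q2_per_component: list[float] = field(default_factory=list)  # cumulative
    press: float = np.nan
    tss: float = np.nan
    failed_folds: list[str] = field(default_factory=list)

    @property
    def r2(self) -> float:
        return self.r2_per_component[-1]

    @property
    def q2(self) -> float:
        return self.q2_per_component[-1] if self.q2_per_component else np.nan


def _scale_block(M: np.ndarray, scaling: str
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    if scaling == "autoscale":
        sd = M.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
    elif scaling == "center":
        sd = np.ones(M.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (M - mean) / sd, mean, sd


def fit_pls(X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 2,
            scaling: str = "autoscale", tol: float = 1e-10,
            max_iter: int = 500) -> PLSModelFit:
    """NIPALS PLS2 with X (and Y) deflation.

    ``X`` and ``Y`` are samples x features frames sharing an index.
    Zero-variance predictors are dropped with a warning under autoscaling.
    Initialization is deterministic: the Y column of maximal variance.
    """
    if list(X.index) != list(Y.index):
        raise ValueError("X and Y must share the same ordered samples")
    n = X.shape[0]
    if n_components > min(n - 1, X.shape[1]):
        raise ValueError(
            f"n_components must be <= min(n-1, p) = {min(n - 1, X.shape[1])}")
    if scaling == "autoscale":
        dead = X.columns[X.std(ddof=1) == 0]
        if len(dead):
            warnings.warn(f"dropping zero-variance predictors: {list(dead)}",
                          stacklevel=2)
            X = X.drop(columns=dead)
    predictor_ids, response_ids = list(X.columns), list(Y.columns)
    Xs, x_mean, x_scale = _scale_block(X.to_numpy(float), scaling)
    Ys, y_mean, y_scale = _scale_block(Y.to_numpy(float), scaling)

    p, q = Xs.shape[1], Ys.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    Xd, Yd = Xs.copy(), Ys.copy()
    for a in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0, ddof=1)))]
        if np.allclose(Yd, 0):
            break
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = Xd @ w
            qv = Yd.T @ t / (t @ t)
            nq = np.linalg.norm(qv)
            if nq == 0 or q == 1:
                break
            u = Yd @ qv / (qv @ qv)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        pv = Xd.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
        Xd = Xd - np.outer(t, pv)
        Yd = Yd - np.outer(t, qv)
    return PLSModelFit(predictor_ids, response_ids, n_components,
                       W, P, Q, T, x_mean, x_scale, y_mean, y_scale, scaling)


def r_squared(model: PLSModelFit, X: pd.DataFrame, Y: pd.DataFrame
              ) -> list[float]:
    """Cumulative fraction of (scaled) Y variance explained, per component."""
    Ys, y_mean, y_scale = _scale_block(Y[model.response_ids].to_numpy(float),
                                       model.scaling)
    tss = (Ys ** 2).sum()
    out = []
    for a in range(1, model.n_components + 1):
        pred = model.predict(X, a)
        resid = (Y[model.response_ids].to_numpy(float) - pred) / y_scale
        out.append(float(1.0 - (resid ** 2).sum() / tss))
    return out


def q_squared_loo(X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 2,
                  scaling: str = "autoscale") -> FitStats:
    """Leave-one-out Q2 with strict per-fold re-centering/re-scaling.

    For every left-out sample the model is refit on the remaining samples
    (scaling recomputed on the training fold) and the held-out responses
    predicted; PRESS and TSS are accumulated on the training-fold scaled
    space, so Q2 = 1 - PRESS/TSS compares prediction against the
    training-fold mean.  Cumulative over components.  Also reports the
    training R2 of the full-data model.
    """
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out Q2 requires n >= 4")
    full = fit_pls(X, Y, n_components, scaling)
    stats = FitStats(r2_per_component=r_squared(full, X, Y))

    press = np.zeros(n_components)
    tss = 0.0
    for i, sample in enumerate(X.index):
        train = X.index != sample
        try:
            sub = fit_pls(X.loc[train], Y.loc[train], n_components, scaling)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"LOO refit failed for {sample}: {exc}", stacklevel=2)
            stats.failed_folds.append(str(sample))
            continue
        y_true = Y.loc[[sample], sub.response_ids].to_numpy(float)
        y_scaled = (y_true - sub.y_mean) / sub.y_scale
        tss += float((y_scaled ** 2).sum())
        for a in range(1, n_components + 1):
            pred = sub.predict(X.loc[[sample]], a)
            resid = (y_true - pred) / sub.y_scale
            press[a - 1] += float((resid ** 2).sum())
    if stats.failed_folds:
        stats.q2_per_component = [np.nan] * n_components
        return stats
    stats.press = float(press[-1])
    stats.tss = tss
    stats.q2_per_component = [float(1.0 - pr / tss) for pr in press]
    return stats


def gene_loadings(model: PLSModelFit, component: int = 1) -> pd.DataFrame:
    """Complete signed ranking of predictors by first-component loading.

    Returned ascending by loading value (ties broken by gene id), with a
    ``rank`` column (1 = most negative loading).
    """
    if not 1 <= component <= model.n_components:
        raise ValueError("component out of range")
    lo = model.x_weights[:, component - 1]
    df = pd.DataFrame({"gene": model.predictor_ids, "loading": lo})
    df = df.sort_values(["loading", "gene"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


@dataclass
class ModulePLSResult:
    module: str
    model: PLSModelFit
    stats: FitStats
    ranking: pd.DataFrame


def fit_all_modules(genes: OmicsMatrix, module_members: dict[str, list[str]],
                    metabolites: OmicsMatrix, cytokines: OmicsMatrix,
                    significant_genes: list[str], n_components: int = 2,
                    scaling: str = "autoscale"
                    ) -> tuple[dict[str, ModulePLSResult], pd.DataFrame]:
    """One PLS model per compound module.

    ``module_members`` maps module name to serum feature ids (metabolites
    and/or cytokines).  X is the significant-gene expression block, shared
    across models; Y is each module's compound block.  Returns the
    per-module results and a summary table (module, n_responses, A,
    R2_cum, Q2_cum).
    """
    if not significant_genes:
        raise ValueError(
            "no significant genes: upstream differential expression "
            "produced an empty predictor list")
    missing = [g for g in significant_genes if g not in genes.values.index]
    if missing:
        raise ValueError(f"significant genes absent from matrix: {missing[:5]}")
    X = genes.values.loc[significant_genes].T  # samples x genes
    serum = pd.concat([metabolites.values, cytokines.values]).T

    results: dict[str, ModulePLSResult] = {}
    rows = []
    for name, members in module_members.items():
        members = [m for m in members if m in serum.columns]
        if len(members) < 1:
            warnings.warn(f"module {name} has no compounds; skipped",
                          stacklevel=2)
            continue
        Y = serum[members]
        a = min(n_components, X.shape[0] - 1, X.shape[1])
        stats = q_squared_loo(X, Y, a, scaling)
        model = fit_pls(X, Y, a, scaling)
        ranking = gene_loadings(model, 1)
        results[name] = ModulePLSResult(name, model, stats, ranking)
        rows.append({"module": name, "n_responses": len(members),
                     "n_components": a, "R2_cum": stats.r2,
                     "Q2_cum": stats.q2})
    summary = pd.DataFrame(rows)
    return results, summary
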