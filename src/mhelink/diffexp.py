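"""Quality control, variance stabilization and per-omic differential tests.

Three test routes, matching how each omic is usually analysed:

* genes and metabolites: generalized-log variance stabilization followed by
  an empirical-Bayes moderated two-sample t-test with Benjamini-Hochberg FDR;
* cytokines: exact two-sided Wilcoxon rank-sum tests on the raw
  concentrations (medians/IQRs reported per group) with BH-FDR;
* metabolite panels additionally pass a detection-based QC filter before
  testing (missingness per group, fraction above the limit of detection).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import OmicsMatrix

# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def metabolite_qc_filter(matrix: OmicsMatrix,
                         lod: float | pd.Series = 0.0,
                         max_missing: float = 0.20,
                         min_above_lod: float = 0.50
                         ) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Detection-based feature filter for targeted metabolomics.

    A feature is retained iff (1) its fraction of missing values is below
    ``max_missing`` (strict) in *every* group, and (2) at least
    ``min_above_lod`` (inclusive) of all its measured values lie strictly
    above the limit of detection.  Returns the filtered matrix and a
    per-feature QC report with both fractions and pass flags.
    """
    if np.ndim(lod) == 0:
        lod = pd.Series(float(lod), index=matrix.values.index)
    else:
        lod = pd.Series(lod).reindex(matrix.values.index)
    vals = matrix.values
    report = pd.DataFrame(index=vals.index)
    missing_ok = pd.Series(True, index=vals.index)
    for grp, cols in ((matrix.case, matrix.case_samples),
                      (matrix.control, matrix.control_samples)):
        frac = vals[cols].isna().mean(axis=1)
        report[f"missing_frac_{grp}"] = frac
        missing_ok &= frac < max_missing
    measured = vals.notna().sum(axis=1)
    above = vals.gt(lod, axis=0).sum(axis=1)
    frac_above = np.where(measured > 0, above / measured, 0.0)
    report["frac_above_lod"] = frac_above
    report["pass_missing"] = missing_ok
    report["pass_lod"] = frac_above >= min_above_lod
    report["retained"] = report["pass_missing"] & report["pass_lod"]

    kept = matrix.subset_features(report.index[report["retained"]])
    if kept.values.shape[0] == 0:
        warnings.warn("QC filter removed every feature", stacklevel=2)
    return kept, report


# ---------------------------------------------------------------------------
# Variance-stabilizing normalization (simplified deterministic glog fit)
# ---------------------------------------------------------------------------


def sd_trend_slope(values: np.ndarray) -> float:
    """Dimensionless slope of the per-feature SD against the rank of its mean.

    Feature means are replaced by their normalized rank in [0, 1]; the
    regression slope is divided by the mean SD, so the statistic compares
    across transformations of different scale.  Zero means a flat
    SD-vs-mean trend (the goal of variance stabilization).
    """
    means = np.nanmean(values, axis=1)
    sds = np.nanstd(values, axis=1, ddof=1)
    ok = np.isfinite(means) & np.isfinite(sds)
    means, sds = means[ok], sds[ok]
    if len(means) < 3 or np.mean(sds) == 0:
        return 0.0
    r = stats.rankdata(means) / len(means)
    slope = np.polyfit(r, sds, 1)[0]
    return float(slope / np.mean(sds))


def glog2(x: np.ndarray, b: float) -> np.ndarray:
    """Generalized log2: log2((x + sqrt(x^2 + b^2)) / 2); -> log2(x) as x >> b."""
    return np.log2((x + np.sqrt(x * x + b * b)) / 2.0)


def vst_normalize(matrix: OmicsMatrix, b: float | None = None,
                  n_grid: int = 41, calibrate: bool = True) -> OmicsMatrix:
    """Variance-stabilize an intensity/concentration matrix.

    Two deterministic steps:

    1. robust per-sample affine calibration against the across-sample
       reference (per-feature median): sample s is mapped through
       ``x' = (x - a_s) / c_s`` with scale and offset from a Theil-Sen fit
       of the sample against the reference, removing sample-to-sample
       shifts and scale factors (exact for an affine distortion);
    2. a generalized log2 transform with a single global ``b`` chosen by
       grid search to flatten the SD-versus-rank-mean trend (see
       :func:`sd_trend_slope`).  Pass ``b`` to skip the search.

    Pass ``calibrate=False`` for absolutely quantified data (e.g. a
    targeted metabolite panel calibrated against internal standards),
    where per-sample affine correction is unwarranted and, on a small
    panel with many coherent group effects, can leak the group signal
    into the sample factors.  Group labels are never used.  NaNs pass
    through.
    """
    vals = matrix.values.to_numpy(float)
    if np.nanstd(vals) == 0:
        warnings.warn("constant matrix: returning glog with unit b",
                      stacklevel=2)
        return matrix.with_values(
            pd.DataFrame(glog2(vals, 1.0), index=matrix.values.index,
                         columns=matrix.values.columns))

    if calibrate:
        ref = np.nanmedian(vals, axis=1)
        calibrated = np.empty_like(vals)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            ok = np.isfinite(col) & np.isfinite(ref)
            if ok.sum() >= 3 and np.ptp(ref[ok]) > 0:
                x, y = ref[ok], col[ok]
                # Theil-Sen is quadratic in the feature count; a
                # deterministic rank-spread subsample keeps it cheap on
                # large matrices without losing the calibration range.
                if x.size > 800:
                    idx = np.argsort(x, kind="mergesort")[
                        np.linspace(0, x.size - 1, 800).astype(int)]
                    x, y = x[idx], y[idx]
                # robust affine fit of the sample against the reference;
                # exact when the sample is an affine image of it
                scale, offset, *_ = stats.theilslopes(y, x)
                if not np.isfinite(scale) or scale <= 0:
                    scale, offset = 1.0, 0.0
            else:
                scale, offset = 1.0, 0.0
            calibrated[:, j] = (col - offset) / scale
    else:
        calibrated = vals.copy()

    if b is None:
        pos = np.abs(calibrated[np.isfinite(calibrated) & (calibrated != 0)])
        if pos.size == 0:
            b = 1.0
        else:
            lo = max(np.quantile(pos, 0.001), 1e-8)
            hi = np.quantile(pos, 0.999)
            grid = np.geomspace(lo, hi, n_grid)
            slopes = [abs(sd_trend_slope(glog2(calibrated, bb))) for bb in grid]
            b = float(grid[int(np.argmin(slopes))])

    out = pd.DataFrame(glog2(calibrated, b), index=matrix.values.index,
                       columns=matrix.values.columns)
    result = matrix.with_values(out)
    result.values.attrs["glog_b"] = b
    return result


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, order-preserving, NaN-safe.

    NaN p-values propagate as NaN and are excluded from the number of
    tests m.
    """
    p = np.asarray(pvals, float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t-test
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return 1e6
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float
                            ) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to sample variances.

    Matches the first two moments of log(s^2) to the scaled-F model of the
    empirical-Bayes variance prior: with ``z = log(s2)``,
    ``e = z - digamma(df/2) + log(df/2)`` has mean ``log(s0^2) +
    digamma(d0/2) - log(d0/2)`` and excess variance ``trigamma(d0/2)``.
    d0 is capped at 1e6 for numerical stability.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return 1e6, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2.0)
    if resid <= 0:
        d0 = 1e6
    else:
        d0 = min(2.0 * _trigamma_inverse(resid), 1e6)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not np.isfinite(s0sq) or s0sq <= 0:
        s0sq = float(np.exp(emean))
    return float(d0), s0sq


def moderated_ttest(matrix: OmicsMatrix, alpha: float = 0.05,
                    prior: tuple[float, float] | None = None,
                    weights: pd.Series | None = None) -> pd.DataFrame:
    """Two-sample moderated t-test per feature (case minus control).

    Per-feature residual variances are shrunk towards a common prior:
    ``s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)``, with ``(d0, s0^2)``
    estimated by moments on ``log s2_g`` unless ``prior`` overrides them
    (``prior=(0, .)`` recovers the ordinary t-test).  Optional per-sample
    ``weights`` enter the group means and residual variances (default
    uniform).  Returns a table with logFC, s2, df, t, p, fdr, significant;
    the fitted prior is stored in ``result.attrs``.
    """
    case_cols = matrix.case_samples
    ctrl_cols = matrix.control_samples
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated t-test requires >= 2 samples per group")

    vals = matrix.values
    if weights is None:
        w = pd.Series(1.0, index=vals.columns)
    else:
        w = pd.Series(weights).reindex(vals.columns)
        if w.isna().any() or (w <= 0).any():
            raise ValueError("weights must be positive for every sample")

    def _wstats(cols):
        x = vals[cols].to_numpy(float)
        ww = w[cols].to_numpy(float)
        wsum = ww.sum()
        mean = (x * ww).sum(axis=1) / wsum
        resid = x - mean[:, None]
        var = (resid * resid * ww).sum(axis=1) / (wsum - ww @ ww / wsum)
        return mean, var, wsum

    m1, v1, ws1 = _wstats(case_cols)
    m2, v2, ws2 = _wstats(ctrl_cols)
    logfc = m1 - m2
    dg = float(n1 + n2 - 2)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg

    if prior is None:
        d0, s0sq = estimate_variance_prior(s2, dg)
    else:
        d0, s0sq = float(prior[0]), float(prior[1])
    s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
    # s0^2 > 0 floors the posterior variance whenever shrinkage is active;
    # a tiny absolute floor guards the unshrunk (d0 = 0) degenerate case.
    s2_post = np.maximum(s2_post, 1e-300)

    se = np.sqrt(s2_post * (1.0 / ws1 + 1.0 / ws2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    df_total = min(d0 + dg, 1e7)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame({
        "logFC": logfc, "s2": s2, "df": dg, "t": t, "p": p,
        "fdr": bh_adjust(p),
    }, index=vals.index)
    out["significant"] = out["fdr"] < alpha
    out.attrs["d0"] = d0
    out.attrs["s0sq"] = s0sq
    out.attrs["df_total"] = df_total
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum panel
# ---------------------------------------------------------------------------


def wilcoxon_panel(matrix: OmicsMatrix, alpha: float = 0.05,
                   exact_max_n: int = 20) -> pd.DataFrame:
    """Exact two-sided Wilcoxon rank-sum tests on a small panel.

    Exact enumeration is used when the total sample size is at most
    ``exact_max_n`` and the feature has no ties; otherwise the normal
    approximation with tie correction.  Medians and IQRs are reported on
    the raw scale; a Fligner-Killeen homoscedasticity p-value is reported
    as a diagnostic but never gates the test.
    """
    case_cols = matrix.case_samples
    ctrl_cols = matrix.control_samples
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("rank-sum panel requires >= 2 samples per group")
    rows = []
    for fid, row in matrix.values.iterrows():
        x = row[case_cols].dropna().to_numpy(float)
        y = row[ctrl_cols].dropna().to_numpy(float)
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        all_tied = len(np.unique(np.concatenate([x, y]))) == 1
        if all_tied:
            warnings.warn(f"{fid}: all values tied, p set to 1", stacklevel=2)
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            method = ("exact" if (len(x) + len(y) <= exact_max_n and not ties)
                      else "asymptotic")
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=method)
            u, p = float(res.statistic), min(float(res.pvalue), 1.0)
        try:
            homo_p = float(stats.fligner(x, y).pvalue) if not all_tied else np.nan
        except Exception:  # degenerate groups
            homo_p = np.nan
        q1c, q3c = np.percentile(x, [25, 75])
        q1k, q3k = np.percentile(y, [25, 75])
        rows.append({
            "feature": fid,
            f"median_{matrix.case}": float(np.median(x)),
            f"iqr_{matrix.case}": float(q3c - q1c),
            f"median_{matrix.control}": float(np.median(y)),
            f"iqr_{matrix.control}": float(q3k - q1k),
            "U": u, "p": p, "homoscedasticity_p": homo_p,
        })
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr"] = bh_adjust(out["p"])
    out["significant"] = out["fdr"] < alpha
    return out


def significant_features(table: pd.DataFrame, alpha: float = 0.05,
                         qcol: str = "fdr") -> list[str]:
    """Feature ids with q < alpha, sorted by q ascending (ties by id)."""
    if qcol not in table.columns:
        raise ValueError(f"table has no {qcol!r} column")
    hits = table[table[qcol] < alpha]
    order = sorted(hits.index, key=lambda fid: (hits.loc[fid, qcol], str(fid)))
    return list(order)
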