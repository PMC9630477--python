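"""Univariable two-sample MR estimators and the sensitivity suite.

All estimators consume a harmonized table (one row per instrument with
aligned ``beta_exp``/``se_exp``/``beta_out``/``se_out``) and return
:class:`MREstimate` records.  The suite covers:

* Wald ratio and fixed-/random-effect inverse-variance-weighted (IVW)
  meta-analysis of the per-variant ratios;
* weighted-median estimation (consistent when < 50% of weight comes from
  invalid instruments), with a parametric-bootstrap standard error;
* MR-Egger regression, whose intercept tests directional pleiotropy under
  the InSIDE assumption;
* Cochran's Q heterogeneity test;
* MR-PRESSO global, per-variant outlier and distortion tests;
* Cook's-distance influence screening on the weighted IVW regression;
* re-estimation after outlier removal and the reverse-direction analysis.

Weights are first-order delta-method weights (1 / se(ratio)^2 with
se(ratio) = se_out / |beta_exp|), so IVW coincides with weighted least
squares of outcome on exposure effects through the origin with weights
1 / se_out^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import ReferencePanel

__all__ = [
    "MREstimate",
    "PressoResult",
    "SensitivityReport",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "cochran_q",
    "mr_presso",
    "cooks_exclusion",
    "rerun_after_removal",
    "estimate_all",
    "reverse_mr",
]

_Z95 = sps.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    """An estimator was called with fewer instruments than it requires."""


@dataclass
class MREstimate:
    """One causal-effect estimate (or Egger intercept) with its uncertainty."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float
    ci_high: float


@dataclass
class PressoResult:
    """MR-PRESSO global heterogeneity, outlier and distortion results."""

    global_rss: float
    global_pval: float
    outlier_indices: np.ndarray
    outlier_pvals: np.ndarray  # Bonferroni-adjusted, aligned with instruments
    distortion_coef: float | None
    distortion_pval: float | None
    n_sim: int


@dataclass
class SensitivityReport:
    """Full sensitivity diagnostics for one exposure-outcome pair."""

    q: float
    q_df: int
    q_pval: float
    egger_intercept: MREstimate
    presso: PressoResult | None
    cooks_excluded: np.ndarray
    excluded: np.ndarray  # union of PRESSO outliers and Cook's exclusions
    post_removal: dict[str, MREstimate] | None


def _finalize(method: str, beta: float, se: float, n: int, df: int | None = None) -> MREstimate:
    """Attach a two-sided p-value and 95% CI (normal, or t with ``df``)."""
    if se > 0:
        if df is None:
            pval = 2.0 * sps.norm.sf(abs(beta) / se)
            half = _Z95 * se
        else:
            pval = 2.0 * sps.t.sf(abs(beta) / se, df)
            half = sps.t.ppf(0.975, df) * se
    else:  # degenerate: exact fit / zero noise
        pval = 1.0 if beta == 0 else np.finfo(float).tiny
        half = 0.0
    pval = float(np.clip(pval, np.finfo(float).tiny, 1.0))
    return MREstimate(method, float(beta), float(se), pval, n, float(beta - half), float(beta + half))


def _arrays(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return (
        h["beta_exp"].to_numpy(dtype=float),
        h["se_exp"].to_numpy(dtype=float),
        h["beta_out"].to_numpy(dtype=float),
        h["se_out"].to_numpy(dtype=float),
    )


def wald_ratio(
    exp_beta: float, exp_se: float, out_beta: float, out_se: float, second_order: bool = False
) -> MREstimate:
    """Per-variant causal estimate out_beta / exp_beta.

    The default SE is the first-order delta-method value out_se / |exp_beta|
    (exposure-side noise ignored), matching the weights used by IVW;
    ``second_order`` adds the exposure-noise term.
    """
    if exp_beta == 0:
        raise ZeroDivisionError("Wald ratio undefined: exposure effect is zero")
    ratio = out_beta / exp_beta
    if second_order:
        se = np.sqrt(out_se**2 / exp_beta**2 + out_beta**2 * exp_se**2 / exp_beta**4)
    else:
        se = out_se / abs(exp_beta)
    return _finalize("wald", ratio, se, 1)


def _ratio_weights(h: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x, _, y, sy = _arrays(h)
    if np.any(x == 0):
        raise ZeroDivisionError("Wald ratio undefined: an exposure effect is zero")
    return y / x, (x / sy) ** 2  # ratios, inverse-variance weights


def ivw(h: pd.DataFrame, effects: str = "auto") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``effects``: ``"fixed"``, ``"random"`` (multiplicative over-dispersion
    floored at 1), or ``"auto"`` — fixed unless Cochran's Q has p < 0.05.
    A single instrument degrades to the Wald ratio.
    """
    if effects not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects mode {effects!r}")
    j = len(h)
    if j < 1:
        raise InsufficientInstrumentsError("IVW requires at least 1 instrument")
    if j == 1:
        row = h.iloc[0]
        return wald_ratio(row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"])
    r, w = _ratio_weights(h)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    if effects == "auto":
        q_pval = float(sps.chi2.sf(q, j - 1))
        effects = "random" if q_pval < 0.05 else "fixed"
    if effects == "fixed":
        return _finalize("ivw_fixed", beta, se_fixed, j)
    scale = max(1.0, np.sqrt(q / (j - 1)))
    return _finalize("ivw_random", beta, se_fixed * scale, j)


def cochran_q(h: pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic about the fixed-effect IVW estimate."""
    j = len(h)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires at least 2 instruments")
    r, w = _ratio_weights(h)
    beta = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - beta) ** 2))
    return q, j - 1, float(sps.chi2.sf(q, j - 1))


def mr_egger(h: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted regression of outcome on exposure effects
    with an intercept, after orienting exposure effects positive.

    Returns ``(slope, intercept)``; the intercept estimates the average
    directional-pleiotropy effect and its two-sided t test (J - 2 df) is the
    Egger pleiotropy test.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 instruments")
    x, _, y, sy = _arrays(h)
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    w = 1.0 / sy**2

    # weighted normal equations with intercept
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design: exposure effects are constant")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    se_slope = float(np.sqrt(sigma2 * sw / det))
    se_int = float(np.sqrt(sigma2 * swxx / det))
    slope_est = _finalize("egger_slope", slope, se_slope, j, df=j - 2)
    int_est = _finalize("egger_intercept", intercept, se_int, j, df=j - 2)
    return slope_est, int_est


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the half-offset cumulative
    normalized weights at 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    w = w / np.sum(w)
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def weighted_median(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The bootstrap redraws per-variant exposure and outcome effects from
    Normal(beta, se^2) and recomputes the weighted median ``n_boot`` times;
    the SE is the standard deviation of the replicates.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, sx, y, sy = _arrays(h)
    r, w = _ratio_weights(h)
    beta = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    xb = x + rng.standard_normal((n_boot, j)) * sx
    yb = y + rng.standard_normal((n_boot, j)) * sy
    xb[xb == 0] = np.finfo(float).tiny
    rb = yb / xb
    wb = (xb / sy) ** 2
    boots = np.array([_weighted_median_point(rb[i], wb[i]) for i in range(n_boot)])
    se = float(boots.std(ddof=1)) if n_boot > 1 else 0.0
    return _finalize("weighted_median", beta, se, j)


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, vectorized over the last axis."""
    swxy = np.sum(w * x * y, axis=-1, keepdims=True)
    swxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (swxy - w * x * y) / (swxx - w * x * x)


def mr_presso(
    h: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: simulation-based pleiotropy residual-sum and outlier tests.

    *Global test*: the observed weighted residual sum of squares of each
    instrument against its leave-one-out IVW prediction is compared with its
    null distribution, obtained by redrawing effects from their estimated
    normal sampling distributions ``n_sim`` times.  *Outlier test*: each
    instrument's observed squared residual against its simulated
    distribution, Bonferroni-corrected across instruments.  *Distortion
    test*: the shift of the IVW estimate after removing flagged outliers,
    against a null of removing equally many random instruments.
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 instruments")
    x, sx, y, sy = _arrays(h)
    w = 1.0 / sy**2
    rng = np.random.default_rng(seed)

    slopes = _loo_slopes(x, y, w)
    resid2_obs = w * (y - slopes * x) ** 2
    rss_obs = float(np.sum(resid2_obs))

    # null draws: exposure effects from their sampling distribution, outcome
    # effects from the leave-one-out prediction of each instrument
    xs = x + rng.standard_normal((n_sim, j)) * sx
    ys = slopes * x + rng.standard_normal((n_sim, j)) * sy
    slopes_sim = _loo_slopes(xs, ys, w)
    resid2_sim = w * (ys - slopes_sim * xs) ** 2
    rss_sim = np.sum(resid2_sim, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outliers = np.flatnonzero(p_adj < outlier_alpha)

    distortion_coef = distortion_pval = None
    if 0 < len(outliers) <= j - 2:
        beta_all = np.sum(w * x * y) / np.sum(w * x * x)
        keep = np.setdiff1d(np.arange(j), outliers)
        beta_no = np.sum(w[keep] * x[keep] * y[keep]) / np.sum(w[keep] * x[keep] ** 2)
        if beta_all != 0:
            distortion_coef = float((beta_no - beta_all) / abs(beta_all))
            null_d = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(j, size=len(outliers), replace=False)
                k = np.setdiff1d(np.arange(j), drop)
                b = np.sum(w[k] * x[k] * y[k]) / np.sum(w[k] * x[k] ** 2)
                null_d[i] = (b - beta_all) / abs(beta_all)
            distortion_pval = float(
                (1 + np.sum(np.abs(null_d) >= abs(distortion_coef))) / (n_sim + 1)
            )
    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_indices=outliers,
        outlier_pvals=p_adj,
        distortion_coef=distortion_coef,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
    )


def cooks_exclusion(h: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
    """Indices of instruments with Cook's distance above ``threshold``
    (default 4/J) in the weighted through-origin IVW regression."""
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError("Cook's-distance screening requires >= 3 instruments")
    if threshold is None:
        threshold = 4.0 / j
    x, _, y, sy = _arrays(h)
    sw = 1.0 / sy
    xs, ys = sw * x, sw * y  # whitened design: ordinary through-origin regression
    sxx = np.sum(xs**2)
    beta = np.sum(xs * ys) / sxx
    e = ys - beta * xs
    hat = xs**2 / sxx
    s2 = np.sum(e**2) / (j - 1)
    if s2 <= np.finfo(float).eps * np.mean(ys**2):  # numerically exact fit
        return np.array([], dtype=int)
    d = e**2 * hat / (s2 * (1.0 - hat) ** 2)
    return np.flatnonzero(d > threshold)


def estimate_all(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> dict[str, MREstimate]:
    """Run every univariable estimator the instrument count allows."""
    out: dict[str, MREstimate] = {}
    j = len(h)
    if j < 1:
        raise InsufficientInstrumentsError("no instruments")
    out["ivw"] = ivw(h, effects="auto")
    if j >= 2:
        out["ivw_fixed"] = ivw(h, effects="fixed")
        out["ivw_random"] = ivw(h, effects="random")
    if j >= 3:
        slope, intercept = mr_egger(h)
        out["egger_slope"] = slope
        out["egger_intercept"] = intercept
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
    return out


def rerun_after_removal(
    h: pd.DataFrame, excluded: np.ndarray | list[int], n_boot: int = 1000, seed: int = 0
) -> dict[str, MREstimate]:
    """Re-estimate all methods after dropping the excluded instrument rows."""
    excluded = np.asarray(excluded, dtype=int)
    if len(excluded) and (excluded.min() < 0 or excluded.max() >= len(h)):
        raise IndexError("excluded indices outside the instrument range")
    keep = np.setdiff1d(np.arange(len(h)), excluded)
    if len(keep) < 2:
        raise InsufficientInstrumentsError(
            f"only {len(keep)} instrument(s) would remain after removal"
        )
    return estimate_all(h.iloc[keep].reset_index(drop=True), n_boot=n_boot, seed=seed)


def sensitivity_report(
    h: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    n_boot: int = 1000,
) -> SensitivityReport:
    """Full sensitivity suite: Q, Egger intercept, MR-PRESSO, Cook's distance,
    and re-estimation after removing the union of flagged instruments."""
    q, df, q_pval = cochran_q(h)
    _, intercept = mr_egger(h)
    presso = mr_presso(h, n_sim=n_sim, seed=seed) if len(h) >= 4 else None
    cooks = cooks_exclusion(h)
    flagged = np.union1d(presso.outlier_indices, cooks) if presso is not None else cooks
    post = None
    if len(flagged) and len(h) - len(flagged) >= 2:
        post = rerun_after_removal(h, flagged, n_boot=n_boot, seed=seed)
    return SensitivityReport(
        q=q,
        q_df=df,
        q_pval=q_pval,
        egger_intercept=intercept,
        presso=presso,
        cooks_excluded=cooks,
        excluded=flagged,
        post_removal=post,
    )


def reverse_mr(
    outcome_as_exposure: pd.DataFrame,
    exposure_as_outcome: pd.DataFrame,
    panel: ReferencePanel | None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 500.0,
    min_f: float = 10.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """Reverse-direction MR with the roles of exposure and outcome swapped.

    Instruments are selected from the original outcome's summary statistics
    at the stricter genome-wide settings (p < 5e-8, clumping r^2 < 0.01).
    """
    from .instruments import select_instruments

    harmonized, _, _ = select_instruments(
        outcome_as_exposure,
        exposure_as_outcome,
        panel,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
        min_f=min_f,
    )
    if harmonized.empty:
        raise InsufficientInstrumentsError(
            "no genome-wide-significant instruments for the reverse direction"
        )
    return estimate_all(harmonized, n_boot=n_boot, seed=seed)
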