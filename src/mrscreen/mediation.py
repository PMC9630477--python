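"""Multivariable MR and mediation decomposition with bootstrap intervals.

Multivariable MR regresses the instruments' outcome effects on the matrix of
their exposure effects by weighted least squares without intercept (weights
1 / se_out^2), giving each exposure's *direct* effect conditional on the
others:

    beta_out_j = sum_i beta_exposure_i,j * theta_i + e_j,   e_j ~ N(0, sigma^2)

Standard errors carry a multiplicative over-dispersion factor floored at 1,
so the single-exposure case reproduces fixed-/random-effect IVW exactly.

Mediation follows the network-MR convention: instruments are selected for
the exposure only; the total effect comes from univariable IVW of the
outcome on the exposure, the direct effect from multivariable MR including
the mediator, and the indirect effect is their difference (product-of-paths
available as an option).  Confidence intervals are percentile intervals from
a parametric bootstrap that redraws every per-variant effect from
Normal(beta, se^2) — the only resampling possible from summary statistics —
with 1,000 replications by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps

from . import estimators as est
from . import instruments as ins
from .simulate import ReferencePanel

__all__ = [
    "MVMRResult",
    "MediationResult",
    "CollinearityError",
    "BootstrapError",
    "mvmr_fit",
    "mediation_decompose",
    "bootstrap_ci",
]

_TOTAL_TOL = 1e-12


class CollinearityError(ValueError):
    """The weighted multivariable design is rank-deficient."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates produced an undefined statistic."""


@dataclass
class MVMRResult:
    """Weighted-least-squares multivariable MR fit."""

    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    sigma2: float  # weighted residual variance (over-dispersion before flooring)
    n_snps: int
    condition_number: float

    def coefficient(self, name: str) -> float:
        return float(self.beta[self.exposures.index(name)])


@dataclass
class MediationResult:
    """Total / direct / indirect decomposition with bootstrap CIs.

    ``total = direct + indirect`` holds identically under the difference
    method.  ``proportion`` is NaN when the total effect is numerically zero.
    """

    total: float
    direct: float
    indirect: float
    proportion: float
    ci: dict[str, tuple[float, float]]
    n_boot: int
    n_snps: int
    method: str
    instrument_policy: str = "exposure"
    total_estimate: est.MREstimate | None = None
    mvmr: MVMRResult | None = None


def mvmr_fit(
    out_beta: np.ndarray,
    out_se: np.ndarray,
    exposure_betas: np.ndarray | pd.DataFrame,
    exposures: list[str] | None = None,
) -> MVMRResult:
    """Fit the multivariable MR weighted least-squares model (no intercept).

    ``exposure_betas`` is the (J x k) matrix of each instrument's marginal
    effect on each exposure.  Raises :class:`CollinearityError` naming the
    offending columns when the weighted design is rank-deficient.
    """
    if isinstance(exposure_betas, pd.DataFrame):
        exposures = list(exposure_betas.columns)
        x = exposure_betas.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(exposure_betas, dtype=float))
        if x.ndim == 2 and x.shape[0] == 1 and len(out_beta) != 1:
            x = x.T
    if x.ndim == 1:
        x = x[:, None]
    j, k = x.shape
    if exposures is None:
        exposures = [f"exposure_{i + 1}" for i in range(k)]
    y = np.asarray(out_beta, dtype=float)
    sy = np.asarray(out_se, dtype=float)
    if len(y) != j or len(sy) != j:
        raise ValueError("outcome effects and exposure-effect matrix must have equal rows")
    if j <= k:
        raise est.InsufficientInstrumentsError(
            f"multivariable MR with {k} exposure(s) needs more than {k} instruments, got {j}"
        )

    sw = 1.0 / sy
    xw, yw = x * sw[:, None], y * sw
    # pivoted QR exposes which columns are linearly dependent
    _, rdiag, piv = sla.qr(xw, pivoting=True, mode="economic")
    diag = np.abs(np.diag(rdiag))
    tol = diag.max() * max(j, k) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < k:
        bad = [exposures[i] for i in piv[rank:]]
        raise CollinearityError(
            f"rank-deficient weighted design (rank {rank} < {k}); "
            f"collinear column(s): {', '.join(bad)}"
        )

    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta
    sigma2 = float(resid @ resid / (j - k))
    scale = max(1.0, np.sqrt(sigma2))
    cov = np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov)) * scale
    pval = np.clip(2.0 * sps.norm.sf(np.abs(beta) / se), np.finfo(float).tiny, 1.0)
    return MVMRResult(
        exposures=exposures,
        beta=beta,
        se=se,
        pval=pval,
        sigma2=sigma2,
        n_snps=j,
        condition_number=float(np.linalg.cond(xw)),
    )


def bootstrap_ci(
    sample_fn: Callable[[np.random.Generator], dict[str, float]],
    n_reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    allow_undefined: frozenset[str] | set[str] = frozenset(),
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for a dict-valued statistic.

    ``sample_fn(rng)`` must return one replicate's statistics.  Raises
    :class:`BootstrapError` if any statistic is undefined (non-finite) in
    more than 10% of replicates, except for names in ``allow_undefined``,
    whose interval is reported as (nan, nan) instead — e.g. a proportion
    mediated when the total effect is numerically zero.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {}
    for _ in range(n_reps):
        stat = sample_fn(rng)
        for name, value in stat.items():
            reps.setdefault(name, []).append(value)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out: dict[str, tuple[float, float]] = {}
    for name, values in reps.items():
        arr = np.asarray(values, dtype=float)
        bad = ~np.isfinite(arr)
        if bad.mean() > 0.10:
            if name in allow_undefined:
                out[name] = (float("nan"), float("nan"))
                continue
            raise BootstrapError(
                f"statistic {name!r} undefined in {bad.sum()}/{n_reps} bootstrap replicates"
            )
        good = arr[~bad]
        out[name] = (float(np.percentile(good, lo_q)), float(np.percentile(good, hi_q)))
    return out


def _align_mediation(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    instruments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-instrument aligned effects on exposure, mediator and outcome,
    all expressed on the exposure's effect allele."""
    h_out = ins.harmonize(exposure, outcome, subset=instruments)
    h_med = ins.harmonize(exposure, mediator, subset=instruments)
    med = h_med.rename(
        columns={"beta_out": "beta_med", "se_out": "se_med"}
    )[["SNP", "beta_med", "se_med"]]
    merged = h_out.merge(med, on="SNP", how="inner")
    return merged


def _decompose_point(
    bx: np.ndarray,
    by: np.ndarray,
    bm: np.ndarray,
    sy: np.ndarray,
    sm: np.ndarray,
    is_exp: np.ndarray,
    method: str,
) -> dict[str, float]:
    """Point decomposition: total (univariable IVW over the exposure's own
    instruments), direct (MVMR over all rows), indirect."""
    w = 1.0 / sy**2
    we, bxe, bye = w[is_exp], bx[is_exp], by[is_exp]
    total = float(np.sum(we * bxe * bye) / np.sum(we * bxe**2))
    x = np.column_stack([bx, bm])
    xw = x * np.sqrt(w)[:, None]
    theta = np.linalg.solve(xw.T @ xw, xw.T @ (by * np.sqrt(w)))
    direct = float(theta[0])
    if method == "difference":
        indirect = total - direct
    else:  # product of paths: (exposure -> mediator) x (mediator -> outcome)
        wm = 1.0 / sm[is_exp] ** 2
        bme = bm[is_exp]
        a_hat = float(np.sum(wm * bxe * bme) / np.sum(wm * bxe**2))
        indirect = a_hat * float(theta[1])
    proportion = indirect / total if abs(total) > _TOTAL_TOL else np.nan
    return {"total": total, "direct": direct, "indirect": indirect, "proportion": proportion}


def mediation_decompose(
    exposure: pd.DataFrame,
    mediator: pd.DataFrame,
    outcome: pd.DataFrame,
    panel: ReferencePanel | None = None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.1,
    window_kb: float = 500.0,
    min_f: float = 10.0,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    method: str = "difference",
    instrument_policy: str = "exposure",
) -> MediationResult:
    """Decompose the exposure's effect on the outcome into the component
    transmitted through the mediator and the remainder.

    Instruments default to the exposure's (network-MR convention): selected
    at ``p_threshold``, optionally LD-clumped, strength-filtered, then the
    mediator's and outcome's effects at those variants are harmonized onto
    the exposure's effect alleles.  ``instrument_policy="union"`` adds the
    mediator's own instruments (selected from the mediator table the same
    way) to the multivariable fit; the total effect is always estimated on
    the exposure's instruments alone.  When exposure and mediator share all
    their instruments through a single causal chain, the mediator column is
    collinear with the exposure column and only the union policy identifies
    the mediator path.

    ``method="difference"`` (default) sets indirect = total - direct;
    ``method="product"`` multiplies the exposure->mediator and
    mediator->outcome path estimates instead.
    """
    if method not in ("difference", "product"):
        raise ValueError(f"unknown mediation method {method!r}")
    if instrument_policy not in ("exposure", "union"):
        raise ValueError(f"unknown instrument policy {instrument_policy!r}")

    def _instruments(table: pd.DataFrame) -> pd.DataFrame:
        sig = ins.select_significant(table, p_threshold)
        if panel is not None:
            sig = ins.ld_clump(sig, panel, r2_threshold=r2_threshold, window_kb=window_kb)
        return ins.compute_strength(sig, int(table["N"].iloc[0]), min_f=min_f).table

    exp_snps = set(_instruments(exposure)["SNP"])
    med_snps: set[str] = set()
    if instrument_policy == "union":
        med_snps = set(_instruments(mediator)["SNP"]) - exp_snps
    all_snps = exp_snps | med_snps
    subset = exposure.loc[exposure["SNP"].isin(all_snps), ["SNP"]]
    aligned = _align_mediation(exposure, mediator, outcome, subset)
    aligned["exposure_instrument"] = aligned["SNP"].isin(exp_snps)
    j = len(aligned)
    if j < 3 or aligned["exposure_instrument"].sum() < 1:
        raise est.InsufficientInstrumentsError(
            f"mediation needs at least 3 harmonized instruments "
            f"(got {j}, of which {int(aligned['exposure_instrument'].sum())} for the exposure)"
        )

    bx = aligned["beta_exp"].to_numpy(dtype=float)
    sx = aligned["se_exp"].to_numpy(dtype=float)
    bm = aligned["beta_med"].to_numpy(dtype=float)
    sm = aligned["se_med"].to_numpy(dtype=float)
    by = aligned["beta_out"].to_numpy(dtype=float)
    sy = aligned["se_out"].to_numpy(dtype=float)
    is_exp = aligned["exposure_instrument"].to_numpy(dtype=bool)

    point = _decompose_point(bx, by, bm, sy, sm, is_exp, method)
    total_est = est.ivw(aligned.loc[is_exp].reset_index(drop=True), effects="auto")
    mvmr = mvmr_fit(by, sy, np.column_stack([bx, bm]), exposures=["exposure", "mediator"])

    def one_rep(rng: np.random.Generator) -> dict[str, float]:
        bxr = bx + rng.standard_normal(j) * sx
        bmr = bm + rng.standard_normal(j) * sm
        byr = by + rng.standard_normal(j) * sy
        return _decompose_point(bxr, byr, bmr, sy, sm, is_exp, method)

    ci = bootstrap_ci(
        one_rep, n_reps=n_boot, seed=seed, level=level, allow_undefined={"proportion"}
    )
    return MediationResult(
        total=point["total"],
        direct=point["direct"],
        indirect=point["indirect"],
        proportion=point["proportion"],
        ci=ci,
        n_boot=n_boot,
        n_snps=j,
        method=method,
        instrument_policy=instrument_policy,
        total_estimate=total_est,
        mvmr=mvmr,
    )
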