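"""Instrument selection: significance filtering, LD clumping, allele
harmonization and instrument-strength (PVE / F statistic) filtering.

The selection cascade mirrors standard two-sample MR practice: keep variants
below a loose exposure p-value threshold (1e-5 by default), thin them by
greedy p-value-ranked LD clumping against a reference panel (r^2 < 0.1 within
500 kb by default), align outcome effect alleles to the exposure, and drop
weak instruments (per-variant F < 10).  The stricter genome-wide settings
used for outcome-side (reverse-direction) instruments are p < 5e-8 with
clumping r^2 < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ReferencePanel

__all__ = [
    "InstrumentSet",
    "MissingVariantError",
    "select_significant",
    "ld_clump",
    "harmonize",
    "compute_strength",
    "select_instruments",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: Palindromic variants with an allele frequency inside this band are
#: strand-ambiguous and dropped during harmonization.
AMBIGUOUS_EAF_BAND = (0.42, 0.58)


class MissingVariantError(KeyError):
    """A variant required for LD computation is absent from the panel."""


@dataclass
class InstrumentSet:
    """Strength-filtered instruments for one exposure.

    ``table`` has one row per retained variant with PVE and F columns;
    ``r_squared`` is the summed PVE of the set and ``f_overall`` the
    set-level F statistic.  ``log`` records each filtering step.
    """

    table: pd.DataFrame
    n_exposure: int
    r_squared: float
    f_overall: float
    log: list[str] = field(default_factory=list)


def select_significant(stats: pd.DataFrame, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Variants with exposure p-value strictly below ``p_threshold``.

    Original row order is preserved; an empty result is allowed.
    """
    return stats.loc[stats["P"] < p_threshold].reset_index(drop=True)


def ld_clump(
    subset: pd.DataFrame,
    panel: ReferencePanel,
    r2_threshold: float = 0.1,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """Greedy p-value-ranked LD clumping.

    Repeatedly take the remaining variant with the smallest p-value as the
    clump index and remove every other remaining variant on the same
    chromosome within ``window_kb`` whose sample r^2 with the index exceeds
    ``r2_threshold``.  Ties on p break by position then id, making the result
    independent of input row order.
    """
    missing = [s for s in subset["SNP"] if s not in panel]
    if missing:
        raise MissingVariantError(
            f"variants absent from the reference panel: {', '.join(missing)}"
        )
    if subset.empty:
        return subset.reset_index(drop=True)

    work = subset.reset_index(drop=True)
    order = work.sort_values(["P", "POS", "SNP"], kind="mergesort").index.to_numpy()
    window_bp = window_kb * 1000.0
    alive = np.ones(len(work), dtype=bool)
    kept: list[int] = []
    chrom = work["CHR"].to_numpy()
    pos = work["POS"].to_numpy(dtype=float)
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        for j in np.flatnonzero(near):
            if panel.r2(work.at[i, "SNP"], work.at[j, "SNP"]) > r2_threshold:
                alive[j] = False
    kept_ids = set(work.loc[kept, "SNP"])
    return work.loc[work["SNP"].isin(kept_ids)].reset_index(drop=True)


def _align_outcome_row(exp_row, out_row) -> tuple[float, float, bool] | None:
    """Orientation of one outcome record against the exposure's alleles.

    Returns ``(beta, eaf, flipped)`` for the outcome effect expressed on the
    exposure's effect allele, or ``None`` if the allele pair is incompatible
    or a palindromic variant is frequency-ambiguous.
    """
    e_ea, e_oa = exp_row["EA"], exp_row["OA"]
    o_ea, o_oa = out_row["EA"], out_row["OA"]
    beta, eaf = out_row["BETA"], out_row["EAF"]

    if (e_ea, e_oa) in _PALINDROMIC:
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return None
        # strand flips are indistinguishable from allele swaps: use frequency
        lo, hi = AMBIGUOUS_EAF_BAND
        f_exp = exp_row["EAF"]
        f_out = eaf if o_ea == e_ea else 1.0 - eaf
        if not (f_exp < lo or f_exp > hi) or not (f_out < lo or f_out > hi):
            return None
        if o_ea != e_ea:
            beta, eaf = -beta, 1.0 - eaf
        if (f_exp - 0.5) * (f_out - 0.5) < 0:  # opposite minor allele: flipped strand
            return (-beta, 1.0 - eaf, True)
        return (beta, eaf, o_ea != e_ea)

    candidates = [
        (o_ea, o_oa, False),
        (_COMPLEMENT.get(o_ea), _COMPLEMENT.get(o_oa), False),
    ]
    for ea, oa, _ in list(candidates):
        candidates.append((oa, ea, True))
    for ea, oa, swapped in candidates:
        if (ea, oa) == (e_ea, e_oa):
            if swapped:
                return (-beta, 1.0 - eaf, True)
            return (beta, eaf, False)
    return None


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    subset: pd.DataFrame | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Where the outcome's effect allele is the exposure's other allele (directly
    or on the complementary strand) the outcome beta is sign-flipped and its
    frequency complemented.  Palindromic (A/T, C/G) variants are aligned by
    allele frequency when both frequencies fall outside the ambiguity band
    ``AMBIGUOUS_EAF_BAND`` and dropped otherwise.  Variants missing from the
    outcome, or with incompatible allele pairs, are dropped and logged.

    Returns one row per harmonized variant: SNP, CHR, POS, EA, OA,
    beta_exp, se_exp, eaf_exp, p_exp, beta_out, se_out, eaf_out, p_out,
    flipped, n_exp, n_out.
    """
    log = log if log is not None else []
    exp = exposure if subset is None else exposure.loc[
        exposure["SNP"].isin(set(subset["SNP"]))
    ]
    out_by_snp = outcome.set_index("SNP", drop=False)

    rows = []
    n_missing = n_incompatible = n_ambiguous = 0
    for _, erow in exp.iterrows():
        snp = erow["SNP"]
        if snp not in out_by_snp.index:
            n_missing += 1
            continue
        orow = out_by_snp.loc[snp]
        aligned = _align_outcome_row(erow, orow)
        if aligned is None:
            if {orow["EA"], orow["OA"]} == {erow["EA"], erow["OA"]} or {
                _COMPLEMENT.get(orow["EA"]),
                _COMPLEMENT.get(orow["OA"]),
            } == {erow["EA"], erow["OA"]}:
                n_ambiguous += 1
                log.append(f"dropped {snp}: palindromic with ambiguous allele frequency")
            else:
                n_incompatible += 1
                log.append(
                    f"dropped {snp}: incompatible alleles "
                    f"{erow['EA']}/{erow['OA']} vs {orow['EA']}/{orow['OA']}"
                )
            continue
        beta_out, eaf_out, flipped = aligned
        rows.append(
            {
                "SNP": snp,
                "CHR": erow["CHR"],
                "POS": erow["POS"],
                "EA": erow["EA"],
                "OA": erow["OA"],
                "beta_exp": erow["BETA"],
                "se_exp": erow["SE"],
                "eaf_exp": erow["EAF"],
                "p_exp": erow["P"],
                "beta_out": beta_out,
                "se_out": orow["SE"],
                "eaf_out": eaf_out,
                "p_out": orow["P"],
                "flipped": flipped,
                "n_exp": erow["N"],
                "n_out": orow["N"],
            }
        )
    if n_missing:
        log.append(f"dropped {n_missing} variant(s) absent from the outcome table")
    columns = [
        "SNP", "CHR", "POS", "EA", "OA",
        "beta_exp", "se_exp", "eaf_exp", "p_exp",
        "beta_out", "se_out", "eaf_out", "p_out",
        "flipped", "n_exp", "n_out",
    ]
    return pd.DataFrame(rows, columns=columns)


def per_snp_pve(beta: np.ndarray, se: np.ndarray, eaf: np.ndarray, n: int) -> np.ndarray:
    """Summary-statistic approximation of per-variant variance explained.

    PVE_j = 2 f (1-f) beta^2 / (2 f (1-f) beta^2 + 2 f (1-f) se^2 n).
    """
    num = 2.0 * eaf * (1.0 - eaf) * beta**2
    den = num + 2.0 * eaf * (1.0 - eaf) * se**2 * n
    return num / den


def compute_strength(
    subset: pd.DataFrame,
    n: int,
    min_f: float = 10.0,
    log: list[str] | None = None,
) -> InstrumentSet:
    """Annotate instruments with PVE and F and drop weak ones (F < ``min_f``).

    Per-variant F_j = (n - 2) PVE_j / (1 - PVE_j); the set-level F uses the
    summed PVE: F = ((n - k - 1) / k) R^2 / (1 - R^2) over the k retained
    instruments.
    """
    log = log if log is not None else []
    beta = subset["BETA"].to_numpy(dtype=float)
    se = subset["SE"].to_numpy(dtype=float)
    eaf = subset["EAF"].to_numpy(dtype=float)
    pve = per_snp_pve(beta, se, eaf, n)
    f_stat = (n - 2) * pve / (1.0 - pve)

    table = subset.copy().reset_index(drop=True)
    table["PVE"] = pve
    table["F"] = f_stat
    weak = table["F"] < min_f
    if weak.any():
        log.append(f"removed {int(weak.sum())} weak instrument(s) with F < {min_f}")
    table = table.loc[~weak].reset_index(drop=True)

    k = len(table)
    if k == 0:
        return InstrumentSet(table=table, n_exposure=n, r_squared=0.0, f_overall=0.0, log=log)
    if n <= k + 1:
        raise ValueError(f"exposure sample size n={n} must exceed k+1={k + 1} instruments")
    r2 = float(table["PVE"].sum())
    f_overall = ((n - k - 1) / k) * r2 / (1.0 - r2)
    return InstrumentSet(table=table, n_exposure=n, r_squared=r2, f_overall=f_overall, log=log)


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    panel: ReferencePanel | None,
    p_threshold: float = 1e-5,
    r2_threshold: float = 0.1,
    window_kb: float = 500.0,
    min_f: float = 10.0,
) -> tuple[pd.DataFrame, InstrumentSet, list[str]]:
    """Full selection cascade: significance -> clump -> strength -> harmonize.

    Returns ``(harmonized, instrument_set, log)``.  Pass ``panel=None`` to
    skip LD clumping (e.g. when instruments are known independent).
    """
    log: list[str] = []
    sig = select_significant(exposure, p_threshold)
    log.append(f"{len(sig)}/{len(exposure)} variant(s) pass p < {p_threshold:g}")
    if panel is not None:
        clumped = ld_clump(sig, panel, r2_threshold=r2_threshold, window_kb=window_kb)
        log.append(f"{len(clumped)} variant(s) survive clumping (r2 <= {r2_threshold}, {window_kb} kb)")
    else:
        clumped = sig
        log.append("clumping skipped: no reference panel supplied")
    n_exp = int(exposure["N"].iloc[0]) if len(exposure) else 0
    iset = compute_strength(clumped, n_exp, min_f=min_f, log=log)
    harmonized = harmonize(exposure, outcome, subset=iset.table, log=log)
    log.append(f"{len(harmonized)} instrument(s) harmonized against the outcome")
    return harmonized, iset, log
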