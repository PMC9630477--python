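"""Benjamini-Hochberg FDR correction within trait-type x panel subgroups.

The immune-trait screen groups its 731 exposures by measurement type (median
fluorescence intensity, absolute count, relative count, morphological
parameter) and by flow-cytometry panel (7 panels), and applies the BH
step-up correction independently within each of the 4 x 7 = 28 subgroups.
Only the primary (IVW) p-values are corrected; sensitivity-method p-values
are reported unadjusted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TRAIT_TYPES",
    "PANELS",
    "bh_adjust",
    "groupwise_fdr",
]

TRAIT_TYPES = ("MFI", "AC", "RC", "MP")
PANELS = (
    "maturation stages of T cell",
    "TBNK",
    "Treg",
    "B cell",
    "Myeloid cell",
    "cDC",
    "Monocyte",
)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[~np.isfinite(p) | (p <= 0) | (p > 1)]
        raise ValueError(f"p-values must lie in (0, 1]; offending values: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


def groupwise_fdr(
    results: pd.DataFrame,
    group_cols: tuple[str, ...] = ("trait_type", "panel"),
    p_col: str = "pval",
    alpha: float = 0.05,
    validate_labels: bool = True,
) -> pd.DataFrame:
    """Apply BH correction independently within each subgroup.

    With the default grouping key (trait_type, panel) and the full label set
    this yields the 28 subgroups of the screen.  Adds ``p_fdr`` and
    ``significant`` columns; empty groups are simply absent.  The grouping
    key is configurable (e.g. add the outcome id to correct per outcome).
    """
    for col in (*group_cols, p_col):
        if col not in results.columns:
            raise ValueError(f"results table lacks required column {col!r}")
    if validate_labels:
        if "trait_type" in group_cols:
            bad = set(results["trait_type"]) - set(TRAIT_TYPES)
            if bad:
                raise ValueError(f"unknown trait_type label(s): {sorted(bad)}")
        if "panel" in group_cols:
            bad = set(results["panel"]) - set(PANELS)
            if bad:
                raise ValueError(f"unknown panel label(s): {sorted(bad)}")

    out = results.copy()
    out["p_fdr"] = np.nan
    for _, idx in out.groupby(list(group_cols), observed=True, sort=False).groups.items():
        out.loc[idx, "p_fdr"] = bh_adjust(out.loc[idx, p_col].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out
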