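"""Synthetic GWAS summary statistics with known causal structure.

Generates paired exposure/outcome (and exposure/mediator/outcome) marginal
association tables plus block-LD reference panels, so every downstream stage
of the MR screen can be checked against planted ground truth.

The generative model is the standard two-sample MR summary-level model.  Each
variant j carries a true exposure effect ``gamma_j ~ N(0, gamma_sd^2)``.  The
true outcome effect is

    Gamma_j = causal_beta * gamma_j + alpha_j

where ``alpha_j = 0`` for valid instruments and, for an ``invalid_frac``
fraction of variants, ``alpha_j = sign(gamma_j) * (pleio_mean + kappa *
|gamma_j| + N(0, pleio_sd^2))`` — a direct (horizontally pleiotropic) path
to the outcome.  Pleiotropy is planted relative to the *exposure-increasing*
allele: because allele labels are arbitrary, "directional" pleiotropy (a
nonzero mean) is only orientation-invariant when defined on that frame, and
it is the frame MR-Egger regresses in.  ``truth.alpha`` records the
exposure-increasing-orientation magnitudes, whose mean is ``pleio_mean``.
``kappa = 0`` (the default) satisfies the InSIDE assumption; ``kappa != 0``
correlates pleiotropy with instrument strength, the regime in which MR-Egger
is known to fail.

Observed marginal effects add sampling noise with the analytic standard error
of a standardized-trait GWAS regression coefficient,

    SE_j = 1 / sqrt(2 * n * eaf_j * (1 - eaf_j)),

and two-sided p-values from the normal approximation.  Marginal effects are
simulated directly at the summary level; the LD reference panel is generated
separately and used only for clumping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "SimulationTruth",
    "ReferencePanel",
    "SUMMARY_COLUMNS",
    "simulate_summary_stats",
    "simulate_ld_panel",
    "simulate_mediation_stats",
    "read_summary_stats",
    "write_summary_stats",
    "read_panel",
    "write_panel",
]

#: Canonical header of a summary-statistics table (tab-delimited on disk).
SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-sample GWAS.

    Defaults mirror the study design being emulated: a 3,757-sample exposure
    GWAS of blood immune-cell traits and a 66,628-sample outcome GWAS of
    total-body bone mineral density.  ``gamma_sd = 0.15`` puts typical
    per-instrument PVE in the fraction-of-a-percent range reported for such
    immune-trait instruments.
    """

    n_snps: int = 50
    n_exp: int = 3757
    n_out: int = 66628
    causal_beta: float = 0.0
    gamma_sd: float = 0.15
    invalid_frac: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.05
    inside_violation: float = 0.0  # kappa: correlation of pleiotropy with gamma_j
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    pos_step: int = 100_000
    chrom: str = "1"
    flip_outcome: bool = False  # swap EA/OA and negate BETA on a random 50% of outcome rows

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= self.invalid_frac <= 1.0):
            raise ConfigurationError(f"invalid_frac must be in [0, 1], got {self.invalid_frac}")
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range bounds must lie in (0, 0.5], got {self.maf_range}")
        if self.n_snps < 1:
            raise ConfigurationError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.n_exp < 2 or self.n_out < 2:
            raise ConfigurationError("sample sizes must be >= 2")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ConfigurationError("gamma_sd and pleio_sd must be non-negative")


@dataclass
class SimulationTruth:
    """Planted ground truth for a simulated dataset.

    Per-SNP arrays are aligned with the row order of the emitted tables.
    For mediation scenarios, ``a`` (exposure -> mediator), ``b`` (mediator ->
    outcome) and ``c`` (direct exposure -> outcome) are recorded and the
    total exposure effect is ``c + a * b``.
    """

    snp: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray
    causal_beta: float
    a: float | None = None
    b: float | None = None
    c: float | None = None
    delta: np.ndarray | None = None  # mediator-specific instrument effects

    @property
    def total_effect(self) -> float:
        if self.a is None:
            return self.causal_beta
        return self.c + self.a * self.b

    @property
    def indirect_effect(self) -> float | None:
        if self.a is None:
            return None
        return self.a * self.b

    @property
    def proportion_mediated(self) -> float | None:
        if self.a is None or self.total_effect == 0:
            return None
        return (self.a * self.b) / self.total_effect


@dataclass
class ReferencePanel:
    """Haplotype reference panel used for LD computation.

    ``haplotypes`` is a (samples x variants) 0/1 allele-count matrix;
    ``variants`` carries SNP/CHR/POS aligned to its columns.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != len(self.variants):
            raise ConfigurationError(
                f"panel has {self.haplotypes.shape[1]} haplotype columns "
                f"but {len(self.variants)} variant records"
            )
        self._index = {s: i for i, s in enumerate(self.variants["SNP"])}

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def column(self, snp: str) -> np.ndarray:
        try:
            return self.haplotypes[:, self._index[snp]]
        except KeyError:
            raise KeyError(f"variant {snp!r} not present in the reference panel") from None

    def r2(self, snp_a: str, snp_b: str) -> float:
        """Squared sample correlation between two variants' allele counts."""
        x, y = self.column(snp_a).astype(float), self.column(snp_b).astype(float)
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:  # monomorphic: no information, treat as unlinked
            return 0.0
        r = np.corrcoef(x, y)[0, 1]
        return float(r * r)

    def r2_matrix(self, snps: list[str]) -> pd.DataFrame:
        cols = np.stack([self.column(s).astype(float) for s in snps], axis=1)
        sd = cols.std(axis=0)
        sd[sd == 0.0] = np.nan
        c = np.corrcoef(cols, rowvar=False)
        r2 = np.nan_to_num(c * c, nan=0.0)
        return pd.DataFrame(r2, index=snps, columns=snps)


# ---------------------------------------------------------------------------
# generation


def _analytic_se(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    # a p of exactly 0 would violate the (0, 1] contract downstream
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Random ordered pairs of distinct nucleotides (palindromic pairs included)."""
    ea_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    oa_idx = (ea_idx + shift) % 4
    return _NUCLEOTIDES[ea_idx], _NUCLEOTIDES[oa_idx]


def _variant_frame(config: SimulationConfig, n: int, rng: np.random.Generator):
    snp = np.array([f"rs{j + 1}" for j in range(n)])
    pos = (np.arange(n) + 1) * config.pos_step
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    ea, oa = _draw_alleles(rng, n)
    return snp, pos, eaf, ea, oa


def _observe(true_beta: np.ndarray, eaf: np.ndarray, n: int, rng: np.random.Generator) -> pd.DataFrame:
    se = _analytic_se(n, eaf)
    beta = true_beta + rng.standard_normal(true_beta.shape) * se
    return beta, se, _two_sided_p(beta, se)


def _assemble(snp, chrom, pos, ea, oa, eaf, beta, se, p, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SNP": snp,
            "CHR": chrom,
            "POS": pos,
            "EA": ea,
            "OA": oa,
            "EAF": eaf,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
        }
    )


def _flip_rows(table: pd.DataFrame, rng: np.random.Generator, frac: float = 0.5) -> pd.DataFrame:
    """Swap EA/OA, complement EAF and negate BETA on a random subset of rows.

    The flipped table encodes identical associations; harmonization must undo
    the relabelling exactly.
    """
    flip = rng.random(len(table)) < frac
    out = table.copy()
    out.loc[flip, ["EA", "OA"]] = out.loc[flip, ["OA", "EA"]].to_numpy()
    out.loc[flip, "EAF"] = 1.0 - out.loc[flip, "EAF"]
    out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    return out


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate an exposure/outcome pair of GWAS summary-statistics tables.

    Returns ``(exposure, outcome, truth)``.  Both tables share SNP ids,
    positions and allele frequencies; the outcome table optionally has a
    random half of its rows allele-flipped (``config.flip_outcome``) to
    exercise harmonization.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp, pos, eaf, ea, oa = _variant_frame(config, n, rng)

    gamma = rng.normal(0.0, config.gamma_sd, size=n)
    n_invalid = int(round(config.invalid_frac * n))
    invalid = np.zeros(n, dtype=bool)
    invalid[rng.permutation(n)[:n_invalid]] = True
    alpha = np.zeros(n)
    alpha[invalid] = (
        config.pleio_mean
        + config.inside_violation * np.abs(gamma[invalid])
        + rng.normal(0.0, config.pleio_sd, size=n_invalid)
    )
    # alpha acts on the exposure-increasing allele; re-express on the emitted one
    big_gamma = config.causal_beta * gamma + np.sign(gamma) * alpha

    b_exp, se_exp, p_exp = _observe(gamma, eaf, config.n_exp, rng)
    b_out, se_out, p_out = _observe(big_gamma, eaf, config.n_out, rng)

    exposure = _assemble(snp, config.chrom, pos, ea, oa, eaf, b_exp, se_exp, p_exp, config.n_exp)
    outcome = _assemble(snp, config.chrom, pos, ea, oa, eaf, b_out, se_out, p_out, config.n_out)
    if config.flip_outcome:
        outcome = _flip_rows(outcome, rng)

    truth = SimulationTruth(
        snp=snp, gamma=gamma, alpha=alpha, valid=~invalid, causal_beta=config.causal_beta
    )
    return exposure, outcome, truth


def simulate_ld_panel(
    n_blocks: int,
    block_size: int,
    rho: float,
    n_haplotypes: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    pos_step: int = 100_000,
    chrom: str = "1",
) -> ReferencePanel:
    """Simulate a haplotype reference panel with block-diagonal AR(1) LD.

    Within a block, each haplotype is a copy-with-probability-``rho`` Markov
    chain over alleles with a common block-level frequency, so the allele
    correlation between variants at lag k is exactly ``rho**k``; blocks are
    independent.  Positions are spaced ``pos_step`` bp apart on one
    chromosome, matching the id/position scheme of
    :func:`simulate_summary_stats` so a panel with ``n_blocks * block_size ==
    n_snps`` aligns variant-for-variant.

    ``rho`` must lie in [0, 1): the copy-chain construction cannot represent
    negative allele correlation.
    """
    if not (0.0 <= rho < 1.0):
        raise ConfigurationError(f"rho must be in [0, 1), got {rho}")
    if n_blocks < 1 or block_size < 1 or n_haplotypes < 2:
        raise ConfigurationError("n_blocks, block_size must be >= 1 and n_haplotypes >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range bounds must lie in (0, 0.5], got {maf_range}")

    rng = np.random.default_rng(seed)
    n_var = n_blocks * block_size
    haps = np.empty((n_haplotypes, n_var), dtype=np.int8)
    for b in range(n_blocks):
        f = rng.uniform(lo, hi)
        start = b * block_size
        col = (rng.random(n_haplotypes) < f).astype(np.int8)
        haps[:, start] = col
        for j in range(1, block_size):
            fresh = (rng.random(n_haplotypes) < f).astype(np.int8)
            copy = rng.random(n_haplotypes) < rho
            col = np.where(copy, col, fresh)
            haps[:, start + j] = col

    variants = pd.DataFrame(
        {
            "SNP": [f"rs{j + 1}" for j in range(n_var)],
            "CHR": chrom,
            "POS": (np.arange(n_var) + 1) * pos_step,
        }
    )
    return ReferencePanel(haplotypes=haps, variants=variants)


def simulate_mediation_stats(
    config: SimulationConfig,
    a: float,
    b: float,
    c: float,
    n_med: int | None = None,
    n_snps_mediator: int | None = None,
    delta_sd: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Simulate exposure/mediator/outcome tables for a mediation scenario.

    The exposure has ``config.n_snps`` instruments with effects ``gamma_j``;
    the mediator additionally has ``n_snps_mediator`` instruments of its own
    with effects ``delta_k`` (disjoint variants).  True marginal effects:

    * mediator  = ``a * gamma_j`` at exposure SNPs, ``delta_k`` at its own;
    * outcome   = ``(c + a * b) * gamma_j + alpha_j`` at exposure SNPs and
      ``b * delta_k`` at mediator SNPs,

    so the planted total exposure effect is ``c + a * b`` and the proportion
    mediated is ``a * b / (c + a * b)``.  Pleiotropy (``invalid_frac`` etc.)
    applies to the exposure instrument set.
    """
    rng = np.random.default_rng(config.seed)
    n_e = config.n_snps
    n_m = n_e if n_snps_mediator is None else n_snps_mediator
    n_med = config.n_exp if n_med is None else n_med
    d_sd = config.gamma_sd if delta_sd is None else delta_sd
    if n_m < 1:
        raise ConfigurationError(f"n_snps_mediator must be >= 1, got {n_m}")
    if n_med < 2:
        raise ConfigurationError("mediator sample size must be >= 2")

    n = n_e + n_m
    cfg_all = dataclasses.replace(config, n_snps=n)
    snp, pos, eaf, ea, oa = _variant_frame(cfg_all, n, rng)

    gamma_e = rng.normal(0.0, config.gamma_sd, size=n_e)
    delta_m = rng.normal(0.0, d_sd, size=n_m)
    n_invalid = int(round(config.invalid_frac * n_e))
    invalid = np.zeros(n, dtype=bool)
    invalid[rng.permutation(n_e)[:n_invalid]] = True
    true_exp = np.concatenate([gamma_e, np.zeros(n_m)])
    alpha = np.zeros(n)
    alpha[invalid] = (
        config.pleio_mean
        + config.inside_violation * np.abs(true_exp[invalid])
        + rng.normal(0.0, config.pleio_sd, size=n_invalid)
    )

    true_med = np.concatenate([a * gamma_e, delta_m])
    true_out = c * true_exp + b * true_med + np.sign(true_exp) * alpha

    b_e, se_e, p_e = _observe(true_exp, eaf, config.n_exp, rng)
    b_m, se_m, p_m = _observe(true_med, eaf, n_med, rng)
    b_o, se_o, p_o = _observe(true_out, eaf, config.n_out, rng)

    exposure = _assemble(snp, config.chrom, pos, ea, oa, eaf, b_e, se_e, p_e, config.n_exp)
    mediator = _assemble(snp, config.chrom, pos, ea, oa, eaf, b_m, se_m, p_m, n_med)
    outcome = _assemble(snp, config.chrom, pos, ea, oa, eaf, b_o, se_o, p_o, config.n_out)
    if config.flip_outcome:
        outcome = _flip_rows(outcome, rng)

    truth = SimulationTruth(
        snp=snp,
        gamma=true_exp,
        alpha=alpha,
        valid=~invalid,
        causal_beta=c + a * b,
        a=a,
        b=b,
        c=c,
        delta=delta_m,
    )
    return exposure, mediator, outcome, truth


# ---------------------------------------------------------------------------
# on-disk formats


def write_summary_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table as tab-delimited text."""
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary-statistics table missing columns: {missing}")
    table[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return table


def write_panel(panel: ReferencePanel, matrix_path: str | Path, variants_path: str | Path) -> None:
    """Write the panel as a plain 0/1 matrix plus a variant map (SNP, CHR, POS)."""
    np.savetxt(matrix_path, panel.haplotypes, fmt="%d")
    panel.variants.to_csv(variants_path, sep="\t", index=False)


def read_panel(matrix_path: str | Path, variants_path: str | Path) -> ReferencePanel:
    haps = np.loadtxt(matrix_path, dtype=np.int8, ndmin=2)
    variants = pd.read_csv(variants_path, sep="\t", dtype={"SNP": str, "CHR": str})
    return ReferencePanel(haplotypes=haps, variants=variants)
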