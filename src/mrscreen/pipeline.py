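"""End-to-end screen orchestration: simulate or ingest summary statistics,
select instruments, estimate causal effects with sensitivity analyses,
apply group-wise FDR, run mediation, and write deterministic result tables
plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import estimators as est
from . import instruments as ins
from . import mediation as med
from . import multiplicity as mult
from . import simulate as sim

__all__ = [
    "ScreenConfig",
    "Thresholds",
    "ValidationIssue",
    "run_screen",
    "validate_inputs",
]

log = logging.getLogger("mrscreen")


@dataclass(frozen=True)
class Thresholds:
    """Selection and testing constants of the screen (all overridable)."""

    exposure_p: float = 1e-5
    outcome_p: float = 5e-8  # reverse-direction instrument threshold
    clump_r2: float = 0.1
    reverse_clump_r2: float = 0.01
    window_kb: float = 500.0
    min_f: float = 10.0
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")


@dataclass
class ScreenConfig:
    """Configuration of one screen run.

    Either ``simulate`` (keyword arguments of
    :class:`mrscreen.simulate.SimulationConfig` plus ``n_exposures`` and
    optionally a ``mediation: {a, b, c}`` block) or ``data`` (paths to
    exposure/outcome/panel files) must be provided.
    """

    out_dir: str = "mrscreen_results"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_boot: int = 1000
    presso_n_sim: int = 1000
    run_reverse: bool = False
    simulate: dict | None = None
    data: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    message: str


def validate_inputs(paths: list[str | Path]) -> list[ValidationIssue]:
    """Validate summary-statistics files: header, alleles, SE > 0,
    p in (0, 1], duplicate ids.  Malformed headers and invalid values are
    fatal; unusual but legal content yields warnings."""
    issues: list[ValidationIssue] = []
    alphabet = {"A", "C", "G", "T"}
    for path in paths:
        path = Path(path)
        if not path.exists():
            issues.append(ValidationIssue("fatal", f"{path}: file not found"))
            continue
        try:
            table = sim.read_summary_stats(path)
        except ValueError as exc:
            issues.append(ValidationIssue("fatal", f"{exc}"))
            continue
        for col in ("EA", "OA"):
            bad = ~table[col].isin(alphabet)
            if bad.any():
                rows = table.index[bad].tolist()[:5]
                issues.append(
                    ValidationIssue("fatal", f"{path}: non-ACGT {col} at row(s) {rows}")
                )
        bad_se = table["SE"] <= 0
        if bad_se.any():
            issues.append(
                ValidationIssue(
                    "fatal", f"{path}: SE <= 0 at row(s) {table.index[bad_se].tolist()[:5]}"
                )
            )
        bad_p = (table["P"] <= 0) | (table["P"] > 1)
        if bad_p.any():
            issues.append(
                ValidationIssue(
                    "fatal", f"{path}: P outside (0, 1] at row(s) {table.index[bad_p].tolist()[:5]}"
                )
            )
        dup = table["SNP"][table["SNP"].duplicated()]
        if len(dup):
            issues.append(
                ValidationIssue("fatal", f"{path}: duplicated variant id(s): {sorted(set(dup))[:5]}")
            )
        if (table["EAF"] <= 0).any() or (table["EAF"] >= 1).any():
            issues.append(ValidationIssue("warning", f"{path}: EAF values at or beyond 0/1"))
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _gather_inputs(config: ScreenConfig):
    """Return (exposures, outcomes, panel, mediation_spec, truths).

    ``exposures`` is a list of dicts with name/table/trait_type/panel;
    ``outcomes`` a list of dicts with name/table.
    """
    combos = list(product(mult.TRAIT_TYPES, mult.PANELS))
    if config.simulate is not None:
        spec = dict(config.simulate)
        n_exposures = int(spec.pop("n_exposures", 1))
        mediation_spec = spec.pop("mediation", None)
        panel_spec = spec.pop("panel", None)
        truths = {}
        exposures, outcomes = [], []
        outcome_table = None
        for i in range(n_exposures):
            cfg = sim.SimulationConfig(**{**spec, "seed": config.seed + i})
            exposure, outcome, truth = sim.simulate_summary_stats(cfg)
            name = f"sim_trait_{i + 1}"
            trait_type, panel_label = combos[i % len(combos)]
            exposures.append(
                {"name": name, "table": exposure, "trait_type": trait_type, "panel": panel_label}
            )
            truths[name] = truth
            if outcome_table is None:
                outcome_table = outcome
                outcomes.append({"name": "sim_outcome", "table": outcome})
            else:  # each exposure pairs with its own outcome realisation
                outcomes.append({"name": f"sim_outcome_{i + 1}", "table": outcome})
        panel = None
        if panel_spec:
            panel = sim.simulate_ld_panel(**{**panel_spec, "seed": config.seed + 10_000})
        return exposures, outcomes, panel, mediation_spec, truths

    if config.data is None:
        raise ValueError("config must provide either a 'simulate' or a 'data' section")
    data = config.data
    exposures = []
    for item in data.get("exposures", []):
        path = Path(item["path"])
        if not path.exists():
            raise FileNotFoundError(f"exposure file not found: {path}")
        exposures.append(
            {
                "name": item.get("name", path.stem),
                "table": sim.read_summary_stats(path),
                "trait_type": item.get("trait_type", "MFI"),
                "panel": item.get("panel", "TBNK"),
                "path": path,
            }
        )
    outcomes = []
    for item in data.get("outcomes", []):
        path = Path(item["path"])
        if not path.exists():
            raise FileNotFoundError(f"outcome file not found: {path}")
        outcomes.append({"name": item.get("name", path.stem), "table": sim.read_summary_stats(path), "path": path})
    panel = None
    if "panel" in data:
        panel = sim.read_panel(data["panel"]["matrix"], data["panel"]["variants"])
    mediation_spec = data.get("mediation")
    if mediation_spec and "mediator_path" in mediation_spec:
        mediation_spec = dict(mediation_spec)
        mediation_spec["mediator_table"] = sim.read_summary_stats(mediation_spec["mediator_path"])
    return exposures, outcomes, panel, mediation_spec, {}


def _estimate_rows(name_exp, name_out, trait_type, panel_label, estimates, extra=None):
    rows = []
    for key, e in estimates.items():
        rows.append(
            {
                "exposure": name_exp,
                "outcome": name_out,
                "trait_type": trait_type,
                "panel": panel_label,
                "method": key,
                "method_tag": e.method,
                "beta": e.beta,
                "se": e.se,
                "pval": e.pval,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_snps": e.n_snps,
                **(extra or {}),
            }
        )
    return rows


def run_screen(config: ScreenConfig) -> Path:
    """Execute the full screen and write result tables to ``config.out_dir``.

    Emits ``mr_results.tsv`` (one row per exposure-outcome-method, with FDR
    annotation on the primary IVW rows), ``sensitivity.tsv``,
    ``instruments.tsv`` (per-variant audit trail), optionally
    ``mediation.tsv``, and ``manifest.json``.  Re-running with the same
    configuration and seed reproduces byte-identical files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    exposures, outcomes, panel, mediation_spec, truths = _gather_inputs(config)
    log.info("screen: %d exposure(s) x %d outcome(s)", len(exposures), len(outcomes))

    result_rows: list[dict] = []
    sens_rows: list[dict] = []
    audit_rows: list[dict] = []
    pair_errors: list[dict] = []

    pairs = (
        list(zip(exposures, outcomes))
        if config.simulate is not None and len(outcomes) == len(exposures)
        else [(e, o) for e in exposures for o in outcomes]
    )
    if config.simulate is not None and len(outcomes) == 1:
        pairs = [(e, outcomes[0]) for e in exposures]

    for expo, outc in pairs:
        pair = (expo["name"], outc["name"])
        try:
            harmonized, iset, sel_log = ins.select_instruments(
                expo["table"],
                outc["table"],
                panel,
                p_threshold=thr.exposure_p,
                r2_threshold=thr.clump_r2,
                window_kb=thr.window_kb,
                min_f=thr.min_f,
            )
            if len(harmonized) < 1:
                raise est.InsufficientInstrumentsError("no harmonized instruments")
            estimates = est.estimate_all(harmonized, n_boot=config.n_boot, seed=config.seed)
            result_rows.extend(
                _estimate_rows(*pair, expo["trait_type"], expo["panel"], estimates)
            )
            for _, row in iset.table.iterrows():
                audit_rows.append(
                    {
                        "exposure": expo["name"],
                        "SNP": row["SNP"],
                        "P": row["P"],
                        "PVE": row["PVE"],
                        "F": row["F"],
                        "fate": "retained" if row["SNP"] in set(harmonized["SNP"]) else "dropped_harmonization",
                    }
                )
            if len(harmonized) >= 3:
                rep = est.sensitivity_report(
                    harmonized, n_sim=config.presso_n_sim, seed=config.seed, n_boot=config.n_boot
                )
                sens_rows.append(
                    {
                        "exposure": pair[0],
                        "outcome": pair[1],
                        "Q": rep.q,
                        "Q_df": rep.q_df,
                        "Q_pval": rep.q_pval,
                        "egger_intercept": rep.egger_intercept.beta,
                        "egger_intercept_se": rep.egger_intercept.se,
                        "egger_intercept_pval": rep.egger_intercept.pval,
                        "presso_global_pval": rep.presso.global_pval if rep.presso else np.nan,
                        "presso_n_outliers": len(rep.presso.outlier_indices) if rep.presso else 0,
                        "presso_distortion_pval": (
                            rep.presso.distortion_pval
                            if rep.presso and rep.presso.distortion_pval is not None
                            else np.nan
                        ),
                        "cooks_n_excluded": len(rep.cooks_excluded),
                        "n_excluded": len(rep.excluded),
                        "post_removal_ivw_beta": (
                            rep.post_removal["ivw"].beta if rep.post_removal else np.nan
                        ),
                        "post_removal_ivw_pval": (
                            rep.post_removal["ivw"].pval if rep.post_removal else np.nan
                        ),
                    }
                )
        except (est.InsufficientInstrumentsError, ZeroDivisionError, ValueError) as exc:
            log.warning("pair %s -> %s failed: %s", pair[0], pair[1], exc)
            pair_errors.append({"exposure": pair[0], "outcome": pair[1], "error": str(exc)})

    results = pd.DataFrame(result_rows)
    if not results.empty:
        primary = results["method"] == "ivw"
        adjusted = mult.groupwise_fdr(
            results.loc[primary], p_col="pval", alpha=thr.fdr_alpha, validate_labels=True
        )
        results = results.merge(
            adjusted[["exposure", "outcome", "method", "p_fdr", "significant"]],
            on=["exposure", "outcome", "method"],
            how="left",
        )

    mediation_table = None
    if mediation_spec is not None:
        mediation_table = _run_mediation(config, mediation_spec, panel)

    _write_tsv(results, out_dir / "mr_results.tsv")
    _write_tsv(pd.DataFrame(sens_rows), out_dir / "sensitivity.tsv")
    _write_tsv(pd.DataFrame(audit_rows), out_dir / "instruments.tsv")
    if mediation_table is not None:
        _write_tsv(mediation_table, out_dir / "mediation.tsv")
    if pair_errors:
        _write_tsv(pd.DataFrame(pair_errors), out_dir / "errors.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {
            "pairs": len(pairs),
            "result_rows": len(results),
            "sensitivity_rows": len(sens_rows),
            "instrument_rows": len(audit_rows),
            "mediation_rows": 0 if mediation_table is None else len(mediation_table),
            "pair_errors": len(pair_errors),
        },
        "inputs": {
            str(item["path"]): _sha256(Path(item["path"]))
            for item in exposures + outcomes
            if "path" in item
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if pair_errors and not result_rows:
        raise RuntimeError(f"all {len(pair_errors)} exposure-outcome pair(s) failed; see errors.tsv")
    return out_dir


def _run_mediation(config: ScreenConfig, spec, panel) -> pd.DataFrame:
    thr = config.thresholds
    if config.simulate is not None:
        sim_kwargs = {
            k: v
            for k, v in config.simulate.items()
            if k not in ("n_exposures", "mediation", "panel", "causal_beta")
        }
        cfg = sim.SimulationConfig(**{**sim_kwargs, "seed": config.seed + 20_000})
        exposure, mediator, outcome, truth = sim.simulate_mediation_stats(
            cfg, a=spec["a"], b=spec["b"], c=spec["c"]
        )
        names = ("sim_exposure", "sim_mediator", "sim_outcome")
        panel = None  # simulated marginal effects carry no LD; nothing to clump
    else:
        exposure = sim.read_summary_stats(spec["exposure_path"])
        mediator = spec.get("mediator_table")
        if mediator is None:
            mediator = sim.read_summary_stats(spec["mediator_path"])
        outcome = sim.read_summary_stats(spec["outcome_path"])
        names = (spec.get("exposure", "exposure"), spec.get("mediator", "mediator"), spec.get("outcome", "outcome"))
    res = med.mediation_decompose(
        exposure,
        mediator,
        outcome,
        panel=panel,
        p_threshold=thr.exposure_p,
        r2_threshold=thr.clump_r2,
        window_kb=thr.window_kb,
        min_f=thr.min_f,
        n_boot=config.n_boot,
        seed=config.seed,
        method=spec.get("method", "difference"),
        instrument_policy=spec.get("instrument_policy", "exposure"),
    )
    return pd.DataFrame(
        [
            {
                "exposure": names[0],
                "mediator": names[1],
                "outcome": names[2],
                "total": res.total,
                "direct": res.direct,
                "indirect": res.indirect,
                "proportion_mediated": res.proportion,
                "total_ci_low": res.ci["total"][0],
                "total_ci_high": res.ci["total"][1],
                "direct_ci_low": res.ci["direct"][0],
                "direct_ci_high": res.ci["direct"][1],
                "indirect_ci_low": res.ci["indirect"][0],
                "indirect_ci_high": res.ci["indirect"][1],
                "proportion_ci_low": res.ci["proportion"][0],
                "proportion_ci_high": res.ci["proportion"][1],
                "n_boot": res.n_boot,
                "n_snps": res.n_snps,
                "method": res.method,
                "instrument_policy": res.instrument_policy,
            }
        ]
    )


def _write_tsv(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _config_echo(config: ScreenConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["thresholds"] = dataclasses.asdict(config.thresholds)
    return echo
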