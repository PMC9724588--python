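"""End-to-end orchestration of the two-sample MR workflow.

From a YAML config the pipeline runs, per exposure: instrument selection
→ LD clumping → harmonization against the outcome → univariable MR (IVW
primary; MR-Egger and weighted median as complementary validators) →
Cochran's Q (with multiplicative-random-effects IVW when heterogeneity
is significant) → leave-one-out → MR-PRESSO.  Exposures passing the IVW
significance gate proceed to multivariable MR against the configured
confounders and to two-step mediation per confounder, followed by a
binary-outcome power calculation.  Everything is driven by the single
config seed, and the report is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mediation_power import PowerSpec, mediation_gate, mr_power_binary, two_step_mediation
from .mr_presso import run_presso
from .mvmr import mvmr_fit
from .summary_data import (
    GwasRecord,
    InstrumentSet,
    LDTable,
    MRError,
    clump,
    harmonize,
    read_gwas_table,
    select_instruments,
    strength_summary,
    variance_explained,
)
from .uvmr import cochran_q, egger, ivw, leave_one_out, weighted_median

logger = logging.getLogger("mrpipe")


@dataclass
class TraitSpec:
    name: str
    table: str
    p_threshold: float = 5e-8


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see README for the YAML layout)."""

    seed: int
    output_dir: str
    exposures: list[TraitSpec]
    outcome: TraitSpec
    outcome_n_total: int | None = None
    outcome_n_cases: int | None = None
    confounders: list[TraitSpec] = field(default_factory=list)
    ld_table: str | None = None
    clump_r2: float = 0.001
    clump_window_bp: int = 1_000_000
    outcome_sig: float = 5e-8
    presso_alpha: float = 0.05
    presso_bonferroni: bool = True
    mediation_alpha: float = 0.05
    ivw_gate_alpha: float = 0.05
    presso_n_sim: int = 1000
    n_boot: int = 1000
    use_proxies: bool = False
    min_proxy_r2: float = 0.8
    power_r2: float | None = None
    power_odds_ratio: float | None = None
    power_alpha: float = 0.05
    mediation_total: str = "pre_presso"  # or "post_presso"
    raw_yaml: str = ""

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        if not isinstance(data, dict):
            raise MRError(f"config {path}: expected a mapping")
        if "seed" not in data:
            raise MRError(f"config {path}: 'seed' is required")
        base = Path(path).parent

        def trait(d, default_p=5e-8):
            return TraitSpec(
                name=str(d["name"]),
                table=str((base / d["table"]).resolve()),
                p_threshold=float(d.get("p_threshold", default_p)),
            )

        thr = data.get("thresholds", {})
        power = data.get("power", {}) or {}
        outcome = data["outcome"]
        cfg = cls(
            seed=int(data["seed"]),
            output_dir=str((base / data.get("output_dir", "mrpipe_out")).resolve()),
            exposures=[trait(e) for e in data["exposures"]],
            outcome=trait(outcome),
            outcome_n_total=outcome.get("n_total"),
            outcome_n_cases=outcome.get("n_cases"),
            confounders=[trait(c) for c in data.get("confounders", [])],
            ld_table=(
                str((base / data["ld_table"]).resolve())
                if data.get("ld_table")
                else None
            ),
            clump_r2=float(thr.get("clump_r2", 0.001)),
            clump_window_bp=int(thr.get("clump_window_bp", 1_000_000)),
            outcome_sig=float(thr.get("outcome_sig", 5e-8)),
            presso_alpha=float(thr.get("presso_alpha", 0.05)),
            presso_bonferroni=bool(thr.get("presso_bonferroni", True)),
            mediation_alpha=float(thr.get("mediation_alpha", 0.05)),
            ivw_gate_alpha=float(thr.get("ivw_gate_alpha", 0.05)),
            presso_n_sim=int(data.get("presso_n_sim", 1000)),
            n_boot=int(data.get("n_boot", 1000)),
            use_proxies=bool(data.get("use_proxies", False)),
            min_proxy_r2=float(data.get("min_proxy_r2", 0.8)),
            power_r2=power.get("r2"),
            power_odds_ratio=power.get("odds_ratio"),
            power_alpha=float(power.get("alpha", 0.05)),
            mediation_total=str(data.get("mediation_total", "pre_presso")),
            raw_yaml=raw,
        )
        for spec in [*cfg.exposures, cfg.outcome, *cfg.confounders]:
            if not Path(spec.table).exists():
                raise MRError(f"config: table for {spec.name} not found: {spec.table}")
        if cfg.ld_table and not Path(cfg.ld_table).exists():
            raise MRError(f"config: LD table not found: {cfg.ld_table}")
        return cfg


def _derived_seed(base: int, *tags) -> int:
    """Stable 31-bit sub-seed for one pipeline stage."""
    h = hashlib.sha256(repr((base, tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _prepare_instruments(
    spec: TraitSpec, ld: LDTable | None, cfg: PipelineConfig
) -> tuple[list[GwasRecord], InstrumentSet]:
    records, _ = read_gwas_table(spec.table)
    selected = select_instruments(records, spec.p_threshold, spec.name)
    clumped = clump(selected, ld, cfg.clump_r2, cfg.clump_window_bp)
    return records, clumped


def _union_instrument_sets(
    primary_name: str,
    clumped: dict[str, InstrumentSet],
    full_tables: dict[str, list[GwasRecord]],
    names: list[str],
    ld: LDTable | None,
    cfg: PipelineConfig,
) -> list[InstrumentSet]:
    """Build per-trait instrument sets over the clumped union of SNPs
    significant for any included trait; the primary trait comes first."""
    best: dict[str, GwasRecord] = {}
    for name in names:
        for rec in clumped[name].records:
            if rec.snp_id not in best or rec.pval < best[rec.snp_id].pval:
                best[rec.snp_id] = rec
    union = clump(
        InstrumentSet("union", list(best.values()), 1.0),
        ld,
        cfg.clump_r2,
        cfg.clump_window_bp,
    )
    union_ids = union.snp_ids
    out = []
    order = [primary_name] + [n for n in names if n != primary_name]
    for name in order:
        lookup = {r.snp_id: r for r in full_tables[name]}
        recs = [lookup[s] for s in union_ids if s in lookup]
        out.append(InstrumentSet(name, recs, 1.0))
    return out


def _post_removal_r2(instruments: InstrumentSet, keep_ids: set[str]) -> float | None:
    vals = [
        variance_explained(r.eaf, r.beta)
        for r in instruments.records
        if r.snp_id in keep_ids
    ]
    vals = [v for v in vals if v is not None]
    return float(sum(vals)) if vals else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the report (also written to disk).

    Every configured exposure appears in the report as ``estimated``,
    ``gated-out`` (IVW not significant), or ``failed`` with the stage
    and reason; a partial report is still written if a stage fails.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = LDTable.from_file(config.ld_table) if config.ld_table else None

    report: dict = {
        "provenance": {
            "package": "mrpipe",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(config.raw_yaml.encode()).hexdigest(),
        },
        "exposures": {},
    }
    tidy_rows: list[dict] = []

    outcome_records, _ = read_gwas_table(config.outcome.table)
    full_tables: dict[str, list[GwasRecord]] = {}
    clumped_sets: dict[str, InstrumentSet] = {}
    for spec in config.confounders:
        try:
            full_tables[spec.name], clumped_sets[spec.name] = _prepare_instruments(
                spec, ld, config
            )
        except MRError as exc:
            report.setdefault("confounder_errors", {})[spec.name] = str(exc)

    for i, spec in enumerate(config.exposures):
        entry: dict = {"name": spec.name}
        report["exposures"][spec.name] = entry
        try:
            full, clumped = _prepare_instruments(spec, ld, config)
            full_tables[spec.name] = full
            clumped_sets[spec.name] = clumped
            entry["strength"] = strength_summary(clumped).to_dict()

            h = harmonize(
                clumped,
                outcome_records,
                outcome_sig_threshold=config.outcome_sig,
                ld=ld,
                use_proxies=config.use_proxies,
                min_proxy_r2=config.min_proxy_r2,
            )
            entry["n_snp_harmonized"] = h.n_snp
            entry["exclusions"] = [list(e) for e in h.exclusions]
            h.to_frame().to_csv(out_dir / f"harmonized_{spec.name}.tsv", sep="\t", index=False)
            h.exclusions_frame().to_csv(
                out_dir / f"exclusions_{spec.name}.tsv", sep="\t", index=False
            )

            est_ivw = ivw(h, mode="fixed")
            est_egger, est_egger_int = egger(h)
            est_wm = weighted_median(
                h, n_boot=config.n_boot, seed=_derived_seed(config.seed, "wm", spec.name)
            )
            het = cochran_q(h, est_ivw.theta, df_loss=1)
            estimates = {
                "ivw_fe": est_ivw,
                "egger_slope": est_egger,
                "egger_intercept": est_egger_int,
                "weighted_median": est_wm,
            }
            if het.pval < 0.05:
                estimates["ivw_mre"] = ivw(h, mode="multiplicative_random")
            entry["uvmr"] = {k: e.to_dict() for k, e in estimates.items()}
            entry["heterogeneity"] = het.to_dict()
            entry["egger_pleiotropy_p"] = est_egger_int.pval

            loo = leave_one_out(h)
            entry["leave_one_out"] = [
                {"dropped": snp, **est.to_dict()} for snp, est in loo
            ]
            pd.DataFrame(entry["leave_one_out"]).to_csv(
                out_dir / f"loo_{spec.name}.tsv", sep="\t", index=False
            )

            presso = None
            if h.n_snp >= 4:
                presso = run_presso(
                    h,
                    n_sim=config.presso_n_sim,
                    seed=_derived_seed(config.seed, "presso", spec.name),
                    alpha=config.presso_alpha,
                    bonferroni=config.presso_bonferroni,
                )
                entry["presso"] = presso.to_dict()
                estimates["presso_corrected"] = presso.corrected

            for key, est in estimates.items():
                tidy_rows.append(
                    {"exposure": spec.name, "outcome": config.outcome.name,
                     "adjusted_for": "", **est.to_dict(), "method": key}
                )

            significant = est_ivw.pval < config.ivw_gate_alpha
            entry["status"] = "estimated" if significant else "gated-out"
            if not significant:
                entry["gate"] = (
                    f"IVW p {est_ivw.pval:.3g} >= {config.ivw_gate_alpha} — "
                    "not carried to MVMR/mediation"
                )
                continue

            conf_names = [c.name for c in config.confounders if c.name in clumped_sets]
            if conf_names:
                sets = _union_instrument_sets(
                    spec.name, clumped_sets, full_tables,
                    [spec.name] + conf_names, ld, config,
                )
                h_mv = harmonize(
                    sets, outcome_records,
                    outcome_sig_threshold=config.outcome_sig,
                    ld=ld, use_proxies=config.use_proxies,
                    min_proxy_r2=config.min_proxy_r2,
                )
                mv = mvmr_fit(h_mv)
                entry["mvmr"] = mv.to_dict()
                tidy_rows.append(
                    {"exposure": spec.name, "outcome": config.outcome.name,
                     "adjusted_for": "+".join(conf_names),
                     **mv.estimates[spec.name].to_dict(), "method": "mvmr"}
                )

            entry["mediation"] = {}
            if config.mediation_total == "post_presso" and presso is not None:
                total_est = presso.corrected
            else:
                total_est = est_ivw
            for conf in config.confounders:
                if conf.name not in clumped_sets:
                    continue
                med: dict = {}
                entry["mediation"][conf.name] = med
                try:
                    h_a = harmonize(
                        clumped, full_tables[conf.name],
                        outcome_sig_threshold=0.0,
                    )
                    a_est = ivw(h_a, mode="fixed")
                    med["a_exposure_to_mediator"] = a_est.to_dict()
                    if not mediation_gate(a_est, config.mediation_alpha):
                        med["status"] = "not-a-mediator"
                        med["gate"] = (
                            f"exposure->{conf.name} p {a_est.pval:.3g} "
                            f">= {config.mediation_alpha}"
                        )
                        continue
                    sets_b = _union_instrument_sets(
                        conf.name, clumped_sets, full_tables,
                        [conf.name, spec.name], ld, config,
                    )
                    h_b = harmonize(
                        sets_b, outcome_records,
                        outcome_sig_threshold=config.outcome_sig,
                        ld=ld, use_proxies=config.use_proxies,
                        min_proxy_r2=config.min_proxy_r2,
                    )
                    b_est = mvmr_fit(h_b).estimates[conf.name]
                    result = two_step_mediation(total_est, a_est, b_est)
                    med.update(result.to_dict())
                    med["status"] = "mediated"
                except MRError as exc:
                    med["status"] = "failed"
                    med["error"] = str(exc)

            if config.outcome_n_total and config.outcome_n_cases:
                r2 = config.power_r2
                if r2 is None and presso is not None:
                    keep = set(h.snp_ids) - set(presso.outlier_ids)
                    r2 = _post_removal_r2(clumped, keep)
                if r2 is None:
                    r2 = entry["strength"]["total_r2"]
                or_hyp = config.power_odds_ratio
                if or_hyp is None:
                    or_hyp = (
                        presso.corrected.odds_ratio if presso is not None
                        else est_ivw.odds_ratio
                    )
                if r2 and 0 < r2 < 1:
                    power = mr_power_binary(
                        PowerSpec(
                            n_total=config.outcome_n_total,
                            k_case_fraction=config.outcome_n_cases / config.outcome_n_total,
                            odds_ratio=or_hyp,
                            r2_instrument=r2,
                            alpha=config.power_alpha,
                        )
                    )
                    entry["power"] = power.to_dict()
        except MRError as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            logger.error("exposure %s failed: %s", spec.name, exc)

    tidy = pd.DataFrame(tidy_rows)
    if not tidy.empty:
        cols = ["method", "exposure", "outcome", "adjusted_for", "n_snp", "b", "se",
                "ci_low", "ci_high", "pval", "or", "or_ci_low", "or_ci_high"]
        tidy = tidy[cols]
    tidy.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=False, default=_json_default)
    logger.info("report written to %s", report_path)
    return report


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
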