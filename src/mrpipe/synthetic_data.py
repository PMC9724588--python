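"""Synthetic two-sample GWAS summary statistics with known ground truth.

Emulates the statistical structure of large-biobank summary data — a
continuous exposure GWAS (UK-Biobank scale), a binary outcome GWAS
(FinnGen-style logistic, log-odds betas), optionally a mediator GWAS —
so every pipeline stage can be tested against a truth the generator
records: the causal effect, per-SNP instrument effects, the pleiotropy
regime, planted outliers, and mediation path coefficients.

Generation is at the summary level (no individual genotypes), matching
the two-sample design: per SNP j,

* eaf_j ~ Uniform(0.05, 0.95), effect allele A / other allele G;
* true effect gamma_j ~ Normal(0, gamma_sd²);
* se_x_j = 1/sqrt(2·eaf(1−eaf)·N_exp); beta_x_j ~ Normal(gamma_j, se_x²);
* outcome truth Gamma_j = theta_true·gamma_j + alpha_j with pleiotropy
  alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd²), independent of
  gamma (InSIDE holds);
* binary-outcome se_y_j = 1/sqrt(2·eaf(1−eaf)·N_out·K·(1−K));
  beta_y_j ~ Normal(Gamma_j, se_y²);
* planted outliers add outlier_magnitude·se_y_j to Gamma_j.

Simulated SNPs are mutually independent (instruments are post-clumping
by construction) and placed far apart so clumping keeps them all.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .summary_data import GwasRecord, write_gwas_table

#: FinnGen diabetic-nephropathy-style case fraction, 3283/213746
DEFAULT_CASE_FRACTION = 3283 / 213746


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic two-sample MR study.

    Defaults mirror a biobank-scale design: ~100 independent instruments
    explaining ~5% of a continuous exposure, a binary outcome GWAS of
    213,746 samples at case fraction 0.0154, and a causal log-odds
    effect of 0.174 per SD (odds ratio ≈ 1.19).
    """

    seed: int
    n_snp: int = 100
    n_exposure_sample: int = 360_000
    n_outcome_sample: int = 213_746
    n_mediator_sample: int = 700_000
    theta_true: float = 0.174
    gamma_sd: float = 0.037
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_outliers: int = 0
    outlier_magnitude: float = 10.0
    case_fraction: float | None = DEFAULT_CASE_FRACTION
    # mediation path coefficients (exposure -a-> mediator -b-> outcome, direct c)
    a_true: float | None = None
    b_true: float | None = None
    c_true: float | None = None
    n_mediator_specific: int = 0
    mediator_gamma_sd: float = 0.037
    # harmonization exercise knobs
    swap_fraction: float = 0.0
    n_palindromic: int = 0

    def validate(self) -> None:
        if self.n_snp < 4:
            raise ValueError("n_snp must be >= 4")
        for name in ("n_exposure_sample", "n_outcome_sample", "n_mediator_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")
        if not (0 <= self.swap_fraction <= 1):
            raise ValueError("swap_fraction must be in [0,1]")
        if self.n_outliers < 0 or self.n_outliers >= self.n_snp:
            raise ValueError("n_outliers must be in [0, n_snp)")
        if self.n_palindromic > self.n_snp:
            raise ValueError("n_palindromic exceeds n_snp")


@dataclass
class SyntheticStudy:
    """Simulated summary tables plus the realized ground truth."""

    exposure_table: list[GwasRecord]
    outcome_table: list[GwasRecord]
    mediator_table: list[GwasRecord] | None
    truth: dict

    def write(self, out_dir) -> dict[str, str]:
        """Write tables (TSV, default dialect) and truth (JSON); returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_gwas_table(self.exposure_table, out / "exposure.tsv")
        paths["exposure"] = str(out / "exposure.tsv")
        write_gwas_table(self.outcome_table, out / "outcome.tsv")
        paths["outcome"] = str(out / "outcome.tsv")
        if self.mediator_table is not None:
            write_gwas_table(self.mediator_table, out / "mediator.tsv")
            paths["mediator"] = str(out / "mediator.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=_jsonable)
        paths["truth"] = str(out / "truth.json")
        return paths


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _positions(n: int) -> tuple[list[str], list[int]]:
    """Spread SNPs over chromosomes 10 Mb apart (no clumping collisions)."""
    chroms = [str(j % 22 + 1) for j in range(n)]
    pos = [1_000_000 + (j // 22) * 10_000_000 for j in range(n)]
    return chroms, pos


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 5e-324, 1.0)


def _records(
    ids, chroms, pos, eaf, beta, se, pval, n, swap: np.ndarray | None = None,
    palindromic: np.ndarray | None = None,
) -> list[GwasRecord]:
    out = []
    for j, snp in enumerate(ids):
        ea, oa = "A", "G"
        if palindromic is not None and palindromic[j]:
            ea, oa = "A", "T"
        b, f = float(beta[j]), float(eaf[j])
        if swap is not None and swap[j]:
            ea, oa = oa, ea
            b, f = -b, 1.0 - f
        out.append(
            GwasRecord(
                snp_id=snp,
                chrom=chroms[j],
                pos=pos[j],
                effect_allele=ea,
                other_allele=oa,
                eaf=f,
                beta=b,
                se=float(se[j]),
                pval=float(pval[j]),
                n=int(n),
            )
        )
    return out


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Generate exposure and outcome summary tables with known truth.

    ``truth`` records the realized per-SNP effects (gamma, Gamma,
    pleiotropy), the planted outlier identities, and the exact
    exposure variance explained, so recovery tests never re-derive the
    estimands.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    j = config.n_snp
    ids = [f"rs{100000 + i}" for i in range(j)]
    chroms, pos = _positions(j)

    eaf = rng.uniform(0.05, 0.95, size=j)
    gamma = rng.normal(0.0, config.gamma_sd, size=j)
    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure_sample)
    beta_x = rng.normal(gamma, se_x)

    alpha = (
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j)
        if (config.pleiotropy_mean != 0 or config.pleiotropy_sd > 0)
        else np.zeros(j)
    )
    big_gamma = config.theta_true * gamma + alpha

    k = config.case_fraction
    if k is None:
        se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome_sample)
    else:
        se_y = 1.0 / np.sqrt(
            2.0 * eaf * (1.0 - eaf) * config.n_outcome_sample * k * (1.0 - k)
        )
    outlier_idx = (
        np.sort(rng.choice(j, size=config.n_outliers, replace=False))
        if config.n_outliers
        else np.array([], dtype=int)
    )
    big_gamma = big_gamma.copy()
    big_gamma[outlier_idx] += config.outlier_magnitude * se_y[outlier_idx]
    beta_y = rng.normal(big_gamma, se_y)

    palin = np.zeros(j, dtype=bool)
    palin[: config.n_palindromic] = True
    swap = (
        rng.random(j) < config.swap_fraction
        if config.swap_fraction > 0
        else None
    )

    exposure = _records(
        ids, chroms, pos, eaf, beta_x, se_x, _two_sided_p(beta_x, se_x),
        config.n_exposure_sample, palindromic=palin,
    )
    outcome = _records(
        ids, chroms, pos, eaf, beta_y, se_y, _two_sided_p(beta_y, se_y),
        config.n_outcome_sample, swap=swap, palindromic=palin,
    )
    truth = {
        "config": asdict(config),
        "snp_ids": ids,
        "eaf": eaf,
        "gamma": gamma,
        "alpha": alpha,
        "big_gamma": big_gamma,
        "outlier_ids": [ids[i] for i in outlier_idx],
        "exposure_r2": float(np.sum(2 * eaf * (1 - eaf) * gamma**2)),
    }
    return SyntheticStudy(exposure, outcome, None, truth)


def simulate_mediation(config: SimulationConfig) -> SyntheticStudy:
    """Generate exposure, mediator, and outcome tables with a mediation path.

    Mediator truth per SNP is a_true·gamma_j plus a mediator-specific
    effect delta_j ~ Normal(0, mediator_gamma_sd²) for
    ``n_mediator_specific`` extra SNPs (zero exposure effect), which
    identify the mediator's direct effect in MVMR.  Outcome truth is
    c_true·gamma_j + b_true·(mediator truth) + pleiotropy, so the total
    exposure effect is c_true + a_true·b_true by construction.
    """
    config.validate()
    if config.a_true is None or config.b_true is None or config.c_true is None:
        raise ValueError("simulate_mediation requires a_true, b_true, c_true")
    if config.n_mediator_specific < 1:
        raise ValueError(
            "simulate_mediation: need >= 1 mediator-specific instrument "
            "(MVMR unidentified otherwise)"
        )
    rng = np.random.default_rng(config.seed)
    j_exp = config.n_snp
    j_med = config.n_mediator_specific
    j = j_exp + j_med
    ids = [f"rs{100000 + i}" for i in range(j)]
    chroms, pos = _positions(j)

    eaf = rng.uniform(0.05, 0.95, size=j)
    gamma = np.zeros(j)
    gamma[:j_exp] = rng.normal(0.0, config.gamma_sd, size=j_exp)
    delta = np.zeros(j)
    delta[j_exp:] = rng.normal(0.0, config.mediator_gamma_sd, size=j_med)

    m_truth = config.a_true * gamma + delta
    alpha = (
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j)
        if (config.pleiotropy_mean != 0 or config.pleiotropy_sd > 0)
        else np.zeros(j)
    )
    big_gamma = config.c_true * gamma + config.b_true * m_truth + alpha

    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure_sample)
    beta_x = rng.normal(gamma, se_x)
    se_m = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_mediator_sample)
    beta_m = rng.normal(m_truth, se_m)
    k = config.case_fraction
    if k is None:
        se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome_sample)
    else:
        se_y = 1.0 / np.sqrt(
            2.0 * eaf * (1.0 - eaf) * config.n_outcome_sample * k * (1.0 - k)
        )
    beta_y = rng.normal(big_gamma, se_y)

    exposure = _records(
        ids, chroms, pos, eaf, beta_x, se_x, _two_sided_p(beta_x, se_x),
        config.n_exposure_sample,
    )
    mediator = _records(
        ids, chroms, pos, eaf, beta_m, se_m, _two_sided_p(beta_m, se_m),
        config.n_mediator_sample,
    )
    outcome = _records(
        ids, chroms, pos, eaf, beta_y, se_y, _two_sided_p(beta_y, se_y),
        config.n_outcome_sample,
    )
    total = config.c_true + config.a_true * config.b_true
    truth = {
        "config": asdict(config),
        "snp_ids": ids,
        "eaf": eaf,
        "gamma": gamma,
        "delta": delta,
        "mediator_truth": m_truth,
        "big_gamma": big_gamma,
        "total_effect": total,
        "true_proportion_mediated": (
            config.a_true * config.b_true / total if total != 0 else None
        ),
        "exposure_instrument_ids": ids[:j_exp],
        "mediator_specific_ids": ids[j_exp:],
    }
    return SyntheticStudy(exposure, outcome, mediator, truth)
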