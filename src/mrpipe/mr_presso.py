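"""MR-PRESSO: pleiotropy residual sum and outlier test.

A simulation-based check for horizontal pleiotropy in IVW MR:

* **global test** — the observed leave-one-out residual sum of squares
  (RSS) is compared with its parametric null distribution, obtained by
  redrawing summary statistics from their sampling errors under the
  fitted causal model;
* **outlier test** — per-SNP empirical p-values from the same simulated
  residual draws, Bonferroni-flagged by default;
* **distortion test** — does removing the flagged outliers change the
  IVW estimate more than removing equally many random SNPs would?

The corrected estimate is plain IVW on the retained instruments
(single-pass removal; no iterated re-testing).  Empirical p-values carry
the +1 correction, so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .summary_data import HarmonizedSet, MRError
from .uvmr import MREstimate, ivw


@dataclass
class PressoResult:
    """Outputs of the global, outlier, and distortion tests."""

    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    distortion_pct: float | None
    distortion_pval: float | None
    corrected: MREstimate
    n_sim: int
    seed: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss,
            "global_pval": self.global_pval,
            "outlier_pvals": self.outlier_pvals,
            "outlier_ids": self.outlier_ids,
            "distortion_pct": self.distortion_pct,
            "distortion_pval": self.distortion_pval,
            "corrected": self.corrected.to_dict(),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "notes": self.notes,
        }


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, O(J) via sufficient statistics."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _loo_slopes_matrix(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out slopes for (n_sim, J) draws."""
    sxy = (w * bx * by).sum(axis=1, keepdims=True)
    sxx = (w * bx * bx).sum(axis=1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso_global(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Global pleiotropy test.

    Observed RSS = Σ_j w_j (beta_y_j − beta_x_j·θ̂₍₋ⱼ₎)² with θ̂₍₋ⱼ₎ the
    leave-one-out IVW slope and w_j = 1/se_y_j².  The null redraws
    beta_x* ~ N(beta_x, se_x²) and beta_y* ~ N(beta_x·θ̂₍₋ⱼ₎, se_y²)
    ``n_sim`` times and recomputes the RSS on each draw;
    global p = (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).

    Returns (rss_obs, global_pval, observed per-SNP residuals,
    simulated per-SNP residual draws of shape (n_sim, J)) — the draws
    feed :func:`presso_outlier`.
    """
    if h.n_snp < 4:
        raise MRError("presso_global: need >= 4 SNPs")
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    by = h.beta_out
    sy = h.se_out
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - bx * theta_loo) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, h.n_snp))
    by_s = rng.normal(bx * theta_loo, sy, size=(n_sim, h.n_snp))
    theta_loo_s = _loo_slopes_matrix(bx_s, by_s, w)
    res_sim = w * (by_s - bx_s * theta_loo_s) ** 2
    rss_sim = res_sim.sum(axis=1)
    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    return rss_obs, global_pval, res_obs, res_sim


def presso_outlier(
    h: HarmonizedSet,
    res_obs: np.ndarray,
    res_sim: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> tuple[list[str], dict[str, float]]:
    """Per-SNP outlier test from the global-test residual draws.

    Empirical p_j = (1 + #{res*_j >= res_obs_j}) / (n_sim + 1); SNPs with
    p_j below alpha/J (Bonferroni, default) or raw alpha are flagged.
    """
    n_sim = res_sim.shape[0]
    pvals = (1 + (res_sim >= res_obs).sum(axis=0)) / (n_sim + 1)
    cut = alpha / h.n_snp if bonferroni else alpha
    outliers = [h.snp_ids[j] for j in range(h.n_snp) if pvals[j] < cut]
    return outliers, {h.snp_ids[j]: float(pvals[j]) for j in range(h.n_snp)}


def presso_distortion(
    h: HarmonizedSet,
    outlier_ids: list[str],
    n_sim: int = 1000,
    seed: int | None = None,
    ivw_mode: str = "fixed",
) -> tuple[float | None, float | None, MREstimate]:
    """Distortion test and outlier-corrected IVW estimate.

    Observed distortion = 100·(θ_without_outliers − θ_all)/|θ_all|.  The
    null removes |outlier_ids| SNPs at random (without replacement)
    ``n_sim`` times; p is the +1-corrected share of random-removal
    distortions at least as extreme in absolute value.  With no outliers
    the distortion is undefined: the full-set IVW is returned with
    (None, None).
    """
    if not outlier_ids:
        return None, None, ivw(h, mode=ivw_mode)
    n_out = len(outlier_ids)
    if n_out >= h.n_snp:
        raise MRError("presso_distortion: all SNPs flagged as outliers")
    outlier_set = set(outlier_ids)
    keep = np.array([s not in outlier_set for s in h.snp_ids])
    theta_all = ivw(h, mode=ivw_mode).theta
    corrected = ivw(h.subset(keep), mode=ivw_mode)
    d_obs = 100.0 * (corrected.theta - theta_all) / abs(theta_all)

    rng = np.random.default_rng(seed)
    d_null = np.empty(n_sim)
    idx = np.arange(h.n_snp)
    for i in range(n_sim):
        drop = rng.choice(idx, size=n_out, replace=False)
        mask = np.ones(h.n_snp, dtype=bool)
        mask[drop] = False
        theta_i = ivw(h.subset(mask), mode=ivw_mode).theta
        d_null[i] = 100.0 * (theta_i - theta_all) / abs(theta_all)
    pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    return float(d_obs), pval, corrected


def run_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    bonferroni: bool = True,
    n_distortion: int = 1000,
    ivw_mode: str = "fixed",
) -> PressoResult:
    """Full MR-PRESSO: global, outlier, and distortion tests in one call.

    Deterministic given (h, n_sim, seed): the distortion null uses a
    seed derived from ``seed`` so the three stages do not share streams.
    """
    notes: list[str] = []
    if np.all(h.se_exp[:, 0] == 0):
        notes.append("no exposure-side SE available; beta_x held fixed in draws")
    rss, global_pval, res_obs, res_sim = presso_global(h, n_sim=n_sim, seed=seed)
    outlier_ids, outlier_pvals = presso_outlier(
        h, res_obs, res_sim, alpha=alpha, bonferroni=bonferroni
    )
    d_pct, d_pval, corrected = presso_distortion(
        h, outlier_ids, n_sim=n_distortion, seed=seed + 1, ivw_mode=ivw_mode
    )
    return PressoResult(
        global_rss=rss,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_ids=outlier_ids,
        distortion_pct=d_pct,
        distortion_pval=d_pval,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
        notes=notes,
    )
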