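"""Univariable two-sample MR estimators and diagnostics.

Given J harmonized instruments with exposure effects beta_x (SE se_x)
and outcome effects beta_y (SE se_y), each SNP provides a Wald ratio
theta_j = beta_y/beta_x.  Estimators here:

* IVW — inverse-variance-weighted mean of the ratios, equivalently
  weighted least squares of beta_y on beta_x through the origin with
  weights 1/se_y²; fixed-effect or multiplicative-random-effect SE.
* MR-Egger — the same regression with a free intercept; a non-zero
  intercept signals directional horizontal pleiotropy (valid under
  InSIDE: pleiotropic effects independent of instrument strength).
* Weighted median — consistent when instruments carrying up to half the
  weight are invalid; SE by parametric bootstrap.
* Cochran's Q heterogeneity test and leave-one-out influence analysis.

P-values are two-sided normal-theory throughout, the summary-data MR
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_data import HarmonizedSet, MRError

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-odds-per-SD (or SD) scale."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "b": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
        }


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity test over per-SNP Wald ratios."""

    q: float
    df: int
    pval: float

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval}


def _estimate(method: str, theta: float, se: float, n_snp: int) -> MREstimate:
    z = theta / se if se > 0 else (np.inf if theta != 0 else 0.0)
    pval = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z975 * se),
        ci_high=float(theta + Z975 * se),
        pval=pval,
        n_snp=n_snp,
    )


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Per-SNP causal estimate beta_y/beta_x and its standard error.

    The default first-order SE, se_y/|beta_x|, ignores exposure-side
    sampling noise — adequate for strong instruments (F > 10).  With
    ``second_order`` the delta-method term beta_y²·se_x²/beta_x⁴ is added.
    """
    if beta_x == 0:
        raise MRError("wald_ratio: beta_x = 0, ratio undefined")
    theta = beta_y / beta_x
    var = (se_y / beta_x) ** 2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return theta, float(np.sqrt(var))


def _ratios(h: HarmonizedSet, second_order: bool = False) -> tuple[np.ndarray, np.ndarray]:
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    if np.any(bx == 0):
        raise MRError("wald_ratio: beta_x = 0, ratio undefined")
    theta = h.beta_out / bx
    var = (h.se_out / bx) ** 2
    if second_order:
        var += h.beta_out**2 * sx**2 / bx**4
    return theta, np.sqrt(var)


def ivw(
    h: HarmonizedSet,
    mode: str = "fixed",
    second_order: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    theta = Σ w_j θ_j / Σ w_j with w_j = 1/se(θ_j)², identical to the
    origin-constrained WLS slope of beta_y on beta_x with weights 1/se_y².
    ``mode='fixed'`` uses se = (Σ w_j)^(−1/2); ``'multiplicative_random'``
    inflates it by sqrt(Q/(J−1)) without truncation below 1, so under-
    dispersion shrinks the SE (pure multiplicative-regression convention).
    """
    if h.n_snp < 2:
        raise MRError("ivw: need >= 2 SNPs")
    theta_j, se_j = _ratios(h, second_order)
    w = 1.0 / se_j**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    if mode == "fixed":
        return _estimate("ivw_fe", theta, se_fe, h.n_snp)
    if mode == "multiplicative_random":
        q = float(np.sum(w * (theta_j - theta) ** 2))
        scale = np.sqrt(q / (h.n_snp - 1))
        return _estimate("ivw_mre", theta, se_fe * scale, h.n_snp)
    raise ValueError(f"unknown IVW mode {mode!r}")


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Weighted regression of beta_y on beta_x with a free intercept and
    weights 1/se_y², after orienting every SNP to beta_x >= 0.  The slope
    is the pleiotropy-adjusted causal estimate; an intercept with p < 0.05
    indicates directional pleiotropy.  SEs carry the multiplicative
    overdispersion scale sqrt(Q_egger/(J−2)), not truncated below 1.
    """
    if h.n_snp < 3:
        raise MRError("egger: need >= 3 SNPs")
    bx = h.beta_exp[:, 0].copy()
    by = h.beta_out.copy()
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    if np.any(bx == 0):
        raise MRError("egger: beta_x = 0 instrument present")
    w = 1.0 / h.se_out**2
    # weighted normal equations for y = a + b x
    sw = w.sum()
    swx = (w * bx).sum()
    swy = (w * by).sum()
    swxx = (w * bx * bx).sum()
    swxy = (w * bx * by).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise MRError("egger: degenerate design (constant beta_x)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    sigma2 = q / (h.n_snp - 2)
    var_slope = sw / det * sigma2
    var_intercept = swxx / det * sigma2
    return (
        _estimate("egger_slope", slope, np.sqrt(var_slope), h.n_snp),
        _estimate("egger_intercept", intercept, np.sqrt(var_intercept), h.n_snp),
    )


def _weighted_median(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j, kind="stable")
    t = theta_j[order]
    p = w[order] / w.sum()
    # cumulative weight at each ratio's "center of mass"
    cum = np.cumsum(p) - 0.5 * p
    return float(np.interp(0.5, cum, t))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    second_order: bool = False,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Orders Wald ratios and returns the value at cumulative normalized
    inverse-variance weight 0.5, linearly interpolated between bracketing
    ratios.  Consistent as long as valid instruments carry more than 50%
    of the weight.  The SE resamples beta_x and beta_y from their normal
    sampling errors ``n_boot`` times; pass ``seed`` for reproducibility.
    """
    if h.n_snp < 3:
        raise MRError("weighted_median: need >= 3 SNPs")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    theta_j, se_j = _ratios(h, second_order)
    w = 1.0 / se_j**2
    theta = _weighted_median(theta_j, w)

    rng = np.random.default_rng(seed)
    bx = h.beta_exp[:, 0]
    sx = h.se_exp[:, 0]
    by = h.beta_out
    sy = h.se_out
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s[bx_s == 0] = np.finfo(float).tiny  # guard degenerate draw
        t_s = by_s / bx_s
        se_s = sy / np.abs(bx_s)
        boots[b] = _weighted_median(t_s, 1.0 / se_s**2)
    se = float(boots.std(ddof=1))
    return _estimate("weighted_median", theta, se, h.n_snp)


def cochran_q(
    h: HarmonizedSet,
    theta_ref: float,
    df_loss: int = 1,
    second_order: bool = False,
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic around a reference estimate.

    Q = Σ w_j (θ_j − theta_ref)² with w_j the Wald-ratio inverse
    variances; df = J − ``df_loss`` (1 for IVW, 2 when theta_ref is the
    Egger slope); p is the upper chi-square tail.  Excess Q indicates
    invalid instruments or pleiotropy.
    """
    if h.n_snp < 2:
        raise MRError("cochran_q: need >= 2 SNPs")
    theta_j, se_j = _ratios(h, second_order)
    w = 1.0 / se_j**2
    q = float(np.sum(w * (theta_j - theta_ref) ** 2))
    df = h.n_snp - df_loss
    pval = float(min(1.0, max(stats.chi2.sf(q, df), 5e-324)))
    return HeterogeneityResult(q=q, df=df, pval=pval)


def leave_one_out(h: HarmonizedSet, mode: str = "fixed") -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each SNP omitted in turn.

    Returns one (dropped snp_id, estimate) pair per instrument, ordered
    by influence — largest |theta_loo − theta_full| first — so the SNP
    driving the estimate, if any, ranks at the top.
    """
    if h.n_snp < 3:
        raise MRError("leave_one_out: need >= 3 SNPs")
    full = ivw(h, mode=mode).theta
    rows = []
    mask = np.ones(h.n_snp, dtype=bool)
    for j in range(h.n_snp):
        mask[j] = False
        est = ivw(h.subset(mask), mode=mode)
        rows.append((h.snp_ids[j], est))
        mask[j] = True
    rows.sort(key=lambda r: (-abs(r[1].theta - full), r[0]))
    return rows
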