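"""Multivariable MR: joint direct effects of several exposures.

With K exposures and J instruments (J > K+1, union of per-exposure
significant SNPs by default), the outcome effects are regressed on the
J×K exposure-effect matrix without intercept, weights 1/se_out².  The
coefficient for each exposure is its *direct* effect on the outcome,
adjusted for the co-exposures — in a mediation structure this is c, not
the total c + a·b that univariable MR returns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .summary_data import HarmonizedSet, MRError
from .uvmr import HeterogeneityResult, MREstimate, _estimate
from scipy import stats


@dataclass
class MvmrResult:
    """Mutually adjusted direct-effect estimates for K exposures."""

    estimates: dict[str, MREstimate]
    conditional_q: HeterogeneityResult
    conditional_f: dict[str, float]
    n_snp: int
    n_exposure: int

    def to_dict(self) -> dict:
        return {
            "estimates": {k: e.to_dict() for k, e in self.estimates.items()},
            "conditional_q": self.conditional_q.to_dict(),
            "conditional_f": self.conditional_f,
            "n_snp": self.n_snp,
            "n_exposure": self.n_exposure,
        }


def _wls_no_intercept(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares through the origin; returns (beta, cov_unit, rss_w)."""
    sw = np.sqrt(w)
    xw = x * sw[:, None]
    yw = y * sw
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    return beta, np.linalg.inv(xtx), rss


def conditional_f_stats(h: HarmonizedSet) -> dict[str, float]:
    """Approximate conditional instrument strength per exposure.

    For exposure k, the co-exposure-explained part of its instrument
    effects is removed by a weighted regression of beta_exp[:,k] on the
    other columns (weights 1/se_exp[:,k]²); the conditional F is the
    mean residual chi-square, Σ r²/se² / (J − K + 1).  With K = 1 this
    is the ordinary mean per-SNP F.  Values below 10 suggest the
    exposure is weakly instrumented *conditionally* on the others.
    """
    j, k = h.beta_exp.shape
    out: dict[str, float] = {}
    for kk in range(k):
        x_k = h.beta_exp[:, kk]
        se_k = h.se_exp[:, kk]
        w = 1.0 / se_k**2
        others = np.delete(h.beta_exp, kk, axis=1)
        if others.shape[1] == 0:
            resid = x_k
        else:
            coef, _, _ = _wls_no_intercept(others, x_k, w)
            resid = x_k - others @ coef
        out[h.exposure_names[kk]] = float(np.sum(resid**2 / se_k**2) / (j - k + 1))
    return out


def mvmr_fit(h: HarmonizedSet) -> MvmrResult:
    """Fit the multivariable IVW model.

    Requires J > K+1 and a full-column-rank exposure matrix.  Per-
    exposure SEs use the weighted-regression covariance scaled by the
    multiplicative overdispersion factor sqrt(Q_cond/(J−K)), not
    truncated below 1.  Conditional-F warnings (< 10) are attached via
    :func:`conditional_f_stats`.
    """
    j, k = h.beta_exp.shape
    if j <= k + 1:
        raise MRError(f"mvmr_fit: {j} SNPs insufficient for {k} exposures (need > K+1)")
    rank = np.linalg.matrix_rank(h.beta_exp)
    if rank < k:
        corr = np.corrcoef(h.beta_exp, rowvar=False)
        pairs = [
            (h.exposure_names[a], h.exposure_names[b])
            for a in range(k)
            for b in range(a + 1, k)
            if abs(corr[a, b]) > 0.999
        ]
        raise MRError(f"mvmr_fit: exposure matrix rank-deficient; collinear: {pairs}")
    w = 1.0 / h.se_out**2
    beta, cov_unit, q_cond = _wls_no_intercept(h.beta_exp, h.beta_out, w)
    sigma2 = q_cond / (j - k)
    ses = np.sqrt(np.diag(cov_unit) * sigma2)
    estimates = {
        name: _estimate("mvmr", beta[kk], ses[kk], j)
        for kk, name in enumerate(h.exposure_names)
    }
    q_p = float(min(1.0, max(stats.chi2.sf(q_cond, j - k), 5e-324)))
    return MvmrResult(
        estimates=estimates,
        conditional_q=HeterogeneityResult(q=q_cond, df=j - k, pval=q_p),
        conditional_f=conditional_f_stats(h),
        n_snp=j,
        n_exposure=k,
    )
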