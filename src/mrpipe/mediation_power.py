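"""Two-step MR mediation and binary-outcome MR power.

Mediation decomposes a total causal effect (exposure → outcome) into an
indirect path through a mediator and a direct remainder:

* step 1 (a): univariable MR of exposure on mediator;
* step 2 (b): mediator's direct effect on the outcome from MVMR
  adjusted for the exposure;
* indirect = a·b (product of coefficients); proportion mediated =
  indirect / total.

Standard errors come from the delta method with zero covariance between
a and b — they are estimated from separate regressions on separate
cohorts, the two-sample design's independence.

Power for a binary outcome uses the standard normal approximation for
an MR design with a given instrument R², sample size, case fraction,
and hypothesized odds ratio per SD of exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .summary_data import MRError
from .uvmr import MREstimate, Z975


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition with delta-method SEs."""

    total: MREstimate
    a: MREstimate
    b: MREstimate
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "total": self.total.to_dict(),
            "a_exposure_to_mediator": self.a.to_dict(),
            "b_mediator_to_outcome_adjusted": self.b.to_dict(),
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "indirect_ci": list(self.indirect_ci),
            "proportion_mediated": self.proportion,
            "proportion_se": self.proportion_se,
            "proportion_ci": list(self.proportion_ci),
        }


@dataclass
class PowerSpec:
    """Inputs and result of the binary-outcome MR power calculation."""

    n_total: int
    k_case_fraction: float
    odds_ratio: float
    r2_instrument: float
    alpha: float = 0.05
    power: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "k_case_fraction": self.k_case_fraction,
            "odds_ratio": self.odds_ratio,
            "r2_instrument": self.r2_instrument,
            "alpha": self.alpha,
            "power": self.power,
        }


def mediation_gate(a: MREstimate, alpha: float = 0.05) -> bool:
    """Proceed to mediation only if the exposure→mediator path is
    significant (strict ``a.pval < alpha``); otherwise the candidate is
    reported as not a mediator."""
    return a.pval < alpha


def two_step_mediation(
    total: MREstimate,
    a: MREstimate,
    b: MREstimate,
    hold_total_fixed: bool = False,
) -> MediationResult:
    """Product-of-coefficients mediation with delta-method SEs.

    indirect = a·b with se = sqrt(a²·se_b² + b²·se_a²); proportion =
    indirect/total with the delta method propagating both the indirect
    and the total variance (set ``hold_total_fixed`` to treat the total
    effect as known).  95% CIs are symmetric on the computed scale.
    All effects must be on coherent scales: log-odds for binary
    outcomes, SD units for continuous mediators.
    """
    if total.theta == 0:
        raise MRError("two_step_mediation: total effect is zero, proportion undefined")
    indirect = a.theta * b.theta
    var_ind = a.theta**2 * b.se**2 + b.theta**2 * a.se**2
    se_ind = math.sqrt(var_ind)
    proportion = indirect / total.theta
    var_prop = var_ind / total.theta**2
    if not hold_total_fixed:
        var_prop += indirect**2 * total.se**2 / total.theta**4
    se_prop = math.sqrt(var_prop)
    return MediationResult(
        total=total,
        a=a,
        b=b,
        indirect=indirect,
        indirect_se=se_ind,
        indirect_ci=(indirect - Z975 * se_ind, indirect + Z975 * se_ind),
        proportion=proportion,
        proportion_se=se_prop,
        proportion_ci=(proportion - Z975 * se_prop, proportion + Z975 * se_prop),
    )


def mr_power_binary(spec: PowerSpec) -> PowerSpec:
    """Power of a two-sample MR design with a binary outcome.

    Uses the closed-form normal approximation: the attenuated per-SD
    association is b = K·(OR/(1 + K·(OR − 1)) − 1) with K the case
    fraction; its sampling variance is v = (K·(1−K) − b²)/(N·R²); the
    two-sided power at level alpha is Φ(|b|/sqrt(v) − z_{1−alpha/2}).
    """
    k = spec.k_case_fraction
    if not (0 < k < 1):
        raise MRError(f"case fraction {k} outside (0,1)")
    if not (0 < spec.r2_instrument < 1):
        raise MRError(f"instrument R2 {spec.r2_instrument} outside (0,1)")
    if not (0 < spec.alpha < 1):
        raise MRError(f"alpha {spec.alpha} outside (0,1)")
    if spec.odds_ratio <= 0:
        raise MRError("odds ratio must be positive")
    if spec.n_total <= 0:
        raise MRError("n_total must be positive")
    b = k * (spec.odds_ratio / (1 + k * (spec.odds_ratio - 1)) - 1)
    v = (k * (1 - k) - b * b) / (spec.n_total * spec.r2_instrument)
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    power = float(stats.norm.cdf(abs(b) / math.sqrt(v) - z_crit))
    return PowerSpec(
        n_total=spec.n_total,
        k_case_fraction=k,
        odds_ratio=spec.odds_ratio,
        r2_instrument=spec.r2_instrument,
        alpha=spec.alpha,
        power=power,
    )
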