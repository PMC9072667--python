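"""Two-step mediation MR with proportion mediated.

Decomposes the total causal effect of an exposure X on an outcome Y into an
indirect component carried by a mediator M and a direct remainder:

* step 1: univariable IVW of M on X's instruments (X -> M);
* step 2: multivariable IVW of Y on (X, M) over the union of instruments;
  the mediator coefficient is the M -> Y effect adjusted for X;
* indirect = step1 * step2 with a product delta-method SE
  sqrt(b1^2 s2^2 + b2^2 s1^2); direct = total - indirect;
* proportion mediated = indirect / total with a ratio delta-method CI.

On binary outcomes everything operates on the log-OR scale; the reported
proportion inherits the usual non-collapsibility caveat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw
from .instruments import DEFAULT_P_THRESHOLD, DEFAULT_R2_THRESHOLD, build_instruments
from .mvmr import assemble_mvmr, mvmr_ivw
from .sumstats import DEFAULT_PALINDROME_EAF_LIMIT, SumStatsTable, harmonize

__all__ = ["MediationResult", "two_step_mediation"]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MediationResult:
    exposure_label: str
    mediator_label: str
    outcome_label: str
    total: MREstimate
    step1: MREstimate
    step2: MREstimate
    indirect_beta: float
    indirect_se: float
    direct_beta: float
    direct_se: float
    proportion: float | None
    proportion_se: float | None
    proportion_ci: tuple[float, float] | None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_label,
            "mediator": self.mediator_label,
            "outcome": self.outcome_label,
            "total_beta": self.total.beta,
            "total_se": self.total.se,
            "total_pval": self.total.pval,
            "step1_beta": self.step1.beta,
            "step1_se": self.step1.se,
            "step2_beta": self.step2.beta,
            "step2_se": self.step2.se,
            "indirect_beta": self.indirect_beta,
            "indirect_se": self.indirect_se,
            "direct_beta": self.direct_beta,
            "direct_se": self.direct_se,
            "proportion": self.proportion,
            "proportion_se": self.proportion_se,
            "proportion_ci_low": None if self.proportion_ci is None else self.proportion_ci[0],
            "proportion_ci_high": None if self.proportion_ci is None else self.proportion_ci[1],
            "flags": ";".join(self.flags),
        }


def two_step_mediation(
    exposure: SumStatsTable,
    mediator: SumStatsTable,
    outcome: SumStatsTable,
    ld: pd.DataFrame | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    het_alpha: float = 0.05,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> MediationResult:
    """Product-of-coefficients mediation decomposition via two MR stages.

    The proportion mediated is suppressed (with a flag) when the total effect
    is too close to zero (|z| < 1, ``unstable_denominator``) or when the
    indirect and total effects disagree in sign (``inconsistent_mediation``),
    since the ratio is not interpretable in either case.
    """
    flags: list[str] = []
    inst = build_instruments(exposure, ld, p_threshold, r2_threshold)
    if len(inst) == 0:
        raise ValueError("no instruments selectable for the exposure")

    total = ivw(harmonize(inst, outcome, palindrome_eaf_limit), het_alpha)
    step1 = ivw(harmonize(inst, mediator, palindrome_eaf_limit), het_alpha)

    mv = assemble_mvmr(
        [exposure, mediator],
        outcome,
        ld=ld,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        palindrome_eaf_limit=palindrome_eaf_limit,
    )
    estimates = mvmr_ivw(mv, het_alpha)
    step2 = next(e for e in estimates if e.exposure_label == mv.exposure_labels[1])

    b1, s1 = step1.beta, step1.se
    b2, s2 = step2.beta, step2.se
    indirect = b1 * b2
    indirect_se = math.sqrt(b1**2 * s2**2 + b2**2 * s1**2)
    direct = total.beta - indirect
    direct_se = math.sqrt(total.se**2 + indirect_se**2)  # covariance ignored

    proportion = proportion_se = None
    proportion_ci = None
    if abs(total.beta) < total.se:  # |z| < 1: ratio denominator unstable
        flags.append("unstable_denominator")
    elif np.sign(indirect) != np.sign(total.beta) and indirect != 0:
        flags.append("inconsistent_mediation")
    else:
        proportion = indirect / total.beta
        proportion_se = math.sqrt(
            (indirect_se / total.beta) ** 2
            + (indirect * total.se / total.beta**2) ** 2
        )
        proportion_ci = (
            proportion - _Z95 * proportion_se,
            proportion + _Z95 * proportion_se,
        )
    if outcome.binary:
        flags.append("log_or_scale_noncollapsible")

    return MediationResult(
        exposure_label=exposure.trait_label,
        mediator_label=mediator.trait_label,
        outcome_label=outcome.trait_label,
        total=total,
        step1=step1,
        step2=step2,
        indirect_beta=indirect,
        indirect_se=indirect_se,
        direct_beta=direct,
        direct_se=direct_se,
        proportion=proportion,
        proportion_se=proportion_se,
        proportion_ci=proportion_ci,
        flags=tuple(flags),
    )
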