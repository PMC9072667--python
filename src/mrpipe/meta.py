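"""Fixed-effects meta-analysis across cohorts and Bonferroni tiering.

Estimates of the same exposure-outcome effect from independent cohorts are
pooled with inverse-variance weights; between-cohort heterogeneity is
summarized by Cochran's Q.  Multiplicity over the outcome panel is handled
by Bonferroni tiers: p below alpha/n_outcomes is "significant", p between
that threshold and alpha is "suggestive", anything else "null".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = ["MetaResult", "fixed_effects_meta", "tier_significance", "bonferroni_threshold"]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MetaResult:
    per_cohort: list[tuple[str, float, float]]
    pooled_beta: float
    pooled_se: float
    pooled_pval: float
    ci_low: float
    ci_high: float
    het_q: float
    het_pval: float
    flags: tuple[str, ...] = ()

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.pooled_beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def fixed_effects_meta(
    estimates: Sequence[tuple[str, float, float]],
    het_warn_alpha: float = 0.05,
) -> MetaResult:
    """Pool (cohort_label, beta, se) tuples with fixed-effects weights 1/se^2.

    A single estimate passes through unchanged with a warning.  Between-cohort
    heterogeneity Q (chi-square, c - 1 df) is always computed and surfaced as
    a flag when significant at ``het_warn_alpha``; pooling stays fixed-effects
    regardless.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to pool")
    betas = np.array([b for _, b, _ in estimates], dtype=float)
    ses = np.array([s for _, _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    flags: tuple[str, ...] = ()
    if len(estimates) == 1:
        warnings.warn("single estimate: meta-analysis is a passthrough", UserWarning, stacklevel=2)
        beta, se = float(betas[0]), float(ses[0])
        q, q_p = 0.0, 1.0
        flags = ("single_cohort",)
    else:
        w = 1.0 / ses**2
        beta = float(np.sum(w * betas) / np.sum(w))
        se = 1.0 / math.sqrt(float(np.sum(w)))
        q = float(np.sum(w * (betas - beta) ** 2))
        q_p = float(stats.chi2.sf(q, len(estimates) - 1))
        if q_p < het_warn_alpha:
            flags = ("cohort_heterogeneity",)
    return MetaResult(
        per_cohort=[(str(c), float(b), float(s)) for c, b, s in estimates],
        pooled_beta=beta,
        pooled_se=se,
        pooled_pval=float(2.0 * stats.norm.sf(abs(beta / se))),
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        het_q=q,
        het_pval=q_p,
        flags=flags,
    )


def bonferroni_threshold(alpha: float, n_outcomes: int) -> float:
    """Per-test significance threshold alpha / n_outcomes."""
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_outcomes


def tier_significance(
    pvals: Iterable[float], n_outcomes: int, alpha: float = 0.05
) -> list[str]:
    """Label each p-value "significant" (p < alpha/n), "suggestive"
    (alpha/n <= p < alpha) or "null" (p >= alpha)."""
    thr = bonferroni_threshold(alpha, n_outcomes)
    labels = []
    for p in pvals:
        if p < thr:
            labels.append("significant")
        elif p < alpha:
            labels.append("suggestive")
        else:
            labels.append("null")
    return labels
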