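"""Monte-Carlo validation experiments for the estimator battery.

Each experiment regenerates synthetic studies with known ground truth and
measures a frequentist operating characteristic of the pipeline: type-I
error and CI coverage of IVW, recovery of planted directional pleiotropy by
the MR-Egger intercept, outlier detection by MR-PRESSO, the weighted
median's breakdown behavior under invalid instruments, and recovery of a
planted mediation proportion.  These are the quantities the package's
acceptance checks assert on; they are exposed as library functions so the
same experiment can be re-run from a script or notebook.

Every experiment takes a ``seed`` and derives per-replicate seeds from it,
so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import egger, ivw, weighted_median
from .mediation import two_step_mediation
from .presso import presso_test
from .simulate import SyntheticTruth, generate_study
from .sumstats import HarmonizedSet

__all__ = [
    "ivw_type_i_error",
    "ivw_coverage",
    "egger_slope_coverage",
    "egger_intercept_recovery",
    "presso_detection",
    "weighted_median_breakdown",
    "mediation_recovery",
]


def _rep_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))


def ivw_type_i_error(n_reps: int = 1000, k: int = 50, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Empirical rejection rate of IVW under a true null (no effect, no
    pleiotropy, strong instruments)."""
    hits = 0
    for r in range(n_reps):
        truth = SyntheticTruth(theta=0.0, k=k, seed=_rep_seed(seed, r))
        est = ivw(generate_study(truth).harmonized())
        hits += est.pval < alpha
    return hits / n_reps


def ivw_coverage(n_reps: int = 1000, theta: float = 0.1, k: int = 100,
                 seed: int = 0) -> tuple[float, float]:
    """(95% CI coverage of the true effect, mean estimate) for IVW."""
    covered, ests = 0, []
    for r in range(n_reps):
        truth = SyntheticTruth(theta=theta, k=k, seed=_rep_seed(seed, r))
        est = ivw(generate_study(truth).harmonized())
        covered += est.ci_low <= theta <= est.ci_high
        ests.append(est.beta)
    return covered / n_reps, float(np.mean(ests))


def egger_slope_coverage(n_reps: int = 1000, theta: float = 0.1, k: int = 100,
                         sigma_alpha: float = 0.05, seed: int = 0) -> float:
    """95% CI coverage of the MR-Egger slope under balanced pleiotropy
    (zero-mean per-SNP effects, InSIDE satisfied)."""
    covered = 0
    for r in range(n_reps):
        truth = SyntheticTruth(
            theta=theta, k=k, mu_alpha=0.0, sigma_alpha=sigma_alpha, rho=0.0,
            seed=_rep_seed(seed, r),
        )
        est = egger(generate_study(truth).harmonized())
        covered += est.ci_low <= theta <= est.ci_high
    return covered / n_reps


def egger_intercept_recovery(
    n_reps: int = 500, theta: float = 0.1, k: int = 100,
    mu_alpha: float = 0.05, sigma_alpha: float = 0.02, seed: int = 0,
) -> tuple[float, float]:
    """(mean Egger intercept, Monte-Carlo SE of that mean) under planted
    directional pleiotropy with per-SNP mean ``mu_alpha``."""
    intercepts = []
    for r in range(n_reps):
        truth = SyntheticTruth(
            theta=theta, k=k, mu_alpha=mu_alpha, sigma_alpha=sigma_alpha,
            rho=0.0, seed=_rep_seed(seed, r),
        )
        intercepts.append(egger(generate_study(truth).harmonized()).egger_intercept)
    intercepts = np.asarray(intercepts)
    return float(intercepts.mean()), float(intercepts.std(ddof=1) / np.sqrt(n_reps))


def presso_detection(
    n_reps: int = 200, k: int = 30, shift: float = 10.0, n_sim: int = 1000,
    theta: float = 0.1, seed: int = 0,
) -> tuple[float, float]:
    """One planted outlier (+``shift`` outcome SEs) among ``k`` clean SNPs.

    Returns (fraction of replicates where the planted outlier is flagged,
    fraction where the outlier-corrected estimate is closer to the true
    effect than the raw one)."""
    flagged = closer = 0
    for r in range(n_reps):
        truth = SyntheticTruth(
            theta=theta, k=k, n_outliers=1, outlier_shift=shift,
            seed=_rep_seed(seed, r),
        )
        study = generate_study(truth)
        rep = presso_test(study.harmonized(), n_sim=n_sim, seed=_rep_seed(seed, 10_000 + r))
        planted = set(study.outlier_ids["Y"])
        if planted & set(rep.outlier_ids):
            flagged += 1
        if rep.beta_corrected is not None:
            if abs(rep.beta_corrected.beta - theta) < abs(rep.beta_raw.beta - theta):
                closer += 1
    return flagged / n_reps, closer / n_reps


def weighted_median_breakdown(
    n_reps: int = 1000, k: int = 20, invalid_fraction: float = 0.25,
    theta: float = 0.2, invalid_ratio: float = 5.0, seed: int = 0,
) -> tuple[float, float]:
    """(bias of the weighted median, Monte-Carlo SD of the estimator) when a
    fraction of equally-weighted instruments point at a wrong ratio.

    With < 50% invalid weight the estimator is consistent: the bias should be
    small relative to its own Monte-Carlo dispersion.  At >= 50% the planted
    invalid cluster captures the median and the bias becomes dominant."""
    n_invalid = int(round(invalid_fraction * k))
    ests = []
    for r in range(n_reps):
        rng = np.random.default_rng(_rep_seed(seed, r))
        bx = np.full(k, 0.2)
        sx = np.full(k, 0.002)
        sy = np.full(k, 0.01)
        slope = np.full(k, theta)
        slope[:n_invalid] = invalid_ratio
        by = slope * bx + rng.normal(0, sy)
        h = HarmonizedSet(
            variant_ids=[f"rs{i}" for i in range(k)],
            beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
        )
        ests.append(weighted_median(h, n_boot=2, seed=1).beta)
    ests = np.asarray(ests)
    return float(ests.mean() - theta), float(ests.std(ddof=1))


def mediation_recovery(
    n_reps: int = 500, delta: float = 0.5, tau: float = 0.2,
    theta_dir: float = 0.1, k: int = 50, seed: int = 0,
) -> dict:
    """Recovery of a planted mediation structure by two-step MR.

    The true proportion mediated is delta*tau / (theta_dir + delta*tau).
    Returns the empirical 95% CI coverage of that proportion, the mean
    estimated proportion, and the mean absolute discrepancy of the
    decomposition total - (direct + indirect) (identically zero by
    construction of the product method)."""
    true_prop = delta * tau / (theta_dir + delta * tau)
    covered = n_ci = 0
    props, decomp = [], []
    for r in range(n_reps):
        truth = SyntheticTruth(
            mediation=True, delta=delta, tau=tau, theta_dir=theta_dir,
            k=k, k_med=k, seed=_rep_seed(seed, r),
        )
        study = generate_study(truth)
        res = two_step_mediation(study.exposure, study.mediator, study.outcome(1))
        if res.proportion is not None:
            props.append(res.proportion)
            n_ci += 1
            lo, hi = res.proportion_ci
            covered += lo <= true_prop <= hi
        decomp.append(abs(res.total.beta - res.direct_beta - res.indirect_beta))
    return {
        "true_proportion": true_prop,
        "coverage": covered / max(n_ci, 1),
        "n_with_ci": n_ci,
        "mean_proportion": float(np.mean(props)) if props else float("nan"),
        "mean_decomposition_error": float(np.mean(decomp)),
    }
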