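"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier test.

Three stages on a harmonized instrument set:

1. **Global test** -- for each variant i an IVW estimate is fitted leaving i
   out; the observed weighted residual sum of squares
   RSS = sum_i (by_i - b_loo(i) * bx_i)^2 / se_y_i^2 is compared against its
   Monte-Carlo null distribution obtained by redrawing
   bx*_i ~ N(bx_i, se_x_i) and by*_i ~ N(b_loo(i) * bx_i, se_y_i).
2. **Outlier test** -- each variant's observed residual contribution gets an
   analogous Monte-Carlo tail p, Bonferroni-adjusted across variants.
3. **Distortion test** -- the shift between the raw IVW estimate and the
   outlier-corrected one is compared against shifts produced by removing
   random variant subsets of the same size.

All Monte-Carlo p-values use the add-one convention (1 + #exceed)/(n_sim + 1),
so they are never exactly zero and are bounded below by 1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, ivw
from .sumstats import HarmonizedSet

__all__ = ["PressoReport", "presso_test"]

DEFAULT_N_SIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05


@dataclass
class PressoReport:
    """Global heterogeneity, per-variant outlier calls and distortion test."""

    applicable: bool
    reason: str | None = None
    global_rss_obs: float | None = None
    global_pval: float | None = None
    outlier_pvals: dict[str, float] = field(default_factory=dict)  # Bonferroni-adjusted
    outlier_raw_pvals: dict[str, float] = field(default_factory=dict)
    outlier_ids: list[str] = field(default_factory=list)
    distortion_pval: float | None = None
    beta_raw: MREstimate | None = None
    beta_corrected: MREstimate | None = None
    n_sim: int = 0
    seed: int | None = None


def _loo_expected(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Leave-one-out IVW slopes (vectorized over the last axis)."""
    s_xx = np.sum(w * bx**2, axis=-1, keepdims=True)
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    denom = s_xx - w * bx**2
    return (s_xy - w * bx * by) / denom


def presso_test(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    seed: int | None = None,
) -> PressoReport:
    """Run the full MR-PRESSO battery on a harmonized instrument set.

    Requires at least 4 instruments (each leave-one-out fit must keep >= 3)
    and ``n_sim >= 1000`` Monte-Carlo replicates.  Raises when every
    instrument is flagged as an outlier, since no corrected estimate exists.
    """
    k = h.n_snp
    if k < 4:
        return PressoReport(
            applicable=False, reason=f"needs >= 4 instruments, got {k}", n_sim=n_sim, seed=seed
        )
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")

    rng = np.random.default_rng(seed)
    bx, by = h.beta_x, h.beta_y
    w = 1.0 / h.se_y**2

    loo = np.asarray(_loo_expected(bx, by, w)).reshape(-1)
    expected = loo * bx
    d_obs = w * (by - expected) ** 2
    rss_obs = float(np.sum(d_obs))

    bx_sim = rng.normal(bx, h.se_x, size=(n_sim, k))
    by_sim = rng.normal(expected, h.se_y, size=(n_sim, k))
    loo_sim = _loo_expected(bx_sim, by_sim, w[None, :])
    d_sim = w[None, :] * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = d_sim.sum(axis=1)

    global_pval = (1.0 + float(np.sum(rss_sim >= rss_obs))) / (n_sim + 1.0)
    raw_p = (1.0 + np.sum(d_sim >= d_obs[None, :], axis=0)) / (n_sim + 1.0)
    adj_p = np.minimum(1.0, raw_p * k)
    flagged = adj_p < outlier_alpha
    ids = h.variant_ids
    outlier_ids = [ids[i] for i in np.flatnonzero(flagged)]

    beta_raw = ivw(h)
    beta_corrected = None
    distortion_pval = None
    n_out = len(outlier_ids)
    if n_out == k:
        raise ValueError("no valid instruments remain: every variant flagged as outlier")
    if n_out > 0 and k - n_out >= 2:
        keep = np.flatnonzero(~flagged)
        beta_corrected = ivw(h.subset(keep))
        d_obs_shift = beta_raw.beta - beta_corrected.beta
        # null distribution of the shift: remove random subsets of size n_out
        ranks = rng.random((n_sim, k)).argsort(axis=1)
        drop_mask = ranks < n_out
        s_xx = np.sum(w * bx**2)
        s_xy = np.sum(w * bx * by)
        s_xx_kept = s_xx - np.sum(np.where(drop_mask, w * bx**2, 0.0), axis=1)
        s_xy_kept = s_xy - np.sum(np.where(drop_mask, w * bx * by, 0.0), axis=1)
        shift_sim = beta_raw.beta - s_xy_kept / s_xx_kept
        distortion_pval = (1.0 + float(np.sum(np.abs(shift_sim) >= abs(d_obs_shift)))) / (
            n_sim + 1.0
        )

    return PressoReport(
        applicable=True,
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=dict(zip(ids, adj_p.tolist())),
        outlier_raw_pvals=dict(zip(ids, raw_p.tolist())),
        outlier_ids=outlier_ids,
        distortion_pval=distortion_pval,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        n_sim=n_sim,
        seed=seed,
    )
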