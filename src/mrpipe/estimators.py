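"""Univariable two-sample MR estimators and their diagnostics.

All estimators consume a :class:`~mrpipe.sumstats.HarmonizedSet` of aligned
per-variant effects (beta_x, se_x, beta_y, se_y):

* :func:`wald_ratio` -- single-variant ratio estimate beta_y / beta_x.
* :func:`ivw` -- inverse-variance-weighted combination of Wald ratios,
  equivalent to a weighted zero-intercept regression of beta_y on beta_x with
  weights 1/se_y^2; Cochran's Q drives a fixed- vs multiplicative
  random-effects model choice.
* :func:`egger` -- weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy.
* :func:`weighted_median` -- weighted-quantile estimate, consistent when
  valid instruments carry more than half the weight.
* :func:`mode_estimator` -- simple and weighted mode of the smoothed Wald
  ratio density, consistent when the largest homogeneous cluster is valid.

Bootstrap standard errors (median and mode) use a parametric resampling of
(beta_x, beta_y) from normals at the observed SEs with a caller-supplied seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimator",
    "InsufficientInstrumentsError",
]

_Z95 = float(stats.norm.ppf(0.975))
DEFAULT_HET_ALPHA = 0.05
DEFAULT_N_BOOT = 1000
_MODE_GRID = 512


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator is given fewer instruments than it needs."""


@dataclass
class MREstimate:
    """One method's causal estimate with uncertainty and diagnostics.

    ``beta`` is on the outcome scale per unit of exposure (log-OR per exposure
    unit for binary outcomes); ``odds_ratio``/``or_ci`` expose the
    exp-transformed scale used for reporting binary outcomes.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_pval: float | None = None
    model: str = "n/a"
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    exposure_label: str | None = None
    conditional_f: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def with_flags(self, *flags: str) -> "MREstimate":
        return dataclasses.replace(self, flags=self.flags + flags)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["odds_ratio"] = self.odds_ratio
        d["or_low"], d["or_high"] = self.or_ci
        d["flags"] = ";".join(self.flags)
        return d


def _normal_estimate(method: str, beta: float, se: float, n_snp: int, **kw) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_snp=n_snp,
        **kw,
    )


def wald_ratio(bx: float, sx: float, by: float, sy: float, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate by/bx.

    The default SE is the first-order delta-method value |sy / bx|, ignoring
    exposure-side uncertainty so that the estimate's weight matches the IVW
    weighting scheme; ``second_order=True`` adds the exposure term
    sqrt(sy^2/bx^2 + by^2 sx^2 / bx^4).
    """
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    if sx <= 0 or sy <= 0:
        raise ValueError("standard errors must be positive")
    beta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = abs(sy / bx)
    return _normal_estimate("wald", beta, se, 1)


def ivw(h: HarmonizedSet, het_alpha: float = DEFAULT_HET_ALPHA) -> MREstimate:
    """Inverse-variance-weighted estimate with heterogeneity-driven model choice.

    Computed in the regression form beta = sum(w bx by) / sum(w bx^2) with
    w = 1/se_y^2, which is identical to the weighted mean of Wald ratios with
    ratio weights bx^2/se_y^2 and remains defined when some bx = 0.  When
    Cochran's Q is significant at ``het_alpha`` the fixed-effects SE is scaled
    by sqrt(Q / (k - 1)) (floored at 1, multiplicative random effects).
    """
    k = h.n_snp
    if k == 0:
        raise InsufficientInstrumentsError("IVW needs at least one instrument")
    if k == 1:
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
        return dataclasses.replace(
            est, method="ivw", model="fixed", flags=est.flags + ("single_variant",)
        )
    w = 1.0 / h.se_y**2
    s_xx = float(np.sum(w * h.beta_x**2))
    if s_xx == 0:
        raise InsufficientInstrumentsError("all exposure effects are zero")
    beta = float(np.sum(w * h.beta_x * h.beta_y)) / s_xx
    se_fixed = 1.0 / math.sqrt(s_xx)
    q = float(np.sum(w * (h.beta_y - beta * h.beta_x) ** 2))
    q_pval = float(stats.chi2.sf(q, k - 1))
    if q_pval < het_alpha:
        scale = max(1.0, math.sqrt(q / (k - 1)))
        se, model = se_fixed * scale, "random"
    else:
        se, model = se_fixed, "fixed"
    return _normal_estimate("ivw", beta, se, k, q_stat=q, q_pval=q_pval, model=model)


def egger(h: HarmonizedSet, het_alpha: float = DEFAULT_HET_ALPHA) -> MREstimate:
    """MR-Egger: weighted regression of beta_y on beta_x with a free intercept.

    Instruments are oriented to the exposure-increasing allele before the fit
    (the intercept is not identifiable otherwise).  The slope is the causal
    estimate; the intercept estimates average directional pleiotropy, tested
    two-sided against a t reference with k - 2 df.  SEs carry a multiplicative
    overdispersion factor max(1, sqrt(RSS_w / (k - 2))); Rucker's Q' (the
    weighted RSS) is reported as the heterogeneity statistic.
    """
    k = h.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    sgn = np.where(h.beta_x < 0, -1.0, 1.0)
    bx = sgn * h.beta_x
    by = sgn * h.beta_y
    w = 1.0 / h.se_y**2
    x = np.column_stack([np.ones(k), bx])
    a = x.T @ (w[:, None] * x)
    if np.linalg.matrix_rank(a) < 2:
        raise InsufficientInstrumentsError("no spread in exposure effects")
    coef = np.linalg.solve(a, x.T @ (w * by))
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (k - 2)))
    cov = scale**2 * np.linalg.inv(a)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tq = float(stats.t.ppf(0.975, k - 2))
    slope, intercept = float(coef[1]), float(coef[0])
    q_pval = float(stats.chi2.sf(rss_w, k - 2))
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=float(2.0 * stats.t.sf(abs(slope / se_slope), k - 2)),
        n_snp=k,
        q_stat=rss_w,
        q_pval=q_pval,
        model="random" if q_pval < het_alpha else "fixed",
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pval=float(2.0 * stats.t.sf(abs(intercept / se_int), k - 2)),
    )


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by linear interpolation of the standardized
    cumulative weight p_i = (cumsum(w) - w/2) / sum(w) at p = 0.5."""
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    cw = np.cumsum(w, axis=-1)
    p = (cw - 0.5 * w) / cw[..., -1:]
    below = p < 0.5
    idx_hi = below.sum(axis=-1)  # first index with p >= 0.5
    idx_hi = np.clip(idx_hi, 1, r.shape[-1] - 1)
    idx_lo = idx_hi - 1
    take = lambda arr, idx: np.take_along_axis(arr, idx[..., None], axis=-1)[..., 0]
    p_lo, p_hi = take(p, idx_lo), take(p, idx_hi)
    r_lo, r_hi = take(r, idx_lo), take(r, idx_hi)
    frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
    est = r_lo + frac * (r_hi - r_lo)
    # clamp when 0.5 falls outside [p_1, p_k] (one variant dominates the weight)
    est = np.where(p_lo >= 0.5, take(r, np.zeros_like(idx_lo)), est)
    est = np.where(p_hi < 0.5, r[..., -1], est)
    return est


def _parametric_boot(h: HarmonizedSet, n_boot: int, seed: int | None):
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, h.n_snp))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, h.n_snp))
    return bx, by


def weighted_median(
    h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Wald ratios are weighted by bx^2/se_y^2 (inverse first-order ratio
    variance); the estimate interpolates the weighted quantile function at
    one half, so it is consistent whenever valid instruments carry > 50% of
    the total weight.
    """
    k = h.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ratios = h.beta_y / h.beta_x
    weights = h.beta_x**2 / h.se_y**2
    est = float(_weighted_median_rows(ratios[None, :], weights[None, :])[0])
    bx, by = _parametric_boot(h, n_boot, seed)
    boot = _weighted_median_rows(by / bx, bx**2 / h.se_y**2)
    se = float(np.std(boot, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    return _normal_estimate("weighted_median", est, se, k)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    h = phi * 0.9 * min(sd, mad / 0.6745) * len(ratios) ** (-1 / 5)
    if h <= 0 or not np.isfinite(h):
        # all ratios (essentially) identical: the mode is the common value
        return float(ratios[np.argmax(weights)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, _MODE_GRID)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimator(
    h: HarmonizedSet,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MREstimate:
    """Mode of the smoothed empirical Wald-ratio density.

    A Gaussian kernel with bandwidth phi * 0.9 min(sd, MAD/0.6745) k^(-1/5)
    smooths the ratio distribution; the estimate is the density argmax over a
    ratio grid.  The simple mode uses equal weights, the weighted mode weights
    each ratio by its inverse first-order variance bx^2/se_y^2.  SE by the
    same parametric bootstrap as the weighted median.
    """
    k = h.n_snp
    if k < 3:
        raise InsufficientInstrumentsError("mode estimators need at least 3 instruments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if phi <= 0:
        raise ValueError("phi must be positive")
    nz = h.beta_x != 0
    if not np.all(nz):
        h = h.subset(np.flatnonzero(nz))
        k = h.n_snp
    ratios = h.beta_y / h.beta_x

    def _w(bx: np.ndarray) -> np.ndarray:
        if weighted:
            return bx**2 / h.se_y**2
        return np.ones_like(bx)

    est = _kde_mode(ratios, _w(h.beta_x), phi)
    bxs, bys = _parametric_boot(h, n_boot, seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bx = bxs[b]
        good = bx != 0
        boot[b] = _kde_mode((bys[b][good] / bx[good]), _w(bx)[good], phi)
    se = float(np.std(boot, ddof=1))
    if se == 0:
        se = float(np.finfo(float).tiny)
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(method, est, se, k)
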