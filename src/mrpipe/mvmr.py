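"""Multivariable MR: joint IVW regression on several exposures.

Genetic associations with the outcome are regressed (no intercept, weights
1/se_y^2) on the matrix of associations with m exposures over the union of
their instruments; coefficient j is the direct effect of exposure j
conditional on the others.  Assembly is complete-case: variants absent from
any exposure table are dropped, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, InsufficientInstrumentsError, DEFAULT_HET_ALPHA
from .instruments import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    ld_clump,
    select_significant,
)
from .sumstats import (
    DEFAULT_PALINDROME_EAF_LIMIT,
    SumStatsTable,
    _align_alleles,
)

__all__ = ["MVMRInput", "assemble_mvmr", "mvmr_ivw"]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MVMRInput:
    """Complete-case design for multivariable IVW.

    ``beta_x_matrix`` is k x m (variants by exposures) on one shared allele
    orientation; rows are oriented so the first exposure's beta is
    non-negative.
    """

    variant_ids: list[str]
    beta_x_matrix: np.ndarray
    se_x_matrix: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    exposure_labels: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x_matrix = np.atleast_2d(np.asarray(self.beta_x_matrix, dtype=float))
        self.se_x_matrix = np.atleast_2d(np.asarray(self.se_x_matrix, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        k, m = self.beta_x_matrix.shape
        if len(self.variant_ids) != k or len(self.beta_y) != k:
            raise ValueError("row count mismatch in MVMR input")
        if m != len(self.exposure_labels):
            raise ValueError("exposure label count mismatch")
        if k <= m:
            raise ValueError(
                f"underdetermined system: {k} variants for {m} exposures (need k > m)"
            )
        if np.any(~np.isfinite(self.beta_x_matrix)) or np.any(~np.isfinite(self.beta_y)):
            raise ValueError("MVMR input contains missing cells")

    @property
    def k(self) -> int:
        return self.beta_x_matrix.shape[0]

    @property
    def m(self) -> int:
        return self.beta_x_matrix.shape[1]


def _joint_clump(
    union: pd.DataFrame, ld, r2_threshold: float
) -> list[str]:
    """Greedy clump of the union instrument list ranked by min p across
    exposures (ties by variant_id)."""
    tbl = SumStatsTable(
        union.rename(columns={"min_pval": "pval"}), trait_label="union"
    )
    kept = ld_clump(tbl, ld, r2_threshold)
    return kept.variant_ids


def assemble_mvmr(
    exposures: Sequence[SumStatsTable],
    outcome: SumStatsTable,
    ld: pd.DataFrame | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> MVMRInput:
    """Select per-exposure instruments, union them, and build the design.

    Instruments are selected per exposure at ``p_threshold`` (clumped against
    ``ld`` when supplied), unioned, jointly re-clumped ranked by the minimum
    p across exposures, then restricted to variants present in every exposure
    table and the outcome table (complete case).  Alleles are aligned to the
    first exposure's orientation; rows are flipped so its beta is >= 0.
    """
    if len(exposures) < 2 and len(exposures) != 1:
        raise ValueError("assemble_mvmr needs at least one exposure")
    labels = [t.trait_label or f"exposure_{i}" for i, t in enumerate(exposures)]

    selected: dict[str, pd.Series] = {}
    for tbl in exposures:
        sig = select_significant(tbl, p_threshold)
        if ld is not None and len(sig):
            sig = ld_clump(sig, ld.loc[sig.variant_ids, sig.variant_ids], r2_threshold)
        for _, row in sig.df.iterrows():
            vid = row["variant_id"]
            p = row["pval"]
            if vid not in selected or p < selected[vid]:
                selected[vid] = p
    if not selected:
        raise ValueError("no instruments selected for any exposure")
    union = pd.DataFrame(
        {
            "variant_id": list(selected.keys()),
            "min_pval": list(selected.values()),
        }
    ).sort_values(["min_pval", "variant_id"], kind="mergesort")

    if ld is not None:
        frame = union.copy()
        # columns needed by SumStatsTable; alleles come from the first exposure
        first = exposures[0].df.set_index("variant_id")
        fallback = {"effect_allele": "A", "other_allele": "G"}
        frame["effect_allele"] = [
            first.loc[v, "effect_allele"] if v in first.index else fallback["effect_allele"]
            for v in frame["variant_id"]
        ]
        frame["other_allele"] = [
            first.loc[v, "other_allele"] if v in first.index else fallback["other_allele"]
            for v in frame["variant_id"]
        ]
        frame["eaf"] = np.nan
        frame["beta"] = 0.0
        frame["se"] = 1.0
        frame["n"] = 1
        order = _joint_clump(
            frame[
                [
                    "variant_id",
                    "effect_allele",
                    "other_allele",
                    "eaf",
                    "beta",
                    "se",
                    "min_pval",
                    "n",
                ]
            ],
            ld.loc[frame["variant_id"], frame["variant_id"]],
            r2_threshold,
        )
    else:
        order = list(union["variant_id"])

    indexed = [t.df.set_index("variant_id") for t in exposures]
    out_idx = outcome.df.set_index("variant_id")
    ref = indexed[0]

    ids: list[str] = []
    bx_rows, sx_rows, by_list, sy_list = [], [], [], []
    dropped: list[tuple[str, str]] = []
    for vid in order:
        if any(vid not in idx.index for idx in indexed):
            dropped.append((vid, "missing_in_exposure"))
            continue
        if vid not in out_idx.index:
            dropped.append((vid, "missing_in_outcome"))
            continue
        if vid in ref.index:
            ea, oa, eaf_ref = (
                ref.loc[vid, "effect_allele"],
                ref.loc[vid, "other_allele"],
                float(ref.loc[vid, "eaf"]),
            )
        else:  # pragma: no cover - union always drawn from exposure tables
            dropped.append((vid, "missing_in_exposure"))
            continue
        row_bx, row_sx = [], []
        ok = True
        for idx in indexed:
            r = idx.loc[vid]
            al = _align_alleles(
                ea, oa, eaf_ref,
                r["effect_allele"], r["other_allele"], float(r["eaf"]),
                palindrome_eaf_limit,
            )
            if not al.ok:
                dropped.append((vid, al.reason))
                ok = False
                break
            row_bx.append(al.sign * float(r["beta"]))
            row_sx.append(float(r["se"]))
        if not ok:
            continue
        o = out_idx.loc[vid]
        al = _align_alleles(
            ea, oa, eaf_ref,
            o["effect_allele"], o["other_allele"], float(o["eaf"]),
            palindrome_eaf_limit,
        )
        if not al.ok:
            dropped.append((vid, al.reason))
            continue
        by = al.sign * float(o["beta"])
        if row_bx[0] < 0:  # orient to first exposure's increasing allele
            row_bx = [-b for b in row_bx]
            by = -by
        ids.append(vid)
        bx_rows.append(row_bx)
        sx_rows.append(row_sx)
        by_list.append(by)
        sy_list.append(float(o["se"]))

    if len(ids) <= len(exposures):
        raise ValueError(
            f"underdetermined system: {len(ids)} variants for {len(exposures)} exposures"
        )
    return MVMRInput(
        variant_ids=ids,
        beta_x_matrix=np.array(bx_rows),
        se_x_matrix=np.array(sx_rows),
        beta_y=np.array(by_list),
        se_y=np.array(sy_list),
        exposure_labels=labels,
        dropped=dropped,
    )


def _conditional_f(inp: MVMRInput, j: int) -> float:
    """Approximate conditional instrument strength for exposure j: weighted
    residual chi-square of its effects after projecting out the co-exposures,
    divided by k - m + 1."""
    x = inp.beta_x_matrix
    k, m = x.shape
    target = x[:, j]
    w = 1.0 / inp.se_x_matrix[:, j] ** 2
    if m == 1:
        resid = target
    else:
        others = np.delete(x, j, axis=1)
        a = others.T @ (w[:, None] * others)
        coef = np.linalg.lstsq(a, others.T @ (w * target), rcond=None)[0]
        resid = target - others @ coef
    return float(np.sum(w * resid**2) / (k - m + 1))


def mvmr_ivw(inp: MVMRInput, het_alpha: float = DEFAULT_HET_ALPHA) -> list[MREstimate]:
    """Multivariable IVW: weighted multiple regression without intercept.

    Returns one estimate per exposure (direct effect conditional on the
    others).  When the residual heterogeneity is significant at ``het_alpha``
    the SEs carry a multiplicative overdispersion factor
    sqrt(RSS_w / (k - m)), floored at 1, so that the m = 1 case reduces
    exactly to univariable IVW.  A per-exposure conditional F diagnostic is
    attached to each estimate.
    """
    x, y = inp.beta_x_matrix, inp.beta_y
    k, m = x.shape
    w = 1.0 / inp.se_y**2
    a = x.T @ (w[:, None] * x)
    if np.linalg.matrix_rank(a) < m:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            f"{inp.exposure_labels[i]}~{inp.exposure_labels[j]}"
            for i in range(m)
            for j in range(i + 1, m)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise InsufficientInstrumentsError(
            "rank-deficient design; collinear exposures: " + (", ".join(pairs) or "unknown")
        )
    coef = np.linalg.solve(a, x.T @ (w * y))
    resid = y - x @ coef
    rss_w = float(np.sum(w * resid**2))
    q_pval = float(stats.chi2.sf(rss_w, k - m))
    if q_pval < het_alpha:
        scale = max(1.0, math.sqrt(rss_w / (k - m)))
        model = "random"
    else:
        scale, model = 1.0, "fixed"
    cov = scale**2 * np.linalg.inv(a)

    out: list[MREstimate] = []
    for j, label in enumerate(inp.exposure_labels):
        b = float(coef[j])
        se = math.sqrt(cov[j, j])
        out.append(
            MREstimate(
                method="mvmr_ivw",
                beta=b,
                se=se,
                ci_low=b - _Z95 * se,
                ci_high=b + _Z95 * se,
                pval=float(2.0 * stats.norm.sf(abs(b / se))),
                n_snp=k,
                q_stat=rss_w,
                q_pval=q_pval,
                model=model,
                exposure_label=label,
                conditional_f=_conditional_f(inp, j),
            )
        )
    return out
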