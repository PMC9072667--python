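"""Instrument selection and strength diagnostics.

Instruments are genome-wide significant variants (p < 5e-8 by default),
pruned to pairwise linkage equilibrium (r^2 < 0.001) with a greedy
best-p-first rule, and screened for weak-instrument bias with the
F-statistic F = R^2 (n - k - 1) / (k (1 - R^2)), where n is the exposure
sample size, k the instrument count and R^2 the variance in the exposure
explained by the instruments.  F > 10 is the conventional strength gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import HarmonizedSet, SumStatsTable

__all__ = [
    "InstrumentSet",
    "GateResult",
    "select_significant",
    "ld_clump",
    "f_statistic",
    "variance_explained",
    "weak_instrument_gate",
    "build_instruments",
    "instrument_set",
]

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_F_MIN = 10.0


@dataclass
class InstrumentSet:
    """Selected instruments with their strength summary."""

    variants: HarmonizedSet
    r2_explained: float
    f_statistic: float
    k: int
    n: int
    approximate_r2: bool = False  # binary exposure: log-odds-scale approximation

    def __post_init__(self) -> None:
        expected = f_statistic(self.r2_explained, self.n, self.k)
        if not np.isclose(expected, self.f_statistic, rtol=0, atol=1e-10):
            raise ValueError("f_statistic inconsistent with r2_explained, n, k")


@dataclass
class GateResult:
    passed: bool
    message: str
    flag: str | None = None


def select_significant(
    table: SumStatsTable, p_threshold: float = DEFAULT_P_THRESHOLD
) -> SumStatsTable:
    """Rows with p strictly below the genome-wide threshold (default 5e-8)."""
    keep = table.df["pval"] < p_threshold
    if not keep.any():
        warnings.warn(
            f"no variant reaches p < {p_threshold:g} for trait "
            f"'{table.trait_label}'; downstream estimators need >= 1 instrument",
            UserWarning,
            stacklevel=2,
        )
    return SumStatsTable(
        table.df[keep].reset_index(drop=True),
        trait_label=table.trait_label,
        cohort_label=table.cohort_label,
        binary=table.binary,
    )


def _ld_as_array(
    ld: pd.DataFrame | np.ndarray, variant_ids: list[str]
) -> np.ndarray:
    if isinstance(ld, pd.DataFrame):
        missing = [v for v in variant_ids if v not in ld.index]
        if missing:
            raise ValueError(f"LD matrix lacks variant(s): {', '.join(missing[:5])}")
        mat = ld.loc[variant_ids, variant_ids].to_numpy(dtype=float)
    else:
        mat = np.asarray(ld, dtype=float)
    k = len(variant_ids)
    if mat.shape != (k, k):
        raise ValueError(f"LD matrix shape {mat.shape} does not match {k} variants")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError("LD matrix must have a unit diagonal")
    if mat.min() < -1e-8 or mat.max() > 1 + 1e-8:
        raise ValueError("LD r^2 entries must lie in [0, 1]")
    return mat


def ld_clump(
    table: SumStatsTable,
    ld: pd.DataFrame | np.ndarray,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> SumStatsTable:
    """Greedy LD pruning: keep the best-p variant, discard everything in LD.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken by lexicographic variant_id) and removes every remaining variant
    with r^2 >= ``r2_threshold`` against it.  The result is ordered by
    selection, is deterministic, and does not depend on input row order.
    """
    ids = table.variant_ids
    mat = _ld_as_array(ld, ids)
    order = sorted(
        range(len(ids)), key=lambda i: (table.df["pval"].iloc[i], ids[i])
    )
    alive = np.ones(len(ids), dtype=bool)
    chosen: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        chosen.append(i)
        alive &= mat[i] < r2_threshold
        alive[i] = False
    return SumStatsTable(
        table.df.iloc[chosen].reset_index(drop=True),
        trait_label=table.trait_label,
        cohort_label=table.cohort_label,
        binary=table.binary,
    )


def f_statistic(r2: float, n: int, k: int) -> float:
    """F = R^2 (n - k - 1) / (k (1 - R^2)) for k instruments at sample size n."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise ValueError("need n > k + 1 >= 2")
    return r2 * (n - k - 1) / (k * (1.0 - r2))


def variance_explained(eaf: np.ndarray, beta: np.ndarray) -> float:
    """Cumulative variance explained: sum over SNPs of 2 f (1 - f) beta^2.

    Assumes a standardized continuous exposure; for binary exposures the same
    expression on the log-odds scale is an approximation and callers should
    carry an ``approximate`` flag.
    """
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(eaf)):
        raise ValueError("variance_explained requires a known eaf for every SNP")
    return float(np.sum(2.0 * eaf * (1.0 - eaf) * beta**2))


def weak_instrument_gate(inst: InstrumentSet, f_min: float = DEFAULT_F_MIN) -> GateResult:
    """Advisory strength gate: pass iff F strictly exceeds ``f_min``."""
    if inst.f_statistic > f_min:
        return GateResult(True, f"F = {inst.f_statistic:.2f} > {f_min:g}")
    msg = (
        f"F = {inst.f_statistic:.2f} <= {f_min:g}: instruments may be weak; "
        "downstream estimates flagged"
    )
    warnings.warn(msg, UserWarning, stacklevel=2)
    return GateResult(False, msg, flag="weak_instruments")


def build_instruments(
    exposure: SumStatsTable,
    ld: pd.DataFrame | np.ndarray | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> SumStatsTable:
    """Significance filter then (if an LD matrix is supplied) greedy clumping."""
    selected = select_significant(exposure, p_threshold)
    if ld is not None and len(selected):
        if isinstance(ld, pd.DataFrame):
            ld = ld.loc[selected.variant_ids, selected.variant_ids]
        selected = ld_clump(selected, ld, r2_threshold)
    return selected


def instrument_set(h: HarmonizedSet, binary_exposure: bool = False) -> InstrumentSet:
    """Strength summary for a harmonized instrument set."""
    if h.eaf is None:
        raise ValueError("harmonized set lacks eaf; cannot compute R^2")
    r2 = variance_explained(h.eaf, h.beta_x)
    r2 = min(r2, 1 - 1e-12)
    k = h.n_snp
    n = h.n_x
    return InstrumentSet(
        variants=h,
        r2_explained=r2,
        f_statistic=f_statistic(r2, n, k),
        k=k,
        n=n,
        approximate_r2=binary_exposure,
    )
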