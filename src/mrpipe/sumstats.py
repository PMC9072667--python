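"""GWAS summary-statistics tables: reading, validation, writing and harmonization.

A :class:`SumStatsTable` holds per-variant association records for one trait
in one cohort (effect sizes are per copy of the effect allele: SD units for
continuous traits, log-odds for binary traits).  :func:`harmonize` aligns an
exposure table and an outcome table onto a shared effect-allele orientation so
that per-variant Wald ratios are well defined, resolving allele swaps, strand
complements and ambiguous palindromic variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SumStatsTable",
    "HarmonizedSet",
    "SumStatsFormatError",
    "HarmonizationError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]
_REQUIRED = [c for c in CANONICAL_COLUMNS if c != "eaf"]
_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs whose strand complement is the allele swap (A/T, C/G)
_PALINDROMES = ({"A", "T"}, {"C", "G"})

DEFAULT_PALINDROME_EAF_LIMIT = 0.42


class SumStatsFormatError(ValueError):
    """Raised when an input table cannot be interpreted as summary statistics."""


class HarmonizationError(ValueError):
    """Raised when exposure and outcome tables cannot be harmonized at all."""


@dataclass
class SumStatsTable:
    """Validated per-variant association records for one trait in one cohort.

    ``df`` carries the canonical columns (``variant_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``); rows that
    violated the invariants at construction time are kept in ``rejected``
    together with the reason they were excluded.
    """

    df: pd.DataFrame
    trait_label: str = ""
    cohort_label: str = ""
    binary: bool = False
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait_label: str = "",
        cohort_label: str = "",
        binary: bool = False,
        validate: bool = True,
    ) -> "SumStatsTable":
        """Build a table from a raw frame, enforcing the row invariants.

        Rows with a non-positive SE, a p-value outside (0, 1], malformed or
        identical alleles, a non-positive sample size or an allele frequency
        outside (0, 1) are moved to ``rejected`` with a reason.  A duplicated
        ``variant_id`` among the surviving rows is an error, not a rejection.
        """
        frame = frame.copy()
        missing = [c for c in _REQUIRED if c not in frame.columns]
        if missing:
            raise SumStatsFormatError(f"missing required column(s): {', '.join(missing)}")
        if "eaf" not in frame.columns:
            frame["eaf"] = np.nan
        frame = frame[CANONICAL_COLUMNS].reset_index(drop=True)
        if not validate:
            return cls(frame, trait_label, cohort_label, binary)

        frame["variant_id"] = frame["variant_id"].astype(str)
        frame["effect_allele"] = frame["effect_allele"].astype(str).str.upper()
        frame["other_allele"] = frame["other_allele"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval", "n"):
            frame[col] = pd.to_numeric(frame[col], errors="coerce")

        reason = pd.Series("", index=frame.index, dtype=object)

        def _flag(mask: pd.Series, why: str) -> None:
            mask = mask & (reason == "")
            reason[mask] = why

        ea, oa = frame["effect_allele"], frame["other_allele"]
        _flag(~ea.isin(_BASES) | ~oa.isin(_BASES), "invalid_alleles")
        _flag(ea == oa, "identical_alleles")
        _flag(~(frame["se"] > 0) | ~np.isfinite(frame["se"]), "nonpositive_se")
        _flag(~(frame["pval"] > 0) | ~(frame["pval"] <= 1), "invalid_pval")
        _flag(~np.isfinite(frame["beta"]), "invalid_beta")
        _flag(~(frame["n"] > 0), "invalid_n")
        eaf_bad = frame["eaf"].notna() & (~(frame["eaf"] > 0) | ~(frame["eaf"] < 1))
        _flag(eaf_bad, "invalid_eaf")

        bad = reason != ""
        rejected = pd.DataFrame(
            {"variant_id": frame.loc[bad, "variant_id"], "reason": reason[bad]}
        ).reset_index(drop=True)
        ok = frame[~bad].reset_index(drop=True)

        dupes = ok["variant_id"][ok["variant_id"].duplicated()]
        if len(dupes):
            raise SumStatsFormatError(
                f"duplicate variant_id(s): {', '.join(sorted(set(dupes))[:5])}"
            )
        return cls(ok, trait_label, cohort_label, binary, rejected)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "",
    cohort_label: str = "",
    binary: bool = False,
) -> SumStatsTable:
    """Read a tab-separated summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's header names (e.g.
    ``{"variant_id": "rsid", "beta": "effect"}``) so foreign dialects such as
    GWAS-SSF can be adapted without rewriting files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        rename = {src: canonical for canonical, src in column_map.items()}
        missing = [src for src in column_map.values() if src not in raw.columns]
        if missing:
            raise SumStatsFormatError(
                f"column_map refers to absent column(s): {', '.join(missing)}"
            )
        raw = raw.rename(columns=rename)
    return SumStatsTable.from_frame(
        raw, trait_label=trait_label, cohort_label=cohort_label, binary=binary
    )


def write_sumstats(table: SumStatsTable, path: str | Path) -> Path:
    """Write the canonical tab-separated dialect (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class HarmonizedSet:
    """Instrument-aligned exposure/outcome effect pairs on one orientation.

    After harmonization every retained variant is oriented to the
    exposure-increasing allele (``beta_x >= 0``) and ``beta_y`` refers to the
    same allele, so the per-variant Wald ratio ``beta_y / beta_x`` does not
    depend on which allele either input table called the effect allele.
    """

    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    n_x: int = 0
    n_y: int = 0
    eaf: np.ndarray | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)
    strand_rescued: list[str] = field(default_factory=list)
    exposure_label: str = ""
    outcome_label: str = ""
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, dtype=float)
        k = len(self.variant_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} length != number of variants")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_snp(self) -> int:
        return len(self.variant_ids)

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        index = np.asarray(index, dtype=int)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in index],
            beta_x=self.beta_x[index],
            se_x=self.se_x[index],
            beta_y=self.beta_y[index],
            se_y=self.se_y[index],
            n_x=self.n_x,
            n_y=self.n_y,
            eaf=None if self.eaf is None else self.eaf[index],
            dropped=list(self.dropped),
            strand_rescued=list(self.strand_rescued),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            cohort_label=self.cohort_label,
        )


@dataclass
class _Alignment:
    ok: bool
    sign: int = 1
    reason: str = ""
    rescued: bool = False


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMES


def _align_alleles(
    ea_x: str,
    oa_x: str,
    eaf_x: float,
    ea_y: str,
    oa_y: str,
    eaf_y: float,
    palindrome_eaf_limit: float,
) -> _Alignment:
    """Decide the sign to apply to the outcome beta so both tables refer to
    the exposure's effect allele, or a reason the variant must be dropped."""
    if _is_palindromic(ea_x, oa_x):
        if (ea_y, oa_y) == (ea_x, oa_x):
            sign = 1
        elif (ea_y, oa_y) == (oa_x, ea_x):
            sign = -1
        else:
            return _Alignment(False, reason="allele_mismatch")
        if eaf_x is None or eaf_y is None or math.isnan(eaf_x) or math.isnan(eaf_y):
            return _Alignment(False, reason="palindrome_missing_eaf")
        eaf_y_eff = eaf_y if sign == 1 else 1.0 - eaf_y
        lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
        if lo <= eaf_x <= hi or lo <= eaf_y_eff <= hi:
            return _Alignment(False, reason="ambiguous_palindrome")
        if (eaf_x < 0.5) != (eaf_y_eff < 0.5):
            return _Alignment(False, reason="ambiguous_palindrome")
        return _Alignment(True, sign=sign)

    if (ea_y, oa_y) == (ea_x, oa_x):
        return _Alignment(True, sign=1)
    if (ea_y, oa_y) == (oa_x, ea_x):
        return _Alignment(True, sign=-1)
    cea, coa = _COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)
    if (cea, coa) == (ea_x, oa_x):
        return _Alignment(True, sign=1, rescued=True)
    if (cea, coa) == (oa_x, ea_x):
        return _Alignment(True, sign=-1, rescued=True)
    return _Alignment(False, reason="allele_mismatch")


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> HarmonizedSet:
    """Align exposure and outcome records onto a common effect allele.

    For each variant shared between the two tables: matching alleles are kept
    as-is, swapped alleles flip the sign of the outcome beta, and a strand
    complement is attempted (and logged) before dropping a variant as
    irreconcilable.  Palindromic (A/T, C/G) variants are retained only when
    both allele frequencies are informative: outside
    ``[palindrome_eaf_limit, 1 - palindrome_eaf_limit]`` and on the same side
    of 0.5 once mapped onto the exposure's effect allele.  Finally every pair
    is re-oriented so the exposure beta is non-negative.
    """
    if not 0 < palindrome_eaf_limit < 0.5:
        raise ValueError("palindrome_eaf_limit must lie in (0, 0.5)")
    out_idx = outcome.df.set_index("variant_id")
    shared = [v for v in exposure.df["variant_id"] if v in out_idx.index]
    if not shared:
        raise HarmonizationError("no shared variants between exposure and outcome")
    exp_idx = exposure.df.set_index("variant_id")

    ids: list[str] = []
    bx, sx, by, sy, eafs = [], [], [], [], []
    nx, ny = [], []
    dropped: list[tuple[str, str]] = []
    rescued: list[str] = []

    for vid in shared:
        e = exp_idx.loc[vid]
        o = out_idx.loc[vid]
        al = _align_alleles(
            e["effect_allele"],
            e["other_allele"],
            float(e["eaf"]),
            o["effect_allele"],
            o["other_allele"],
            float(o["eaf"]),
            palindrome_eaf_limit,
        )
        if not al.ok:
            dropped.append((vid, al.reason))
            continue
        if al.rescued:
            rescued.append(vid)
        b_x, b_y = float(e["beta"]), al.sign * float(o["beta"])
        eaf = float(e["eaf"])
        if b_x < 0:  # orient to the exposure-increasing allele
            b_x, b_y = -b_x, -b_y
            eaf = 1.0 - eaf if not math.isnan(eaf) else eaf
        ids.append(vid)
        bx.append(b_x)
        sx.append(float(e["se"]))
        by.append(b_y)
        sy.append(float(o["se"]))
        eafs.append(eaf)
        nx.append(float(e["n"]))
        ny.append(float(o["n"]))

    return HarmonizedSet(
        variant_ids=ids,
        beta_x=np.array(bx),
        se_x=np.array(sx),
        beta_y=np.array(by),
        se_y=np.array(sy),
        n_x=int(np.median(nx)) if nx else 0,
        n_y=int(np.median(ny)) if ny else 0,
        eaf=np.array(eafs),
        dropped=dropped,
        strand_rescued=rescued,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        cohort_label=outcome.cohort_label,
    )
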