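"""Synthetic two-sample GWAS summary statistics with known causal structure.

Summary statistics are generated directly on the observation scale (no
individual-level simulation): per-SNP true effects follow a linear structural
model over traits (exposures -> mediators -> outcomes), observed estimates
are drawn from normals at the analytic standard errors

* continuous traits (SD units):  se = 1 / sqrt(2 n f (1 - f))
* binary traits (log-odds):      se = 1 / sqrt(2 n f (1 - f) phi (1 - phi))

with f the effect-allele frequency and phi the case fraction.  The generator
plants everything the pipeline is meant to detect -- a causal effect, a
pleiotropy regime (directional mean, dispersion, correlation with instrument
strength), outliers, a mediator chain with known proportion mediated, two
independent outcome cohorts, decoy null SNPs for the significance filter and
block LD for the clumping step -- and records the ground truth for recovery
tests.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical seeds give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .instruments import build_instruments
from .sumstats import HarmonizedSet, SumStatsTable, harmonize, write_sumstats

__all__ = [
    "LDSpec",
    "TraitSpec",
    "StudyDesign",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_study",
    "study_preset",
    "PRESETS",
]

_TINY = float(np.finfo(float).tiny)
# non-palindromic allele pairs only: palindrome handling is exercised by
# dedicated unit tests, not by silently losing synthetic instruments
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class LDSpec:
    """Block-diagonal LD: each lead SNP heads a block of ``block_size``
    variants in mutual r^2 = ``r2_within``; blocks are independent."""

    block_size: int = 1
    r2_within: float = 0.9


@dataclass
class TraitSpec:
    """One trait in a structural design.

    ``k``/``r2`` define the trait's own instruments (k lead SNPs scaled to a
    target explained variance); ``parents`` maps upstream trait labels to
    structural coefficients, so the trait's total per-SNP effect is its own
    gamma plus the coefficient-weighted parental effects.  Outcome-side traits
    may add per-SNP pleiotropy (mean ``mu_alpha``, sd ``sigma_alpha``,
    correlation ``rho`` with the first parent's instrument effects), planted
    outliers, and a second independent cohort.
    """

    label: str
    n: int
    binary: bool = False
    case_fraction: float | None = None
    k: int = 0
    r2: float = 0.0
    parents: dict[str, float] = field(default_factory=dict)
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    n_cohort2: int | None = None
    case_fraction2: float | None = None
    n_outliers: int = 0
    outlier_shift: float = 0.0


@dataclass
class StudyDesign:
    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    mediators: list[TraitSpec] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld: LDSpec = field(default_factory=LDSpec)
    n_decoy: int = 0

    @property
    def traits(self) -> list[TraitSpec]:
        return self.exposures + self.mediators + self.outcomes


@dataclass
class SyntheticTruth:
    """Ground truth for a single exposure -> (mediator) -> outcome study.

    Without mediation the outcome model is beta_y = theta * gamma + alpha;
    with mediation the SEM is M = delta X, Y = theta_dir X + tau M, so the
    total exposure effect is theta_dir + delta * tau (the ``theta`` field is
    overwritten to keep that identity).  ``design`` switches the generator to
    an explicit multi-trait layout (used by the study presets).
    """

    theta: float = 0.1
    k: int = 50
    n_exp: int = 200_000
    n_out1: int = 300_000
    n_out2: int = 200_000
    r2_target: float = 0.1
    binary_outcome: bool = True
    case_fraction: float = 0.2
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho: float = 0.0
    n_outliers: int = 0
    outlier_shift: float = 0.0
    mediation: bool = False
    delta: float = 0.0
    tau: float = 0.0
    theta_dir: float = 0.0
    k_med: int = 50
    r2_med: float = 0.1
    n_med: int = 150_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld: LDSpec = field(default_factory=LDSpec)
    n_decoy: int | None = None
    seed: int = 0
    design: StudyDesign | None = None

    def __post_init__(self) -> None:
        if self.mediation:
            self.theta = self.theta_dir + self.delta * self.tau

    @property
    def total_effect(self) -> float:
        return self.theta


def _scalar_design(truth: SyntheticTruth) -> StudyDesign:
    exposures = [TraitSpec("X", n=truth.n_exp, k=truth.k, r2=truth.r2_target)]
    mediators: list[TraitSpec] = []
    if truth.mediation:
        mediators = [
            TraitSpec(
                "M", n=truth.n_med, k=truth.k_med, r2=truth.r2_med,
                parents={"X": truth.delta},
            )
        ]
        parents_y = {"X": truth.theta_dir, "M": truth.tau}
    else:
        parents_y = {"X": truth.theta}
    outcomes = [
        TraitSpec(
            "Y",
            n=truth.n_out1,
            binary=truth.binary_outcome,
            case_fraction=truth.case_fraction if truth.binary_outcome else None,
            parents=parents_y,
            mu_alpha=truth.mu_alpha,
            sigma_alpha=truth.sigma_alpha,
            rho=truth.rho,
            n_cohort2=truth.n_out2,
            case_fraction2=truth.case_fraction if truth.binary_outcome else None,
            n_outliers=truth.n_outliers,
            outlier_shift=truth.outlier_shift,
        )
    ]
    n_decoy = truth.k if truth.n_decoy is None else truth.n_decoy
    return StudyDesign(
        exposures=exposures,
        mediators=mediators,
        outcomes=outcomes,
        maf_range=truth.maf_range,
        ld=truth.ld,
        n_decoy=n_decoy,
    )


@dataclass
class SyntheticStudy:
    """Generated tables plus the ground truth needed by recovery tests."""

    tables: dict[str, SumStatsTable]
    design: StudyDesign
    truth: SyntheticTruth
    variant_ids: list[str]
    maf: np.ndarray
    true_effects: dict[str, np.ndarray]
    lead_ids: dict[str, list[str]]
    outlier_ids: dict[str, list[str]]

    def table(self, label: str, cohort: int = 1) -> SumStatsTable:
        key = label if cohort == 1 else f"{label}@c2"
        return self.tables[key]

    @property
    def exposure(self) -> SumStatsTable:
        return self.table("X")

    @property
    def mediator(self) -> SumStatsTable:
        return self.table("M")

    def outcome(self, cohort: int = 1) -> SumStatsTable:
        return self.table("Y", cohort)

    def ld_frame(self) -> pd.DataFrame:
        """Block-diagonal LD r^2 matrix over the panel."""
        p = len(self.variant_ids)
        mat = np.eye(p)
        b = self.design.ld.block_size
        if b > 1:
            n_core = sum(t.k for t in self.design.traits if t.k > 0) * b
            for start in range(0, n_core, b):
                mat[start : start + b, start : start + b] = self.design.ld.r2_within
            np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=self.variant_ids, columns=self.variant_ids)

    def harmonized(
        self,
        exposure_label: str = "X",
        outcome_label: str = "Y",
        cohort: int = 1,
        p_threshold: float = 5e-8,
        clump: bool = False,
        r2_threshold: float = 0.001,
    ) -> HarmonizedSet:
        """Instrument selection then harmonization, as the pipeline would."""
        ld = self.ld_frame() if clump else None
        inst = build_instruments(
            self.table(exposure_label), ld, p_threshold, r2_threshold
        )
        return harmonize(inst, self.table(outcome_label, cohort))

    def write(self, outdir: str | Path, include_ld: bool = True) -> dict[str, Path]:
        """Write every table (and the LD matrix and truth sidecar) as text."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for key, tbl in self.tables.items():
            fname = key.replace("@", "_") + ".tsv"
            paths[key] = write_sumstats(tbl, outdir / fname)
        if include_ld:
            ld_path = outdir / "ld.tsv"
            self.ld_frame().to_csv(ld_path, sep="\t")
            paths["ld"] = ld_path
        truth_path = outdir / "truth.yaml"
        with open(truth_path, "w") as fh:
            yaml.safe_dump(_truth_as_dict(self), fh, sort_keys=True)
        paths["truth"] = truth_path
        return paths


def _truth_as_dict(study: SyntheticStudy) -> dict:
    d = {
        "seed": study.truth.seed,
        "outlier_ids": {k: list(v) for k, v in study.outlier_ids.items()},
        "traits": {},
    }
    for t in study.design.traits:
        d["traits"][t.label] = {
            "n": t.n,
            "binary": t.binary,
            "k": t.k,
            "r2": t.r2,
            "parents": dict(t.parents),
            "mu_alpha": t.mu_alpha,
            "sigma_alpha": t.sigma_alpha,
        }
    if study.truth.design is None:
        d["theta"] = study.truth.theta
        if study.truth.mediation:
            d["delta"] = study.truth.delta
            d["tau"] = study.truth.tau
            d["theta_dir"] = study.truth.theta_dir
    return d


def _se_model(n: int, maf: np.ndarray, case_fraction: float | None) -> np.ndarray:
    var = 2.0 * n * maf * (1.0 - maf)
    if case_fraction is not None:
        var = var * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(var)


def generate_study(truth: SyntheticTruth) -> SyntheticStudy:
    """Generate all summary-statistic tables for a study with known truth."""
    design = truth.design or _scalar_design(truth)
    lo, hi = design.maf_range
    if not (0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
    for t in design.traits:
        if t.binary and not (t.case_fraction and 0 < t.case_fraction < 1):
            raise ValueError(f"binary trait '{t.label}' needs a case_fraction in (0,1)")

    root = np.random.SeedSequence(truth.seed)
    ss_panel, ss_gamma, ss_alpha, ss_outlier, ss_noise = root.spawn(5)

    traits = design.traits
    labels = [t.label for t in traits]
    if len(set(labels)) != len(labels):
        raise ValueError("trait labels must be unique")
    by_label = {t.label: t for t in traits}
    for t in traits:
        for p in t.parents:
            if p not in by_label or labels.index(p) >= labels.index(t.label):
                raise ValueError(f"parent '{p}' of '{t.label}' must be defined earlier")

    b = design.ld.block_size
    lead_pos: dict[str, np.ndarray] = {}
    cursor = 0
    for t in traits:
        if t.k > 0:
            lead_pos[t.label] = cursor + b * np.arange(t.k)
            cursor += t.k * b
    n_core = cursor
    p_total = n_core + design.n_decoy
    variant_ids = [f"rs{i + 1:06d}" for i in range(p_total)]

    rng_panel = np.random.default_rng(ss_panel)
    maf = rng_panel.uniform(lo, hi, p_total)
    pair_idx = rng_panel.integers(0, len(_ALLELE_PAIRS), p_total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    # own per-SNP instrument effects, scaled to the target explained variance
    rng_gamma = np.random.default_rng(ss_gamma)
    gamma_own: dict[str, np.ndarray] = {}
    for t in traits:
        g = np.zeros(p_total)
        if t.k > 0 and t.r2 > 0:
            pos = lead_pos[t.label]
            u = rng_gamma.uniform(0.5, 1.5, t.k)
            signs = rng_gamma.choice([-1.0, 1.0], t.k)
            denom = np.sum(2.0 * maf[pos] * (1.0 - maf[pos]) * u**2)
            scale = np.sqrt(t.r2 / denom)
            lead_gamma = scale * u * signs
            for j, p0 in enumerate(pos):
                g[p0 : p0 + b] = lead_gamma[j]  # LD partners share the signal
        gamma_own[t.label] = g

    # total genetic effects through the structural model
    total: dict[str, np.ndarray] = {}
    for t in traits:
        g = gamma_own[t.label].copy()
        for parent, coef in t.parents.items():
            g += coef * total[parent]
        total[t.label] = g

    # pleiotropy on top of the structural effects (core SNPs only)
    rng_alpha = np.random.default_rng(ss_alpha)
    true_effects: dict[str, np.ndarray] = {}
    for t in traits:
        eff = total[t.label].copy()
        if t.mu_alpha != 0.0 or t.sigma_alpha != 0.0:
            z = rng_alpha.normal(size=p_total)
            alpha = np.zeros(p_total)
            core = slice(0, n_core)
            alpha[core] = t.mu_alpha + t.sigma_alpha * z[core]
            if t.parents:
                first = next(iter(t.parents))
                if t.rho != 0.0 and first in lead_pos:
                    pos = lead_pos[first]
                    g = np.abs(total[first][pos])  # instrument strength
                    gt = (g - g.mean()) / (g.std() or 1.0)
                    alpha[pos] = t.mu_alpha + t.sigma_alpha * (
                        t.rho * gt + np.sqrt(1.0 - t.rho**2) * z[pos]
                    )
                # directional pleiotropy is defined on the exposure-increasing
                # allele of the first parent; flip it onto the reported allele
                # so harmonization recovers the planted direction
                gfull = total[first]
                alpha *= np.where(gfull != 0, np.sign(gfull), 1.0)
            eff = eff + alpha
        true_effects[t.label] = eff

    # planted outliers, expressed in units of the cohort-1 outcome SE
    rng_outlier = np.random.default_rng(ss_outlier)
    outlier_ids: dict[str, list[str]] = {}
    for t in traits:
        if t.n_outliers > 0 and t.parents:
            first = next(iter(t.parents))
            pos = lead_pos[first]
            chosen = np.sort(rng_outlier.choice(pos, size=t.n_outliers, replace=False))
            se1 = _se_model(t.n, maf[chosen], t.case_fraction if t.binary else None)
            true_effects[t.label][chosen] += t.outlier_shift * se1
            outlier_ids[t.label] = [variant_ids[i] for i in chosen]

    # observed tables: one draw per trait per cohort
    rng_noise = np.random.default_rng(ss_noise)
    tables: dict[str, SumStatsTable] = {}
    from scipy import stats as _stats

    for t in traits:
        cohorts = [(1, t.n, t.case_fraction if t.binary else None)]
        if t.n_cohort2:
            cf2 = t.case_fraction2 if t.binary else None
            cohorts.append((2, t.n_cohort2, cf2))
        for c, n, cf in cohorts:
            se = _se_model(n, maf, cf)
            beta_hat = true_effects[t.label] + se * rng_noise.normal(size=p_total)
            pval = np.maximum(2.0 * _stats.norm.sf(np.abs(beta_hat / se)), _TINY)
            df = pd.DataFrame(
                {
                    "variant_id": variant_ids,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": maf,
                    "beta": beta_hat,
                    "se": se,
                    "pval": pval,
                    "n": n,
                }
            )
            key = t.label if c == 1 else f"{t.label}@c2"
            tables[key] = SumStatsTable(
                df,
                trait_label=t.label,
                cohort_label=f"cohort{c}",
                binary=t.binary,
            )

    return SyntheticStudy(
        tables=tables,
        design=design,
        truth=truth,
        variant_ids=variant_ids,
        maf=maf,
        true_effects=true_effects,
        lead_ids={k: [variant_ids[i] for i in v] for k, v in lead_pos.items()},
        outlier_ids=outlier_ids,
    )


def _paper_shape_design() -> StudyDesign:
    """Four correlated metabolic exposures, 18 outcomes in two independent
    cohorts (12 binary disease traits + 6 continuous lipid traits) and three
    lipid mediators -- the layout of a diabetes/glycemic-traits-to-
    cardiovascular-outcomes MR study at consortium scale."""
    exposures = [
        TraitSpec("fg", n=133_010, k=35, r2=0.03),
        TraitSpec("fi", n=133_010, k=18, r2=0.015),
        TraitSpec("hba1c", n=88_355, k=38, r2=0.03),
        TraitSpec(
            "t2dm", n=898_130, binary=True, case_fraction=74_124 / 898_130,
            k=286, r2=0.35, parents={"fg": 0.25, "fi": 0.15, "hba1c": 0.2},
        ),
    ]
    mediators = [
        TraitSpec("hdl", n=440_000, k=75, r2=0.08, parents={"t2dm": -0.035}),
        TraitSpec("tg", n=440_000, k=75, r2=0.08, parents={"t2dm": 0.058}),
        TraitSpec("apoa", n=440_000, k=75, r2=0.08, parents={"t2dm": -0.018}),
    ]

    def cvd(label: str, parents: dict[str, float]) -> TraitSpec:
        return TraitSpec(
            label, n=350_000, binary=True, case_fraction=0.06,
            parents=parents, sigma_alpha=0.003,
            n_cohort2=220_000, case_fraction2=0.12,
        )

    def lipid(label: str, parents: dict[str, float]) -> TraitSpec:
        return TraitSpec(
            label, n=440_000, parents=parents, sigma_alpha=0.003, n_cohort2=180_000
        )

    outcomes = [
        cvd("pad", {"t2dm": 0.168, "hdl": -0.57, "fi": 0.5, "fg": 0.3}),
        cvd("mi", {"t2dm": 0.115, "hdl": -0.26, "tg": 0.08, "apoa": -0.05,
                   "fi": 0.3, "hba1c": 0.15}),
        cvd("ihd", {"t2dm": 0.121, "fg": 0.17, "fi": 0.35, "hba1c": 0.24}),
        cvd("stroke", {"t2dm": 0.083, "fi": 0.17}),
        cvd("is", {"t2dm": 0.077, "fi": 0.2}),
        cvd("hf", {"t2dm": 0.049, "fi": 0.18}),
        cvd("ht", {"t2dm": 0.0122, "hdl": -0.022, "fi": 0.09}),
        cvd("ca", {"t2dm": 0.0044, "hdl": -0.018, "fg": 0.012, "hba1c": 0.017,
                   "fi": 0.03}),
        cvd("mchde", {"t2dm": 0.003, "fg": 0.008, "fi": 0.021}),
        cvd("cm", {"t2dm": 0.001, "fg": 0.003}),
        cvd("af", {"t2dm": 0.0}),
        cvd("ih", {}),
        lipid("hdl_c", {"t2dm": -0.035, "fi": -0.44}),
        lipid("ldl_c", {"hba1c": 0.186}),
        lipid("tg_c", {"t2dm": 0.058}),
        lipid("apoa_c", {"t2dm": -0.018, "fi": -0.24}),
        lipid("apob_c", {"hba1c": 0.054}),
        lipid("lpa_c", {"fi": -0.14}),
    ]
    return StudyDesign(
        exposures=exposures,
        mediators=mediators,
        outcomes=outcomes,
        n_decoy=300,
    )


def study_preset(name: str, seed: int = 0) -> SyntheticTruth:
    """Named ground-truth configurations covering the pipeline's regimes."""
    presets = {
        "null": dict(theta=0.0, k=50),
        "effect": dict(theta=0.1, k=100),
        "directional_pleiotropy": dict(
            theta=0.1, k=100, mu_alpha=0.05, sigma_alpha=0.02, rho=0.0
        ),
        "balanced_pleiotropy": dict(theta=0.1, k=100, mu_alpha=0.0, sigma_alpha=0.05),
        "outlier": dict(theta=0.1, k=30, n_outliers=1, outlier_shift=10.0),
        "mediation": dict(
            mediation=True, delta=0.5, tau=0.2, theta_dir=0.1, k=50, k_med=50
        ),
        "paper_shape": dict(design=_paper_shape_design()),
    }
    if name not in presets:
        raise ValueError(
            f"unknown preset '{name}'; available: {', '.join(sorted(presets))}"
        )
    return SyntheticTruth(seed=seed, **presets[name])


PRESETS = (
    "null",
    "effect",
    "directional_pleiotropy",
    "balanced_pleiotropy",
    "outlier",
    "mediation",
    "paper_shape",
)
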