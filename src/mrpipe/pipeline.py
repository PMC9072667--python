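"""Orchestration of the full study grid from a single configuration.

For every exposure x outcome x cohort cell: select instruments, harmonize,
run the estimator battery (IVW, MR-Egger, weighted median, simple and
weighted mode, MR-PRESSO), then pool per-outcome cohort estimates with
fixed-effects meta-analysis and assign Bonferroni tiers; finally run
multivariable MR across all exposures and two-step mediation for mediators
that show a significant exposure association.  The grid is fail-soft: a cell
that errors is recorded and the rest of the grid completes.
"""

from __future__ import annotations

import dataclasses
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    InsufficientInstrumentsError,
    egger,
    ivw,
    mode_estimator,
    weighted_median,
)
from .instruments import (
    f_statistic,
    ld_clump,
    select_significant,
    variance_explained,
)
from .mediation import two_step_mediation
from .meta import bonferroni_threshold, fixed_effects_meta, tier_significance
from .mvmr import assemble_mvmr, mvmr_ivw
from .presso import presso_test
from .sumstats import SumStatsTable, harmonize, read_sumstats

logger = logging.getLogger("mrpipe")

__all__ = [
    "TraitFile",
    "RunConfig",
    "GridResults",
    "run_uvmr_grid",
    "run_mvmr_and_mediation",
    "run_pipeline",
    "make_config_for_study",
]


@dataclass
class TraitFile:
    label: str
    path: str
    binary: bool = False
    cohort: str = "cohort1"


@dataclass
class RunConfig:
    """Resolved run configuration; every default is echoed back on write."""

    exposures: list[TraitFile]
    outcomes: list[TraitFile]
    seed: int
    n_outcomes_for_bonferroni: int
    mediators: list[TraitFile] = field(default_factory=list)
    ld_path: str | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    f_min: float = 10.0
    palindrome_eaf_limit: float = 0.42
    n_boot: int = 1000
    phi: float = 1.0
    het_alpha: float = 0.05
    ratio_se_order: str = "first"
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    alpha: float = 0.05
    mvmr_scope: str = "significant"  # or "all"
    mediation_exposure: str | None = None
    outdir: str | None = None
    column_map: dict | None = None

    def __post_init__(self) -> None:
        self.exposures = [t if isinstance(t, TraitFile) else TraitFile(**t) for t in self.exposures]
        self.outcomes = [t if isinstance(t, TraitFile) else TraitFile(**t) for t in self.outcomes]
        self.mediators = [t if isinstance(t, TraitFile) else TraitFile(**t) for t in self.mediators]
        if self.seed is None:
            raise ValueError("seed is mandatory")
        n_labels = len({t.label for t in self.outcomes})
        if self.n_outcomes_for_bonferroni < n_labels:
            raise ValueError(
                "n_outcomes_for_bonferroni must be >= number of distinct outcomes"
            )
        if self.mvmr_scope not in ("significant", "all"):
            raise ValueError("mvmr_scope must be 'significant' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path


@dataclass
class GridResults:
    results: pd.DataFrame
    pooled: pd.DataFrame
    drop_log: pd.DataFrame
    failures: pd.DataFrame
    instruments: pd.DataFrame
    tables: dict = field(default_factory=dict, repr=False)
    ld: pd.DataFrame | None = field(default=None, repr=False)


def _cell_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def _estimate_row(est, exposure, outcome, cohort, extra=None) -> dict:
    row = {"exposure": exposure, "outcome": outcome, "cohort": cohort}
    row.update(est.to_dict())
    if extra:
        row.update(extra)
    return row


def _run_cell(inst_table, outcome_table, cfg: RunConfig, seed: int):
    """All estimators for one exposure x outcome x cohort cell."""
    rows, drops, fails = [], [], []
    exposure = inst_table.trait_label
    outcome, cohort = outcome_table.trait_label, outcome_table.cohort_label
    cell = {"exposure": exposure, "outcome": outcome, "cohort": cohort}

    h = harmonize(inst_table, outcome_table, cfg.palindrome_eaf_limit)
    for vid, reason in h.dropped:
        drops.append({**cell, "variant_id": vid, "stage": "harmonize", "reason": reason})
    if h.n_snp == 0:
        fails.append({**cell, "method": "all", "reason": "no_instruments"})
        return rows, drops, fails

    def _try(name, fn):
        try:
            rows.append(_estimate_row(fn(), exposure, outcome, cohort))
        except (InsufficientInstrumentsError, ValueError, ZeroDivisionError) as exc:
            fails.append({**cell, "method": name, "reason": str(exc)})

    _try("ivw", lambda: ivw(h, cfg.het_alpha))
    _try("egger", lambda: egger(h, cfg.het_alpha))
    _try("weighted_median", lambda: weighted_median(h, cfg.n_boot, seed))
    _try("simple_mode", lambda: mode_estimator(h, False, cfg.phi, cfg.n_boot, seed + 1))
    _try("weighted_mode", lambda: mode_estimator(h, True, cfg.phi, cfg.n_boot, seed + 2))

    try:
        rep = presso_test(h, cfg.presso_n_sim, cfg.presso_alpha, seed + 3)
        if rep.applicable:
            est = rep.beta_corrected if rep.beta_corrected is not None else rep.beta_raw
            extra = {
                "presso_global_pval": rep.global_pval,
                "presso_outliers": ";".join(rep.outlier_ids),
                "presso_distortion_pval": rep.distortion_pval,
            }
            row = _estimate_row(est, exposure, outcome, cohort, extra)
            row["method"] = "presso"
            rows.append(row)
            for vid in rep.outlier_ids:
                drops.append(
                    {**cell, "variant_id": vid, "stage": "presso", "reason": "outlier"}
                )
        else:
            fails.append({**cell, "method": "presso", "reason": rep.reason})
    except ValueError as exc:
        fails.append({**cell, "method": "presso", "reason": str(exc)})
    return rows, drops, fails


def _load_tables(cfg: RunConfig):
    tables = {}
    drops = []
    for kind, files in (
        ("exposure", cfg.exposures),
        ("outcome", cfg.outcomes),
        ("mediator", cfg.mediators),
    ):
        for tf in files:
            tbl = read_sumstats(
                tf.path, cfg.column_map, trait_label=tf.label,
                cohort_label=tf.cohort, binary=tf.binary,
            )
            for _, r in tbl.rejected.iterrows():
                drops.append(
                    {
                        "exposure": "", "outcome": "", "cohort": tf.cohort,
                        "variant_id": r["variant_id"], "stage": "read",
                        "reason": r["reason"],
                    }
                )
            tables[(kind, tf.label, tf.cohort)] = tbl
    return tables, drops


def run_uvmr_grid(cfg: RunConfig, threads: int = 1) -> GridResults:
    """Run the univariable battery over every exposure x outcome x cohort."""
    tables, drops = _load_tables(cfg)
    ld = None
    if cfg.ld_path:
        ld = pd.read_csv(cfg.ld_path, sep="\t", index_col=0)

    inst_rows = []
    instruments: dict[str, SumStatsTable] = {}
    for tf in cfg.exposures:
        tbl = tables[("exposure", tf.label, tf.cohort)]
        sig = select_significant(tbl, cfg.p_threshold)
        kept = set(sig.variant_ids)
        for vid in tbl.variant_ids:
            if vid not in kept:
                drops.append(
                    {
                        "exposure": tf.label, "outcome": "", "cohort": "",
                        "variant_id": vid, "stage": "selection",
                        "reason": "above_p_threshold",
                    }
                )
        if ld is not None and len(sig):
            clumped = ld_clump(sig, ld.loc[sig.variant_ids, sig.variant_ids], cfg.r2_threshold)
            kept2 = set(clumped.variant_ids)
            for vid in sig.variant_ids:
                if vid not in kept2:
                    drops.append(
                        {
                            "exposure": tf.label, "outcome": "", "cohort": "",
                            "variant_id": vid, "stage": "clump", "reason": "in_ld",
                        }
                    )
            sig = clumped
        instruments[tf.label] = sig
        k = len(sig)
        if k and sig.df["eaf"].notna().all():
            r2 = min(variance_explained(sig.df["eaf"], sig.df["beta"]), 1 - 1e-12)
            n = int(sig.df["n"].median())
            f = f_statistic(r2, n, k) if n > k + 1 else float("nan")
        else:
            r2, n, f = float("nan"), 0, float("nan")
        weak = not (f > cfg.f_min)
        if weak:
            logger.warning("exposure %s: F = %.2f <= %g", tf.label, f, cfg.f_min)
        inst_rows.append(
            {
                "exposure": tf.label, "k": k, "r2_explained": r2, "n": n,
                "f_statistic": f, "weak_instruments": weak,
                "approximate_r2": tf.binary,
            }
        )

    cells = []
    for tf_e in cfg.exposures:
        for tf_o in cfg.outcomes:
            cells.append((tf_e, tf_o))
    cells.sort(key=lambda c: (c[0].label, c[1].label, c[1].cohort))

    results_rows, failures = [], []

    def _work(args):
        idx, (tf_e, tf_o) = args
        inst = instruments[tf_e.label]
        if len(inst) == 0:
            return (
                [],
                [],
                [
                    {
                        "exposure": tf_e.label, "outcome": tf_o.label,
                        "cohort": tf_o.cohort, "method": "all",
                        "reason": "no_instruments",
                    }
                ],
            )
        out_tbl = tables[("outcome", tf_o.label, tf_o.cohort)]
        try:
            return _run_cell(inst, out_tbl, cfg, _cell_seed(cfg.seed, idx))
        except Exception as exc:  # fail-soft: the grid continues
            logger.error("cell %s/%s/%s failed: %s", tf_e.label, tf_o.label, tf_o.cohort, exc)
            return (
                [],
                [],
                [
                    {
                        "exposure": tf_e.label, "outcome": tf_o.label,
                        "cohort": tf_o.cohort, "method": "all", "reason": str(exc),
                    }
                ],
            )

    work = list(enumerate(cells))
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            outputs = list(pool.map(_work, work))
    else:
        outputs = [_work(w) for w in work]
    weak_by_exp = {r["exposure"]: r["weak_instruments"] for r in inst_rows}
    for rows, d, f in outputs:
        for row in rows:
            if weak_by_exp.get(row["exposure"]):
                row["flags"] = ";".join(filter(None, [row.get("flags", ""), "weak_instruments"]))
        results_rows.extend(rows)
        drops.extend(d)
        failures.extend(f)

    results = pd.DataFrame(results_rows)
    if len(results):
        results = results.sort_values(["exposure", "outcome", "cohort", "method"]).reset_index(drop=True)

    pooled_rows = []
    if len(results):
        ivw_rows = results[results["method"] == "ivw"]
        for (exp_label, out_label), grp in ivw_rows.groupby(["exposure", "outcome"], sort=True):
            est = [(c, b, s) for c, b, s in zip(grp["cohort"], grp["beta"], grp["se"])]
            if len(est) == 1:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    meta = fixed_effects_meta(est)
            else:
                meta = fixed_effects_meta(est)
            pooled_rows.append(
                {
                    "exposure": exp_label,
                    "outcome": out_label,
                    "n_cohorts": len(est),
                    "pooled_beta": meta.pooled_beta,
                    "pooled_se": meta.pooled_se,
                    "pooled_pval": meta.pooled_pval,
                    "ci_low": meta.ci_low,
                    "ci_high": meta.ci_high,
                    "odds_ratio": meta.odds_ratio,
                    "or_low": meta.or_ci[0],
                    "or_high": meta.or_ci[1],
                    "het_q": meta.het_q,
                    "het_pval": meta.het_pval,
                    "flags": ";".join(meta.flags),
                }
            )
    pooled = pd.DataFrame(pooled_rows)
    if len(pooled):
        tiers = tier_significance(
            pooled["pooled_pval"], cfg.n_outcomes_for_bonferroni, cfg.alpha
        )
        pooled["tier"] = tiers
        pooled = pooled.sort_values(["exposure", "outcome"]).reset_index(drop=True)

    return GridResults(
        results=results,
        pooled=pooled,
        drop_log=pd.DataFrame(drops),
        failures=pd.DataFrame(failures),
        instruments=pd.DataFrame(inst_rows),
        tables=tables,
        ld=ld,
    )


def run_mvmr_and_mediation(cfg: RunConfig, grid: GridResults) -> dict[str, pd.DataFrame]:
    """Multivariable MR on selected outcomes plus two-step mediation.

    MVMR runs for outcomes whose pooled univariable estimate is Bonferroni
    significant for at least one exposure (``mvmr_scope='all'`` overrides).
    Mediation runs for mediators whose exposure association is itself
    Bonferroni significant, on the outcomes significant for that exposure.
    """
    tables = grid.tables
    exposure_tables = [tables[("exposure", t.label, t.cohort)] for t in cfg.exposures]
    thr = bonferroni_threshold(cfg.alpha, cfg.n_outcomes_for_bonferroni)

    if len(grid.pooled):
        sig = grid.pooled[grid.pooled["tier"] == "significant"]
        sig_outcomes = set(sig["outcome"])
        sig_by_exposure = {
            e: set(g["outcome"]) for e, g in sig.groupby("exposure")
        }
    else:
        sig_outcomes, sig_by_exposure = set(), {}
    outcome_labels = sorted({t.label for t in cfg.outcomes})
    if cfg.mvmr_scope == "all":
        mvmr_outcomes = outcome_labels
    else:
        mvmr_outcomes = sorted(sig_outcomes)

    mvmr_rows, fails = [], []
    if len(cfg.exposures) >= 2:
        for out_label in mvmr_outcomes:
            for tf_o in [t for t in cfg.outcomes if t.label == out_label]:
                out_tbl = tables[("outcome", tf_o.label, tf_o.cohort)]
                try:
                    inp = assemble_mvmr(
                        exposure_tables, out_tbl, grid.ld,
                        cfg.p_threshold, cfg.r2_threshold, cfg.palindrome_eaf_limit,
                    )
                    for est in mvmr_ivw(inp, cfg.het_alpha):
                        row = _estimate_row(est, est.exposure_label, out_label, tf_o.cohort)
                        mvmr_rows.append(row)
                except (ValueError, InsufficientInstrumentsError) as exc:
                    fails.append(
                        {"outcome": out_label, "cohort": tf_o.cohort, "reason": str(exc)}
                    )

    med_rows = []
    med_exposure = cfg.mediation_exposure or (cfg.exposures[0].label if cfg.exposures else None)
    if cfg.mediators and med_exposure:
        exp_tbl = next(
            tables[("exposure", t.label, t.cohort)]
            for t in cfg.exposures
            if t.label == med_exposure
        )
        med_outcomes = sorted(sig_by_exposure.get(med_exposure, set()))
        if cfg.mvmr_scope == "all":
            med_outcomes = outcome_labels
        for tf_m in cfg.mediators:
            med_tbl = tables[("mediator", tf_m.label, tf_m.cohort)]
            # mediator gate: the exposure must causally shift the mediator
            try:
                inst = select_significant(exp_tbl, cfg.p_threshold)
                gate = ivw(harmonize(inst, med_tbl, cfg.palindrome_eaf_limit), cfg.het_alpha)
            except Exception as exc:
                fails.append({"outcome": tf_m.label, "cohort": tf_m.cohort, "reason": str(exc)})
                continue
            if gate.pval >= thr:
                logger.info(
                    "mediator %s skipped: exposure association p = %.3g >= %.3g",
                    tf_m.label, gate.pval, thr,
                )
                med_rows.append(
                    {
                        "exposure": med_exposure, "mediator": tf_m.label,
                        "outcome": "", "cohort": "",
                        "flags": "mediator_not_associated", "skipped": True,
                    }
                )
                continue
            for out_label in med_outcomes:
                for tf_o in [t for t in cfg.outcomes if t.label == out_label]:
                    out_tbl = tables[("outcome", tf_o.label, tf_o.cohort)]
                    try:
                        res = two_step_mediation(
                            exp_tbl, med_tbl, out_tbl, grid.ld,
                            cfg.p_threshold, cfg.r2_threshold,
                            cfg.het_alpha, cfg.palindrome_eaf_limit,
                        )
                        row = res.to_dict()
                        row["cohort"] = tf_o.cohort
                        row["skipped"] = False
                        med_rows.append(row)
                    except (ValueError, InsufficientInstrumentsError) as exc:
                        fails.append(
                            {"outcome": out_label, "cohort": tf_o.cohort, "reason": str(exc)}
                        )

    mvmr_df = pd.DataFrame(mvmr_rows)
    if len(mvmr_df):
        mvmr_df = mvmr_df.sort_values(["outcome", "cohort", "exposure"]).reset_index(drop=True)
    med_df = pd.DataFrame(med_rows)
    if len(med_df) and "mediator" in med_df:
        med_df = med_df.sort_values(["mediator", "outcome", "cohort"]).reset_index(drop=True)
    return {"mvmr": mvmr_df, "mediation": med_df, "failures": pd.DataFrame(fails)}


def run_pipeline(cfg: RunConfig, threads: int = 1) -> dict[str, pd.DataFrame]:
    """Full study: UVMR grid, pooling/tiering, MVMR, mediation; write outputs."""
    logger.info("running UVMR grid: %d exposures x %d outcome tables",
                len(cfg.exposures), len(cfg.outcomes))
    grid = run_uvmr_grid(cfg, threads=threads)
    extra = run_mvmr_and_mediation(cfg, grid)
    out = {
        "results": grid.results,
        "pooled": grid.pooled,
        "drop_log": grid.drop_log,
        "failures": pd.concat(
            [grid.failures, extra["failures"]], ignore_index=True
        ) if len(grid.failures) or len(extra["failures"]) else pd.DataFrame(),
        "instruments": grid.instruments,
        "mvmr": extra["mvmr"],
        "mediation": extra["mediation"],
    }
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        cfg.to_yaml(outdir / "resolved_config.yaml")
        logger.info("wrote results to %s", outdir)
    return out


def make_config_for_study(
    study, outdir: str | Path, include_ld: bool = False, n_boot: int = 200, **overrides
) -> RunConfig:
    """Write a synthetic study to disk and build a matching run config.

    ``n_boot`` defaults to a desk-scale 200 bootstrap replicates for the
    grid's median/mode standard errors (the estimator-level default is 1000).
    """
    outdir = Path(outdir)
    paths = study.write(outdir / "data", include_ld=include_ld)
    design = study.design

    def tf(spec, cohort):
        key = spec.label if cohort == 1 else f"{spec.label}@c2"
        return TraitFile(
            label=spec.label,
            path=str(paths[key]),
            binary=spec.binary,
            cohort=f"cohort{cohort}",
        )

    exposures = [tf(t, 1) for t in design.exposures]
    mediators = [tf(t, 1) for t in design.mediators]
    outcomes = []
    for t in design.outcomes:
        outcomes.append(tf(t, 1))
        if t.n_cohort2:
            outcomes.append(tf(t, 2))
    kwargs = dict(
        exposures=exposures,
        outcomes=outcomes,
        mediators=mediators,
        seed=study.truth.seed,
        n_outcomes_for_bonferroni=len(design.outcomes),
        ld_path=str(paths["ld"]) if include_ld and "ld" in paths else None,
        n_boot=n_boot,
        outdir=str(outdir / "results"),
        mediation_exposure=design.exposures[-1].label if design.mediators else None,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
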