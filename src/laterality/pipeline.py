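"""End-to-end analysis pipeline.

``run_full_report`` chains the stages in the order of the original
analysis: inclusion filter -> individual scoring -> group classification
tests -> genotype x behavior mixed models on LI and |LI| -> temporal
consistency (Spearman correlations and per-behavior mixed models), and
collects every stage's output plus a log of exclusions, gate decisions and
applied transforms into one bundle that can be written to disk as a CSV
set and a JSON summary.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .consistency import consistency_report
from .group_tests import EmptyTableError, group_test_report, population_bias_test
from .mixed_models import (
    ConvergenceError,
    fit_lmm,
    genotype_behavior_spec,
    residual_diagnostics,
    session_consistency_spec,
    tukey_posthoc,
)
from .scoring import BEHAVIORS, Z_THRESHOLD, filter_min_counts, score_table

__all__ = ["RunConfig", "ReportBundle", "run_full_report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one full pipeline run."""

    alpha: float = 0.05
    z_threshold: float = Z_THRESHOLD
    min_counts: int = 10
    transform_li: str = "identity"
    transform_abs_li: str = "identity"
    run_group_tests: bool = True
    run_lmm: bool = True
    run_consistency: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.z_threshold <= 0 or self.min_counts < 1:
            raise ValueError("z_threshold must be > 0 and min_counts >= 1")

    def to_dict(self) -> dict[str, Any]:
        return {
            "alpha": self.alpha, "z_threshold": self.z_threshold,
            "min_counts": self.min_counts, "transform_li": self.transform_li,
            "transform_abs_li": self.transform_abs_li,
            "run_group_tests": self.run_group_tests, "run_lmm": self.run_lmm,
            "run_consistency": self.run_consistency, "seed": self.seed,
        }


@dataclass
class ReportBundle:
    config: RunConfig
    scored_session1: pd.DataFrame
    exclusions_session1: pd.DataFrame
    group_omnibus: pd.DataFrame | None = None
    group_posthocs: pd.DataFrame | None = None
    population_bias: pd.DataFrame | None = None
    lmm_anova: pd.DataFrame | None = None          # stacked tables, 'response' column
    lmm_posthocs: pd.DataFrame | None = None
    lmm_diagnostics: pd.DataFrame | None = None
    scored_pairs: pd.DataFrame | None = None
    exclusions_pairs: pd.DataFrame | None = None
    spearman: pd.DataFrame | None = None
    consistency_anova: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, Any]:
        """JSON-serializable digest assembled from the stage tables."""

        def records(df):
            if df is None:
                return None
            return json.loads(df.to_json(orient="records"))

        return {
            "package_version": __version__,
            "python": platform.python_version(),
            "config": self.config.to_dict(),
            "n_scored_session1": int(len(self.scored_session1)),
            "n_excluded_session1": int(len(self.exclusions_session1)),
            "group_omnibus": records(self.group_omnibus),
            "group_posthocs": records(self.group_posthocs),
            "population_bias": records(self.population_bias),
            "lmm_anova": records(self.lmm_anova),
            "lmm_posthocs": records(self.lmm_posthocs),
            "lmm_diagnostics": records(self.lmm_diagnostics),
            "spearman": records(self.spearman),
            "consistency_anova": records(self.consistency_anova),
            "log": self.log,
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "scored_session1.csv": self.scored_session1,
            "exclusions_session1.csv": self.exclusions_session1,
            "group_omnibus.csv": self.group_omnibus,
            "group_posthocs.csv": self.group_posthocs,
            "population_bias.csv": self.population_bias,
            "lmm_anova.csv": self.lmm_anova,
            "lmm_posthocs.csv": self.lmm_posthocs,
            "lmm_diagnostics.csv": self.lmm_diagnostics,
            "scored_pairs.csv": self.scored_pairs,
            "exclusions_pairs.csv": self.exclusions_pairs,
            "spearman_consistency.csv": self.spearman,
            "consistency_anova.csv": self.consistency_anova,
        }
        for name, df in tables.items():
            if df is not None:
                df.to_csv(outdir / name, index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        with open(outdir / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        return outdir


def _lmm_stage(scored1: pd.DataFrame, config: RunConfig, log: list[str]):
    anovas, posthocs, diags = [], [], []
    for response, transform in (("li", config.transform_li),
                                ("abs_li", config.transform_abs_li)):
        spec = genotype_behavior_spec(response, transform=transform)
        try:
            fit = fit_lmm(scored1, spec)
        except ConvergenceError as exc:
            raise StageError(f"lmm[{response}]: {exc}") from exc
        log.append(f"lmm[{response}]: transform={transform}, "
                   f"vcomp={ {k: round(v, 6) for k, v in fit.vcomp.items()} }, "
                   f"scale={fit.scale:.6f}")
        log.extend(f"lmm[{response}]: {w}" for w in fit.warnings)
        tab = fit.anova.copy()
        tab.insert(0, "response", response)
        anovas.append(tab)
        diag = residual_diagnostics(fit)
        diags.append({"response": response, "transform": transform,
                      "shapiro_stat": diag.shapiro_stat, "shapiro_p": diag.shapiro_p,
                      "variance_ratio": diag.variance_ratio,
                      "heteroscedastic": diag.heteroscedastic,
                      "recommend_transform": diag.recommend_transform})
        if diag.recommend_transform and transform == "identity":
            log.append(f"lmm[{response}]: residual normality rejected "
                       f"(Shapiro-Wilk p={diag.shapiro_p:.3g}); "
                       "consider a registered transform")
        for factor in ("genotype", "behavior"):
            term = f"C({factor}, Sum)"
            row = tab[tab["term"] == term]
            if len(row) and float(row["p"].iloc[0]) <= config.alpha:
                ph = tukey_posthoc(fit, factor)
                ph.insert(0, "factor", factor)
                ph.insert(0, "response", response)
                posthocs.append(ph)
                log.append(f"lmm[{response}]: omnibus {factor} significant "
                           f"(p={float(row['p'].iloc[0]):.4g}); Tukey post-hocs run")
            else:
                log.append(f"lmm[{response}]: omnibus {factor} not significant; "
                           "post-hocs gated off")
    anova = pd.concat(anovas, ignore_index=True)
    ph = pd.concat(posthocs, ignore_index=True) if posthocs else pd.DataFrame(
        columns=["response", "factor", "contrast", "estimate", "se", "df", "t", "p_tukey"]
    )
    return anova, ph, pd.DataFrame(diags)


def _consistency_lmm_stage(pairs_scored: pd.DataFrame, config: RunConfig, log: list[str]):
    rows = []
    from .consistency import paired_sessions

    for response, transform in (("li", config.transform_li),
                                ("abs_li", config.transform_abs_li)):
        for behavior in BEHAVIORS:
            wide = paired_sessions(pairs_scored, behavior, response)
            if len(wide) < 8 or wide["genotype"].nunique() < 2:
                log.append(f"consistency-lmm[{response}/{behavior}]: "
                           f"only {len(wide)} pairs; model skipped")
                continue
            spec = session_consistency_spec("s2", "s1", transform=transform)
            try:
                fit = fit_lmm(wide, spec)
            except (ConvergenceError, ValueError) as exc:
                log.append(f"consistency-lmm[{response}/{behavior}]: failed ({exc})")
                continue
            log.extend(f"consistency-lmm[{response}/{behavior}]: {w}" for w in fit.warnings)
            tab = fit.anova.copy()
            tab.insert(0, "behavior", behavior)
            tab.insert(0, "measure", response)
            rows.append(tab)
    if not rows:
        return pd.DataFrame(
            columns=["measure", "behavior", "term", "F", "df_num", "df_den", "p", "eta_p2"]
        )
    return pd.concat(rows, ignore_index=True)


def run_full_report(counts: pd.DataFrame, config: RunConfig | None = None) -> ReportBundle:
    """Run every analysis stage on a tidy count table.

    ``counts`` must contain session-1 rows and, for the consistency stage,
    session-2 rows; validation is assumed done (use :func:`laterality.io.
    read_counts_csv` for files).  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    config = config or RunConfig()
    log: list[str] = [
        f"laterality {__version__} full report",
        f"config: {config.to_dict()}",
        f"input: {len(counts)} records, "
        f"{counts['animal_id'].nunique()} animals",
    ]

    s1 = counts[counts["session"] == 1]
    kept1, dropped1 = filter_min_counts(s1, min_n=config.min_counts)
    for rec in dropped1.itertuples():
        log.append(f"excluded (session 1): {rec.animal_id}/{rec.behavior} "
                   f"N={rec.n_right + rec.n_left} ({rec.reason})")
    try:
        scored1 = score_table(kept1, threshold=config.z_threshold)
    except Exception as exc:
        raise StageError(f"scoring: {exc}") from exc

    bundle = ReportBundle(config=config, scored_session1=scored1,
                          exclusions_session1=dropped1, log=log)

    if config.run_group_tests:
        try:
            omnibus, posthocs = group_test_report(scored1, alpha=config.alpha)
        except Exception as exc:
            raise StageError(f"group-tests: {exc}") from exc
        bundle.group_omnibus, bundle.group_posthocs = omnibus, posthocs
        log.append(f"group-tests: {len(omnibus)} behavior x genotype tables, "
                   f"{len(posthocs)} post-hoc rows")
        pop_rows = []
        for behavior in BEHAVIORS:
            if behavior not in set(scored1["behavior"].astype(str)):
                log.append(f"population-bias[{behavior}]: no scored records")
                continue
            try:
                res = population_bias_test(scored1, behavior)
            except EmptyTableError:
                log.append(f"population-bias[{behavior}]: no lateralized animals")
                continue
            pop_rows.append({"behavior": behavior, "n_left": res.n_left,
                             "n_right": res.n_right, "p": res.p,
                             "population_bias": res.biased})
        bundle.population_bias = pd.DataFrame(pop_rows)

    if config.run_lmm:
        try:
            bundle.lmm_anova, bundle.lmm_posthocs, bundle.lmm_diagnostics = _lmm_stage(
                scored1, config, log
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"lmm: {exc}") from exc

    if config.run_consistency and (counts["session"] == 2).any():
        kept_b, dropped_b = filter_min_counts(
            counts, min_n=config.min_counts, require_both_sessions=True
        )
        for rec in dropped_b.itertuples():
            log.append(f"excluded (paired): {rec.animal_id}/{rec.behavior} "
                       f"session {rec.session} ({rec.reason})")
        scored_b = score_table(kept_b, threshold=config.z_threshold)
        bundle.scored_pairs, bundle.exclusions_pairs = scored_b, dropped_b
        try:
            bundle.spearman = consistency_report(scored_b)
            bundle.consistency_anova = _consistency_lmm_stage(scored_b, config, log)
        except Exception as exc:
            raise StageError(f"consistency: {exc}") from exc
        log.append("consistency: Spearman and per-behavior models complete")

    return bundle
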