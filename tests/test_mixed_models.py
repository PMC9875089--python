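"""REML engine, Satterthwaite F-tests, Tukey HSD, diagnostics, transforms."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laterality.mixed_models import (
    LmmSpec,
    estimated_marginal_means,
    eta_p2_from_f,
    fit_lmm,
    genotype_behavior_spec,
    residual_diagnostics,
    session_consistency_spec,
    tukey_posthoc,
)
from laterality.scoring import filter_min_counts, score_table
from laterality.simulate import default_paper_like_config, simulate_cohort
from laterality.transforms import TRANSFORMS, apply_transform

GENOTYPES = ("WT", "HET", "KO")
BEHAVIORS = ("GC", "FRT", "SG", "BC")


def balanced_frame(rng, n_per_cell=6, cell_means=None, resid_sd=1.0,
                   batch_sd=0.0, animal_sd=0.0):
    """Balanced genotype x behavior layout with one row per animal x behavior."""
    rows = []
    for g in GENOTYPES:
        for i in range(n_per_cell):
            aid = f"{g}{i}"
            batch = 1 + (i % 2)
            a_eff = rng.normal(0, animal_sd) if animal_sd else 0.0
            for b in BEHAVIORS:
                mu = cell_means[(g, b)] if cell_means else 0.0
                eps = rng.normal(0, resid_sd) if resid_sd else 0.0
                b_eff = {1: -batch_sd, 2: batch_sd}[batch] if batch_sd else 0.0
                rows.append((aid, g, b, 1, batch, mu + a_eff + b_eff + eps))
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "behavior",
                                       "session", "batch", "li"])


def anova_oracle_f(df):
    """Brute-force balanced two-way ANOVA F statistics (genotype, behavior,
    interaction) from sums of squares of cell means."""
    y = df["li"].to_numpy()
    gm = y.mean()
    a = df.groupby("genotype")["li"].mean()
    b = df.groupby("behavior")["li"].mean()
    cell = df.groupby(["genotype", "behavior"])["li"].mean()
    k = len(df) // (len(a) * len(b))
    ssa = len(b) * k * ((a - gm) ** 2).sum()
    ssb = len(a) * k * ((b - gm) ** 2).sum()
    ssab = k * sum((cell[g, h] - a[g] - b[h] + gm) ** 2 for g, h in cell.index)
    merged = df.merge(cell.rename("m"), left_on=["genotype", "behavior"],
                      right_index=True)
    sse = ((merged["li"] - merged["m"]) ** 2).sum()
    dfe = len(df) - len(a) * len(b)
    mse = sse / dfe
    return np.array([(ssa / 2) / mse, (ssb / 3) / mse, (ssab / 6) / mse]), dfe


def test_eta_p2_from_f_examples():
    assert eta_p2_from_f(0.0, 3, 150) == 0.0
    assert eta_p2_from_f(7.133, 3, 150) == pytest.approx(0.1248, abs=5e-5)
    assert eta_p2_from_f(1e9, 3, 150) == pytest.approx(1.0, abs=1e-6)
    # monotone increasing in F
    fs = [eta_p2_from_f(f, 2, 40) for f in (0.5, 1, 2, 4, 8)]
    assert all(x < y for x, y in zip(fs, fs[1:]))


def test_noiseless_fit_recovers_generating_cell_means_exactly():
    rng = np.random.default_rng(0)
    means = {(g, b): 0.1 * i - 0.3 * j
             for i, g in enumerate(GENOTYPES) for j, b in enumerate(BEHAVIORS)}
    df = balanced_frame(rng, cell_means=means, resid_sd=0.0)
    fit = fit_lmm(df, genotype_behavior_spec("li"))
    import patsy
    grid = pd.DataFrame([(g, b) for g in GENOTYPES for b in BEHAVIORS],
                        columns=["genotype", "behavior"])
    (mat,) = patsy.build_design_matrices([fit._design_info], grid)
    pred = np.asarray(mat) @ fit.params.to_numpy()
    for p, (g, b) in zip(pred, grid.itertuples(index=False)):
        assert p == pytest.approx(means[(g, b)], abs=1e-12)


def test_ols_limit_matches_anova_oracle():
    """With no random terms the Type III F equals the balanced two-way
    fixed-effects decomposition, and the denominator df is exactly n - p."""
    rng = np.random.default_rng(3)
    df = balanced_frame(rng, resid_sd=1.0)
    spec = LmmSpec(response="li", fixed="C(genotype, Sum) * C(behavior, Sum)",
                   random=(), factors=("genotype", "behavior"))
    fit = fit_lmm(df, spec)
    oracle, dfe = anova_oracle_f(df)
    assert np.abs(fit.anova["F"].to_numpy() - oracle).max() < 1e-6
    assert np.abs(fit.anova["df_den"].to_numpy() - dfe).max() < 1e-6


def test_boundary_fit_matches_anova_oracle():
    """Random-intercept variances generated (and estimated) at zero: the
    mixed-model F collapses to the fixed-effects ANOVA F."""
    rng = np.random.default_rng(4)  # REML lands on the double boundary here
    df = balanced_frame(rng, resid_sd=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lmm(df, genotype_behavior_spec("li"))
    assert all(v == 0.0 for v in fit.vcomp.values())
    assert any("singular" in w for w in fit.warnings)
    oracle, _ = anova_oracle_f(df)
    assert np.abs(fit.anova["F"].to_numpy() - oracle).max() < 1e-6


def test_estimates_match_statsmodels_mixedlm():
    """Independent estimation route: statsmodels MixedLM with crossed
    variance components reaches the same REML optimum."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(7)
    df = balanced_frame(rng, n_per_cell=8, resid_sd=0.6, batch_sd=0.4,
                        animal_sd=0.5)
    fit = fit_lmm(df, genotype_behavior_spec("li"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            "li ~ C(genotype, Sum) * C(behavior, Sum)", df,
            groups=np.ones(len(df)),
            vc_formula={"batch": "0 + C(batch)", "animal_id": "0 + C(animal_id)"},
        )
        mf = md.fit(reml=True, method=["powell"], maxiter=2000)
    assert np.abs(mf.fe_params.to_numpy() - fit.params.to_numpy()).max() < 1e-4
    assert mf.scale == pytest.approx(fit.scale, rel=1e-3)
    sm_vc = dict(zip(md.exog_vc.names, mf.vcomp))
    for name, v in fit.vcomp.items():
        assert sm_vc[name] == pytest.approx(v, rel=2e-2, abs=1e-4)


def test_anova_table_matches_lmerTest_satterthwaite(tmp_path, scored_session1):
    """Gold-standard cross-check: R's lmerTest (Satterthwaite, Type III,
    sum contrasts) reproduces our F statistics, denominator dfs and
    p-values on a shared dataset."""
    import json
    import shutil
    import subprocess

    assert shutil.which("Rscript"), "Rscript expected on PATH"
    data_csv = tmp_path / "scored.csv"
    scored_session1.to_csv(data_csv, index=False)
    out_json = tmp_path / "anova.json"
    rcode = f"""
    suppressMessages(library(lmerTest))
    d <- read.csv("{data_csv}")
    d$genotype <- factor(d$genotype, levels=c("WT","HET","KO"))
    d$behavior <- factor(d$behavior, levels=c("GC","FRT","SG","BC"))
    options(contrasts=c("contr.sum","contr.poly"))
    m <- lmer(li ~ genotype*behavior + (1|batch) + (1|animal_id), data=d, REML=TRUE)
    a <- anova(m, type=3, ddf="Satterthwaite")
    out <- list(F=a$"F value", ddf=a$DenDF, p=a$"Pr(>F)")
    writeLines(jsonlite::toJSON(out, digits=10), "{out_json}")
    """
    script = tmp_path / "check.R"
    script.write_text(rcode)
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    with open(out_json) as fh:
        ref = json.load(fh)
    fit = fit_lmm(scored_session1, genotype_behavior_spec("li"))
    # rows in both tables: genotype, behavior, interaction
    for i, row in enumerate(fit.anova.itertuples()):
        assert row.F == pytest.approx(ref["F"][i], rel=1e-4)
        assert row.df_den == pytest.approx(ref["ddf"][i], rel=5e-3)
        assert row.p == pytest.approx(ref["p"][i], abs=1e-4)


def test_fixed_effects_converge_to_ols_when_variances_vanish():
    rng = np.random.default_rng(4)  # REML optimum at the boundary for this draw
    df = balanced_frame(rng, resid_sd=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lmm(df, genotype_behavior_spec("li"))
    assert all(v == 0 for v in fit.vcomp.values())
    import patsy
    _, X = patsy.dmatrices("li ~ C(genotype, Sum) * C(behavior, Sum)", df)
    beta_ols = np.linalg.lstsq(np.asarray(X), df["li"].to_numpy(), rcond=None)[0]
    assert np.abs(fit.params.to_numpy() - beta_ols).max() < 1e-4


def test_random_group_with_single_level_dropped_with_warning():
    rng = np.random.default_rng(5)
    df = balanced_frame(rng, resid_sd=1.0)
    df["batch"] = 1
    with pytest.warns(UserWarning, match="batch"):
        fit = fit_lmm(df, genotype_behavior_spec("li"))
    assert "batch" not in fit.vcomp


def test_satterthwaite_df_fractional_and_bounded(scored_session1):
    fit = fit_lmm(scored_session1, genotype_behavior_spec("li"))
    for row in fit.anova.itertuples():
        assert 1.0 < row.df_den <= fit.df_resid + 1e-6
        assert row.p == pytest.approx(stats.f.sf(row.F, row.df_num, row.df_den),
                                      abs=1e-12)
        assert row.eta_p2 == pytest.approx(
            eta_p2_from_f(row.F, row.df_num, row.df_den), abs=1e-12
        )


def test_tukey_flags_strongest_behavior_contrasts(scored_session1):
    """The default cohort generates the food-reaching test far more strongly
    lateralized; all three FRT contrasts on |LI| should reject, no others."""
    fit = fit_lmm(scored_session1, genotype_behavior_spec("abs_li"))
    ph = tukey_posthoc(fit, "behavior")
    frt = ph[ph["contrast"].str.contains("FRT")]
    other = ph[~ph["contrast"].str.contains("FRT")]
    assert len(frt) == 3
    assert (frt["p_tukey"] <= 0.05).all()
    assert (other["p_tukey"] > 0.05).all()


def test_tukey_two_level_factor_reduces_to_t_test():
    rng = np.random.default_rng(9)
    rows = []
    for g in ("WT", "KO"):
        for i in range(12):
            rows.append((f"{g}{i}", g, "GC", 1, 1,
                         rng.normal(0.3 if g == "KO" else 0.0, 1.0)))
    df = pd.DataFrame(rows, columns=["animal_id", "genotype", "behavior",
                                     "session", "batch", "li"])
    spec = LmmSpec(response="li", fixed="C(genotype, Sum)", random=(),
                   factors=("genotype",))
    fit = fit_lmm(df, spec)
    ph = tukey_posthoc(fit, "genotype")
    assert len(ph) == 1
    t, nu = ph["t"].iloc[0], ph["df"].iloc[0]
    p_t = 2 * stats.t.sf(abs(t), nu)
    assert ph["p_tukey"].iloc[0] == pytest.approx(p_t, abs=1e-6)


def test_tukey_zero_noise_identical_means_gives_zero_contrasts():
    means = {(g, b): 0.25 for g in GENOTYPES for b in BEHAVIORS}
    df = balanced_frame(np.random.default_rng(1), cell_means=means, resid_sd=0.0)
    fit = fit_lmm(df, genotype_behavior_spec("li"))
    ph = tukey_posthoc(fit, "behavior")
    assert np.abs(ph["estimate"]).max() < 1e-12


def test_tukey_unknown_factor_is_an_error(scored_session1):
    fit = fit_lmm(scored_session1, genotype_behavior_spec("li"))
    with pytest.raises(ValueError):
        tukey_posthoc(fit, "session")


def test_parameter_recovery_of_genotype_direction_shift():
    """A latent direction shift for KO animals is recovered by the model:
    over replicates, the fitted KO - WT marginal-mean difference on LI
    tracks the latent-truth difference within Monte-Carlo error."""
    diffs = []
    for seed in range(40):
        cfg = default_paper_like_config(seed=seed)
        cfg = type(cfg)(
            n_per_genotype=cfg.n_per_genotype, behaviors=cfg.behaviors,
            direction_shift={"WT": 0.0, "HET": 0.0, "KO": 0.6},
            batch_effect_sd=cfg.batch_effect_sd, n_sessions=1, seed=seed,
        )
        counts, latent = simulate_cohort(cfg)
        kept, _ = filter_min_counts(counts)
        scored = score_table(kept)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lmm(scored, genotype_behavior_spec("li"))
        emm = estimated_marginal_means(fit, "genotype").set_index("level")
        est = emm.loc["KO", "emmean"] - emm.loc["WT", "emmean"]
        truth = (
            latent[latent.genotype == "KO"]["theta"].mean()
            - latent[latent.genotype == "WT"]["theta"].mean()
        ) * 2.0  # E[LI | theta] = 2 theta - 1
        diffs.append(est - truth)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 2 * se + 0.02


def test_genotype_power_is_monotone_in_effect_size():
    """Empirical rejection rate of the genotype term is (weakly)
    non-decreasing in the knockout direction shift over {0, 0.1, 0.2, 0.4}
    on the latent logit scale; a 0.05 allowance absorbs Monte-Carlo noise
    at 80 replicates per effect size."""
    import dataclasses

    rates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for delta in (0.0, 0.1, 0.2, 0.4):
            rejections = 0
            n_rep = 80
            for seed in range(n_rep):
                cfg = default_paper_like_config(seed=10_000 + seed)
                cfg = dataclasses.replace(
                    cfg,
                    direction_shift={"WT": 0.0, "HET": 0.0, "KO": delta},
                    n_sessions=1,
                )
                counts, _ = simulate_cohort(cfg)
                kept, _ = filter_min_counts(counts)
                fit = fit_lmm(score_table(kept), genotype_behavior_spec("li"))
                p = float(fit.anova.loc[fit.anova["term"] == "C(genotype, Sum)",
                                        "p"].iloc[0])
                rejections += p <= 0.05
            rates.append(rejections / n_rep)
    assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:])), rates
    assert rates[-1] > rates[0], rates  # real power at the largest shift


def test_consistency_model_links_sessions():
    """Session-2 LI regressed on session-1 LI: strong coupling for the
    food-reaching test yields a significant baseline term."""
    counts, _ = simulate_cohort(default_paper_like_config(seed=4))
    kept, _ = filter_min_counts(counts, require_both_sessions=True)
    scored = score_table(kept)
    from laterality.consistency import paired_sessions

    wide = paired_sessions(scored, "FRT", "li")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lmm(wide, session_consistency_spec("s2", "s1"))
    row = fit.anova[fit.anova["term"] == "s1"]
    assert float(row["p"].iloc[0]) < 0.001
    assert float(row["df_num"].iloc[0]) == 1


# ---------------------------------------------------------------------------
# diagnostics and transforms
# ---------------------------------------------------------------------------

def _quick_fit(resid_sampler, n=200):
    rng = np.random.default_rng(21)
    rows = []
    for i in range(n):
        g = GENOTYPES[i % 3]
        rows.append((f"a{i}", g, "GC", 1, 1, resid_sampler(rng)))
    df = pd.DataFrame(rows, columns=["animal_id", "genotype", "behavior",
                                     "session", "batch", "li"])
    spec = LmmSpec(response="li", fixed="C(genotype, Sum)", random=(),
                   factors=("genotype",))
    return fit_lmm(df, spec)


def test_diagnostics_pass_for_normal_residuals():
    hits = 0
    rng = np.random.default_rng(77)
    for _ in range(30):
        vals = rng.normal(size=200)
        fit = _quick_fit(lambda r, v=iter(vals): next(v))
        d = residual_diagnostics(fit)
        hits += d.shapiro_p > 0.05
    assert hits >= 27  # normal residuals should pass in >= 90% of replicates


def test_diagnostics_recommend_transform_for_lognormal_residuals():
    fit = _quick_fit(lambda r: r.lognormal(0, 1.2))
    d = residual_diagnostics(fit)
    assert d.shapiro_p <= 0.05
    assert d.recommend_transform


def test_diagnostics_flag_constant_residuals_as_degenerate():
    fit = _quick_fit(lambda r: 0.0)
    d = residual_diagnostics(fit)
    assert d.degenerate
    assert not d.recommend_transform


def test_transforms_are_monotone_and_registered():
    x = np.linspace(-0.99, 0.99, 41)
    for name in ("identity", "sqrt", "logit_pm1", "rank_normal"):
        y = apply_transform(name, x)
        assert np.all(np.diff(y) > -1e-12), name
    y01 = apply_transform("logit", np.array([0.0, 0.5, 1.0]))
    assert np.all(np.isfinite(y01))  # boundary clamp keeps the logit finite
    with pytest.raises(KeyError):
        apply_transform("box-cox", x)
    assert set(TRANSFORMS) >= {"identity", "sqrt", "logit", "rank_normal"}
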