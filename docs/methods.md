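# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Individual scoring

Each record is one animal's right/left event tally for one behavior in one
session. The binomial Z-score `Z = (R − N/2)/√(N·p·q)` with `p = q = 0.5`
tests the animal's own counts against side-indifference; `|Z| > 1.96`
(strict inequality; `Z = ±1.96` exactly is ambilateral) defines an
individually significant preference. The laterality index `LI = (R − L)/N`
and its absolute value carry direction and strength; `Z = LI·√N` is an
algebraic identity the test suite enforces to 1e−12. No continuity
correction is applied — the score is used as a fixed classification rule,
not as a calibrated test. Because the rule is applied to a discrete count,
its effective two-sided exact level varies with `N`: for `N ≥ 30` the exact
doubled-tail binomial p of a just-classified animal can reach 0.0708, which
is the tolerance the asymptotic-agreement test documents.

The inclusion rule keeps a record iff its own `N ≥ 10` (inclusive).
Analyses that pair two sessions (consistency) keep an animal × behavior
combination only when **both** sessions pass; single-session analyses use
every passing record, including animals whose other session failed. The
rule is stated per behavior and session; the both-sessions extension for
paired analyses is the package's choice, forced by the fact that a
correlation needs both measurements.

Event caps: the food-reaching test and barrier crossing stop being coded
after 50 events, so `N ≤ 50` is a validated invariant for those behaviors.

## Group-level tests

Left/ambilateral/right (L/A/R) animal counts per behavior × genotype are
tested against a **uniform-thirds** null (`N/3` expected per category) with
Pearson's χ² on 2 df and an asymptotic p. Uniform thirds is the null that
reproduces every recomputable reference statistic exactly (e.g. (2,9,3) →
6.143, (1,12,2) → 14.8, (2,11,5) → 7). Small tables are tested anyway —
cells as small as 3 animals occur in this design — with a warning whenever
an expected frequency falls below 5.

Post-hoc pairwise comparisons (L-vs-R, L-vs-A, R-vs-A) run only when the
omnibus p ≤ α (default 0.05). Each is an exact binomial test of `a`
successes in `a + b` trials at p = ½, two-sided by the **tail-doubling
rule** `p = min(1, 2·min(lower tail, upper tail))`, then Bonferroni
adjusted with m = 3 (the comparisons within one table, not the number of
tables). These conventions jointly reproduce the recomputable reference
values (0.010 and 0.039 for the heterozygous self-grooming table). A pair
with no animals at all is reported as undefined rather than p = 1.

One reference cell is internally inconsistent: L/A/R = (7,1,3) was
published with χ² = 2 but p = 0.078, and only the p is consistent with the
counts (χ² = 5.091). `laterality.datasets.verify_reported_statistics`
recomputes all twelve cells and flags this one instead of matching the
misprint.

The population-bias test drops ambilateral animals and tests `n_L` against
`n_L + n_R` with the same exact binomial; a non-significant result in a
cohort full of lateralized individuals is the classic signature of
individual-level lateralization without population-level asymmetry.

## Mixed models

Models are random-intercept LMMs, `y = Xβ + Σ_k Z_k b_k + e`, fitted by
REML (profile likelihood over the variance ratios, L-BFGS-B on the log
scale with a Nelder–Mead polish if a line search stalls). The genotype
model uses `LI` or `|LI|` from session 1 with genotype × behavior fixed
effects and crossed random intercepts for batch and animal identity; the
per-behavior consistency models regress the session-2 measure on the
session-1 measure × genotype with a batch intercept.

Design choices:

* **Type III tests with sum-to-zero coding.** The cohort is unbalanced
  (18/18/12 animals, behavior-specific exclusions), so marginal tests with
  sum contrasts are required for interpretable main effects alongside the
  interaction.
* **Satterthwaite denominator df.** Per-contrast moment matching
  `ν = 2f²/(∇f' A ∇f)` with `f = ℓ'(X'V⁻¹X)⁻¹ℓ`, the observed REML
  information `A` obtained by central finite differences on the natural
  variance scale (components estimated at the zero boundary are held
  fixed); multi-df terms combine eigencontrast dfs through
  `E = Σ ν_i/(ν_i − 2)`, `ddf = 2E/(E − q)`. In the OLS limit (no free
  components) this reduces exactly to `n − p`. The implementation matches
  R's lmerTest to three-plus significant figures on shared fixtures, and
  statsmodels' MixedLM reaches the same REML optimum; both serve as
  independent oracles in the test suite.
* **Partial η² from F**, `F·df₁/(F·df₁ + df₂)`, rather than from sums of
  squares, so the effect size is well defined under fractional dfs.
* **Singular fits.** A variance ratio driven to the boundary is reported
  as an exactly-zero component with a warning, never an error; optimizer
  failure raises instead of silently falling back.
* **Gatekeeping.** Tukey HSD post-hocs (estimated marginal means averaged
  over a balanced factor grid, studentized-range adjustment with the
  contrast's Satterthwaite df) run only for omnibus-significant factors.
* **Transforms.** Bounded responses can leave residuals non-normal;
  diagnostics (Shapiro–Wilk, plus a max/min grouped residual-variance
  ratio flagged above 4) recommend a transform when normality is rejected.
  The registry holds identity, signed square root, logit with boundary
  clamp ε = 0.005 (and a [−1, 1] variant), and Blom rank-normal scores;
  the transform used is recorded in the run log. Which transform a given
  published analysis used is not recoverable from the main text, so the
  default is identity and the choice is left explicit to the user.

Published F statistics for this stage depend on the original raw data and
are deliberately not asserted; the acceptance surface instead pins
noiseless recovery, exact agreement with a brute-force ANOVA decomposition
in the zero-variance limit, Monte-Carlo type-I calibration (the genotype
term rejects at 4–5% under the null), power monotonicity in the effect
size, and parameter recovery against the generator's latent truth.

## Temporal consistency

One-tailed (ρ > 0) Spearman correlations with average-rank ties, per
behavior and measure, on the both-sessions-filtered pairs. For n ≤ 9 the p
is exact, by full enumeration of rank permutations conditioned on the
observed tie pattern; otherwise the usual t approximation is used.
Adjustment is Bonferroni with m = the behaviors tested within one measure
(4 by default) — the minimal family consistent with correcting each
reported analysis block; the alternative family of all 8 tests across both
measures would only rescale the adjusted values by 2.

## Synthetic cohorts

The generator emulates the emulated study's design: 48 animals (WT 18,
HET 18, KO 12), two batches of 24 balanced within genotype, two sessions,
four behaviors. Per animal × behavior, a latent right-bias
`θ ~ Beta(κ_b, κ_b)` sets individual lateralization strength (symmetric, so
no population bias; a beta-binomial rather than fixed-p binomial because
only overdispersion yields many strongly lateralized individuals with a
balanced population). Genotype and batch effects shift `logit(θ)`; the
default genotype shift is 0, encoding the null result the cohort design
established. Sessions are coupled by a Gaussian copula on the Beta
quantiles with normal correlation `2·sin(ρπ/6)`, so the per-behavior
parameter ρ is the target **Spearman** correlation of the latent biases
(tests compare against the exact finite-n expectation of the sample
Spearman statistic, which is biased toward zero by O(1/n)). Counts are
`Binomial(N, θ)` with `N` uniform on a per-behavior range, or below the
10-event floor with a per-behavior dropout probability.

Defaults, chosen once: κ = 0.4 for the food-reaching test versus 3 for the
three spontaneous behaviors, giving cohort mean |LI| near 0.8 versus ~0.3
as in published group summaries; ρ = 0.9 (FRT), 0.5 (BC), 0 (GC, SG) for
direction; dropout 0.25/0.05/0.12/0.02 (GC/FRT/SG/BC), approximating the
published per-behavior exclusion counts (grid climbing loses the most
animals; paired n ≈ 24/43/37/47); event floors 10 except barrier crossing
at 25, since that frequent behavior nearly always reaches its 50-event cap
and binomial noise would otherwise attenuate its observed direction
consistency well below the latent target. Strength (|LI|) consistency is
not a separate dial: strong direction coupling induces it (ρ_dir = 0.9 →
strength rank correlation ≈ 0.7, matching the observed FRT pattern; ρ_dir
= 0.5 → ≈ 0.14, i.e. BC strength consistency is absent, as observed). For
scenarios needing strength-without-direction consistency, a per-behavior
mirror flag reflects the session-2 bias about 0.5 with probability ½.

What the generator does **not** model: aging across sessions, cage-pair
dependence, experimenter-specific coding styles beyond a batch intercept,
behavior-specific event-count distributions (only the floor and cap are
known), and any real dependence between behaviors within an animal (latent
biases are drawn independently per behavior). Passing tests therefore show
that the pipeline recovers the structure this generative family encodes at
the study's sample sizes — not that real data satisfy that family.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to keep estimates stable while the
suite stays desk-runnable: 1000 null cohorts for type-I calibration
(binomial SE ≈ 0.7 percentage points), 100 cohorts for the end-to-end
pattern regeneration (thresholds set at nominal rates minus three binomial
SEs, or simple majorities for pattern counts), 200 replicates for latent
correlation recovery, 40 for parameter recovery. All randomness is seeded;
the suite is deterministic.
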