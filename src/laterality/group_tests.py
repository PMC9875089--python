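"""Group-level tests on left/ambilateral/right classification counts.

For each behavior x genotype cell the number of left-preferring (L),
ambilateral (A) and right-preferring (R) animals is tested against a random
(uniform-thirds) distribution with a Pearson chi-square goodness-of-fit test
on 2 degrees of freedom.  Where the omnibus test rejects, the three pairwise
category comparisons (L-vs-R, L-vs-A, R-vs-A) are followed up with exact
two-sided binomial tests, Bonferroni-corrected for the three comparisons.

A separate population-level test asks whether lateralized animals (L or R,
ambilateral excluded) are split asymmetrically between the two sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .scoring import AMBILATERAL, LEFT, RIGHT

__all__ = [
    "ClassificationTable",
    "PosthocResult",
    "GroupTestResult",
    "classification_tables",
    "chi2_random_distribution",
    "binomial_posthocs",
    "population_bias_test",
    "exact_binomial_p",
    "group_test_report",
]

#: Pairwise category comparisons run after a significant omnibus test.
PAIRS = (("L", "R"), ("L", "A"), ("R", "A"))


class EmptyTableError(ValueError):
    """Raised for a classification table with zero animals."""


@dataclass(frozen=True)
class ClassificationTable:
    """L/A/R animal counts for one behavior x genotype cell."""

    behavior: str
    genotype: str
    n_left: int
    n_ambi: int
    n_right: int

    def __post_init__(self) -> None:
        if min(self.n_left, self.n_ambi, self.n_right) < 0:
            raise ValueError("classification counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_left + self.n_ambi + self.n_right

    def count(self, category: str) -> int:
        return {"L": self.n_left, "A": self.n_ambi, "R": self.n_right}[category]


@dataclass(frozen=True)
class PosthocResult:
    comparison: str          # e.g. "L-vs-A"
    n_first: int
    n_second: int
    p_raw: float | None      # None when both categories are empty
    p_adjusted: float | None


@dataclass(frozen=True)
class GroupTestResult:
    table: ClassificationTable
    chi2: float
    df: int
    p: float
    expected: float
    posthocs: list[PosthocResult] = field(default_factory=list)


def exact_binomial_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value by the tail-doubling rule.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` for X ~ Binomial(n, p).
    For the symmetric p = 0.5 case this coincides with the
    minimum-likelihood rule except for the cap at 1.
    """
    if n == 0:
        raise ValueError("binomial test undefined for n = 0")
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def classification_tables(scored: pd.DataFrame) -> list[ClassificationTable]:
    """Tabulate L/A/R animal counts per behavior x genotype from scored rows.

    Expects one row per animal for each behavior (i.e. a single session,
    already filtered); the ``classification`` column is counted directly.
    """
    tables = []
    for (behavior, genotype), grp in scored.groupby(
        ["behavior", "genotype"], observed=True, sort=False
    ):
        cls = grp["classification"].value_counts()
        tables.append(
            ClassificationTable(
                behavior=str(behavior),
                genotype=str(genotype),
                n_left=int(cls.get(LEFT, 0)),
                n_ambi=int(cls.get(AMBILATERAL, 0)),
                n_right=int(cls.get(RIGHT, 0)),
            )
        )
    return tables


def chi2_random_distribution(
    table: ClassificationTable,
    alpha: float = 0.05,
    run_posthocs: bool = True,
) -> GroupTestResult:
    """Pearson goodness-of-fit test of L/A/R counts against uniform thirds.

    The null expectation is ``total/3`` per category; df = 2; the p-value is
    asymptotic, with no continuity correction.  Totals below 15 leave some
    expected frequency under 5, where the asymptotic p is rough — a warning
    is emitted but the test still runs (small cells are routinely tested in
    this design).  When the omnibus p <= ``alpha`` and ``run_posthocs`` is
    set, Bonferroni-corrected pairwise binomial post-hocs are attached.
    """
    if table.total == 0:
        raise EmptyTableError(
            f"no animals in table {table.behavior}/{table.genotype}"
        )
    expected = table.total / 3.0
    if expected < 5:
        warnings.warn(
            f"{table.behavior}/{table.genotype}: expected frequency "
            f"{expected:.2f} < 5; asymptotic chi-square p is approximate",
            stacklevel=2,
        )
    chi2, p = stats.chisquare([table.n_left, table.n_ambi, table.n_right])
    posthocs = (
        binomial_posthocs(table) if (run_posthocs and p <= alpha) else []
    )
    return GroupTestResult(
        table=table, chi2=float(chi2), df=2, p=float(p),
        expected=expected, posthocs=posthocs,
    )


def binomial_posthocs(table: ClassificationTable) -> list[PosthocResult]:
    """Pairwise exact binomial tests between the three categories.

    Each pair (a, b) is tested as ``a`` successes in ``a + b`` trials at
    p = 0.5 (two-sided, tail doubling); p-values are Bonferroni-adjusted for
    the m = 3 comparisons within the table.  A pair with no animals at all
    is reported as undefined rather than p = 1.
    """
    out = []
    for first, second in PAIRS:
        a, b = table.count(first), table.count(second)
        if a + b == 0:
            out.append(PosthocResult(f"{first}-vs-{second}", a, b, None, None))
            continue
        p_raw = exact_binomial_p(a, a + b)
        out.append(
            PosthocResult(
                comparison=f"{first}-vs-{second}",
                n_first=a,
                n_second=b,
                p_raw=p_raw,
                p_adjusted=min(1.0, 3.0 * p_raw),
            )
        )
    return out


@dataclass(frozen=True)
class PopulationBiasResult:
    n_left: int
    n_right: int
    p: float

    @property
    def biased(self) -> bool:
        return self.p <= 0.05


def population_bias_test(scored: pd.DataFrame, behavior: str) -> PopulationBiasResult:
    """Test for a population-level side bias among lateralized animals.

    Counts LEFT vs RIGHT classified animals for ``behavior`` (ambilateral
    animals carry no directional information and are excluded) and runs an
    exact two-sided binomial test at p = 0.5.  A non-significant result with
    many lateralized animals is the signature of individual-level
    lateralization without a population-level asymmetry.
    """
    sub = scored[scored["behavior"] == behavior]
    n_l = int((sub["classification"] == LEFT).sum())
    n_r = int((sub["classification"] == RIGHT).sum())
    if n_l + n_r == 0:
        raise EmptyTableError(
            f"no lateralized animals for behavior {behavior}; "
            "population bias undefined"
        )
    return PopulationBiasResult(n_l, n_r, exact_binomial_p(n_l, n_l + n_r))


def group_test_report(
    scored: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full group-test stage over a scored single-session table.

    Returns ``(omnibus, posthocs)`` data frames: one omnibus chi-square row
    per behavior x genotype cell, and one row per post-hoc comparison for
    the cells whose omnibus test rejected at ``alpha``.
    """
    omni_rows, ph_rows = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-cell warnings collected once per run
        for tab in classification_tables(scored):
            res = chi2_random_distribution(tab, alpha=alpha)
            omni_rows.append(
                {
                    "behavior": tab.behavior,
                    "genotype": tab.genotype,
                    "n_left": tab.n_left,
                    "n_ambi": tab.n_ambi,
                    "n_right": tab.n_right,
                    "total": tab.total,
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                    "expected_per_cell": res.expected,
                    "small_expected": res.expected < 5,
                }
            )
            for ph in res.posthocs:
                ph_rows.append(
                    {
                        "behavior": tab.behavior,
                        "genotype": tab.genotype,
                        "comparison": ph.comparison,
                        "n_first": ph.n_first,
                        "n_second": ph.n_second,
                        "p_raw": ph.p_raw,
                        "p_adjusted": ph.p_adjusted,
                    }
                )
    posthocs = pd.DataFrame(
        ph_rows,
        columns=[
            "behavior", "genotype", "comparison",
            "n_first", "n_second", "p_raw", "p_adjusted",
        ],
    )
    return pd.DataFrame(omni_rows), posthocs
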