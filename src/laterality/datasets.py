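"""Built-in reference tables.

``REPORTED_CLASSIFICATION_TABLES`` holds the published session-1
left/ambilateral/right classification counts from a serotonin-transporter
(5-HTT) knockout mouse cohort — 18 wild type (WT), 18 heterozygous (HET)
and 12 homozygous knockout (KO) females scored on four behaviors — together
with the chi-square statistic and p-value the original analysis reported
for each cell.  The counts are data (inputs); the reported statistics exist
so that :func:`verify_reported_statistics` can recompute every test from
the counts and flag any cell where the published statistic disagrees with
the recomputation beyond printing precision.

One such discrepancy is known: the FRT/KO cell (L=7, A=1, R=3) was
published with chi-square 2 but p 0.078, and only the p-value is consistent
with the counts (chi-square 5.09); the published statistic for that cell is
evidently a misprint.
"""

from __future__ import annotations

import pandas as pd

from .group_tests import ClassificationTable, chi2_random_distribution

__all__ = ["REPORTED_CLASSIFICATION_TABLES", "reported_tables", "verify_reported_statistics"]

# behavior, genotype, n_left, n_ambi, n_right, reported chi2, reported p
# (p values published as "< 0.001" are stored as 0.001 with p_is_bound=True)
_ROWS = [
    ("GC", "WT", 2, 9, 3, 6.14, 0.046, False),
    ("GC", "HET", 1, 9, 3, 8.0, 0.018, False),
    ("GC", "KO", 1, 2, 0, 2.0, 0.368, False),
    ("FRT", "WT", 5, 3, 10, 4.33, 0.115, False),
    ("FRT", "HET", 4, 4, 8, 2.0, 0.368, False),
    ("FRT", "KO", 7, 1, 3, 2.0, 0.078, False),
    ("SG", "WT", 0, 12, 0, 24.0, 0.001, True),
    ("SG", "HET", 1, 12, 2, 14.8, 0.001, True),
    ("SG", "KO", 2, 8, 2, 6.0, 0.050, False),
    ("BC", "WT", 2, 11, 5, 7.0, 0.030, False),
    ("BC", "HET", 2, 8, 8, 4.0, 0.135, False),
    ("BC", "KO", 2, 6, 4, 2.0, 0.368, False),
]

REPORTED_CLASSIFICATION_TABLES = pd.DataFrame(
    _ROWS,
    columns=["behavior", "genotype", "n_left", "n_ambi", "n_right",
             "reported_chi2", "reported_p", "p_is_upper_bound"],
)


def reported_tables() -> list[ClassificationTable]:
    """The reference counts as :class:`ClassificationTable` objects."""
    return [
        ClassificationTable(r.behavior, r.genotype, r.n_left, r.n_ambi, r.n_right)
        for r in REPORTED_CLASSIFICATION_TABLES.itertuples()
    ]


def verify_reported_statistics(chi2_tol: float = 0.005) -> pd.DataFrame:
    """Recompute every reference chi-square test and flag disagreements.

    A cell is flagged when the recomputed statistic differs from the
    reported one by more than ``chi2_tol`` relative to printing precision
    (reported values carry 2-3 significant digits).  Returns one row per
    cell with recomputed ``chi2``/``p`` and a boolean ``discrepant`` column.
    """
    rows = []
    for r in REPORTED_CLASSIFICATION_TABLES.itertuples():
        table = ClassificationTable(r.behavior, r.genotype, r.n_left, r.n_ambi, r.n_right)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = chi2_random_distribution(table, run_posthocs=False)
        chi2_ok = abs(res.chi2 - r.reported_chi2) <= chi2_tol * max(1.0, r.reported_chi2)
        p_ok = (res.p <= r.reported_p + 5e-4) if r.p_is_upper_bound else (
            abs(res.p - r.reported_p) <= 5e-4 + 0.0005
        )
        rows.append({
            "behavior": r.behavior, "genotype": r.genotype,
            "chi2": res.chi2, "p": res.p,
            "reported_chi2": r.reported_chi2, "reported_p": r.reported_p,
            "chi2_matches": chi2_ok, "p_matches": p_ok,
            "discrepant": not (chi2_ok and p_ok),
        })
    return pd.DataFrame(rows)
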