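"""Temporal consistency of laterality measures across two sessions.

An animal's side preference is temporally consistent when its session-1
measure predicts its session-2 measure.  Alongside the per-behavior
consistency mixed models, this module provides the direct nonparametric
check: a one-tailed (positive) Spearman rank correlation per behavior and
measure, Bonferroni-adjusted over the behaviors tested for that measure.

Only animals whose event counts pass the inclusion rule in *both* sessions
enter a correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConsistencyResult",
    "spearman_consistency",
    "adjust_consistency_pvalues",
    "consistency_report",
    "paired_sessions",
]

#: Exact permutation p-values are used up to this sample size.
EXACT_N_MAX = 9


class ConstantInputError(ValueError):
    """Raised when one session's values are constant (rho undefined)."""


@dataclass
class ConsistencyResult:
    behavior: str
    measure: str
    rho: float
    n: int
    p_raw: float
    p_adjusted: float | None = None


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """One-tailed exact p by enumerating all n! rank permutations.

    Ties are handled with average ranks in both the observed statistic and
    every permuted statistic, so the reference distribution conditions on
    the observed tie pattern.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = rx - rx.mean()
    sx = math.sqrt(float(rx @ rx))
    ry_c = ry - ry.mean()
    sy = math.sqrt(float(ry_c @ ry_c))
    perms = np.array(list(permutations(ry_c)))      # n! x n
    rhos = (perms @ rx) / (sx * sy)
    return float(np.mean(rhos >= rho_obs - 1e-12))


def spearman_consistency(
    session1: np.ndarray | pd.Series,
    session2: np.ndarray | pd.Series,
    behavior: str = "",
    measure: str = "",
) -> ConsistencyResult:
    """One-tailed (rho > 0) Spearman correlation between paired sessions.

    Average ranks for ties; exact permutation p for n <= 9, the usual
    t-approximation otherwise.  Constant input in either session leaves the
    correlation undefined and raises :class:`ConstantInputError`.
    """
    x = np.asarray(session1, dtype=float)
    y = np.asarray(session2, dtype=float)
    if len(x) != len(y):
        raise ValueError("sessions must be paired (equal length)")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(
            f"constant values in one session for {behavior or 'input'}; "
            "rank correlation undefined"
        )
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_N_MAX:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y, alternative="greater").pvalue)
    return ConsistencyResult(behavior=behavior, measure=measure, rho=rho, n=n, p_raw=p)


def adjust_consistency_pvalues(
    results: list[ConsistencyResult], m: int | None = None
) -> list[ConsistencyResult]:
    """Bonferroni-adjust raw p-values within one family of correlations.

    The family defaults to the results passed in (one per behavior for a
    single measure); ``p_adjusted = min(1, m * p_raw)``.
    """
    if not results:
        raise ValueError("no consistency results to adjust")
    m = m if m is not None else len(results)
    for res in results:
        res.p_adjusted = min(1.0, m * res.p_raw)
    return results


def paired_sessions(scored: pd.DataFrame, behavior: str, measure: str) -> pd.DataFrame:
    """Pivot a two-session scored table into paired session-1/2 columns.

    Expects rows already filtered with the both-sessions inclusion rule.
    Returns columns ``animal_id, genotype, batch, s1, s2`` for ``behavior``.
    """
    sub = scored[scored["behavior"] == behavior]
    empty = pd.DataFrame(columns=["animal_id", "genotype", "batch", "s1", "s2"])
    if sub.empty:
        return empty
    wide = sub.pivot_table(
        index=["animal_id", "genotype", "batch"],
        columns="session", values=measure, observed=True,
    ).reset_index()
    wide = wide.rename(columns={1: "s1", 2: "s2"})
    if "s1" not in wide.columns or "s2" not in wide.columns:
        return empty
    return wide.dropna(subset=["s1", "s2"])


def consistency_report(
    scored_pairs: pd.DataFrame,
    measures: tuple[str, ...] = ("li", "abs_li"),
    behaviors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-behavior x measure Spearman consistency table.

    ``scored_pairs`` is a scored two-session table already passed through
    the both-sessions filter.  Adjustment is Bonferroni within each
    measure, m = number of behaviors actually tested for that measure.
    Behaviors with undefined correlations (constant input) appear with NaN
    rho and are excluded from the adjustment family.
    """
    if behaviors is None:
        behaviors = tuple(pd.unique(scored_pairs["behavior"]))
    rows = []
    for measure in measures:
        results = []
        for behavior in behaviors:
            pairs = paired_sessions(scored_pairs, behavior, measure)
            if len(pairs) < 3:
                rows.append({"behavior": behavior, "measure": measure,
                             "rho": np.nan, "n": len(pairs),
                             "p_raw": np.nan, "p_adjusted": np.nan,
                             "note": "fewer than 3 pairs"})
                continue
            try:
                res = spearman_consistency(
                    pairs["s1"], pairs["s2"], behavior=behavior, measure=measure
                )
            except ConstantInputError:
                rows.append({"behavior": behavior, "measure": measure,
                             "rho": np.nan, "n": len(pairs),
                             "p_raw": np.nan, "p_adjusted": np.nan,
                             "note": "constant input; rho undefined"})
                continue
            results.append(res)
        adjust_consistency_pvalues(results)
        for res in results:
            rows.append({"behavior": res.behavior, "measure": res.measure,
                         "rho": res.rho, "n": res.n, "p_raw": res.p_raw,
                         "p_adjusted": res.p_adjusted, "note": ""})
    return pd.DataFrame(rows)
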