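"""Reading and validating tidy side-choice count tables.

The interchange format for every pipeline stage is one tidy CSV with the
columns ``animal_id, genotype, behavior, session, batch, n_right, n_left``
(one row per animal x behavior x session).  Genotypes may be written in
slash notation (``+/+``, ``+/-``, ``-/-``) or as ``WT``/``HET``/``KO``;
they are normalized to the latter on input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scoring import BEHAVIORS, GENOTYPES

__all__ = ["SchemaError", "read_counts_csv", "normalize_genotype", "write_scored_csv"]

REQUIRED_COLUMNS = ["animal_id", "genotype", "behavior", "session", "batch",
                    "n_right", "n_left"]

GENOTYPE_ALIASES = {
    "+/+": "WT", "WT": "WT", "wt": "WT",
    "+/-": "HET", "+/−": "HET", "HET": "HET", "het": "HET",
    "-/-": "KO", "−/−": "KO", "KO": "KO", "ko": "KO",
}


class SchemaError(ValueError):
    """Input table violates the count-table schema; lists every bad row."""


def normalize_genotype(token: str) -> str:
    try:
        return GENOTYPE_ALIASES[str(token).strip()]
    except KeyError:
        raise ValueError(f"unknown genotype token {token!r}") from None


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy count CSV.

    All schema violations — missing columns, unknown genotype or behavior
    tokens, non-integer or negative counts, invalid sessions, duplicated
    (animal, behavior, session) keys — are collected and reported together,
    with 1-based data row numbers, rather than failing at the first one.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    problems: list[str] = []
    genotypes = []
    for i, row in df.iterrows():
        rowno = i + 1
        tok = str(row["genotype"]).strip()
        if tok in GENOTYPE_ALIASES:
            genotypes.append(GENOTYPE_ALIASES[tok])
        else:
            genotypes.append(None)
            problems.append(f"row {rowno}: unknown genotype {tok!r}")
        if str(row["behavior"]).strip() not in BEHAVIORS:
            problems.append(f"row {rowno}: unknown behavior {row['behavior']!r}")
        try:
            if int(row["session"]) not in (1, 2):
                problems.append(f"row {rowno}: session must be 1 or 2")
        except (TypeError, ValueError):
            problems.append(f"row {rowno}: non-integer session {row['session']!r}")
        for col in ("n_right", "n_left"):
            try:
                v = int(row[col])
                if v < 0:
                    problems.append(f"row {rowno}: negative {col}")
                elif float(row[col]) != v:
                    problems.append(f"row {rowno}: non-integer {col}")
            except (TypeError, ValueError):
                problems.append(f"row {rowno}: non-integer {col} {row[col]!r}")

    dup = df.duplicated(subset=["animal_id", "behavior", "session"], keep=False)
    if dup.any():
        for i in df.index[dup]:
            problems.append(
                f"row {i + 1}: duplicate key "
                f"({df.at[i, 'animal_id']}, {df.at[i, 'behavior']}, {df.at[i, 'session']})"
            )
    if problems:
        raise SchemaError(f"{path}: invalid count table:\n" + "\n".join(problems))

    df = df.copy()
    df["genotype"] = genotypes
    df["behavior"] = df["behavior"].astype(str).str.strip()
    df["session"] = df["session"].astype(int)
    df["batch"] = df["batch"].astype(int)
    df["n_right"] = df["n_right"].astype(int)
    df["n_left"] = df["n_left"].astype(int)
    df["genotype"] = pd.Categorical(df["genotype"], categories=list(GENOTYPES))
    df["behavior"] = pd.Categorical(df["behavior"], categories=list(BEHAVIORS))
    return df


def write_scored_csv(scored: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    scored.to_csv(path, index=False)
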