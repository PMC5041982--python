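"""Differential-expression thresholds and STAT3/STAT1 annotation cross-tab.

Gene tables carry a signed linear fold change (negative = downregulated),
an FDR-adjusted significance, and prior regulation annotations for STAT3
and STAT1 (``Pos``, ``Neg``, or ``None`` for unannotated).  Genes passing
fdr < 0.01 and |fold change| >= 1.5 (strict on fdr, inclusive on
magnitude) are split by direction and cross-tabulated against the prior
annotations, yielding the summary fractions of interest — e.g. the share
of downregulated genes previously shown to be positively STAT1-regulated,
and the number co-regulated by both transcription factors.

The packaged fixture ``table3.tsv`` is the study's curated gene table
(48 down- and 42 up-regulated genes with prior annotations); it prints no
per-gene fdr — the rows are already past the significance filter — so the
fixture stores fdr = 0 for every row.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PRIORS",
    "read_gene_table",
    "load_table3",
    "filter_de",
    "crosstab",
    "CrosstabSummary",
]

PRIORS = ("Pos", "Neg", "None")
_COLUMNS = ["gene", "refseq", "fold_change", "fdr", "stat3_prior", "stat1_prior"]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (gene, refseq, fold_change, fdr, stat3_prior, stat1_prior).

    Priors are the literal strings Pos/Neg/None (never parsed as NaN);
    ``log2`` fold changes can be converted upstream — this table is linear
    and signed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df["fold_change"] = df["fold_change"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    for col in ("stat3_prior", "stat1_prior"):
        bad = set(df[col]) - set(PRIORS)
        if bad:
            raise ValueError(f"{col}: unknown annotation values {sorted(bad)}")
    return df[_COLUMNS]


def load_table3() -> pd.DataFrame:
    """The packaged curated gene-table fixture (48 down / 42 up genes)."""
    with resources.as_file(resources.files("hit2lead.data") / "table3.tsv") as p:
        return read_gene_table(p)


def filter_de(
    genes: pd.DataFrame, fdr_max: float = 0.01, fc_min: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split genes into (down, up) by the significance/magnitude thresholds.

    down: fdr < fdr_max and fold_change <= -fc_min;
    up:   fdr < fdr_max and fold_change >= +fc_min.
    fdr is compared strictly, fold-change magnitude inclusively.
    """
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1 (linear fold change), got {fc_min}")
    sig = genes["fdr"] < fdr_max
    down = genes[sig & (genes["fold_change"] <= -fc_min)].reset_index(drop=True)
    up = genes[sig & (genes["fold_change"] >= fc_min)].reset_index(drop=True)
    return down, up


@dataclass
class CrosstabSummary:
    """Counts by (direction, stat3_prior, stat1_prior) plus named fractions.

    ``fractions`` maps a name to a (numerator, denominator, value) tuple;
    a fraction with denominator 0 has value None (undefined, not 0).
    """

    counts: dict[tuple[str, str, str], int]
    n_down: int
    n_up: int
    fractions: dict[str, tuple[int, int, float | None]]

    def count(self, direction: str, stat3: str, stat1: str) -> int:
        return self.counts.get((direction, stat3, stat1), 0)

    def to_dict(self) -> dict:
        return {
            "n_down": self.n_down,
            "n_up": self.n_up,
            "cells": {f"{d}|{s3}|{s1}": v for (d, s3, s1), v in sorted(self.counts.items())},
            "fractions": {
                name: {"numerator": num, "denominator": den, "value": val}
                for name, (num, den, val) in self.fractions.items()
            },
        }


def _frac(num: int, den: int) -> tuple[int, int, float | None]:
    return (num, den, (num / den) if den else None)


def crosstab(down: pd.DataFrame, up: pd.DataFrame) -> CrosstabSummary:
    """Cross-tabulate regulated genes against their STAT3/STAT1 priors.

    The derived quantities include: the number of STAT3-annotated genes in
    both directions; downregulated genes with prior positive STAT1
    regulation (as a fraction of all down genes); co-regulated
    (STAT3-Pos & STAT1-Pos) down genes; STAT3-unannotated down genes with
    STAT1-Pos; and the Pos/Neg split among STAT3-annotated down genes.
    """
    overlap = set(down["gene"]) & set(up["gene"])
    if overlap:
        raise ValueError(f"genes in both down and up lists: {sorted(overlap)}")
    counts: dict[tuple[str, str, str], int] = {}
    for direction, df in (("down", down), ("up", up)):
        for (s3, s1), grp in df.groupby(["stat3_prior", "stat1_prior"]):
            counts[(direction, s3, s1)] = len(grp)

    n_down, n_up = len(down), len(up)
    down_s3 = down[down["stat3_prior"] != "None"]
    up_s3 = up[up["stat3_prior"] != "None"]
    n_down_stat1_pos = int((down["stat1_prior"] == "Pos").sum())
    n_co = int(((down["stat3_prior"] == "Pos") & (down["stat1_prior"] == "Pos")).sum())
    n_down_s3none_s1pos = int(
        ((down["stat3_prior"] == "None") & (down["stat1_prior"] == "Pos")).sum()
    )
    fractions = {
        "down_stat1_pos_of_down": _frac(n_down_stat1_pos, n_down),
        "down_stat3pos_stat1pos": _frac(n_co, n_down),
        "down_stat3none_stat1pos": _frac(n_down_s3none_s1pos, n_down),
        "stat3_annotated_down": _frac(len(down_s3), n_down),
        "stat3_annotated_up": _frac(len(up_s3), n_up),
        "stat3_annotated_total": _frac(len(down_s3) + len(up_s3), n_down + n_up),
        "down_stat3_pos_of_stat3_annotated": _frac(
            int((down_s3["stat3_prior"] == "Pos").sum()), len(down_s3)
        ),
        "down_stat3_neg_of_stat3_annotated": _frac(
            int((down_s3["stat3_prior"] == "Neg").sum()), len(down_s3)
        ),
    }
    return CrosstabSummary(counts=counts, n_down=n_down, n_up=n_up, fractions=fractions)
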