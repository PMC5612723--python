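"""The functional-diversity score D_F.

A gene's functional diversity combines three annotation-derived counts: the
number of within-species paralogues P (self excluded), the number of
protein-coding isoforms I, and the number of annotated domains/motifs M_i in
each isoform (Prosite-profile style). Raw counts are heavy-tailed — zinc-finger
genes can carry dozens of paralogues or domain repeats — so each count enters
on a log2 scale, which keeps outliers in the analysis without letting them
dominate:

    D_F = log2 P + log2 I + sum_i log2 M_i

log2 of a zero count is undefined; since P = 0 (singleton gene) and M_i = 0
(no annotated profile) are legitimate annotations, every count is floored at 1
before the transform by default, so those terms contribute 0 and the gene stays
in the analysis. An ``add-one`` mode (log2(x + 1)) is available for users who
prefer a strictly increasing transform at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from funcdiv.data_model import GeneRecord

logger = logging.getLogger(__name__)

#: Recognised zero-handling modes for the log2 transform.
ZERO_MODES = ("floor", "add-one")


@dataclass(frozen=True)
class DiversityScore:
    """D_F for one gene in one species (dimensionless, log2 scale)."""

    gene_id: str
    species_id: str
    human_symbol: str
    df_value: float


def log2_floor(x: int, mode: str = "floor") -> float:
    """log2 with zero handling: ``floor`` gives log2(max(x, 1)), ``add-one`` log2(x + 1).

    Always finite and >= 0 for x >= 0; raises for negative counts.
    """
    if x < 0:
        raise ValueError(f"count must be non-negative, got {x}")
    if mode == "floor":
        return math.log2(max(x, 1))
    if mode == "add-one":
        return math.log2(x + 1)
    raise ValueError(f"unknown zero-handling mode {mode!r}; expected one of {ZERO_MODES}")


def compute_df(record: GeneRecord, mode: str = "floor") -> DiversityScore:
    """Compute D_F = log2 P + log2 I + sum over isoforms of log2 M_i."""
    value = log2_floor(record.paralogue_count, mode)
    value += log2_floor(record.isoform_count, mode)
    for m in record.motif_counts:
        value += log2_floor(m, mode)
    return DiversityScore(
        gene_id=record.gene_id,
        species_id=record.species_id,
        human_symbol=record.human_symbol,
        df_value=value,
    )


def score_all(records: Iterable[GeneRecord], mode: str = "floor") -> list[DiversityScore]:
    """Score every record, preserving input order."""
    return [compute_df(rec, mode) for rec in records]


def group_mean_df(
    scores: Sequence[DiversityScore],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean D_F per (group, species) for genes mapped to functional groups.

    ``groups`` maps human symbols to group labels (for example a GO-term
    class); symbols mapped to no score are ignored with a warning. Returns a
    frame with columns group, species_id, mean_df, n sorted on the first two.
    """
    known = {s.human_symbol for s in scores}
    unknown = sorted(set(groups) - known)
    if unknown:
        logger.warning(
            "group_mean_df: %d grouped symbol(s) have no score and are ignored: %s",
            len(unknown), unknown[:10],
        )
    rows = [
        {"group": groups[s.human_symbol], "species_id": s.species_id, "df": s.df_value}
        for s in scores
        if s.human_symbol in groups
    ]
    if not rows:
        return pd.DataFrame(columns=["group", "species_id", "mean_df", "n"])
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["group", "species_id"], as_index=False)
        .agg(mean_df=("df", "mean"), n=("df", "size"))
        .sort_values(["group", "species_id"], kind="stable", ignore_index=True)
    )
    return out


def write_scores_table(
    records: Iterable[GeneRecord],
    scores: Iterable[DiversityScore],
    path,
) -> None:
    """Write a scores TSV: human_symbol, species_id, gene_id, P, I, sum_M, df_value."""
    rows = []
    for rec, score in zip(records, scores, strict=True):
        rows.append(
            {
                "human_symbol": rec.human_symbol,
                "species_id": rec.species_id,
                "gene_id": rec.gene_id,
                "P": rec.paralogue_count,
                "I": rec.isoform_count,
                "sum_M": sum(rec.motif_counts),
                "df_value": f"{score.df_value:.6f}",
            }
        )
    pd.DataFrame(
        rows, columns=["human_symbol", "species_id", "gene_id", "P", "I", "sum_M", "df_value"]
    ).to_csv(path, sep="\t", index=False)
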