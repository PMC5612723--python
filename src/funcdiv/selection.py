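"""Correlation-based gene selection across the phylogeny.

Each orthologue group contributes a vector of D_F values over the species in
which a one-to-one orthologue exists, paired with those species' cell-type
numbers C_s. Groups are stratified into first-seen cohorts (worm-first,
fly-first, vertebrate-only) and a group is selected when its Pearson
correlation r between D_F and C_s exceeds the positive boundary r_crit(n) —
the correlation magnitude at two-tailed p = 0.05 for a t-test on n - 2 degrees
of freedom:

    r_crit = t_c / sqrt(t_c^2 + (n - 2)),   t_c = t quantile at 1 - alpha/2

Because the boundary is two-tailed but only positive correlations are kept,
the null selection rate is alpha / 2. Selection needs at least six paired
observations (four degrees of freedom).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from funcdiv.data_model import (
    CIONA,
    FLY,
    HUMAN,
    VERTEBRATES,
    WORM,
    Cohort,
    GeneRecord,
    OrthologueSet,
    SpeciesTable,
)
from funcdiv.diversity import DiversityScore

logger = logging.getLogger(__name__)

#: Minimum paired observations for a gene to enter selection (4 df).
MIN_ORTHOLOGUES = 6


class ZeroVarianceError(ValueError):
    """Correlation is undefined because one vector is constant."""


@dataclass
class CorrelationResult:
    """Per-gene selection outcome (the row type of the results table)."""

    human_symbol: str
    cohort: Cohort
    n: int
    r: float
    r_crit: float
    selected: bool
    df_by_species: dict[str, float] = field(default_factory=dict)


def assign_cohort(oset: OrthologueSet, ciona_cohort: bool = False) -> Cohort:
    """First-seen cohort of an orthologue group.

    Worm-first if a one-to-one C. elegans orthologue exists; else fly-first if
    a one-to-one D. melanogaster orthologue exists; else vertebrate if all six
    vertebrates have one-to-one orthologues; else unassigned (excluded).
    ``ciona_cohort=True`` additionally routes Ciona-first genes into a
    seven-species cohort instead of leaving them unassigned.
    """
    one_to_one = {sid for sid, rec in oset.records.items() if rec.one_to_one}
    if WORM in one_to_one:
        return Cohort.WORM_FIRST
    if FLY in one_to_one:
        return Cohort.FLY_FIRST
    if ciona_cohort and CIONA in one_to_one:
        return Cohort.CIONA_FIRST
    if all(v in one_to_one for v in VERTEBRATES):
        return Cohort.VERTEBRATE
    return Cohort.UNASSIGNED


def contributing_species(oset: OrthologueSet, cohort: Cohort) -> tuple[str, ...]:
    """Species whose records enter the gene's correlation vector.

    Only one-to-one records count. The vertebrate cohort is restricted to
    exactly the six vertebrate species even if an invertebrate record exists
    without orthology support for an earlier cohort.
    """
    one_to_one = tuple(
        sid for sid, rec in sorted(oset.records.items()) if rec.one_to_one
    )
    if cohort is Cohort.VERTEBRATE:
        return tuple(sid for sid in one_to_one if sid in VERTEBRATES)
    if cohort is Cohort.CIONA_FIRST:
        return tuple(sid for sid in one_to_one if sid in VERTEBRATES or sid == CIONA)
    return one_to_one


def eligible(oset: OrthologueSet) -> bool:
    """True when the group can enter selection: assigned cohort, >= 6 orthologues.

    The vertebrate cohort requires exactly the six vertebrate species (n = 6).
    """
    if oset.cohort is Cohort.UNASSIGNED:
        return False
    if oset.cohort is Cohort.VERTEBRATE:
        return set(oset.contributing_species) == set(VERTEBRATES)
    return oset.n_orthologues >= MIN_ORTHOLOGUES


def build_orthologue_sets(
    records: Iterable[GeneRecord],
    ciona_cohort: bool = False,
) -> list[OrthologueSet]:
    """Group records by human symbol and assign cohorts.

    Groups without a human record are dropped with a warning (the human gene
    indexes the orthologue group). At most one record per species is allowed.
    """
    by_symbol: dict[str, dict[str, GeneRecord]] = {}
    for rec in records:
        slot = by_symbol.setdefault(rec.human_symbol, {})
        if rec.species_id in slot:
            raise ValueError(
                f"orthologue group {rec.human_symbol!r}: two records for "
                f"species {rec.species_id!r}"
            )
        slot[rec.species_id] = rec
    osets = []
    for symbol in sorted(by_symbol):
        recs = by_symbol[symbol]
        if HUMAN not in recs:
            logger.warning("orthologue group %r has no human record; dropped", symbol)
            continue
        oset = OrthologueSet(human_symbol=symbol, records=recs)
        oset.cohort = assign_cohort(oset, ciona_cohort=ciona_cohort)
        oset.contributing_species = contributing_species(oset, oset.cohort)
        osets.append(oset)
    return osets


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length vectors.

    Requires n >= 3; raises :class:`ZeroVarianceError` when either vector is
    constant (the correlation is undefined, and callers exclude the gene).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    r = float(np.sum(xc * yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson correlation at level ``alpha`` for n pairs.

    r_crit = t_c / sqrt(t_c^2 + df) with df = n - 2 and t_c the two-tailed
    alpha quantile of Student's t on df degrees of freedom. Monotonically
    decreasing in n.
    """
    if n < 3:
        raise ValueError(f"critical_r needs n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = n - 2
    t_c = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return t_c / math.sqrt(t_c * t_c + df)


def correlate_and_select(
    osets: Sequence[OrthologueSet],
    scores: Iterable[DiversityScore],
    species: SpeciesTable,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate D_F with cell-type number for every eligible orthologue group.

    For each eligible group, the (C_s, D_F) pairs over its contributing species
    are correlated; the gene is selected when r exceeds the unrounded boundary
    r_crit(n) (strict inequality, positive tail only). Groups with a missing
    score or constant D_F are excluded with a logged reason. Results are sorted
    by human symbol.
    """
    score_index: dict[tuple[str, str], float] = {}
    for s in scores:
        score_index[(s.human_symbol, s.species_id)] = s.df_value

    results: list[CorrelationResult] = []
    for oset in sorted(osets, key=lambda o: o.human_symbol):
        if not eligible(oset):
            continue
        df_by_species: dict[str, float] = {}
        missing = []
        for sid in oset.contributing_species:
            key = (oset.human_symbol, sid)
            if key not in score_index:
                missing.append(sid)
            else:
                df_by_species[sid] = score_index[key]
        if missing:
            logger.warning(
                "gene %r: no D_F score for contributing species %s; excluded",
                oset.human_symbol, missing,
            )
            continue
        xs = [float(species.cell_types(sid)) for sid in oset.contributing_species]
        ys = [df_by_species[sid] for sid in oset.contributing_species]
        try:
            r = pearson_r(xs, ys)
        except ZeroVarianceError:
            logger.info("gene %r: constant D_F vector; excluded", oset.human_symbol)
            continue
        n = len(xs)
        r_crit = critical_r(n, alpha)
        results.append(
            CorrelationResult(
                human_symbol=oset.human_symbol,
                cohort=oset.cohort,
                n=n,
                r=r,
                r_crit=r_crit,
                selected=bool(r > r_crit),
                df_by_species=df_by_species,
            )
        )
    return results


def cohort_summary(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Cohort x orthologue-count summary of the selection (Table-1 shape).

    Columns: cohort, n_orthologues, r_crit_2dp, genes_selected. The 2-dp
    rounding of r_crit is presentational; selection always compares against
    the unrounded boundary.
    """
    rows: dict[tuple[str, int], dict] = {}
    for res in results:
        key = (str(res.cohort), res.n)
        slot = rows.setdefault(
            key,
            {
                "cohort": str(res.cohort),
                "n_orthologues": res.n,
                "r_crit_2dp": round(res.r_crit, 2),
                "genes_selected": 0,
            },
        )
        if res.selected:
            slot["genes_selected"] += 1
    order = {c.value: i for i, c in enumerate(Cohort)}
    frame = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (order.get(r["cohort"], 99), -r["n_orthologues"])),
        columns=["cohort", "n_orthologues", "r_crit_2dp", "genes_selected"],
    )
    return frame


def selected_symbols(results: Sequence[CorrelationResult]) -> set[str]:
    """Convenience: the set of selected human symbols."""
    return {res.human_symbol for res in results if res.selected}
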