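"""Synthetic Ensembl-like datasets with planted statistical structure.

The generator emulates the real inputs of the analysis — per-species gene
annotation tables, a term-annotation table and an interaction edge list —
with controllable signal, so every pipeline stage can be exercised and
validated without any database access.

Latent model. For each gene, a latent per-species diversity target

    d*_s = mu + b * z(C_s) + eps_s,    eps_s ~ N(0, sigma^2)

is drawn, where z(C_s) is the standardised log cell-type number of species s
(log spacing stops the two primates, which share C = 171, from dominating
leverage). For signal genes the slope is calibrated per gene,

    b = sigma_eff * rho / (sqrt(1 - rho^2) * sd(z over the gene's species)),

with sigma_eff^2 = sigma^2 + 1/12 folding in the count-realisation error, so
that the correlation target rho refers to the realised (C, D_F) pairs of the
species the gene actually has — a vertebrate-only gene sees a much narrower
complexity spread than a worm-to-human gene and gets a steeper slope. For
null genes b = 0. The latent target is
then realised into integer counts by allocating the log2 budget to the
isoform count first, then the per-isoform motif counts, with the paralogue
term absorbing the rounding residual — isoforms are the major contributor to
the diversity score, and this order preserves that. The realised record's
D_F is guaranteed within one log2 unit of d*_s; negative targets clamp to
the all-ones record.

Cohort structure (which species carry an orthologue) and per-species dropout
are planted per gene, respecting each cohort's minimum orthologue count.
Planted annotation terms cover a chosen fraction of signal genes against a
background rate, and planted interaction cliques receive high-confidence
scores (>= 0.7) while noise edges stay below the confidence threshold.

All randomness flows from one seeded numpy Generator; equal configurations
produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from funcdiv.data_model import (
    FLY,
    HUMAN,
    CIONA,
    VERTEBRATES,
    WORM,
    Cohort,
    GeneRecord,
    IsoformRecord,
    OrthologueSet,
    SpeciesTable,
    default_species_table,
    write_annotation_table,
    write_species_table,
    write_term_annotations,
)

MAX_ISOFORMS = 40  # cap keeps realised records within annotation-plausible range


@dataclass(frozen=True)
class PlantedTerm:
    """A term planted into the annotation table with known enrichment."""

    term_id: str
    signal_fraction: float   # probability a signal gene carries the term
    background_rate: float   # probability a background gene carries it


@dataclass(frozen=True)
class GeneSpec:
    """Which species carry the gene, and whether diversity tracks complexity."""

    human_symbol: str
    species_present: tuple[str, ...]
    signal: bool
    cohort: Cohort


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real analysis: ~2000 input genes of which roughly a
    tenth carry signal, nine species, cohort proportions matching the
    worm-first / fly-first / vertebrate strata, four planted enriched terms
    (the enriched-set structure), and three planted interaction cliques of
    44, 8 and 6 genes (the three recovered networks).
    """

    seed: int = 0
    n_genes: int = 2000
    frac_signal: float = 0.1
    rho: float = 0.9
    cohort_mix: dict = field(
        default_factory=lambda: {
            Cohort.WORM_FIRST: 0.50,
            Cohort.FLY_FIRST: 0.25,
            Cohort.VERTEBRATE: 0.25,
        }
    )
    dropout: float = 0.1
    n_terms: int = 20
    planted_terms: tuple[PlantedTerm, ...] = (
        PlantedTerm("TERM_METH_HIST_BINDING", 0.60, 0.03),
        PlantedTerm("TERM_ANION_BINDING", 0.50, 0.05),
        PlantedTerm("TERM_HISTONE_MOD", 0.70, 0.04),
        PlantedTerm("TERM_CHROMATIN_MOD", 0.80, 0.02),
    )
    background_term_rate: float = 0.05
    clique_sizes: tuple[int, ...] = (44, 8, 6)
    noise_edge_rate: float = 0.001
    # Latent-model shape: baseline log2 diversity, residual sd, allocation
    # weights for the isoform / motif / paralogue components.
    mu: float = 10.0
    sigma: float = 1.5
    weights: tuple[float, float, float] = (0.45, 0.35, 0.20)  # (I, M, P)

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_signal <= 1.0:
            raise ValueError("frac_signal must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if any(s < 2 for s in self.clique_sizes):
            raise ValueError("clique sizes must be >= 2")
        for term in self.planted_terms:
            if not (0.0 <= term.signal_fraction <= 1.0 and 0.0 <= term.background_rate <= 1.0):
                raise ValueError(f"term {term.term_id!r}: proportions must be in [0, 1]")
        total = sum(self.cohort_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"cohort_mix must sum to 1, got {total}")


@dataclass
class SimResult:
    """A complete synthetic dataset plus the planted ground truth."""

    records: list[GeneRecord]
    truth: pd.DataFrame            # human_symbol, signal, cohort, n_species
    annotations: dict[str, set[str]]
    edges: pd.DataFrame            # gene_a, gene_b, score
    species: SpeciesTable
    config: SimConfig

    @property
    def signal_symbols(self) -> set[str]:
        return set(self.truth.loc[self.truth["signal"], "human_symbol"])


# ---------------------------------------------------------------------------
# Latent model and count realisation

def _z_complexity(species: SpeciesTable) -> dict[str, float]:
    """Standardised log cell-type number per species."""
    ids = species.species_ids
    logc = np.log([species.cell_types(s) for s in ids])
    z = (logc - logc.mean()) / logc.std()
    return dict(zip(ids, z))


def _nearest_log2_int(target: float, lo: int = 1, hi: int | None = None) -> int:
    """Integer >= lo whose log2 is nearest to ``target``."""
    raw = 2.0 ** max(target, 0.0)
    lo_c = max(lo, int(math.floor(raw)))
    hi_c = max(lo, int(math.ceil(raw)))
    if hi is not None:
        lo_c, hi_c = min(lo_c, hi), min(hi_c, hi)
    if lo_c == hi_c:
        return lo_c
    return min((lo_c, hi_c), key=lambda c: abs(math.log2(c) - target))


def realise_counts(target: float, weights: tuple[float, float, float]) -> tuple[int, int, list[int]]:
    """Realise a latent log2 budget into (P, I, per-isoform M) counts.

    Allocation order: isoform count first, then the paralogue share, then the
    motif budget spread greedily over the isoforms so rounding errors cancel.
    The realised D_F is within one log2 unit of the (non-negative) target;
    negative targets clamp to the all-ones record.
    """
    w_i, w_m, w_p = weights
    if target <= 0.0:
        return 1, 1, [1]
    i_count = _nearest_log2_int(w_i * target, hi=MAX_ISOFORMS)
    remaining = target - math.log2(i_count)
    p_share = (w_p / (w_p + w_m)) * max(remaining, 0.0)
    p_count = _nearest_log2_int(p_share)
    remaining -= math.log2(max(p_count, 1))
    motifs = []
    for left in range(i_count, 0, -1):
        per = max(remaining, 0.0) / left
        m = _nearest_log2_int(per)
        motifs.append(m)
        remaining -= math.log2(m)
    return p_count, i_count, motifs


def simulate_gene(
    spec: GeneSpec,
    species: SpeciesTable,
    rho: float,
    rng: np.random.Generator,
    mu: float = 10.0,
    sigma: float = 1.5,
    weights: tuple[float, float, float] = (0.45, 0.35, 0.20),
) -> OrthologueSet:
    """Draw one orthologue set with realised integer counts.

    Signal genes get slope b = sigma * rho / sqrt(1 - rho^2) against the
    standardised log complexity axis; null genes get b = 0.
    """
    z = _z_complexity(species)
    z_sub = [z[s] for s in spec.species_present]
    z_mean = float(np.mean(z_sub))
    z_sd = float(np.std(z_sub))
    if spec.signal and rho > 0 and z_sd > 0:
        # Calibrate the slope against the complexity spread of THIS gene's
        # species and against the total noise (residual plus ~Uniform(-1/2,
        # 1/2) count-realisation error), so corr(C, D_F) over the realised
        # pairs targets rho regardless of cohort.
        sigma_eff = math.sqrt(sigma * sigma + 1.0 / 12.0)
        b = sigma_eff * rho / (math.sqrt(1.0 - rho * rho) * z_sd)
    else:
        b = 0.0
    records: dict[str, GeneRecord] = {}
    for sid in species.species_ids:
        if sid not in spec.species_present:
            continue
        latent = mu + b * (z[sid] - z_mean) + sigma * rng.standard_normal()
        p, i, motifs = realise_counts(latent, weights)
        records[sid] = GeneRecord(
            gene_id=f"{sid}_{spec.human_symbol}",
            species_id=sid,
            human_symbol=spec.human_symbol,
            paralogue_count=p,
            isoforms=tuple(
                IsoformRecord(f"{sid}_{spec.human_symbol}_iso{j + 1:02d}", m)
                for j, m in enumerate(motifs)
            ),
            one_to_one=True,
        )
    oset = OrthologueSet(human_symbol=spec.human_symbol, records=records)
    oset.cohort = spec.cohort
    oset.contributing_species = tuple(
        sid for sid in species.species_ids if sid in records
    )
    return oset


# ---------------------------------------------------------------------------
# Cohort / dropout structure

_OPTIONAL = {
    # cohort -> (required species, droppable species)
    Cohort.WORM_FIRST: ((WORM, HUMAN), (FLY, CIONA) + VERTEBRATES[:-1]),
    Cohort.FLY_FIRST: ((FLY, HUMAN), (CIONA,) + VERTEBRATES[:-1]),
    Cohort.VERTEBRATE: (VERTEBRATES, ()),
}


def _draw_species_presence(
    cohort: Cohort, dropout: float, rng: np.random.Generator
) -> tuple[str, ...]:
    """Species carrying the gene, respecting the cohort's minimum of six."""
    required, optional = _OPTIONAL[cohort]
    kept = [s for s in optional if rng.random() >= dropout]
    minimum = 6
    dropped = [s for s in optional if s not in kept]
    while len(required) + len(kept) < minimum and dropped:
        idx = int(rng.integers(len(dropped)))
        kept.append(dropped.pop(idx))
    return tuple(s for s in (list(required) + kept))


# ---------------------------------------------------------------------------
# Annotations and edges

def simulate_annotations(
    genes: Sequence[str],
    signal_genes: set[str],
    planted_terms: Sequence[PlantedTerm],
    rng: np.random.Generator,
    n_background_terms: int = 0,
    background_term_rate: float = 0.05,
) -> dict[str, set[str]]:
    """Assign terms to genes: planted terms by signal status, background at random."""
    annotations: dict[str, set[str]] = {}
    for term in planted_terms:
        for gene in genes:
            rate = term.signal_fraction if gene in signal_genes else term.background_rate
            if rng.random() < rate:
                annotations.setdefault(gene, set()).add(term.term_id)
    for t in range(n_background_terms):
        term_id = f"TERM_BG{t + 1:03d}"
        for gene in genes:
            if rng.random() < background_term_rate:
                annotations.setdefault(gene, set()).add(term_id)
    return annotations


def simulate_edges(
    genes: Sequence[str],
    clique_sizes: Sequence[int],
    noise_edge_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Edge list with planted high-confidence cliques plus sub-threshold noise.

    Cliques are planted over the leading genes of ``genes`` in order (callers
    put the genes that should cluster first); within-clique scores are uniform
    in [0.7, 1.0], noise-edge scores uniform in [0, 0.7), so noise never
    survives the high-confidence filter. ``noise_edge_rate`` is the per-pair
    probability of a noise edge.
    """
    if sum(clique_sizes) > len(genes):
        raise ValueError("clique sizes exceed the number of genes")
    rows = []
    start = 0
    clique_pairs = set()
    for size in clique_sizes:
        members = genes[start:start + size]
        start += size
        for i in range(size):
            for j in range(i + 1, size):
                a, b = members[i], members[j]
                clique_pairs.add(frozenset((a, b)))
                rows.append((a, b, 0.7 + 0.3 * rng.random()))
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    if noise_edge_rate > 0 and n_pairs:
        n_noise = int(rng.binomial(n_pairs, noise_edge_rate))
        for _ in range(n_noise):
            i, j = rng.choice(n, size=2, replace=False)
            a, b = genes[int(i)], genes[int(j)]
            if frozenset((a, b)) in clique_pairs:
                continue
            rows.append((a, b, 0.7 * rng.random()))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).astype(
        {"score": float}
    )


# ---------------------------------------------------------------------------
# Full dataset

def simulate_dataset(config: SimConfig, species: SpeciesTable | None = None) -> SimResult:
    """Generate a complete dataset under one seed.

    Signal genes are placed first in the symbol order so that planted
    interaction cliques (which occupy the leading labels) fall among them.
    """
    species = species if species is not None else default_species_table()
    rng = np.random.default_rng(config.seed)

    n_signal = int(round(config.n_genes * config.frac_signal))
    cohorts = list(config.cohort_mix)
    probs = np.array([config.cohort_mix[c] for c in cohorts], dtype=float)
    probs /= probs.sum()

    specs: list[GeneSpec] = []
    for g in range(config.n_genes):
        symbol = f"G{g + 1:05d}"
        signal = g < n_signal
        cohort = cohorts[int(rng.choice(len(cohorts), p=probs))]
        present = _draw_species_presence(cohort, config.dropout, rng)
        specs.append(GeneSpec(symbol, present, signal, cohort))

    records: list[GeneRecord] = []
    truth_rows = []
    for spec in specs:
        oset = simulate_gene(
            spec, species, config.rho, rng,
            mu=config.mu, sigma=config.sigma, weights=config.weights,
        )
        records.extend(oset.records[sid] for sid in oset.contributing_species)
        truth_rows.append(
            {
                "human_symbol": spec.human_symbol,
                "signal": spec.signal,
                "cohort": str(spec.cohort),
                "n_species": len(spec.species_present),
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["human_symbol", "signal", "cohort", "n_species"])

    symbols = [s.human_symbol for s in specs]
    signal_set = {s.human_symbol for s in specs if s.signal}
    annotations = simulate_annotations(
        symbols, signal_set, config.planted_terms, rng,
        n_background_terms=max(0, config.n_terms - len(config.planted_terms)),
        background_term_rate=config.background_term_rate,
    )
    edges = simulate_edges(symbols, config.clique_sizes, config.noise_edge_rate, rng)
    return SimResult(
        records=records, truth=truth, annotations=annotations,
        edges=edges, species=species, config=config,
    )


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact TSV dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "species": outdir / "species.tsv",
        "terms": outdir / "terms.tsv",
        "edges": outdir / "edges.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_annotation_table(result.records, paths["annotations"])
    write_species_table(result.species, paths["species"])
    write_term_annotations(result.annotations, paths["terms"])
    result.edges.assign(score=result.edges["score"].map("{:.6f}".format)).to_csv(
        paths["edges"], sep="\t", index=False
    )
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
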