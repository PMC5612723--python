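"""Domain types and readers/writers for the annotation, species, term and edge tables.

All exchange formats are flat UTF-8 TSV with a header row. The annotation table
carries one row per isoform, with the gene-level fields (paralogue count,
orthology flag, human-symbol index) repeated on every row of the gene; a JSON
dialect with nested isoform lists is accepted as an alternative. A species
table maps each genome to its cell-type number, the proxy for organismal
complexity, in fixed phylogenetic (clade) order from worm to human.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Canonical species identifiers for the nine-genome phylogeny.
WORM = "celegans"
FLY = "dmelanogaster"
CIONA = "cintestinalis"
HUMAN = "hsapiens"
VERTEBRATES = ("trubripes", "xtropicalis", "ggallus", "mmusculus", "mmulatta", HUMAN)

#: (species_id, cell_type_count, clade_rank) for the default nine metazoans,
#: cell-type numbers after Vogel & Chothia as used throughout the analysis.
DEFAULT_SPECIES = (
    (WORM, 29, 1),
    (FLY, 60, 2),
    (CIONA, 71, 3),
    ("trubripes", 114, 4),
    ("xtropicalis", 121, 5),
    ("ggallus", 150, 6),
    ("mmusculus", 157, 7),
    ("mmulatta", 171, 8),
    (HUMAN, 171, 9),
)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table violates a content invariant (bad value, duplicate row)."""


class Cohort(str, enum.Enum):
    """First-seen stratum of an orthologue set.

    The stratum is the earliest species in the worm-to-human phylogeny with a
    one-to-one orthologue of the human gene; it fixes which critical-value row
    the gene is tested against.
    """

    WORM_FIRST = "WORM_FIRST"
    FLY_FIRST = "FLY_FIRST"
    CIONA_FIRST = "CIONA_FIRST"  # opt-in seven-species cohort
    VERTEBRATE = "VERTEBRATE"
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class IsoformRecord:
    """One protein-coding isoform with its annotated domain/motif count M."""

    isoform_id: str
    motif_count: int

    def __post_init__(self) -> None:
        if self.motif_count < 0:
            raise ValidationError(
                f"isoform {self.isoform_id!r}: motif_count must be >= 0, "
                f"got {self.motif_count}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One gene in one species.

    ``paralogue_count`` is the within-species paralogue count with the gene
    itself excluded, so singleton genes carry P = 0. ``human_symbol`` indexes
    the orthologue group by the official human gene symbol. ``one_to_one``
    records whether the gene is annotated as the unique orthologue of the
    human gene; it is stored rather than recomputed (homology-type inference
    needs a live compara service) and is True by convention on human records.
    """

    gene_id: str
    species_id: str
    human_symbol: str
    paralogue_count: int
    isoforms: tuple[IsoformRecord, ...]
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.paralogue_count < 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: paralogue_count must be >= 0"
            )
        if len(self.isoforms) < 1:
            raise ValidationError(f"gene {self.gene_id!r}: needs >= 1 isoform")

    @property
    def isoform_count(self) -> int:
        """I, the number of protein-coding isoforms."""
        return len(self.isoforms)

    @property
    def motif_counts(self) -> tuple[int, ...]:
        """Per-isoform M values in stored order."""
        return tuple(iso.motif_count for iso in self.isoforms)


@dataclass(frozen=True)
class SpeciesTable:
    """Ordered species list with cell-type numbers (the complexity axis C_s)."""

    entries: tuple[tuple[str, int, int], ...]  # (species_id, cell_type_count, clade_rank)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValidationError(f"duplicate species entries: {dupes}")
        for sid, count, _rank in self.entries:
            if not isinstance(count, (int,)) or isinstance(count, bool) or count < 1:
                raise ValidationError(
                    f"species {sid!r}: cell_type_count must be a positive "
                    f"integer, got {count!r}"
                )

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in sorted(self.entries, key=lambda e: e[2]))

    def cell_types(self, species_id: str) -> int:
        for sid, count, _ in self.entries:
            if sid == species_id:
                return count
        raise KeyError(species_id)

    def __contains__(self, species_id: str) -> bool:
        return any(e[0] == species_id for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class OrthologueSet:
    """All records of one orthologue group, indexed by the human gene symbol."""

    human_symbol: str
    records: dict[str, GeneRecord]  # species_id -> record, at most one each
    cohort: Cohort = Cohort.UNASSIGNED
    contributing_species: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if HUMAN not in self.records:
            raise ValidationError(
                f"orthologue set {self.human_symbol!r}: human record required"
            )
        for sid, rec in self.records.items():
            if rec.species_id != sid:
                raise ValidationError(
                    f"orthologue set {self.human_symbol!r}: record keyed "
                    f"{sid!r} has species_id {rec.species_id!r}"
                )

    @property
    def n_orthologues(self) -> int:
        """Number of species contributing to the correlation vector."""
        return len(self.contributing_species)


def default_species_table() -> SpeciesTable:
    """The packaged nine-species table (C. elegans 29 ... H. sapiens 171)."""
    return SpeciesTable(entries=DEFAULT_SPECIES)


# ---------------------------------------------------------------------------
# Annotation tables

_ANNOTATION_COLUMNS = (
    "gene_id",
    "species_id",
    "human_symbol",
    "paralogue_count",
    "isoform_id",
    "motif_count",
    "one_to_one",
)

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"row {row}: column {column!r} has non-boolean value {value!r}")


def _parse_count(value, column: str, row: int) -> int:
    try:
        number = int(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"row {row}: column {column!r} has non-integer value {value!r}"
        ) from exc
    if number < 0:
        raise ValidationError(f"row {row}: column {column!r} is negative ({number})")
    return number


def read_annotation_table(path: str | Path, format: str | None = None) -> list[GeneRecord]:
    """Read a per-isoform annotation table into grouped :class:`GeneRecord`\\ s.

    ``format`` is ``"tsv"`` or ``"json"``; when omitted it is inferred from the
    file suffix (``.json`` means JSON, anything else TSV). Row order within the
    file does not affect the result: rows are grouped by (species, gene) and
    isoforms kept in first-appearance order after a stable sort on isoform id.

    If a ``protein_coding`` column is present, rows flagged false are dropped
    before grouping, so only protein-coding isoforms enter I and the M sum.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        return _read_annotation_json(path)
    if format != "tsv":
        raise ValueError(f"unknown annotation format {format!r}")
    return _read_annotation_tsv(path)


def _read_annotation_tsv(path: Path) -> list[GeneRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"annotation table {path} is missing column(s): {missing}")
    rows = []
    for i, raw in enumerate(frame.itertuples(index=False), start=2):  # 1 = header line
        row = raw._asdict()
        if "protein_coding" in frame.columns and not _parse_bool(
            row["protein_coding"], "protein_coding", i
        ):
            continue
        rows.append(
            {
                "gene_id": row["gene_id"],
                "species_id": row["species_id"],
                "human_symbol": row["human_symbol"],
                "paralogue_count": _parse_count(row["paralogue_count"], "paralogue_count", i),
                "isoform_id": row["isoform_id"],
                "motif_count": _parse_count(row["motif_count"], "motif_count", i),
                "one_to_one": _parse_bool(row["one_to_one"], "one_to_one", i),
                "_row": i,
            }
        )
    return _group_rows(rows)


def _group_rows(rows: list[dict]) -> list[GeneRecord]:
    seen: set[tuple[str, str, str]] = set()
    grouped: dict[tuple[str, str], list[dict]] = {}
    for row in rows:
        key3 = (row["species_id"], row["gene_id"], row["isoform_id"])
        if key3 in seen:
            raise ValidationError(
                f"row {row['_row']}: duplicate (species_id, gene_id, isoform_id) {key3}"
            )
        seen.add(key3)
        grouped.setdefault((row["species_id"], row["gene_id"]), []).append(row)

    records = []
    for (species_id, gene_id), group in sorted(grouped.items()):
        group = sorted(group, key=lambda r: r["isoform_id"])
        first = group[0]
        for row in group[1:]:
            for column in ("human_symbol", "paralogue_count", "one_to_one"):
                if row[column] != first[column]:
                    raise ValidationError(
                        f"gene {gene_id!r} in {species_id!r}: inconsistent "
                        f"{column} across isoform rows"
                    )
        records.append(
            GeneRecord(
                gene_id=gene_id,
                species_id=species_id,
                human_symbol=first["human_symbol"],
                paralogue_count=first["paralogue_count"],
                isoforms=tuple(
                    IsoformRecord(r["isoform_id"], r["motif_count"]) for r in group
                ),
                one_to_one=first["one_to_one"],
            )
        )
    return records


def _read_annotation_json(path: Path) -> list[GeneRecord]:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    rows = []
    for g, gene in enumerate(payload):
        for key in ("gene_id", "species_id", "human_symbol", "paralogue_count", "isoforms"):
            if key not in gene:
                raise SchemaError(f"gene entry {g}: missing field {key!r}")
        for iso in gene["isoforms"]:
            if "isoform_id" not in iso or "motif_count" not in iso:
                raise SchemaError(
                    f"gene {gene['gene_id']!r}: isoform entries need "
                    "isoform_id and motif_count"
                )
            if not iso.get("protein_coding", True):
                continue
            rows.append(
                {
                    "gene_id": gene["gene_id"],
                    "species_id": gene["species_id"],
                    "human_symbol": gene["human_symbol"],
                    "paralogue_count": _parse_count(gene["paralogue_count"], "paralogue_count", g),
                    "isoform_id": iso["isoform_id"],
                    "motif_count": _parse_count(iso["motif_count"], "motif_count", g),
                    "one_to_one": _parse_bool(gene.get("one_to_one", True), "one_to_one", g),
                    "_row": g,
                }
            )
    return _group_rows(rows)


def write_annotation_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords back to the flat per-isoform TSV dialect."""
    rows = []
    for rec in records:
        for iso in rec.isoforms:
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "species_id": rec.species_id,
                    "human_symbol": rec.human_symbol,
                    "paralogue_count": rec.paralogue_count,
                    "isoform_id": iso.isoform_id,
                    "motif_count": iso.motif_count,
                    "one_to_one": rec.one_to_one,
                }
            )
    frame = pd.DataFrame(rows, columns=list(_ANNOTATION_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Species tables

def read_species_table(path: str | Path) -> SpeciesTable:
    """Read a species table TSV (species_id, cell_type_count, clade_rank)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("species_id", "cell_type_count", "clade_rank") if c not in frame.columns]
    if missing:
        raise SchemaError(f"species table {path} is missing column(s): {missing}")
    if len(frame) < 2:
        raise ValidationError("species table needs at least two species")
    entries = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        count = _parse_count(row.cell_type_count, "cell_type_count", i)
        if count < 1:
            raise ValidationError(f"row {i}: cell_type_count must be positive")
        entries.append((row.species_id, count, int(row.clade_rank)))
    entries.sort(key=lambda e: e[2])
    return SpeciesTable(entries=tuple(entries))


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(table.entries, key=lambda e: e[2]),
        columns=["species_id", "cell_type_count", "clade_rank"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Term annotations and edge lists

def read_term_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (gene_symbol, term_id) into a gene -> terms mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("gene_symbol", "term_id") if c not in frame.columns]
    if missing:
        raise SchemaError(f"term table {path} is missing column(s): {missing}")
    mapping: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        mapping.setdefault(row.gene_symbol, set()).add(row.term_id)
    return mapping


def write_term_annotations(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"gene_symbol": gene, "term_id": term}
        for gene in sorted(mapping)
        for term in sorted(mapping[gene])
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "term_id"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an interaction edge list TSV (gene_a, gene_b, score in [0, 1])."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "score": float})
    missing = [c for c in ("gene_a", "gene_b", "score") if c not in frame.columns]
    if missing:
        raise SchemaError(f"edge list {path} is missing column(s): {missing}")
    bad = frame.index[(frame["score"] < 0) | (frame["score"] > 1)]
    if len(bad):
        raise ValidationError(
            f"edge list {path}: score outside [0, 1] at row(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"
        )
    return frame


def write_edge_list(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Per-gene results table

_RESULT_FIXED = ("human_symbol", "cohort", "n_orthologues", "r", "r_crit", "selected")


def write_results_table(results: Sequence, path: str | Path, species: SpeciesTable | None = None) -> None:
    """Write per-gene correlation results to TSV.

    One row per gene: human_symbol, cohort, n_orthologues, one ``df_<species>``
    column per species (blank where the species does not contribute), r,
    r_crit, selected. Numeric values are written at 6 decimal places, so a
    write-then-read round trip preserves them to that precision.
    """
    species = species if species is not None else default_species_table()
    df_cols = [f"df_{sid}" for sid in species.species_ids]
    rows = []
    for res in results:
        row = {
            "human_symbol": res.human_symbol,
            "cohort": str(res.cohort),
            "n_orthologues": res.n,
            "r": "" if res.r is None else f"{res.r:.6f}",
            "r_crit": "" if res.r_crit is None else f"{res.r_crit:.6f}",
            "selected": str(bool(res.selected)).lower(),
        }
        for sid in species.species_ids:
            value = res.df_by_species.get(sid)
            row[f"df_{sid}"] = "" if value is None else f"{value:.6f}"
        rows.append(row)
    columns = list(_RESULT_FIXED[:3]) + df_cols + list(_RESULT_FIXED[3:])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back; df_* / r columns as floats, selected as bool."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _RESULT_FIXED if c not in frame.columns]
    if missing:
        raise SchemaError(f"results table {path} is missing column(s): {missing}")
    out = frame.copy()
    out["n_orthologues"] = out["n_orthologues"].astype(int)
    for column in [c for c in frame.columns if c.startswith("df_")] + ["r", "r_crit"]:
        out[column] = pd.to_numeric(out[column].replace("", pd.NA))
    out["selected"] = frame["selected"].str.lower().isin(_TRUTHY)
    return out
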