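"""Term over/under-representation among selected genes.

Each annotation term defines a 2x2 table: of N reference genes, K carry the
term; of the n selected genes, k carry it. Fold enrichment is the ratio of the
term's frequency in the selection to its frequency in the reference,
(k/n)/(K/N), and significance is the exact hypergeometric tail (one-sided
Fisher test) — the standard over-representation test. A term is flagged
enriched when fold > 2.5 and the upper-tail p < 0.05 (both strict), and
depleted when fold < 1 with lower-tail p < 0.05. No multiple-testing
correction is applied by default (raw p plus the fold filter); optional
Benjamini-Hochberg is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

#: Sentinel fold value for terms absent from the reference (K = 0).
UNDEFINED_FOLD = math.nan


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2x2 counts, fold enrichment and tail probabilities."""

    term_id: str
    k: int          # selected genes with the term
    n: int          # selected genes total
    K: int          # reference genes with the term
    N: int          # reference genes total
    fold: float
    p_over: float
    p_under: float
    enriched: bool
    depleted: bool

    @property
    def p_value(self) -> float:
        """The tail probability in the flagged (or smaller-tail) direction."""
        if self.depleted:
            return self.p_under
        return self.p_over

    @property
    def direction(self) -> str:
        return "under" if self.fold < 1 else "over"


def _check_bounds(k: int, n: int, K: int, N: int) -> None:
    # op-level bounds: k <= n and K <= N; k > K is tolerated as a ratio
    # (impossible as a draw, and the tail probabilities degenerate to 0/1)
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent 2x2 counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= n <= N and 0 <= K <= N)"
        )


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Fold enrichment (k/n)/(K/N); NaN when the term is absent from the reference."""
    if n < 1 or N < 1:
        raise ValueError(f"need n >= 1 and N >= 1, got n={n}, N={N}")
    _check_bounds(k, n, K, N)
    if K == 0:
        return UNDEFINED_FOLD
    return (k / n) / (K / N)


def hypergeom_p(k: int, n: int, K: int, N: int, direction: str = "over") -> float:
    """Exact hypergeometric tail probability for the 2x2 overlap.

    ``over``: P(X >= k); ``under``: P(X <= k); X ~ hypergeometric with N
    genes, K carrying the term, n drawn. Exact tail sum — no normal
    approximation.
    """
    _check_bounds(k, n, K, N)
    dist = stats.hypergeom(N, K, n)
    if direction == "over":
        return float(min(1.0, dist.sf(k - 1)))
    if direction == "under":
        return float(min(1.0, dist.cdf(k)))
    raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")


def enrich_terms(
    selected: set[str],
    reference: set[str],
    annotations: Mapping[str, Iterable[str]],
    fold_min: float = 2.5,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotated term for over/under-representation in ``selected``.

    ``annotations`` maps gene symbols to their terms; genes outside the
    reference are ignored. One result is produced per term with K >= 1,
    sorted by ascending flagged-direction p (ties by term id). With
    ``fdr=True`` the flag thresholds are applied to Benjamini-Hochberg
    adjusted tail probabilities instead of raw ones.
    """
    offenders = sorted(selected - reference)
    if offenders:
        raise ValueError(
            f"selected genes missing from the reference set: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    N = len(reference)
    n = len(selected)
    if N < 1:
        raise ValueError("reference set is empty")

    term_ref: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in reference:
            continue
        for term in terms:
            term_ref.setdefault(term, set()).add(gene)
    if not term_ref:
        raise ValueError("annotations cover no reference gene")

    raw: list[tuple[str, int, int, float, float, float]] = []
    for term in sorted(term_ref):
        members = term_ref[term]
        K = len(members)
        k = len(members & selected)
        fold = fold_enrichment(k, n, K, N) if n >= 1 else UNDEFINED_FOLD
        p_over = hypergeom_p(k, n, K, N, "over")
        p_under = hypergeom_p(k, n, K, N, "under")
        raw.append((term, k, K, fold, p_over, p_under))

    if fdr:
        from statsmodels.stats.multitest import multipletests

        adj_over = multipletests([r[4] for r in raw], method="fdr_bh")[1]
        adj_under = multipletests([r[5] for r in raw], method="fdr_bh")[1]
    else:
        adj_over = [r[4] for r in raw]
        adj_under = [r[5] for r in raw]

    results = []
    for (term, k, K, fold, p_over, p_under), q_over, q_under in zip(raw, adj_over, adj_under):
        enriched = bool(not math.isnan(fold) and fold > fold_min and q_over < alpha)
        depleted = bool(not math.isnan(fold) and fold < 1.0 and q_under < alpha)
        results.append(
            EnrichmentResult(
                term_id=term, k=k, n=n, K=K, N=N, fold=fold,
                p_over=p_over, p_under=p_under,
                enriched=enriched, depleted=depleted,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def union_enriched_genes(
    results: Sequence[EnrichmentResult],
    annotations: Mapping[str, Iterable[str]],
    selected: set[str],
) -> tuple[set[str], dict[str, set[str]]]:
    """Non-redundant union of selected genes across the enriched terms.

    Returns the union set and a per-term membership mapping (term -> selected
    genes carrying it) for Venn-style summaries. The union is never larger
    than the sum of the per-term counts.
    """
    per_term: dict[str, set[str]] = {}
    enriched_terms = {r.term_id for r in results if r.enriched}
    for gene, terms in annotations.items():
        if gene not in selected:
            continue
        for term in terms:
            if term in enriched_terms:
                per_term.setdefault(term, set()).add(gene)
    union: set[str] = set()
    for members in per_term.values():
        union |= members
    return union, per_term


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    """Enrichment TSV: term_id, k, n, K, N, fold, p_over, p_under, flag."""
    rows = []
    for r in results:
        flag = "enriched" if r.enriched else ("depleted" if r.depleted else "")
        rows.append(
            {
                "term_id": r.term_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "fold": "" if math.isnan(r.fold) else f"{r.fold:.6f}",
                "p_over": f"{r.p_over:.6g}", "p_under": f"{r.p_under:.6g}",
                "flag": flag,
            }
        )
    pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "fold", "p_over", "p_under", "flag"]
    ).to_csv(path, sep="\t", index=False)


def write_union_table(per_term: Mapping[str, set[str]], path) -> None:
    """Union TSV: gene_symbol, comma-joined contributing terms."""
    by_gene: dict[str, list[str]] = {}
    for term in sorted(per_term):
        for gene in per_term[term]:
            by_gene.setdefault(gene, []).append(term)
    rows = [
        {"gene_symbol": gene, "terms": ",".join(terms)}
        for gene, terms in sorted(by_gene.items())
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "terms"]).to_csv(path, sep="\t", index=False)
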