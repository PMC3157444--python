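"""Local gene-set over-representation analysis (DAVID-style reporting).

Per term, the p-value is the upper-tail hypergeometric probability of the
observed list/term overlap and fold enrichment is (count/list size) /
(population hits/population size). The reporting rule keeps terms with
p < 0.05 and fold enrichment > 2, ranked by descending overlap count.
An EASE-style conservative variant (one observed hit removed before taking
the tail) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom


@dataclass(frozen=True)
class GeneSetAnnotation:
    term_id: str
    name: str
    genes: frozenset[str]


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    count: int            # |list ∩ term|
    list_size: int
    population_hits: int  # |universe ∩ term|
    population_size: int
    fold_enrichment: float
    p_value: float
    passes: bool = False


def fisher_enrichment(gene_list, universe, annotations,
                      ease: bool = False) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each annotation term.

    ``gene_list`` must be a subset of ``universe``; term members are
    harmonized to the universe (terms with no member in the universe are
    dropped). With ``ease=True`` one hit is deducted from the overlap
    before taking the tail (DAVID's EASE score).
    """
    genes = set(gene_list)
    uni = set(universe)
    if not genes or not uni:
        raise ValueError("gene list and universe must be nonempty")
    stray = genes - uni
    if stray:
        raise ValueError(f"gene list not contained in universe: {sorted(stray)[:5]}")

    n, N = len(genes), len(uni)
    out = []
    for term in annotations:
        members = term.genes & uni
        K = len(members)
        if K == 0:
            continue
        k = len(genes & members)
        tail_at = k - 1 if ease else k
        p = 1.0 if tail_at <= 0 else float(hypergeom.sf(tail_at - 1, N, K, n))
        fold = (k / n) / (K / N)
        out.append(EnrichmentResult(
            term_id=term.term_id, name=term.name, count=k, list_size=n,
            population_hits=K, population_size=N,
            fold_enrichment=fold, p_value=p,
        ))
    return out


def filter_and_rank(results, p_cutoff: float = 0.05,
                    fold_cutoff: float = 2.0) -> list[EnrichmentResult]:
    """Strictly filter (p < p_cutoff AND fold > fold_cutoff), rank by count.

    Ties broken by ascending p, then term id.
    """
    kept = []
    for r in results:
        r.passes = r.p_value < p_cutoff and r.fold_enrichment > fold_cutoff
        if r.passes:
            kept.append(r)
    return sorted(kept, key=lambda r: (-r.count, r.p_value, r.term_id))
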