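"""Gene-set over-representation for pathogenically mutated gene lists.

Database-agnostic: gene sets arrive as GMT, the universe defaults to the
union of the supplied collection.  Each set is tested with the one-sided
(enrichment) hypergeometric tail — over-representation is directional; a
two-sided exact test is available behind a flag — and Benjamini-Hochberg
adjustment is applied across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .assoc_stats import bh_adjust, hypergeom_two_sided_p
from .cohort_model import GeneSet


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p_one_sided: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if self.overlap > min(self.list_size, self.set_size):
            raise ValueError("overlap exceeds list or set size")
        if self.p_adjusted < self.p_one_sided - 1e-15:
            raise ValueError("adjusted p below raw p")


def overrepresentation(gene_list: Iterable[str],
                       gene_sets: Sequence[GeneSet],
                       universe: Optional[Iterable[str]] = None,
                       two_sided: bool = False) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in ``gene_list``.

    The universe defaults to all genes appearing in the supplied gene-set
    collection.  Every set is intersected with the universe before testing;
    a list gene outside the universe is an error naming the gene.  Results
    are sorted by p (ties by set name).
    """
    genes = set(gene_list)
    if universe is None:
        uni = set().union(*(s.members for s in gene_sets)) if gene_sets else set()
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    for g in sorted(genes):
        if g not in uni:
            raise ValueError(f"list gene {g!r} not in universe")

    M = len(uni)
    n = len(genes)
    raw: list[tuple[str, int, int, float]] = []
    for s in gene_sets:
        members = s.members & uni
        K = len(members)
        k = len(genes & members)
        if two_sided:
            p = hypergeom_two_sided_p(k, n - k, K - k, M - K - (n - k))
        else:
            p = float(stats.hypergeom.sf(k - 1, M, K, n))
        raw.append((s.name, k, K, min(1.0, p)))
    adjusted = bh_adjust([p for *_, p in raw])
    results = [
        EnrichmentResult(set_name=name, overlap=k, list_size=n, set_size=K,
                         universe_size=M, p_one_sided=p, p_adjusted=q)
        for (name, k, K, p), q in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_one_sided, r.set_name))
    return results


ENRICHMENT_COLUMNS = ("set_name", "overlap", "list_size", "set_size",
                      "universe_size", "p_one_sided", "p_adjusted")


def write_enrichment(results: Iterable[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in results:
            fh.write(f"{r.set_name}\t{r.overlap}\t{r.list_size}\t{r.set_size}"
                     f"\t{r.universe_size}\t{r.p_one_sided:.6g}"
                     f"\t{r.p_adjusted:.6g}\n")
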