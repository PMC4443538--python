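"""Local over-representation analysis against GMT gene-set collections.

For a query gene list drawn from a background of N genes, a term with K
background members and k overlapping query genes gets the one-sided
upper-tail hypergeometric p-value P(X >= k).  The EASE variant removes
one overlapping gene before taking the tail (P(X >= k-1)), a deliberately
conservative score that penalizes single-gene overlaps.  Benjamini-
Hochberg q-values are computed across each collection, but the raw
p-value remains the primary column.

Enriched-term gene lists can be cross-tabulated against an expression
clustering: each overlapping gene is attributed to every cluster that
contains at least one of its probes, giving the per-term
"cluster (count)" breakdown and the modal-cluster percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cluster import Partition
from .errors import ConfigurationError, InputFormatError
from .gene_sets import ProbeGeneMap

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (a local stand-in for GO/KEGG/Reactome terms)."""

    sets: dict  # term -> set of gene symbols
    source: str = "custom"

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise InputFormatError(f"gene set {term!r} is empty")

    @classmethod
    def from_gmt(cls, path, source: str | None = None) -> "GeneSetCollection":
        """Read standard GMT: term <tab> description <tab> gene...."""
        sets: dict = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputFormatError(
                        f"{path}:{ln}: GMT line needs term, description, >=1 gene"
                    )
                term = parts[0]
                if term in sets:
                    raise InputFormatError(f"{path}:{ln}: duplicate term {term!r}")
                sets[term] = {g for g in parts[2:] if g}
        return cls(sets=sets, source=source or str(path))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term, genes in self.sets.items():
                fh.write("\t".join([term, self.source, *sorted(genes)]) + "\n")


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics and cluster breakdown."""

    term: str
    k: int  # query genes in the term
    n: int  # query size (within background)
    K: int  # term genes in the background
    N: int  # background size
    p_value: float
    ease_p: float
    q_value: float | None = None
    overlap: tuple = ()
    cluster_breakdown: dict = field(default_factory=dict)
    modal_cluster: int | None = None
    modal_pct: int | None = None


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    # P(X >= k) for X ~ Hypergeom(N, K, n); sf is P(X > k-1)
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeometric_enrichment(
    query,
    background,
    collection: GeneSetCollection,
    ease: bool = True,
) -> list[EnrichmentResult]:
    """One-sided over-representation test of every term in the collection.

    Query genes outside the background are dropped with a warning; term
    gene sets are intersected with the background before testing.
    Results are sorted by raw p-value.
    """
    background = set(background)
    if not background:
        raise ConfigurationError("background gene set is empty")
    query = set(query)
    outside = query - background
    if outside:
        log.warning(
            "%d query genes outside the background dropped (e.g. %s)",
            len(outside), sorted(outside)[0],
        )
    query &= background
    N, n = len(background), len(query)
    results = []
    for term, genes in collection.sets.items():
        term_bg = genes & background
        K = len(term_bg)
        overlap = tuple(sorted(query & term_bg))
        k = len(overlap)
        p = _upper_tail(k, N, K, n)
        ease_p = _upper_tail(max(k - 1, 0), N, K, n) if ease else p
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N,
                p_value=p, ease_p=ease_p, overlap=overlap,
            )
        )
    if results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def crosstab_clusters(
    results: list[EnrichmentResult],
    partition: Partition,
    mapping: ProbeGeneMap,
) -> list[EnrichmentResult]:
    """Attribute each term's overlapping genes to expression clusters.

    A gene belongs to a cluster if any of its probes does; a gene whose
    probes span clusters counts once in each.  The modal cluster is the
    one holding the most overlapping genes, reported with its share of
    the overlap rounded to a whole percent.
    """
    probe_cluster = partition.labels()
    gene_probes = mapping.probes_for_gene()
    for r in results:
        breakdown: dict = {}
        for gene in r.overlap:
            clusters = {
                int(probe_cluster[p])
                for p in gene_probes.get(gene, ())
                if p in probe_cluster.index
            }
            for c in clusters:
                breakdown[c] = breakdown.get(c, 0) + 1
        r.cluster_breakdown = dict(sorted(breakdown.items()))
        if breakdown:
            modal = max(breakdown, key=lambda c: (breakdown[c], -c))
            r.modal_cluster = modal
            r.modal_pct = round(100.0 * breakdown[modal] / len(r.overlap))
        else:
            r.modal_cluster = None
            r.modal_pct = None
    return results
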