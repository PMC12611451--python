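"""Pathway overrepresentation analysis for miRNA target-gene sets.

Given the pooled target genes of the selected hub miRNAs, each pathway is
tested with the one-sided hypergeometric (upper-tail) test against a
background universe, p-values are corrected with Benjamini-Hochberg FDR,
pathways are bucketed into biological categories by name keywords, and the
genes that recur across many significant pathways of a category are
flagged as that category's relevant genes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import (
    EnrichmentResult,
    PathwayCollection,
    ValidationError,
    normalize_gene_symbol,
)

logger = logging.getLogger("cerna")

#: Name substrings used to bucket pathways, derived from the enriched
#: pathway names reported for each category.  First match wins in
#: CATEGORY_PRIORITY order; all matching is case-insensitive after unicode
#: hyphens are mapped to ASCII.
DEFAULT_CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "asd_related": (
        "NOTCH", "AKT", "PTEN", "MECP2", "mTORC1", "RUNX2", "HOX", "PI3K", "PI5P",
    ),
    "replication": (
        "replicat", "HDR", "homologous", "strand exchange", "strand break",
        "ATM-mediated",
    ),
    "immune": (
        "interleukin", "NF-kB", "NF-kappaB", "interferon", "TNFR", "FCERI",
        "immunoregulatory", "TAK1", "dectin",
    ),
    "transcription": (
        "transcri", "mRNA", "RNA polymerase", "snRNA", "rRNA", "tRNA",
        "splicing", "SUMOylation", "translation", "nucleolus",
    ),
}

#: Fixed evaluation order so a name matching several categories is
#: categorized deterministically.
CATEGORY_PRIORITY: tuple[str, ...] = ("asd_related", "replication", "immune", "transcription")

_HYPHEN_TABLE = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


@dataclass(frozen=True)
class OraConfig:
    """Thresholds and keyword lists of the overrepresentation analysis.

    fdr_threshold
        BH-adjusted significance level (q < threshold).
    min_overlap_genes
        A pathway is only called significant when at least this many query
        genes fall in it ("enriched by at least 15 genes").
    relevance_cutoffs
        Per category, the minimum number of significant pathways a gene
        must enrich to count as relevant (3, except 2 for replication,
        whose gene sets are smaller).
    bh_over_all_pathways
        If True, the BH family size m is the full collection; the default
        counts only pathways actually tested (overlap k >= 1).
    """

    fdr_threshold: float = 0.05
    min_overlap_genes: int = 15
    category_keywords: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_KEYWORDS)
    )
    relevance_cutoffs: Mapping[str, int] = field(
        default_factory=lambda: {
            "transcription": 3,
            "immune": 3,
            "asd_related": 3,
            "replication": 2,
        }
    )
    bh_over_all_pathways: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold):
            raise ValidationError("fdr_threshold must be positive")
        if self.min_overlap_genes < 1:
            raise ValidationError("min_overlap_genes must be >= 1")
        for cat, kws in self.category_keywords.items():
            if not kws:
                raise ValidationError(f"category {cat!r} has no keywords")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), including k.

    X counts query hits in a pathway of size ``K`` when ``n`` query genes
    are drawn without replacement from a universe of ``N``.  Evaluated via
    the survival function, which works in log space internally, so tiny
    tail probabilities do not underflow to 0 prematurely.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"hypergeometric bounds violated: k={k} K={K} n={n} N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j>=i} min(1, p_(j) * m / j)`` on the sorted scale.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def run_ora(
    query_genes: Iterable[str],
    pathways: PathwayCollection,
    cfg: OraConfig | None = None,
) -> list[EnrichmentResult]:
    """Test every pathway with query overlap >= 1 for overrepresentation.

    The effective query is the intersection with the background; the BH
    family is the set of tested pathways (or the whole collection when
    ``bh_over_all_pathways``).  Significance requires both q below the FDR
    threshold and overlap of at least ``min_overlap_genes`` genes.
    """
    cfg = cfg or OraConfig()
    query = frozenset(normalize_gene_symbol(g) for g in query_genes)
    effective = query & pathways.background
    if not effective:
        raise ValidationError("query disjoint from background: nothing to test")
    n = len(effective)
    N = len(pathways.background)

    tested = []
    for p in pathways.pathways:
        k = len(effective & p.genes)
        if k >= 1:
            tested.append((p, k))
    if not tested:
        return []
    p_raw = [hypergeom_tail(k, len(p.genes), n, N) for p, k in tested]
    if cfg.bh_over_all_pathways:
        m_extra = len(pathways.pathways) - len(tested)
        q = bh_adjust(p_raw + [1.0] * m_extra)[: len(p_raw)]
    else:
        q = bh_adjust(p_raw)
    results = [
        EnrichmentResult(
            pathway_id=p.pathway_id,
            pathway_name=p.pathway_name,
            k=k,
            K=len(p.genes),
            n=n,
            N=N,
            p_raw=pr,
            q_bh=qv,
            significant=bool(qv < cfg.fdr_threshold and k >= cfg.min_overlap_genes),
        )
        for (p, k), pr, qv in zip(tested, p_raw, q)
    ]
    logger.info(
        "ORA: %d/%d pathways tested, %d significant (q<%g, k>=%d)",
        len(tested), len(pathways.pathways),
        sum(r.significant for r in results), cfg.fdr_threshold, cfg.min_overlap_genes,
    )
    return results


def categorize_pathway_name(name: str, cfg: OraConfig | None = None) -> str:
    """Category of a single pathway name by keyword match; ``other`` if none."""
    cfg = cfg or OraConfig()
    hay = name.translate(_HYPHEN_TABLE).lower()
    for cat in CATEGORY_PRIORITY:
        for kw in cfg.category_keywords.get(cat, ()):
            if kw.translate(_HYPHEN_TABLE).lower() in hay:
                return cat
    for cat in cfg.category_keywords:  # user-defined categories outside the fixed order
        if cat in CATEGORY_PRIORITY:
            continue
        for kw in cfg.category_keywords[cat]:
            if kw.translate(_HYPHEN_TABLE).lower() in hay:
                return cat
    return "other"


def categorize_pathways(
    results: Sequence[EnrichmentResult], cfg: OraConfig | None = None
) -> list[EnrichmentResult]:
    """Assign each result its pathway category (first match wins)."""
    cfg = cfg or OraConfig()
    return [
        dataclasses.replace(r, category=categorize_pathway_name(r.pathway_name, cfg))
        for r in results
    ]


def select_relevant_genes(
    results: Sequence[EnrichmentResult],
    pathways: PathwayCollection,
    cfg: OraConfig | None = None,
    query_genes: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Per category, the query genes recurring across enough significant pathways.

    A gene counts toward a category once per significant pathway of that
    category containing it; genes meeting the category's relevance cutoff
    are retained.  Restricting to query genes (when given) keeps pathway
    bystander genes out.
    """
    cfg = cfg or OraConfig()
    by_id = {p.pathway_id: p for p in pathways.pathways}
    query = (
        frozenset(normalize_gene_symbol(g) for g in query_genes)
        if query_genes is not None
        else None
    )
    out: dict[str, frozenset[str]] = {}
    for cat, cutoff in cfg.relevance_cutoffs.items():
        counts: dict[str, int] = {}
        for r in results:
            if not r.significant or r.category != cat:
                continue
            genes = by_id[r.pathway_id].genes
            if query is not None:
                genes = genes & query
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        out[cat] = frozenset(g for g, c in counts.items() if c >= cutoff)
    return out
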