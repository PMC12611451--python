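"""Risk-gene overlap, tripartite network assembly and coverage ranking.

The last stage of the workflow: intersect each group's relevant genes with
a risk catalog, take the two-group overlap (Venn), restrict the
circRNA->miRNA->gene relations to those shared genes, and ask which
circRNAs' sponged miRNAs collectively regulate all of them — the
"full-cover" candidates — plus which of a candidate's miRNAs are also
sponged by the other group's circRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .io_model import (
    CeRNANetwork,
    CoverageEntry,
    CoverageReport,
    RiskGeneCatalog,
    SpongeMap,
    TargetMap,
    ValidationError,
    normalize_gene_symbol,
)

logger = logging.getLogger("cerna")


@dataclass(frozen=True)
class VennResult:
    """Two-set partition: items only in A, in both, only in B."""

    a_only: frozenset[str]
    shared: frozenset[str]
    b_only: frozenset[str]
    labels: tuple[str, str] = ("A", "B")


@dataclass(frozen=True)
class MinCoverResult:
    """A set of circRNAs jointly covering the target genes."""

    circrnas: frozenset[str]
    exact: bool  # True: proven minimum; False: greedy approximation


def cross_reference_risk(genes: Iterable[str], catalog: RiskGeneCatalog) -> frozenset[str]:
    """Genes present in the risk catalog (after symbol normalization)."""
    return frozenset(
        g for g in (normalize_gene_symbol(x) for x in genes) if g in catalog.entries
    )


def venn(
    set_a: Iterable[str],
    set_b: Iterable[str],
    labels: tuple[str, str] = ("A", "B"),
) -> VennResult:
    """Partition two gene sets into A-only / shared / B-only."""
    a = frozenset(set_a)
    b = frozenset(set_b)
    return VennResult(a_only=a - b, shared=a & b, b_only=b - a, labels=labels)


def build_network(
    sponge: SpongeMap, targets: TargetMap, genes: Iterable[str]
) -> CeRNANetwork:
    """Tripartite network restricted to a gene set of interest.

    Keeps miRNA->gene edges landing in ``genes`` and circRNA->miRNA edges
    whose miRNA retains at least one gene edge, so no miRNA dangles.
    """
    gene_set = frozenset(normalize_gene_symbol(g) for g in genes)
    if not gene_set:
        raise ValidationError("build_network requires a non-empty gene set")
    mg = frozenset((m, g) for m, g in targets.edges if g in gene_set)
    linked_mirnas = frozenset(m for m, _ in mg)
    cm = frozenset((c, m) for c, m in sponge.edges if m in linked_mirnas)
    # miRNAs with gene edges but no sponging circRNA would dangle downstream-only
    reachable = frozenset(m for _, m in cm)
    mg = frozenset((m, g) for m, g in mg if m in reachable)
    if not cm:
        logger.warning("restricted network is empty: no circRNA reaches the gene set")
    return CeRNANetwork(cm, mg)


def coverage_rank(net: CeRNANetwork, target_genes: Iterable[str]) -> CoverageReport:
    """Per-circRNA coverage of the target genes via length-2 paths.

    Ranked by coverage count descending, then circRNA id ascending; a
    circRNA reaching every target gene is flagged ``full_cover``.
    """
    targets = frozenset(normalize_gene_symbol(g) for g in target_genes)
    if not targets:
        raise ValidationError("coverage_rank requires non-empty target genes")
    entries = []
    for c in net.circrnas:
        covered = net.genes_reachable_from(c) & targets
        entries.append(
            CoverageEntry(
                circrna=c,
                covered_genes=covered,
                coverage_count=len(covered),
                full_cover=covered == targets,
            )
        )
    entries.sort(key=lambda e: (-e.coverage_count, e.circrna))
    return CoverageReport(tuple(entries), targets)


def min_cover(
    net: CeRNANetwork,
    target_genes: Iterable[str],
    exact_limit: int = 20,
) -> MinCoverResult:
    """Smallest circRNA set whose joint miRNA targets cover all target genes.

    Exact search (subsets in order of increasing size) up to ``exact_limit``
    candidate circRNAs; beyond that, the standard greedy set-cover
    heuristic with the approximation flagged in the result.
    """
    targets = frozenset(normalize_gene_symbol(g) for g in target_genes)
    if not targets:
        return MinCoverResult(frozenset(), exact=True)
    cover_sets = {
        c: net.genes_reachable_from(c) & targets
        for c in net.circrnas
        if net.genes_reachable_from(c) & targets
    }
    union = frozenset().union(*cover_sets.values()) if cover_sets else frozenset()
    missing = targets - union
    if missing:
        raise ValidationError(f"uncoverable genes: {sorted(missing)}")

    candidates = sorted(cover_sets)
    if len(candidates) <= exact_limit:
        for size in range(1, len(candidates) + 1):
            best = None
            for combo in combinations(candidates, size):
                if frozenset().union(*(cover_sets[c] for c in combo)) >= targets:
                    best = combo
                    break  # candidates sorted, so first hit is lexicographic min
            if best is not None:
                return MinCoverResult(frozenset(best), exact=True)
        raise AssertionError("unreachable: union covers targets")  # pragma: no cover
    logger.info(
        "min_cover: %d candidates exceed exact limit %d; using greedy approximation",
        len(candidates), exact_limit,
    )
    chosen: set[str] = set()
    remaining = set(targets)
    while remaining:
        c = max(candidates, key=lambda c: (len(cover_sets[c] & remaining), c))
        gain = cover_sets[c] & remaining
        chosen.add(c)
        remaining -= gain
    return MinCoverResult(frozenset(chosen), exact=False)


def shared_mirnas(
    circ_id: str, own_group: SpongeMap, other_group: SpongeMap
) -> dict[str, frozenset[str]]:
    """miRNAs of one circRNA also sponged in the other group.

    Returns each shared miRNA mapped to the other-group circRNAs sponging
    it — the cross-group regulatory overlap of a candidate circRNA.
    """
    if circ_id not in own_group.circrnas:
        raise ValidationError(f"{circ_id!r} is not a circRNA of group {own_group.group_label!r}")
    own_mirnas = own_group.mirnas_of(circ_id)
    out: dict[str, frozenset[str]] = {}
    for m in own_mirnas:
        partners = frozenset(c for c, mm in other_group.edges if mm == m)
        if partners:
            out[m] = partners
    return out
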