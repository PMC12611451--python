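"""Hub-miRNA selection and reverse circRNA search.

A miRNA sponged by many distinct circRNAs is a candidate regulatory hub.
This module computes miRNA in-degree on a sponge map, places a frequency
cutoff either at a fixed value (the study's "eight or more" / "five or
more" rule) or at the elbow of the sorted distinct-degree curve, and then
reverse-ranks circRNAs by how many selected hub miRNAs each one sponges.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_model import DegreeProfile, SpongeMap, ValidationError

logger = logging.getLogger("cerna")


@dataclass(frozen=True)
class HubSelectionConfig:
    """How to pick hub miRNAs and rank circRNAs in the reverse search.

    cutoff_mode
        ``"fixed"`` uses ``fixed_cutoff`` as the inclusive in-degree
        threshold; ``"elbow"`` derives it from the degree curve.
    top_k
        Number of circRNAs kept by the reverse search.
    tie_policy
        ``"keep_ties"`` retains every circRNA tied with the rank-k hit
        count; ``"lexicographic"`` truncates strictly at k.
    """

    cutoff_mode: str = "fixed"
    fixed_cutoff: int = 8
    top_k: int = 10
    tie_policy: str = "keep_ties"

    def __post_init__(self) -> None:
        if self.cutoff_mode not in ("fixed", "elbow"):
            raise ValidationError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.tie_policy not in ("keep_ties", "lexicographic"):
            raise ValidationError(f"unknown tie_policy {self.tie_policy!r}")
        if self.fixed_cutoff < 1:
            raise ValidationError("fixed_cutoff must be >= 1")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")


def compute_in_degree(sponge: SpongeMap) -> DegreeProfile:
    """Count, per miRNA, the distinct circRNAs that sponge it.

    Edges are already deduplicated, so in-degree is distinct-circRNA count
    by construction and the in-degrees sum to the edge count.
    """
    if not sponge.edges:
        raise ValidationError("no edges: cannot compute in-degrees of an empty sponge map")
    counts = Counter(m for _, m in sponge.edges)
    return DegreeProfile(dict(counts), group_label=sponge.group_label)


def elbow_cutoff(profile: DegreeProfile) -> int:
    """Inclusive in-degree threshold at the elbow of the degree curve.

    The distinct in-degree values are sorted descending into a curve
    ``y(i), i = 1..d``; the elbow is the point maximizing perpendicular
    distance to the chord joining ``(1, y(1))`` and ``(d, y(d))``
    (kneedle-style, no smoothing).  Distance ties break toward the larger
    in-degree, i.e. the stricter cutoff.  With fewer than three distinct
    values the curve has no interior, and the maximum in-degree is
    returned with a warning.
    """
    values = np.array(sorted(set(profile.counts.values()), reverse=True), dtype=float)
    d = len(values)
    if d < 3:
        logger.warning(
            "degenerate elbow: only %d distinct in-degree value(s); using max", d
        )
        return int(values[0])
    x = np.arange(1, d + 1, dtype=float)
    # |cross product| of (P - A) with the chord direction; constant |chord|
    # denominator does not affect the argmax.
    cross = np.abs((x - 1.0) * (values[-1] - values[0]) - (d - 1.0) * (values - values[0]))
    best = np.flatnonzero(cross == cross.max())[0]  # first index = larger degree
    return int(values[best])


def select_frequent_mirnas(profile: DegreeProfile, cutoff: int) -> frozenset[str]:
    """All miRNAs with in-degree >= cutoff (inclusive, "eight or more")."""
    if cutoff < 1:
        raise ValidationError("cutoff must be >= 1")
    selected = frozenset(m for m, deg in profile.counts.items() if deg >= cutoff)
    if not selected:
        logger.warning("no miRNA reaches in-degree cutoff %d", cutoff)
    return selected


def reverse_search(
    sponge: SpongeMap,
    selected: frozenset[str] | set[str],
    cfg: HubSelectionConfig | None = None,
) -> list[tuple[str, int]]:
    """Rank circRNAs by how many selected hub miRNAs each sponges.

    Returns ``(circRNA, hit_count)`` pairs with hit_count >= 1, sorted by
    hit count descending then id ascending, truncated at ``cfg.top_k``
    (ties at the boundary kept under the default tie policy).
    """
    if not selected:
        raise ValidationError("reverse search needs a non-empty selected miRNA set")
    cfg = cfg or HubSelectionConfig()
    selected = frozenset(selected)
    hits = Counter(c for c, m in sponge.edges if m in selected)
    ranked = sorted(hits.items(), key=lambda cm: (-cm[1], cm[0]))
    if len(ranked) <= cfg.top_k:
        return ranked
    if cfg.tie_policy == "keep_ties":
        boundary = ranked[cfg.top_k - 1][1]
        kept = [r for r in ranked if r[1] >= boundary]
        if len(kept) > cfg.top_k:
            logger.info(
                "reverse search kept %d circRNAs tied at hit_count %d beyond top_k=%d",
                len(kept) - cfg.top_k, boundary, cfg.top_k,
            )
        return kept
    return ranked[: cfg.top_k]
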