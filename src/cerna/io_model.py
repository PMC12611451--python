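"""Domain types, identifier normalization and file I/O for sponge-network data.

The pipeline is file-driven: circRNA->miRNA sponge maps and miRNA->gene
target maps arrive as TSV snapshots of database exports, pathway
collections as GMT, and risk-gene catalogs as TSV.  Everything read here is
normalized once (identifier case, hyphen variants, duplicate rows) so that
downstream modules can treat edges as plain sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("cerna")

SCHEMA_VERSION = "1.0"

# Unicode hyphen variants seen in journal typesetting (U+2010..U+2014, minus).
_HYPHEN_TABLE = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


class CernaError(Exception):
    """Base class for all package errors."""


class ValidationError(CernaError):
    """An input value violates a documented precondition."""


class FormatError(CernaError):
    """A file does not conform to its expected format."""


class Evidence(str, Enum):
    """Evidence tier of a validated miRNA->gene interaction."""

    STRONG = "strong"
    WEAK = "weak"

    @classmethod
    def parse(cls, token: str) -> "Evidence":
        t = token.strip().lower()
        try:
            return cls(t)
        except ValueError:
            raise FormatError(
                f"unknown evidence token {token!r}; expected one of "
                f"{[e.value for e in cls]}"
            ) from None


# ---------------------------------------------------------------------------
# Identifier normalization
# ---------------------------------------------------------------------------

def _clean(raw: str) -> str:
    return raw.translate(_HYPHEN_TABLE).strip()


def normalize_mirna_id(raw: str) -> str:
    """Canonicalize a miRNA identifier to the ``hsa-miR-...`` dialect.

    Handles the casing mixtures that appear in hand-curated tables
    (``mir-623``, ``MIR-4722-5P``), restores a missing species prefix as
    human (``hsa-``), and maps unicode hyphen variants to ASCII.  Arm
    suffixes (``-3p``/``-5p``) are kept, lowercased.  Idempotent.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("empty miRNA identifier")
    s = _clean(str(raw))
    tokens = s.split("-")
    low = [t.lower() for t in tokens]
    if low[0] in ("mir", "let"):
        species, rest, rest_low = "hsa", tokens, low
    elif (
        len(tokens) >= 2
        and len(tokens[0]) == 3
        and tokens[0].isalpha()
        and low[1] in ("mir", "let")
    ):
        species, rest, rest_low = low[0], tokens[1:], low[1:]
    else:
        raise ValidationError(f"unrecognized miRNA identifier {raw!r}")
    stem = "miR" if rest_low[0] == "mir" else "let"
    tail = "-".join(t.lower() for t in rest[1:])
    return f"{species}-{stem}-{tail}" if tail else f"{species}-{stem}"


def normalize_circ_id(raw: str) -> str:
    """Trim and hyphen-normalize a circRNA name; otherwise opaque.

    circRNA nomenclature is inconsistent across databases, so no attempt is
    made to reconcile naming dialects beyond whitespace/hyphen cleanup.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("empty circRNA identifier")
    return _clean(str(raw))


def normalize_gene_symbol(raw: str) -> str:
    """Uppercase, trimmed, hyphen-normalized HGNC-style gene symbol."""
    if raw is None or not str(raw).strip():
        raise ValidationError("empty gene symbol")
    return _clean(str(raw)).upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpongeMap:
    """Bipartite circRNA->miRNA edge set for one study group."""

    edges: frozenset[tuple[str, str]]
    group_label: str = ""

    @property
    def circrnas(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for _, m in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mirnas_of(self, circ_id: str) -> frozenset[str]:
        return frozenset(m for c, m in self.edges if c == circ_id)


@dataclass(frozen=True)
class TargetMap:
    """miRNA->gene validated-target edges at a single evidence tier."""

    edges: frozenset[tuple[str, str]]
    evidence: Evidence = Evidence.STRONG

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for m, _ in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    def genes_of(self, mirna_id: str) -> frozenset[str]:
        return frozenset(g for m, g in self.edges if m == mirna_id)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    pathway_name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets plus the background universe used for enrichment."""

    pathways: tuple[Pathway, ...]
    background: frozenset[str]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate pathway ids in collection")

    @classmethod
    def build(
        cls,
        pathways: Iterable[tuple[str, str, Iterable[str]]],
        background: Iterable[str] | None = None,
    ) -> "PathwayCollection":
        """Assemble a collection; background defaults to the gene union.

        With an explicit background, pathway genes outside it are dropped
        (logged) so that every gene set is a subset of the universe.
        """
        built: list[Pathway] = []
        if background is not None:
            bg = frozenset(normalize_gene_symbol(g) for g in background)
        else:
            bg = None
        dropped = 0
        for pid, name, genes in pathways:
            gs = frozenset(normalize_gene_symbol(g) for g in genes)
            if bg is not None:
                kept = gs & bg
                dropped += len(gs) - len(kept)
                gs = kept
            if not gs:
                raise ValidationError(f"pathway {pid!r} has no genes in background")
            built.append(Pathway(pid.strip(), name.strip() or pid.strip(), gs))
        if bg is None:
            bg = frozenset().union(*(p.genes for p in built)) if built else frozenset()
        if dropped:
            logger.info("dropped %d pathway genes outside the explicit background", dropped)
        return cls(tuple(built), bg)


@dataclass(frozen=True)
class RiskGeneCatalog:
    """Catalog of disorder-associated genes (SFARI-style), symbol-keyed."""

    entries: Mapping[str, str]  # gene symbol -> score category ("" if absent)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.entries)

    def __contains__(self, gene: str) -> bool:
        return normalize_gene_symbol(gene) in self.entries


@dataclass(frozen=True)
class DegreeProfile:
    """Per-miRNA in-degree: distinct circRNAs sponging each miRNA."""

    counts: Mapping[str, int]
    group_label: str = ""

    def __post_init__(self) -> None:
        bad = [m for m, d in self.counts.items() if d < 1]
        if bad:
            raise ValidationError(f"in-degree < 1 for {bad[:3]}")


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's overrepresentation outcome."""

    pathway_id: str
    pathway_name: str
    k: int  # query genes in pathway
    K: int  # pathway size (within background)
    n: int  # query genes in background
    N: int  # background size
    p_raw: float
    q_bh: float
    significant: bool
    category: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValidationError(
                f"inconsistent contingency counts k={self.k} K={self.K} n={self.n} N={self.N}"
            )
        if not (0.0 <= self.p_raw <= 1.0 and self.p_raw <= self.q_bh <= 1.0):
            raise ValidationError(
                f"invalid probabilities p={self.p_raw} q={self.q_bh}"
            )


@dataclass(frozen=True)
class CeRNANetwork:
    """Tripartite circRNA -> miRNA -> gene network (no dangling miRNAs)."""

    circ_mirna_edges: frozenset[tuple[str, str]]
    mirna_gene_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        up = frozenset(m for _, m in self.circ_mirna_edges)
        down = frozenset(m for m, _ in self.mirna_gene_edges)
        if up != down:
            raise ValidationError(
                "dangling miRNA nodes: every miRNA needs both an upstream "
                f"and a downstream edge (up-only={sorted(up - down)[:3]}, "
                f"down-only={sorted(down - up)[:3]})"
            )

    @property
    def circrnas(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.circ_mirna_edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(m for _, m in self.circ_mirna_edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.mirna_gene_edges)

    @property
    def n_edges(self) -> int:
        return len(self.circ_mirna_edges) + len(self.mirna_gene_edges)

    def genes_reachable_from(self, circ_id: str) -> frozenset[str]:
        """Genes reachable from a circRNA via one sponged miRNA (length-2 paths)."""
        ms = frozenset(m for c, m in self.circ_mirna_edges if c == circ_id)
        return frozenset(g for m, g in self.mirna_gene_edges if m in ms)


@dataclass(frozen=True)
class CoverageEntry:
    circrna: str
    covered_genes: frozenset[str]
    coverage_count: int
    full_cover: bool


@dataclass(frozen=True)
class CoverageReport:
    entries: tuple[CoverageEntry, ...]  # ranked: coverage desc, then id asc
    target_genes: frozenset[str]

    @property
    def full_cover_circrnas(self) -> tuple[str, ...]:
        return tuple(e.circrna for e in self.entries if e.full_cover)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    cols = {c.strip().lower(): c for c in df.columns}
    out = {}
    for want in required:
        if want.lower() not in cols:
            raise FormatError(f"{path}: missing required column {want!r}")
        out[want] = cols[want.lower()]
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df.rename(columns={v: k for k, v in out.items()})


def read_sponge_table(path: str | Path, group_label: str = "") -> SpongeMap:
    """Read a circRNA->miRNA TSV (columns ``circRNA``, ``miRNA``; extras ignored).

    Duplicate rows — intentional in curated tables that repeat a pair across
    gene rows — collapse silently, with the collapsed count logged.
    """
    df = _read_tsv(path, ["circRNA", "miRNA"])
    edges = set()
    n_rows = 0
    for circ, mir in zip(df["circRNA"], df["miRNA"]):
        if pd.isna(circ) or pd.isna(mir):
            continue
        n_rows += 1
        edges.add((normalize_circ_id(circ), normalize_mirna_id(mir)))
    if not edges:
        raise FormatError(f"{path}: no usable circRNA-miRNA rows")
    if n_rows > len(edges):
        logger.info("%s: collapsed %d duplicate sponge rows", path, n_rows - len(edges))
    return SpongeMap(frozenset(edges), group_label=group_label)


def read_target_map(
    path: str | Path, evidence_filter: Evidence | str = Evidence.STRONG
) -> TargetMap:
    """Read a miRNA->gene TSV (columns ``miRNA``, ``gene``, ``evidence``).

    Only rows whose evidence tier matches ``evidence_filter`` are retained.
    """
    want = Evidence.parse(evidence_filter if isinstance(evidence_filter, str) else evidence_filter.value)
    df = _read_tsv(path, ["miRNA", "gene", "evidence"])
    edges = set()
    for mir, gene, ev in zip(df["miRNA"], df["gene"], df["evidence"]):
        if pd.isna(mir) or pd.isna(gene) or pd.isna(ev):
            continue
        if Evidence.parse(ev) is want:
            edges.add((normalize_mirna_id(mir), normalize_gene_symbol(gene)))
    return TargetMap(frozenset(edges), evidence=want)


def read_gmt(path: str | Path, universe_path: str | Path | None = None) -> PathwayCollection:
    """Read a GMT gene-set file (``id<TAB>description<TAB>gene...`` per line).

    Background defaults to the union of all pathway genes; a universe file
    (one gene symbol per line) overrides it.
    """
    path = Path(path)
    raw: list[tuple[str, str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {fields[0]!r} has no genes")
            raw.append((fields[0], fields[1], genes))
    if not raw:
        raise FormatError(f"{path}: empty GMT file")
    universe = None
    if universe_path is not None:
        with open(universe_path, encoding="utf-8") as fh:
            universe = [ln.strip() for ln in fh if ln.strip()]
    return PathwayCollection.build(raw, background=universe)


def read_risk_catalog(path: str | Path) -> RiskGeneCatalog:
    """Read a risk-gene TSV (column ``gene``; optional ``score``)."""
    df = _read_tsv(path, ["gene"])
    score_col = next((c for c in df.columns if c.strip().lower() == "score"), None)
    entries: dict[str, str] = {}
    for _, row in df.iterrows():
        if pd.isna(row["gene"]):
            continue
        g = normalize_gene_symbol(row["gene"])
        score = "" if score_col is None or pd.isna(row[score_col]) else str(row[score_col]).strip()
        entries[g] = score
    if not entries:
        raise FormatError(f"{path}: no genes in risk catalog")
    return RiskGeneCatalog(entries)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_sponge_table(sponge: SpongeMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(sponge.edges), columns=["circRNA", "miRNA"])
    df.to_csv(path, sep="\t", index=False)


def write_target_map(targets: TargetMap, path: str | Path) -> None:
    rows = [(m, g, targets.evidence.value) for m, g in sorted(targets.edges)]
    pd.DataFrame(rows, columns=["miRNA", "gene", "evidence"]).to_csv(path, sep="\t", index=False)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in collection.pathways:
            fh.write("\t".join([p.pathway_id, p.pathway_name, *sorted(p.genes)]) + "\n")


def write_risk_catalog(catalog: RiskGeneCatalog, path: str | Path) -> None:
    rows = sorted(catalog.entries.items())
    pd.DataFrame(rows, columns=["gene", "score"]).to_csv(path, sep="\t", index=False)


def _network_graph(net: CeRNANetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for c in net.circrnas:
        g.add_node(c, layer="circRNA")
    for m in net.mirnas:
        g.add_node(m, layer="miRNA")
    for gene in net.genes:
        g.add_node(gene, layer="gene")
    g.add_edges_from(net.circ_mirna_edges)
    g.add_edges_from(net.mirna_gene_edges)
    return g


def write_network(net: CeRNANetwork, path: str | Path, format: str = "edge_tsv") -> None:
    """Serialize a tripartite network as ``edge_tsv``, ``graphml`` or ``json``."""
    path = Path(path)
    if format == "edge_tsv":
        rows = [(c, m, "circRNA-miRNA") for c, m in sorted(net.circ_mirna_edges)]
        rows += [(m, g, "miRNA-gene") for m, g in sorted(net.mirna_gene_edges)]
        pd.DataFrame(rows, columns=["source", "target", "layer"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(_network_graph(net), path)
    elif format == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "circ_mirna_edges": sorted(map(list, net.circ_mirna_edges)),
            "mirna_gene_edges": sorted(map(list, net.mirna_gene_edges)),
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network_edge_tsv(path: str | Path) -> CeRNANetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return CeRNANetwork(frozenset(), frozenset())
    cm = frozenset(
        (s, t) for s, t, l in zip(df["source"], df["target"], df["layer"]) if l == "circRNA-miRNA"
    )
    mg = frozenset(
        (s, t) for s, t, l in zip(df["source"], df["target"], df["layer"]) if l == "miRNA-gene"
    )
    return CeRNANetwork(cm, mg)


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (frozenset, set)):
        return sorted(_jsonable(x) for x in obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_report(obj, path: str | Path) -> None:
    """Serialize any result object to schema-versioned JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "report": _jsonable(obj)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged fixtures (worked examples transcribed from the source tables)
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    """Path of a packaged fixture file by bare name."""
    p = Path(__file__).parent / "fixtures" / name
    if not p.exists():
        raise ValidationError(f"no packaged fixture named {name!r}")
    return p


def load_table1_sponge() -> SpongeMap:
    """ASD-group circRNA-miRNA-gene table as a sponge map (19 printed rows)."""
    return read_sponge_table(fixture_path("table1_asd_network.tsv"), group_label="ASD")


def load_table2_sponge() -> SpongeMap:
    """Placenta-group circRNA-miRNA-gene table as a sponge map (24 printed rows)."""
    return read_sponge_table(fixture_path("table2_placenta_network.tsv"), group_label="placenta")


def _load_table_targets(name: str) -> TargetMap:
    df = pd.read_csv(fixture_path(name), sep="\t", dtype=str)
    edges = frozenset(
        (normalize_mirna_id(m), normalize_gene_symbol(g))
        for m, g in zip(df["miRNA"], df["gene"])
    )
    return TargetMap(edges, evidence=Evidence.STRONG)


def load_table1_targets() -> TargetMap:
    """miRNA->gene pairs of the ASD-group table (strong-validated tier)."""
    return _load_table_targets("table1_asd_network.tsv")


def load_table2_targets() -> TargetMap:
    """miRNA->gene pairs of the placenta-group table (strong-validated tier)."""
    return _load_table_targets("table2_placenta_network.tsv")


def load_figure8_gene_lists() -> dict[str, frozenset[str]]:
    """The published risk-overlap gene lists: asd_only / placenta_only / shared."""
    raw = json.loads(fixture_path("figure8_gene_lists.json").read_text(encoding="utf-8"))
    return {
        key: frozenset(normalize_gene_symbol(g) for g in raw[key])
        for key in ("asd_only", "placenta_only", "shared")
    }
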