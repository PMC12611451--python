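"""Synthetic interactome generator with planted, recoverable structure.

No public accessions back the study's database snapshots, so every
pipeline stage is exercised against generated data instead: a bipartite
circRNA->miRNA sponge map with heavy-tailed circRNA out-degrees, a
miRNA->gene target map, a pathway collection and a risk catalog.  The
generator plants three recoverable signals and records them as ground
truth: hub miRNAs with boosted in-degree, one circRNA wired to cover all
target genes, and one pathway overrepresented in the query gene set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    Evidence,
    PathwayCollection,
    RiskGeneCatalog,
    SpongeMap,
    TargetMap,
    ValidationError,
    fixture_path,
    write_gmt,
    write_risk_catalog,
    write_sponge_table,
    write_target_map,
)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic interactome.

    degree_dispersion is the negative-binomial shape of circRNA out-degree
    (smaller = heavier tail); hub_boost is the number of extra distinct
    circRNA partners each planted hub receives, and doubles as the planted
    in-degree floor recorded in the ground truth; enrichment_effect is the
    fraction of the query gene list drawn from the planted pathway.
    """

    n_circ: int = 150
    n_mirna: int = 400
    n_gene: int = 1000
    n_pathway: int = 50
    degree_dispersion: float = 0.5
    mean_out_degree: float = 3.0
    n_planted_hubs: int = 12
    hub_boost: int = 20
    plant_full_cover: bool = True
    n_target_genes: int = 5
    n_query_genes: int = 200
    enrichment_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_circ", "n_mirna", "n_gene", "n_pathway", "n_target_genes", "n_query_genes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_planted_hubs > self.n_mirna:
            raise ValidationError("cannot plant more hubs than miRNAs")
        if self.hub_boost > self.n_circ:
            raise ValidationError("hub_boost exceeds the number of circRNAs")
        if not (0.0 <= self.enrichment_effect <= 1.0):
            raise ValidationError("enrichment_effect must lie in [0, 1]")
        if self.degree_dispersion <= 0:
            raise ValidationError("degree_dispersion must be positive")
        if self.n_target_genes > self.n_gene or self.n_query_genes > self.n_gene:
            raise ValidationError("target/query genes exceed the gene universe")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery experiments."""

    planted_hubs: frozenset[str]
    hub_degree_floor: int  # every planted hub has in-degree >= this
    planted_cover_circ: str | None
    target_genes: frozenset[str]
    planted_pathway_id: str
    query_genes: frozenset[str]
    seed: int


@dataclass(frozen=True)
class SyntheticBundle:
    sponge: SpongeMap
    targets: TargetMap
    pathways: PathwayCollection
    risk_catalog: RiskGeneCatalog
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=SimConfig())


def _circ_name(i: int) -> str:
    return f"hsa-SYNC{i:04d}_0001"


def _mirna_name(i: int) -> str:
    return f"hsa-miR-{10000 + i}"


def _gene_name(i: int) -> str:
    return f"SYNG{i:04d}"


def generate_interactome(cfg: SimConfig | None = None) -> SyntheticBundle:
    """Draw one synthetic bundle, fully reproducible from ``cfg.seed``.

    Background sponge edges attach each circRNA (out-degree drawn from a
    negative binomial, floored at 1) to uniformly chosen miRNAs; planted
    hubs then receive ``hub_boost`` extra distinct circRNA partners.  Each
    target gene is regulated by one designated planted hub plus one decoy
    miRNA; the planted cover circRNA sponges all designated hubs.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    circs = [_circ_name(i) for i in range(cfg.n_circ)]
    mirnas = [_mirna_name(i) for i in range(cfg.n_mirna)]
    genes = [_gene_name(i) for i in range(cfg.n_gene)]

    # --- sponge map: heavy-tailed out-degrees, uniform attachment --------
    r = cfg.degree_dispersion
    mu = max(cfg.mean_out_degree - 1.0, 1e-9)  # +1 floor keeps every circRNA wired
    p_nb = r / (r + mu)
    out_deg = 1 + rng.negative_binomial(r, p_nb, size=cfg.n_circ)
    out_deg = np.minimum(out_deg, cfg.n_mirna)
    edges: set[tuple[str, str]] = set()
    for i, c in enumerate(circs):
        chosen = rng.choice(cfg.n_mirna, size=int(out_deg[i]), replace=False)
        for j in chosen:
            edges.add((c, mirnas[int(j)]))

    hub_idx = rng.choice(cfg.n_mirna, size=cfg.n_planted_hubs, replace=False)
    planted_hubs = [mirnas[int(j)] for j in sorted(hub_idx)]
    for m in planted_hubs:
        partners = {c for c, mm in edges if mm == m}
        pool = [c for c in circs if c not in partners]
        if len(pool) < cfg.hub_boost:
            raise ValidationError("hub_boost infeasible: not enough unused circRNA partners")
        extra = rng.choice(len(pool), size=cfg.hub_boost, replace=False)
        for j in extra:
            edges.add((pool[int(j)], m))

    # --- target genes, risk catalog, miRNA->gene map ---------------------
    gene_idx = rng.permutation(cfg.n_gene)
    target_genes = [genes[int(j)] for j in sorted(gene_idx[: cfg.n_target_genes])]
    non_target = [g for g in genes if g not in set(target_genes)]

    tedges: set[tuple[str, str]] = set()
    n_tg_per_mirna = rng.poisson(3.0, size=cfg.n_mirna)
    for i, m in enumerate(mirnas):
        k = int(min(max(n_tg_per_mirna[i], 1), len(non_target)))
        chosen = rng.choice(len(non_target), size=k, replace=False)
        for j in chosen:
            tedges.add((m, non_target[int(j)]))

    # each target gene: one designated planted hub plus one decoy regulator
    non_hub = [m for m in mirnas if m not in set(planted_hubs)]
    designated: list[str] = []
    for i, g in enumerate(target_genes):
        hub = planted_hubs[i % len(planted_hubs)]
        designated.append(hub)
        tedges.add((hub, g))
        decoy = non_hub[int(rng.integers(len(non_hub)))]
        tedges.add((decoy, g))

    cover_circ: str | None = None
    if cfg.plant_full_cover:
        cover_circ = circs[int(rng.integers(cfg.n_circ))]
        for hub in designated:
            edges.add((cover_circ, hub))

    risk_extra = [genes[int(j)] for j in sorted(gene_idx[cfg.n_target_genes : cfg.n_target_genes + cfg.n_gene // 10])]
    scores = ("1", "2", "3", "S")
    risk_entries = {g: scores[int(rng.integers(4))] for g in target_genes + risk_extra}

    # --- pathway collection with one planted enriched pathway ------------
    q_in = int(round(cfg.enrichment_effect * cfg.n_query_genes))
    planted_core_idx = rng.choice(cfg.n_gene, size=max(q_in, 1), replace=False)
    planted_core = [genes[int(j)] for j in sorted(planted_core_idx)]
    filler = [g for g in genes if g not in set(planted_core)]
    filler_pick = rng.choice(len(filler), size=min(20, len(filler)), replace=False)
    planted_pathway_genes = planted_core + [filler[int(j)] for j in sorted(filler_pick)]

    pathway_rows: list[tuple[str, str, list[str]]] = []
    planted_pid = "SYNP0000"
    pathway_rows.append((planted_pid, "planted signalling pathway", planted_pathway_genes))
    for i in range(1, cfg.n_pathway):
        size = int(rng.integers(20, 80))
        chosen = rng.choice(cfg.n_gene, size=min(size, cfg.n_gene), replace=False)
        pathway_rows.append(
            (f"SYNP{i:04d}", f"synthetic pathway {i}", [genes[int(j)] for j in sorted(chosen)])
        )
    pathways = PathwayCollection.build(pathway_rows, background=genes)

    # --- query gene list: planted fraction + uniform remainder -----------
    rest_pool = [g for g in genes if g not in set(planted_core)]
    rest_pick = rng.choice(len(rest_pool), size=cfg.n_query_genes - q_in, replace=False)
    query = frozenset(planted_core[:q_in]) | frozenset(rest_pool[int(j)] for j in rest_pick)

    truth = GroundTruth(
        planted_hubs=frozenset(planted_hubs),
        hub_degree_floor=cfg.hub_boost,
        planted_cover_circ=cover_circ,
        target_genes=frozenset(target_genes),
        planted_pathway_id=planted_pid,
        query_genes=query,
        seed=cfg.seed,
    )
    return SyntheticBundle(
        sponge=SpongeMap(frozenset(edges), group_label="synthetic"),
        targets=TargetMap(frozenset(tedges), evidence=Evidence.STRONG),
        pathways=pathways,
        risk_catalog=RiskGeneCatalog(risk_entries),
        truth=truth,
        config=cfg,
    )


def null_ora_experiment(
    n_genes: int = 1000,
    n_pathways: int = 200,
    n_query: int = 50,
    n_replicates: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical false-discovery behaviour of the ORA under the null.

    Queries are drawn uniformly from the background, so every pathway
    called significant is a false discovery.  Returns the empirical FDR
    (mean of V / max(R, 1) over replicates), the Monte-Carlo standard
    error at the nominal level, and the fraction of replicates whose
    minimum raw p dips below the Bonferroni level.
    """
    from .enrichment import OraConfig, run_ora

    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    rows = []
    for i in range(n_pathways):
        size = int(rng.integers(20, 80))
        chosen = rng.choice(n_genes, size=size, replace=False)
        rows.append((f"NULLP{i:04d}", f"null pathway {i}", [genes[int(j)] for j in sorted(chosen)]))
    collection = PathwayCollection.build(rows, background=genes)
    cfg = OraConfig(fdr_threshold=fdr_threshold, min_overlap_genes=1)

    fdp = np.empty(n_replicates)
    min_p_below_bonf = 0
    for rep in range(n_replicates):
        pick = rng.choice(n_genes, size=n_query, replace=False)
        query = [genes[int(j)] for j in pick]
        results = run_ora(query, collection, cfg)
        n_disc = sum(r.significant for r in results)
        fdp[rep] = n_disc / max(n_disc, 1) if n_disc else 0.0
        if results and min(r.p_raw for r in results) < fdr_threshold / n_pathways:
            min_p_below_bonf += 1
    return {
        "empirical_fdr": float(fdp.mean()),
        "mc_standard_error": float(np.sqrt(fdr_threshold * (1 - fdr_threshold) / n_replicates)),
        "fraction_min_p_below_bonferroni": min_p_below_bonf / n_replicates,
        "n_replicates": n_replicates,
    }


def recovery_experiment(
    n_seeds: int = 200, base_seed: int = 0, cfg: SimConfig | None = None
) -> dict[str, float]:
    """Planted-structure recovery rates over independently seeded bundles.

    Per seed: hub recovery is exact equality between the miRNAs selected
    at the planted in-degree floor and the planted hubs; cover recovery
    requires the planted circRNA to be the sole full-cover candidate;
    pathway recovery requires the planted pathway to attain the minimum
    BH-adjusted q.
    """
    from .enrichment import OraConfig, run_ora
    from .hub_selection import compute_in_degree, select_frequent_mirnas
    from .overlap_network import build_network, coverage_rank

    base = cfg or SimConfig()
    hub_ok = cover_ok = pathway_ok = 0
    ora_cfg = OraConfig(min_overlap_genes=1)
    for i in range(n_seeds):
        seed = (base_seed + i) % 2**31
        bundle = generate_interactome(dataclasses.replace(base, seed=seed))
        profile = compute_in_degree(bundle.sponge)
        selected = select_frequent_mirnas(profile, bundle.truth.hub_degree_floor)
        hub_ok += selected == bundle.truth.planted_hubs
        net = build_network(bundle.sponge, bundle.targets, bundle.truth.target_genes)
        cov = coverage_rank(net, bundle.truth.target_genes)
        cover_ok += cov.full_cover_circrnas == (bundle.truth.planted_cover_circ,)
        results = run_ora(bundle.truth.query_genes, bundle.pathways, ora_cfg)
        best = min(results, key=lambda r: (r.q_bh, r.p_raw))
        pathway_ok += best.pathway_id == bundle.truth.planted_pathway_id
    return {
        "hub_recovery_rate": hub_ok / n_seeds,
        "cover_recovery_rate": cover_ok / n_seeds,
        "pathway_recovery_rate": pathway_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(outdir: str | Path, cfg: SimConfig | None = None) -> dict[str, str]:
    """Emit the worked-example fixtures plus one synthetic bundle.

    Copies the packaged transcription of the published tables and gene
    lists, generates a synthetic bundle from ``cfg``, and writes a
    manifest of SHA-256 checksums so regeneration can be verified.
    Returns the manifest mapping (filename -> checksum).
    """
    cfg = cfg or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("table1_asd_network.tsv", "table2_placenta_network.tsv", "figure8_gene_lists.json"):
        shutil.copy(fixture_path(name), outdir / name)

    bundle = generate_interactome(cfg)
    write_sponge_table(bundle.sponge, outdir / "synthetic_sponge.tsv")
    write_target_map(bundle.targets, outdir / "synthetic_targets.tsv")
    write_gmt(bundle.pathways, outdir / "synthetic_pathways.gmt")
    (outdir / "synthetic_universe.txt").write_text(
        "\n".join(sorted(bundle.pathways.background)) + "\n", encoding="utf-8"
    )
    write_risk_catalog(bundle.risk_catalog, outdir / "synthetic_risk.tsv")
    truth_payload = {
        "seed": cfg.seed,
        "planted_hubs": sorted(bundle.truth.planted_hubs),
        "hub_degree_floor": bundle.truth.hub_degree_floor,
        "planted_cover_circ": bundle.truth.planted_cover_circ,
        "target_genes": sorted(bundle.truth.target_genes),
        "planted_pathway_id": bundle.truth.planted_pathway_id,
        "query_genes": sorted(bundle.truth.query_genes),
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth_payload, indent=1), encoding="utf-8"
    )

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.name != "manifest.json" and p.is_file()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
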