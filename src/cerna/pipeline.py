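"""End-to-end two-group workflow driver.

Runs, for each study group: in-degree profiling -> hub cutoff -> hub
selection -> reverse circRNA search -> target-gene expansion -> pathway
ORA -> categorization -> relevant-gene selection -> risk-catalog
cross-reference; then compares the groups (Venn), restricts the tripartite
network to the shared risk genes, ranks circRNAs by gene coverage, finds a
minimum covering set, and reports cross-group miRNA sharing for every
full-cover circRNA.  Every threshold actually used is echoed in the
machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment, hub_selection, overlap_network
from .io_model import (
    CernaError,
    Evidence,
    SpongeMap,
    ValidationError,
    read_gmt,
    read_risk_catalog,
    read_sponge_table,
    read_target_map,
    write_network,
    write_report,
)

logger = logging.getLogger("cerna")

STAGES = (
    "load_inputs", "group_a", "group_b", "venn",
    "network", "coverage", "min_cover", "shared_mirnas", "write_outputs",
)


class StageError(CernaError):
    """A pipeline stage failed; carries the stage name and an input digest."""

    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {digest}: {cause}")
        self.stage = stage
        self.digest = digest


@dataclass(frozen=True)
class GroupConfig:
    sponge_path: str
    label: str
    cutoff_mode: str = "fixed"
    fixed_cutoff: int = 8
    top_k: int = 10
    tie_policy: str = "keep_ties"

    def hub_config(self) -> hub_selection.HubSelectionConfig:
        return hub_selection.HubSelectionConfig(
            cutoff_mode=self.cutoff_mode,
            fixed_cutoff=self.fixed_cutoff,
            top_k=self.top_k,
            tie_policy=self.tie_policy,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the two-group run needs; loadable from YAML."""

    group_a: GroupConfig
    group_b: GroupConfig
    target_map_path: str
    gmt_path: str
    risk_catalog_path: str
    output_dir: str
    evidence_filter: str = "strong"
    universe_path: str | None = None
    fdr_threshold: float = 0.05
    min_overlap_genes: int = 15
    relevance_cutoffs: dict[str, int] | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.group_a.label == self.group_b.label:
            raise ValidationError("group labels must be distinct")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        raw["group_a"] = GroupConfig(**raw["group_a"])
        raw["group_b"] = GroupConfig(**raw["group_b"])
        return cls(**raw)

    def ora_config(self) -> enrichment.OraConfig:
        kwargs: dict[str, Any] = {
            "fdr_threshold": self.fdr_threshold,
            "min_overlap_genes": self.min_overlap_genes,
        }
        if self.relevance_cutoffs:
            kwargs["relevance_cutoffs"] = dict(self.relevance_cutoffs)
        return enrichment.OraConfig(**kwargs)


@dataclass
class PipelineReport:
    """Machine-readable run record; ``timings`` is the only clock-dependent field."""

    schema_version: str = "1.0"
    config: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)
    venn: dict = field(default_factory=dict)
    full_cover_circrnas: list = field(default_factory=list)
    coverage: list = field(default_factory=list)
    min_cover: dict = field(default_factory=dict)
    shared_mirnas: dict = field(default_factory=dict)
    output_files: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)


def _digest(obj: Any) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _run_group(
    group: GroupConfig,
    targets,
    pathways,
    catalog,
    ora_cfg: enrichment.OraConfig,
    outdir: Path,
):
    sponge = read_sponge_table(group.sponge_path, group_label=group.label)
    profile = hub_selection.compute_in_degree(sponge)
    if group.cutoff_mode == "elbow":
        cutoff = hub_selection.elbow_cutoff(profile)
    else:
        cutoff = group.fixed_cutoff
    selected = hub_selection.select_frequent_mirnas(profile, cutoff)
    ranked = (
        hub_selection.reverse_search(sponge, selected, group.hub_config())
        if selected
        else []
    )
    query = frozenset().union(*(targets.genes_of(m) for m in selected)) if selected else frozenset()
    results: list = []
    relevant: dict[str, frozenset[str]] = {}
    if query and (query & pathways.background):
        results = enrichment.run_ora(query, pathways, ora_cfg)
        results = enrichment.categorize_pathways(results, ora_cfg)
        relevant = enrichment.select_relevant_genes(results, pathways, ora_cfg, query_genes=query)
    else:
        logger.warning("group %s: no hub target genes overlap the background", group.label)
    relevant_union = frozenset().union(*relevant.values()) if relevant else frozenset()
    risk_genes = overlap_network.cross_reference_risk(relevant_union, catalog)

    ora_path = outdir / f"ora_{group.label}.tsv"
    with open(ora_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tpathway_name\tcategory\tk\tK\tn\tN\tp_raw\tq_bh\tsignificant\n")
        for r in sorted(results, key=lambda r: (r.q_bh, r.pathway_id)):
            fh.write(
                f"{r.pathway_id}\t{r.pathway_name}\t{r.category}\t{r.k}\t{r.K}\t"
                f"{r.n}\t{r.N}\t{r.p_raw:.6g}\t{r.q_bh:.6g}\t{r.significant}\n"
            )

    summary = {
        "label": group.label,
        "cutoff_mode": group.cutoff_mode,
        "cutoff_used": int(cutoff),
        "n_mirnas": len(profile.counts),
        "selected_mirnas": sorted(selected),
        "ranked_circrnas": [{"id": c, "hit_count": h} for c, h in ranked],
        "n_query_genes": len(query),
        "n_pathways_tested": len(results),
        "n_significant_pathways": sum(r.significant for r in results),
        "relevant_genes": {cat: sorted(gs) for cat, gs in relevant.items()},
        "risk_genes": sorted(risk_genes),
    }
    return sponge, risk_genes, summary, [str(ora_path)]


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full two-group workflow and write all artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=_config_echo(cfg))
    t0 = time.perf_counter()

    def stage(name: str, fn, *args):
        t = time.perf_counter()
        try:
            out = fn(*args)
        except CernaError as exc:
            raise StageError(name, _digest(args), exc) from exc
        report.timings[name] = round(time.perf_counter() - t, 6)
        return out

    targets = stage("load_inputs", read_target_map, cfg.target_map_path, Evidence.parse(cfg.evidence_filter))
    pathways = read_gmt(cfg.gmt_path, cfg.universe_path)
    catalog = read_risk_catalog(cfg.risk_catalog_path)
    ora_cfg = cfg.ora_config()

    sponge_a, risk_a, summary_a, files_a = stage(
        "group_a", _run_group, cfg.group_a, targets, pathways, catalog, ora_cfg, outdir
    )
    sponge_b, risk_b, summary_b, files_b = stage(
        "group_b", _run_group, cfg.group_b, targets, pathways, catalog, ora_cfg, outdir
    )
    report.groups = {cfg.group_a.label: summary_a, cfg.group_b.label: summary_b}
    report.output_files += files_a + files_b

    vr = stage("venn", overlap_network.venn, risk_a, risk_b, (cfg.group_a.label, cfg.group_b.label))
    report.venn = {
        "labels": list(vr.labels),
        "a_only": sorted(vr.a_only),
        "shared": sorted(vr.shared),
        "b_only": sorted(vr.b_only),
    }
    venn_path = outdir / "venn.json"
    venn_path.write_text(json.dumps(report.venn, indent=1), encoding="utf-8")
    report.output_files.append(str(venn_path))

    if not vr.shared:
        logger.warning("no shared risk genes between groups; skipping network stages")
        report.timings["total"] = round(time.perf_counter() - t0, 6)
        emit_report(report, outdir / "report.json")
        return report

    combined = SpongeMap(sponge_a.edges | sponge_b.edges, group_label="combined")
    net = stage("network", overlap_network.build_network, combined, targets, vr.shared)
    cov = stage("coverage", overlap_network.coverage_rank, net, vr.shared)
    mc = stage("min_cover", overlap_network.min_cover, net, vr.shared)

    report.full_cover_circrnas = list(cov.full_cover_circrnas)
    report.coverage = [
        {
            "circrna": e.circrna,
            "coverage_count": e.coverage_count,
            "covered_genes": sorted(e.covered_genes),
            "full_cover": e.full_cover,
        }
        for e in cov.entries
    ]
    report.min_cover = {"circrnas": sorted(mc.circrnas), "exact": mc.exact}

    shared_info: dict[str, dict[str, list[str]]] = {}
    for circ in cov.full_cover_circrnas:
        own, other = (
            (sponge_a, sponge_b) if circ in sponge_a.circrnas else (sponge_b, sponge_a)
        )
        sm = overlap_network.shared_mirnas(circ, own, other)
        shared_info[circ] = {m: sorted(cs) for m, cs in sorted(sm.items())}
    report.timings["shared_mirnas"] = 0.0
    report.shared_mirnas = shared_info

    cov_path = outdir / "coverage.tsv"
    with open(cov_path, "w", encoding="utf-8") as fh:
        fh.write("circRNA\tcoverage_count\tfull_cover\tcovered_genes\n")
        for e in cov.entries:
            fh.write(
                f"{e.circrna}\t{e.coverage_count}\t{e.full_cover}\t{','.join(sorted(e.covered_genes))}\n"
            )
    net_path = outdir / "network.graphml"
    write_network(net, net_path, format="graphml")
    sm_path = outdir / "shared_mirnas.json"
    sm_path.write_text(json.dumps(shared_info, indent=1, sort_keys=True), encoding="utf-8")
    report.output_files += [str(cov_path), str(net_path), str(sm_path)]

    report.timings["total"] = round(time.perf_counter() - t0, 6)
    emit_report(report, outdir / "report.json")
    report.output_files.append(str(outdir / "report.json"))
    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def worked_example_config(workdir: str | Path) -> PipelineConfig:
    """Materialize the published-table worked example as a runnable config.

    The two sponge tables are the packaged transcriptions of the study's
    ASD and placenta networks; the miRNA->gene rows of those tables become
    the strong-evidence target map.  Pathway annotation is a small
    Reactome-style GMT wiring each table gene into its labelled category,
    against a 100-gene universe, and the risk catalog carries every gene
    the published risk search returned.  Because the tables are already
    the post-selection networks, the in-degree cutoff is 1 and the
    per-category relevance cutoffs are 1.
    """
    from .io_model import fixture_path, load_figure8_gene_lists

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    import pandas as pd

    rows = []
    for name in ("table1_asd_network.tsv", "table2_placenta_network.tsv"):
        df = pd.read_csv(fixture_path(name), sep="\t", dtype=str)
        rows += [(m, g, "strong") for m, g in zip(df["miRNA"], df["gene"])]
    targets_path = workdir / "targets.tsv"
    pd.DataFrame(sorted(set(rows)), columns=["miRNA", "gene", "evidence"]).to_csv(
        targets_path, sep="\t", index=False
    )

    filler = [f"BG{i:04d}" for i in range(95)]
    gmt_path = workdir / "pathways.gmt"
    gmt_path.write_text(
        "RX1\tInterleukin-1 signalling\tPSMD11\tCREBBP\n"
        "RX2\tPIP3 activates AKT signalling\tNOTCH1\tTBL1X\tCREBBP\n"
        "RX3\tmRNA splicing - major pathway\tSRSF11\tPSMD11\n"
        "RX4\tHDR through homologous recombination (HRR)\tCREBBP\tSRSF11\n",
        encoding="utf-8",
    )
    universe_path = workdir / "universe.txt"
    universe_path.write_text(
        "\n".join(["PSMD11", "CREBBP", "TBL1X", "SRSF11", "NOTCH1", *filler]) + "\n",
        encoding="utf-8",
    )

    lists = load_figure8_gene_lists()
    risk_genes = sorted(lists["asd_only"] | lists["placenta_only"] | lists["shared"])
    risk_path = workdir / "risk_catalog.tsv"
    risk_path.write_text(
        "gene\tscore\n" + "".join(f"{g}\t1\n" for g in risk_genes), encoding="utf-8"
    )

    return PipelineConfig(
        group_a=GroupConfig(
            sponge_path=str(fixture_path("table1_asd_network.tsv")),
            label="ASD", cutoff_mode="fixed", fixed_cutoff=1,
        ),
        group_b=GroupConfig(
            sponge_path=str(fixture_path("table2_placenta_network.tsv")),
            label="placenta", cutoff_mode="fixed", fixed_cutoff=1,
        ),
        target_map_path=str(targets_path),
        gmt_path=str(gmt_path),
        universe_path=str(universe_path),
        risk_catalog_path=str(risk_path),
        output_dir=str(workdir / "out"),
        min_overlap_genes=1,
        relevance_cutoffs={"transcription": 1, "immune": 1, "asd_related": 1, "replication": 1},
    )


def emit_report(report: PipelineReport, path: str | Path) -> None:
    """Write the versioned JSON run record."""
    write_report(report, path)


def read_report(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return payload["report"]
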