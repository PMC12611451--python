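"""Risk overlap, Venn partition, network assembly, coverage and set cover."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerna import (
    CeRNANetwork,
    RiskGeneCatalog,
    SpongeMap,
    TargetMap,
    ValidationError,
    build_network,
    coverage_rank,
    cross_reference_risk,
    load_figure8_gene_lists,
    min_cover,
    shared_mirnas,
    venn,
)

SHARED5 = frozenset({"PSMD11", "CREBBP", "TBL1X", "SRSF11", "NOTCH1"})


class TestRiskCrossReference:
    CATALOG = RiskGeneCatalog({"NOTCH1": "1", "CREBBP": "1"})

    def test_intersection(self):
        assert cross_reference_risk({"NOTCH1", "FAKE1"}, self.CATALOG) == {"NOTCH1"}

    def test_empty_query(self):
        assert cross_reference_risk(set(), self.CATALOG) == frozenset()

    def test_figure8_asd_genes_all_in_catalog(self):
        lists = load_figure8_gene_lists()
        asd_side = lists["asd_only"] | lists["shared"]
        catalog = RiskGeneCatalog({g: "1" for g in asd_side | lists["placenta_only"]})
        assert cross_reference_risk(asd_side, catalog) == asd_side


class TestVenn:
    def test_table_gene_columns_share_five_genes(self, table1_targets, table2_targets):
        vr = venn(table1_targets.genes, table2_targets.genes, ("ASD", "placenta"))
        assert len(vr.shared) == 5
        assert vr.shared == SHARED5

    def test_identical_sets(self):
        vr = venn({"A", "B"}, {"A", "B"})
        assert vr.a_only == vr.b_only == frozenset() and vr.shared == {"A", "B"}

    def test_disjoint_sets(self):
        vr = venn({"A"}, {"B"})
        assert vr.shared == frozenset()

    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    @settings(derandomize=True, max_examples=80)
    def test_partition_sizes(self, a, b):
        a = {f"G{i}" for i in a}
        b = {f"G{i}" for i in b}
        vr = venn(a, b)
        assert vr.a_only | vr.shared == a and vr.b_only | vr.shared == b
        assert len(vr.a_only) + len(vr.shared) == len(a)
        assert not (vr.a_only & vr.b_only or vr.a_only & vr.shared or vr.b_only & vr.shared)


class TestBuildNetwork:
    def test_published_candidate_path_present(self, combined_sponge, combined_targets):
        net = build_network(combined_sponge, combined_targets, SHARED5)
        assert ("hsa-MAN1A2_0008", "hsa-miR-623") in net.circ_mirna_edges
        assert ("hsa-miR-623", "NOTCH1") in net.mirna_gene_edges

    def test_unregulated_genes_give_empty_network(self, combined_sponge, combined_targets, caplog):
        with caplog.at_level("WARNING", logger="cerna"):
            net = build_network(combined_sponge, combined_targets, {"UNREGULATED"})
        assert net.n_edges == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_empty_gene_set_rejected(self, combined_sponge, combined_targets):
        with pytest.raises(ValidationError):
            build_network(combined_sponge, combined_targets, set())

    def test_no_dangling_mirnas_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            sponge = SpongeMap(frozenset(
                (f"c{rng.integers(8)}", f"m{rng.integers(10)}") for _ in range(30)
            ))
            targets = TargetMap(frozenset(
                (f"m{rng.integers(10)}", f"G{rng.integers(6)}") for _ in range(20)
            ))
            genes = {f"G{i}" for i in rng.choice(6, size=3, replace=False)}
            net = build_network(sponge, targets, genes)
            up = {m for _, m in net.circ_mirna_edges}
            down = {m for m, _ in net.mirna_gene_edges}
            assert up == down  # tripartite, no dangling intermediates
            assert net.genes <= {g.upper() for g in genes}


class TestCoverage:
    def test_placenta_candidate_covers_all_five(self, table2_sponge, table2_targets):
        net = build_network(table2_sponge, table2_targets, SHARED5)
        cov = coverage_rank(net, SHARED5)
        assert cov.full_cover_circrnas == ("hsa-MAN1A2_0008",)
        top = cov.entries[0]
        assert top.circrna == "hsa-MAN1A2_0008" and top.coverage_count == 5

    def test_asd_group_has_no_full_cover(self, table1_sponge, table1_targets):
        net = build_network(table1_sponge, table1_targets, SHARED5)
        cov = coverage_rank(net, SHARED5)
        assert cov.full_cover_circrnas == ()
        # brute-force path enumeration over the printed rows gives max 4
        # (hsa-PAPPA2_0005 reaches CREBBP, TBL1X, SRSF11, NOTCH1)
        best = {}
        for c, m in table1_sponge.edges:
            for mm, g in table1_targets.edges:
                if mm == m and g in SHARED5:
                    best.setdefault(c, set()).add(g)
        assert max(len(v) for v in best.values()) == 4
        assert cov.entries[0].coverage_count == 4
        assert set(cov.entries[0].covered_genes) == best["hsa-PAPPA2_0005"]

    def test_single_edge_network(self):
        net = CeRNANetwork(frozenset({("c", "m")}), frozenset({("m", "G")}))
        cov = coverage_rank(net, {"G"})
        assert cov.entries[0].full_cover

    def test_adding_edges_never_decreases_coverage(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cm = {(f"c{rng.integers(5)}", f"m{rng.integers(6)}") for _ in range(12)}
            mg = {(f"m{rng.integers(6)}", f"G{rng.integers(5)}") for _ in range(10)}
            mirnas = {m for _, m in cm} & {m for m, _ in mg}
            cm = {(c, m) for c, m in cm if m in mirnas}
            mg = {(m, g) for m, g in mg if m in mirnas}
            net = CeRNANetwork(frozenset(cm), frozenset(mg))
            targets = {f"G{i}" for i in range(5)}
            before = {e.circrna: e.coverage_count for e in coverage_rank(net, targets).entries}
            extra_m = next(iter(mirnas), None)
            if extra_m is None:
                continue
            net2 = CeRNANetwork(net.circ_mirna_edges, net.mirna_gene_edges | {(extra_m, "G0")})
            after = {e.circrna: e.coverage_count for e in coverage_rank(net2, targets).entries}
            assert all(after[c] >= n for c, n in before.items())


def _random_instance(rng, n_circ, n_genes=6):
    """Random tripartite net where circ i owns a private miRNA."""
    cm, mg = set(), set()
    for i in range(n_circ):
        cm.add((f"c{i:02d}", f"m{i:02d}"))
        for g in rng.choice(n_genes, size=rng.integers(1, n_genes + 1), replace=False):
            mg.add((f"m{i:02d}", f"G{g}"))
    return CeRNANetwork(frozenset(cm), frozenset(mg))


def _brute_force_min_cover_size(net, targets):
    circs = sorted(net.circrnas)
    best = None
    for size in range(0, len(circs) + 1):
        for combo in combinations(circs, size):
            covered = set().union(*(net.genes_reachable_from(c) for c in combo)) if combo else set()
            if covered >= targets:
                return size
    return best


class TestMinCover:
    def test_placenta_minimum_cover_is_single_circrna(self, table2_sponge, table2_targets):
        net = build_network(table2_sponge, table2_targets, SHARED5)
        mc = min_cover(net, SHARED5)
        assert mc.exact and mc.circrnas == {"hsa-MAN1A2_0008"}

    def test_empty_targets_empty_cover(self, table2_sponge, table2_targets):
        net = build_network(table2_sponge, table2_targets, SHARED5)
        assert min_cover(net, set()).circrnas == frozenset()

    def test_uncoverable_genes_listed(self, table2_sponge, table2_targets):
        net = build_network(table2_sponge, table2_targets, SHARED5)
        with pytest.raises(ValidationError, match="GHOST"):
            min_cover(net, SHARED5 | {"GHOST"})

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            net = _random_instance(rng, n_circ=int(rng.integers(3, 12)))
            targets = net.genes  # coverable by construction
            mc = min_cover(net, targets)
            assert mc.exact
            assert len(mc.circrnas) == _brute_force_min_cover_size(net, set(targets))

    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            net = _random_instance(rng, n_circ=10)
            targets = net.genes
            exact = min_cover(net, targets, exact_limit=20)
            greedy = min_cover(net, targets, exact_limit=0)
            assert not greedy.exact
            assert len(greedy.circrnas) >= len(exact.circrnas)

    def test_planted_two_circ_cover_recovered(self):
        # two circRNAs split the targets; no single circ covers everything
        cm = {("cA", "mA"), ("cB", "mB"), ("cC", "mC")}
        mg = {("mA", "G1"), ("mA", "G2"), ("mB", "G3"), ("mB", "G4"), ("mC", "G1")}
        net = CeRNANetwork(frozenset(cm), frozenset(mg))
        mc = min_cover(net, {"G1", "G2", "G3", "G4"})
        assert mc.exact and mc.circrnas == {"cA", "cB"}


class TestSharedMirnas:
    def test_candidate_shares_three_mirnas_with_asd_group(self, table1_sponge, table2_sponge):
        sm = shared_mirnas("hsa-MAN1A2_0008", table2_sponge, table1_sponge)
        assert set(sm) == {"hsa-miR-6875-3p", "hsa-miR-942-5p", "hsa-miR-4722-5p"}

    def test_mir6875_partners_match_published_list(self, table1_sponge, table2_sponge):
        sm = shared_mirnas("hsa-MAN1A2_0008", table2_sponge, table1_sponge)
        assert sm["hsa-miR-6875-3p"] == {
            "hsa-PAPPA2_0005", "hsa-PAPPA_0016", "hsa-SCLT1_0001", "hsa-ERC1_0001"
        }

    def test_disjoint_groups_share_nothing(self):
        a = SpongeMap(frozenset({("c1", "m1")}))
        b = SpongeMap(frozenset({("c2", "m2")}))
        assert shared_mirnas("c1", a, b) == {}

    def test_unknown_circ_errors(self, table2_sponge, table1_sponge):
        with pytest.raises(ValidationError):
            shared_mirnas("hsa-NOPE_0001", table2_sponge, table1_sponge)
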