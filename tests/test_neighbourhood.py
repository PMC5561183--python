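import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcekit.architecture import Architecture, architectures_from_hits
from mcekit.io import GeneLocus
from mcekit.neighbourhood import (
    Neighbourhood,
    NeighbourhoodWeights,
    cluster_neighbourhoods,
    extract_neighbourhood,
    neighbourhood_similarity,
    summarise_neighbourhoods,
)


def locus(gid, start, end, strand="+", contig="c1", genome="G1", pid=None):
    return GeneLocus(gid, genome, contig, start, end, strand, pid or gid)


def arch_map(**types):
    """protein_id -> single-domain Architecture named after its value."""
    out = {}
    for pid, domain in types.items():
        if domain == "MCE":
            out[pid] = Architecture(pid, ("MCE",), 1, "I")
        elif domain is None:
            out[pid] = Architecture(pid, (), 0, "non_mce")
        else:
            out[pid] = Architecture(pid, (domain,), 0, "non_mce")
    return out


def nbhd(focal, slots, focal_type="I"):
    return Neighbourhood(focal, focal_type, slots, orientation_normalized=True)


W = NeighbourhoodWeights(r=0.5)


class TestWeights:
    def test_centre_weight_is_one(self):
        assert W.weight(1) == 1.0
        assert W.weight(-1) == 1.0

    def test_non_increasing_in_distance(self):
        values = [W.weight(i) for i in range(1, 11)]
        assert values == sorted(values, reverse=True)

    def test_invalid_r_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                NeighbourhoodWeights(r=bad)


class TestExtractNeighbourhood:
    def test_simple_geometry(self):
        loci = [
            locus("up", 8000, 9000),
            locus("focal", 10000, 11000, pid="F"),
            locus("down", 12000, 13000),
        ]
        archs = arch_map(F="MCE", up="PermA", down="DUF330")
        n = extract_neighbourhood(loci, loci[1], archs)
        assert n.slots == {-1: "PermA", +1: "DUF330"}
        assert n.focal_type == "I"

    def test_minus_strand_swaps_sides(self):
        loci = [
            locus("up", 8000, 9000, strand="-"),
            locus("focal", 10000, 11000, strand="-", pid="F"),
            locus("down", 12000, 13000, strand="-"),
        ]
        archs = arch_map(F="MCE", up="PermA", down="DUF330")
        n = extract_neighbourhood(loci, loci[1], archs)
        assert n.slots == {+1: "PermA", -1: "DUF330"}

    def test_at_most_max_genes_per_side(self):
        loci = [locus("focal", 50000, 51000, pid="F")]
        archs = {"F": Architecture("F", ("MCE",), 1, "I")}
        for i in range(12):  # 12 genes upstream within 10 kb
            start = 49500 - i * 700
            loci.append(locus(f"u{i}", start - 400, start))
            archs[f"u{i}"] = Architecture(f"u{i}", (f"D{i}",), 0, "non_mce")
        loci.sort(key=lambda g: g.start)
        focal = next(g for g in loci if g.gene_id == "focal")
        n = extract_neighbourhood(loci, focal, archs)
        assert set(n.slots) == {-i for i in range(1, 11)}
        assert n.slots[-1] == "D0"  # nearest gene occupies slot -1
        assert n.slots[-10] == "D9"

    def test_window_cut_uses_boundary_distance(self):
        loci = [
            locus("far", 1, 100),  # gap to focal start: 19900 > 10000
            locus("near", 12000, 13000),
            locus("focal", 20000, 21000, pid="F"),
        ]
        archs = arch_map(F="MCE", far="X", near="Y")
        n = extract_neighbourhood(loci, loci[2], archs)
        assert n.slots == {-1: "Y"}

    def test_other_contigs_excluded(self):
        loci = [
            locus("focal", 10000, 11000, pid="F"),
            locus("elsewhere", 10500, 11500, contig="c2"),
        ]
        archs = arch_map(F="MCE", elsewhere="X")
        n = extract_neighbourhood(loci, loci[0], archs)
        assert n.slots == {}

    def test_domainless_neighbour_is_matchable_none(self):
        loci = [locus("focal", 10000, 11000, pid="F"), locus("bare", 12000, 12500)]
        archs = arch_map(F="MCE", bare=None)
        n = extract_neighbourhood(loci, loci[0], archs)
        assert n.slots == {+1: "NONE"}

    def test_synonym_merging_applied(self):
        loci = [locus("focal", 10000, 11000, pid="F"), locus("nbr", 12000, 12500)]
        archs = {
            "F": Architecture("F", ("MCE",), 1, "I"),
            "nbr": Architecture("nbr", ("ABC_tran", "AAA_21"), 0, "non_mce"),
        }
        n = extract_neighbourhood(
            loci, loci[0], archs, synonym_map={"ABC_tran, AAA_21": "ABC_tran"}
        )
        assert n.slots == {+1: "ABC_tran"}

    def test_focal_absent_from_loci_is_error(self):
        ghost = locus("ghost", 1000, 2000, pid="F")
        with pytest.raises(ValueError, match="ghost"):
            extract_neighbourhood([locus("a", 1, 100)], ghost, {})


class TestSimilarity:
    def test_identity_is_one(self):
        a = nbhd("a", {-1: "X", +2: "Y"})
        assert neighbourhood_similarity(a, a, W) == 1.0

    def test_total_disagreement_is_zero(self):
        a = nbhd("a", {-1: "X", +1: "Y"})
        b = nbhd("b", {-1: "Z", +1: "Q"})
        assert neighbourhood_similarity(a, b, W) == 0.0

    def test_hand_computed_case(self):
        # matches at +-1, mismatch at +2, all else absent in both:
        # S = (1 + 1) / (1 + 1 + 0.5) = 0.8
        a = nbhd("a", {-1: "P", +1: "Q", +2: "R"})
        b = nbhd("b", {-1: "P", +1: "Q", +2: "S"})
        assert neighbourhood_similarity(a, b, W) == pytest.approx(0.8)

    def test_present_vs_absent_is_mismatch(self):
        a = nbhd("a", {-1: "P", +1: "Q"})
        b = nbhd("b", {-1: "P"})
        assert neighbourhood_similarity(a, b, W) == pytest.approx(0.5)

    def test_non_normalized_rejected(self):
        a = nbhd("a", {-1: "P"})
        raw = Neighbourhood("b", "I", {-1: "P"}, orientation_normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            neighbourhood_similarity(a, raw, W)

    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetric_and_bounded(self, seed):
        rng = random.Random(seed)

        def rand_nbhd(name):
            slots = {
                i: rng.choice("XYZ")
                for i in range(-5, 6)
                if i != 0 and rng.random() < 0.5
            }
            return nbhd(name, slots)

        a, b = rand_nbhd("a"), rand_nbhd("b")
        s = neighbourhood_similarity(a, b, W)
        assert 0.0 <= s <= 1.0
        assert s == neighbourhood_similarity(b, a, W)
        if a.slots:
            assert neighbourhood_similarity(a, a, W) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10**6), st.integers(2, 8))
    def test_inner_corruption_costs_at_least_as_much(self, seed, k):
        rng = random.Random(seed)
        slots = {i: "X" for i in range(-8, 9) if i != 0}
        a = nbhd("a", slots)
        inner = dict(slots)
        inner[1] = "CORRUPT"
        outer = dict(slots)
        outer[k] = "CORRUPT"
        s_inner = neighbourhood_similarity(a, nbhd("b", inner), W)
        s_outer = neighbourhood_similarity(a, nbhd("c", outer), W)
        assert s_inner <= s_outer


class TestClustering:
    def test_identical_pair_merges_at_one(self):
        a = nbhd("a", {-1: "X"})
        b = nbhd("b", {-1: "X"})
        result = cluster_neighbourhoods([a, b], W, tau=0.5)
        assert len(set(result.labels.values())) == 1
        assert result.trace == (("a", "b", 1.0),)

    def test_all_dissimilar_stay_singletons(self):
        ns = [nbhd(f"n{i}", {-1: f"X{i}"}) for i in range(4)]
        result = cluster_neighbourhoods(ns, W, tau=0.1)
        assert len(set(result.labels.values())) == 4
        assert result.trace == ()

    def test_three_planted_classes_recovered(self):
        ns = []
        planted = {}
        for cls, pattern in enumerate(
            [{-1: "A", +1: "B"}, {-1: "C", +1: "D"}, {-1: "E", +1: "F"}]
        ):
            for i in range(4):
                slots = dict(pattern)
                if i % 2:
                    slots[+3] = "NOISE"  # within-class S stays >= 0.8
                name = f"c{cls}_{i}"
                ns.append(nbhd(name, slots))
                planted[name] = cls
        result = cluster_neighbourhoods(ns, W, tau=0.5)
        assert len(set(result.labels.values())) == 3
        for x, cx in planted.items():
            for y, cy in planted.items():
                assert (result.labels[x] == result.labels[y]) == (cx == cy)

    def test_trace_similarities_non_increasing(self):
        rng = random.Random(3)
        ns = [
            nbhd(
                f"n{i}",
                {j: rng.choice("XY") for j in range(-3, 4) if j != 0},
            )
            for i in range(12)
        ]
        result = cluster_neighbourhoods(ns, W, tau=0.0, linkage="single")
        sims = [s for _, _, s in result.trace]
        assert sims == sorted(sims, reverse=True)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            cluster_neighbourhoods([nbhd("a", {-1: "X"})], W, tau=1.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_neighbourhoods([], W, tau=0.5)


class TestSummarise:
    def test_single_neighbourhood_is_100_percent(self):
        ns = [nbhd("a", {-1: "X"})]
        clustering = cluster_neighbourhoods(ns, W, tau=0.5)
        summary = summarise_neighbourhoods(clustering, ns, "I")
        assert summary.iloc[0]["percentage"] == pytest.approx(100.0)
        assert summary.iloc[0]["consensus"] == "-1:X"

    def test_two_equal_clusters_split_50_50(self):
        ns = [nbhd(f"a{i}", {-1: "X"}) for i in range(5)] + [
            nbhd(f"b{i}", {-1: "Y"}) for i in range(5)
        ]
        clustering = cluster_neighbourhoods(ns, W, tau=0.5)
        summary = summarise_neighbourhoods(clustering, ns, "I")
        assert sorted(summary["percentage"]) == [pytest.approx(50.0)] * 2
        assert summary["percentage"].sum() == pytest.approx(100.0)

    def test_majority_consensus_per_slot(self):
        ns = [
            nbhd("a", {-1: "X", +1: "Q"}),
            nbhd("b", {-1: "X", +1: "Q"}),
            nbhd("c", {-1: "X", +1: "R"}),
        ]
        clustering = cluster_neighbourhoods(ns, W, tau=0.5)
        summary = summarise_neighbourhoods(clustering, ns, "I")
        assert summary.iloc[0]["consensus"] == "-1:X|+1:Q"

    def test_fifty_nine_of_hundred_pattern(self):
        # arithmetic pattern: one cluster of 59 among 100 focal genes -> 59%
        ns = [nbhd(f"m{i}", {-1: "Perm", +1: "DUF330"}) for i in range(59)]
        ns += [nbhd(f"o{i}", {-1: f"U{i}", +1: f"V{i}"}) for i in range(41)]
        clustering = cluster_neighbourhoods(ns, W, tau=0.5)
        summary = summarise_neighbourhoods(clustering, ns, "I")
        assert summary.iloc[0]["size"] == 59
        assert summary.iloc[0]["percentage"] == pytest.approx(59.0)


class TestStrandFlipInvariance:
    def _flip(self, loci):
        span = max(g.end for g in loci) + 1000
        return [
            GeneLocus(
                g.gene_id, g.genome_id, g.contig,
                span - g.end + 1, span - g.start + 1,
                "+" if g.strand == "-" else "-", g.protein_id,
            )
            for g in loci
        ]

    def test_reverse_complementing_contig_preserves_neighbourhoods(
        self, small_dataset, small_architectures
    ):
        ds = small_dataset
        focal_genes = {g.gene_id: g for g in ds.loci}
        flipped_all = []
        by_contig = {}
        for g in ds.loci:
            by_contig.setdefault((g.genome_id, g.contig), []).append(g)
        flipped_map = {}
        for contig_genes in by_contig.values():
            for g in self._flip(contig_genes):
                flipped_map[g.gene_id] = g
                flipped_all.append(g)
        checked = 0
        for row in ds.truth.context_truth.itertuples():
            focal = focal_genes[row.gene_id]
            orig = extract_neighbourhood(ds.loci, focal, small_architectures)
            flip = extract_neighbourhood(
                flipped_all, flipped_map[row.gene_id], small_architectures
            )
            assert flip.slots == orig.slots, row.gene_id
            checked += 1
        assert checked > 10


class TestContextRecovery:
    def test_top_consensus_matches_planted_template(
        self, small_dataset, small_architectures
    ):
        ds = small_dataset
        by_gene = {g.gene_id: g for g in ds.loci}
        for focal_type in ("I", "III", "IV"):
            rows = ds.truth.context_truth[
                ds.truth.context_truth["focal_type"] == focal_type
            ]
            ns = [
                extract_neighbourhood(ds.loci, by_gene[r.gene_id], small_architectures)
                for r in rows.itertuples()
            ]
            clustering = cluster_neighbourhoods(ns, W, tau=0.5)
            summary = summarise_neighbourhoods(clustering, ns, focal_type)
            assert summary.iloc[0]["consensus"] == rows.iloc[0]["template"]


class TestEcoliFixture:
    def test_type_labels(self, ecoli):
        archs = architectures_from_hits(
            ecoli.hits, protein_ids=[p.protein_id for p in ecoli.proteins]
        )
        assert archs["mlaD"].type_label == "I"
        assert archs["pqiB"].type_label == "III"
        assert archs["yebT"].type_label == "IV"

    def test_pqiB_neighbourhood(self, ecoli):
        archs = architectures_from_hits(
            ecoli.hits, protein_ids=[p.protein_id for p in ecoli.proteins]
        )
        by_gene = {g.gene_id: g for g in ecoli.loci}
        n = extract_neighbourhood(ecoli.loci, by_gene["pqiB_g"], archs)
        assert n.slots[-1] == "PqiA"
        assert n.slots[+1] == "DUF330"

    def test_yebT_has_no_duf330(self, ecoli):
        archs = architectures_from_hits(
            ecoli.hits, protein_ids=[p.protein_id for p in ecoli.proteins]
        )
        by_gene = {g.gene_id: g for g in ecoli.loci}
        n = extract_neighbourhood(ecoli.loci, by_gene["yebT_g"], archs)
        assert "DUF330" not in n.slots.values()
        assert n.slots[-1] == "PqiA"
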