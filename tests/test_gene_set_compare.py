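import numpy as np
import pytest

from gcstratify.gene_set_compare import (
    cluster_loci,
    find_improved,
    find_novel,
    select_best_per_locus,
)
from gcstratify.io_formats import ModelError
from gcstratify.synthetic import (
    SOURCE_LABELS,
    SimulationConfig,
    simulate_genome,
    simulate_sources,
)

from conftest import make_model


def m(tid, start, end, strand="+", seqid="chr1", source="orig_snap", aed=None):
    return make_model(tid=tid, seqid=seqid, cds=[(start, end)], start=start,
                      end=end, strand=strand, source=source, aed=aed)


class TestClusterLoci:
    def test_transitive_chain_is_one_locus(self):
        loci = cluster_loci([m("A", 1, 100), m("B", 50, 150), m("C", 140, 200)])
        assert len(loci) == 1
        assert {x.transcript_id for x in loci[0].members} == {"A", "B", "C"}
        assert (loci[0].span.start, loci[0].span.end) == (1, 200)

    def test_opposite_strands_split_when_strand_aware(self):
        models = [m("A", 1, 100, "+"), m("B", 50, 150, "-")]
        assert len(cluster_loci(models, strand_aware=True)) == 2
        assert len(cluster_loci(models, strand_aware=False)) == 1

    def test_disjoint_models_are_singletons(self):
        loci = cluster_loci([m("A", 1, 100), m("B", 300, 400), m("C", 600, 700)])
        assert [len(l.members) for l in loci] == [1, 1, 1]

    def test_deterministic_ordering(self):
        models = [m("B", 300, 400, seqid="chr2"), m("A", 1, 100), m("C", 600, 700)]
        loci = cluster_loci(models)
        assert [(l.seqid, l.span.start) for l in loci] == [
            ("chr1", 1), ("chr1", 600), ("chr2", 300)
        ]


class TestSelectBest:
    def test_min_aed_wins(self):
        loci = cluster_loci([m("a", 1, 100, aed=0.3, source="orig_snap"),
                             m("b", 1, 100, aed=0.1, source="high_snap")])
        best = select_best_per_locus(loci, SOURCE_LABELS)
        assert [x.transcript_id for x in best] == ["b"]

    def test_aed_tie_goes_to_longer_spliced_length(self):
        loci = cluster_loci([m("short", 1, 900, aed=0.2), m("long", 1, 1200, aed=0.2)])
        assert select_best_per_locus(loci)[0].transcript_id == "long"

    def test_full_tie_resolved_by_source_order(self):
        models = [m("x", 1, 100, aed=0.2, source="low_snap"),
                  m("y", 1, 100, aed=0.2, source="orig_aug")]
        best = select_best_per_locus(cluster_loci(models), SOURCE_LABELS)
        assert best[0].transcript_id == "y"  # orig_aug precedes low_snap
        # and is stable under input permutation
        best2 = select_best_per_locus(cluster_loci(models[::-1]), SOURCE_LABELS)
        assert best2[0].transcript_id == "y"

    def test_missing_aed_is_error(self):
        with pytest.raises(ModelError):
            select_best_per_locus(cluster_loci([m("a", 1, 100)]))

    def test_one_winner_per_locus(self):
        rng = np.random.default_rng(2)
        models = []
        for i in range(40):
            base = 1 + 500 * i
            for j, lab in enumerate(SOURCE_LABELS):
                models.append(m(f"{lab}:{i}", base, base + 99, source=lab,
                                aed=float(rng.random())))
        loci = cluster_loci(models)
        best = select_best_per_locus(loci, SOURCE_LABELS)
        assert len(best) == len(loci) == 40


class TestFindNovel:
    def test_overlap_is_not_novel(self):
        assert find_novel([m("q", 100, 200)], [m("r", 150, 250)]) == []

    def test_other_seqid_is_novel(self):
        novel = find_novel([m("q", 1, 100, seqid="chr2")], [m("r", 1, 100, seqid="chr1")])
        assert [x.transcript_id for x in novel] == ["q"]

    def test_single_bp_overlap_is_not_novel(self):
        assert find_novel([m("q", 100, 200)], [m("r", 200, 300)]) == []
        novel = find_novel([m("q", 100, 200)], [m("r", 201, 300)])
        assert [x.transcript_id for x in novel] == ["q"]

    def test_strand_agnostic_by_default(self):
        assert find_novel([m("q", 100, 200, "+")], [m("r", 100, 200, "-")]) == []

    def test_self_comparison_is_empty(self):
        models = [m(f"t{i}", 1 + 300 * i, 100 + 300 * i) for i in range(5)]
        assert find_novel(models, models) == []

    def test_antitone_in_reference_collection(self):
        rng = np.random.default_rng(10)
        query = [m(f"q{i}", int(s), int(s) + 50) for i, s in
                 enumerate(rng.integers(1, 5000, 30))]
        ref1 = [m(f"r{i}", int(s), int(s) + 50) for i, s in
                enumerate(rng.integers(1, 5000, 20))]
        ref2 = [m(f"s{i}", int(s), int(s) + 50) for i, s in
                enumerate(rng.integers(1, 5000, 20))]
        with_one = {x.transcript_id for x in find_novel(query, ref1)}
        with_two = {x.transcript_id for x in find_novel(query, ref1, ref2)}
        assert with_two <= with_one


class TestFindImproved:
    def test_lower_aed_from_nonstandard_source(self):
        std = [m("s", 1, 100, aed=0.4, source="orig_snap")]
        merged = [m("h", 1, 100, aed=0.2, source="high_snap")]
        out = find_improved(std, merged)
        assert len(out) == 1
        imp = out[0]
        assert (imp.standard_id, imp.replacement_id) == ("s", "h")
        assert (imp.aed_before, imp.aed_after) == (0.4, 0.2)

    def test_standard_model_itself_is_not_improvement(self):
        std = [m("s", 1, 100, aed=0.4, source="orig_snap")]
        assert find_improved(std, std) == []

    def test_equal_aed_is_not_improvement(self):
        std = [m("s", 1, 100, aed=0.2, source="orig_snap")]
        merged = [m("h", 1, 100, aed=0.2, source="high_snap")]
        assert find_improved(std, merged) == []


class TestAgainstSimulatedSixSources:
    def test_merge_equals_per_locus_argmin_oracle(self):
        cfg = SimulationConfig(seed=21, n_genes=120)
        genome, models, truth = simulate_genome(cfg)
        sources = simulate_sources(models, truth, cfg)
        all_models = [x for lst in sources.values() for x in lst]
        merged = select_best_per_locus(cluster_loci(all_models), SOURCE_LABELS)

        # oracle: the six copies of one true gene share its exact coordinates,
        # so group by the true transcript id and take the argmin by the same
        # tie-break chain, brute force
        rank = {s: i for i, s in enumerate(SOURCE_LABELS)}
        by_gene = {}
        for x in all_models:
            by_gene.setdefault(x.transcript_id.split(":")[1], []).append(x)
        expected = {
            min(v, key=lambda x: (x.aed, -x.spliced_length, rank[x.source_label],
                                  x.transcript_id)).transcript_id
            for v in by_gene.values()
        }
        assert {x.transcript_id for x in merged} == expected

    def test_improved_flags_exactly_nonstandard_strict_wins(self):
        cfg = SimulationConfig(seed=22, n_genes=100)
        genome, models, truth = simulate_genome(cfg)
        sources = simulate_sources(models, truth, cfg)
        standard = sources["orig_snap"]
        all_models = [x for lst in sources.values() for x in lst]
        merged = select_best_per_locus(cluster_loci(all_models), SOURCE_LABELS)
        improved = find_improved(standard, merged,
                                 standard_sources=("orig_snap", "orig_aug"))
        got = {i.standard_id for i in improved}

        merged_by_gene = {x.transcript_id.split(":")[1]: x for x in merged}
        expect = set()
        for s in standard:
            winner = merged_by_gene[s.transcript_id.split(":")[1]]
            if winner.source_label not in ("orig_snap", "orig_aug") and winner.aed < s.aed:
                expect.add(s.transcript_id)
        assert got == expect
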