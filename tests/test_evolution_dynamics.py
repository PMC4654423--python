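import numpy as np
import pytest

from wrky.evolution_dynamics import (
    HomologPair,
    codon_align,
    detect_segmental,
    detect_tandem,
    divergence_time,
    find_homolog_pairs,
    ng86_kaks,
    reciprocal_best_hits,
    segmental_pairs,
)
from wrky.io_formats import GeneModel, SeqRecord
from wrky.synthetic_data import generate_genome, random_cds

from oracles import ng86_oracle


def _pair(a, b):
    return HomologPair(*sorted((a, b)), identity=1.0, aln_length=100)


def _models(spec):
    """spec: list of (gene_id, chromosome, rank)."""
    return {
        gid: GeneModel(gid, chrom, "+", ((rank * 1000 + 1, rank * 1000 + 500),),
                       rank)
        for gid, chrom, rank in spec
    }


class TestHomologPairs:
    def test_identical_pair_included(self):
        recs = [SeqRecord("a", "MKVLLDAGHE" * 10),
                SeqRecord("b", "MKVLLDAGHE" * 10)]
        pairs = find_homolog_pairs(recs)
        assert len(pairs) == 1 and pairs[0].identity == 1.0

    def test_divergent_pair_excluded(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        other = list(seq)
        for i in rng.choice(100, size=20, replace=False):
            other[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
        recs = [SeqRecord("a", seq), SeqRecord("b", "".join(other))]
        assert find_homolog_pairs(recs, min_identity=0.90) == []

    def test_three_identical_give_three_pairs(self):
        recs = [SeqRecord(x, "MKVLLDAGHE" * 8) for x in "abc"]
        assert len(find_homolog_pairs(recs)) == 3


class TestTandem:
    def test_adjacent_ranks(self):
        models = _models([("a", "chr1", 4), ("b", "chr1", 5)])
        out = detect_tandem([_pair("a", "b")], models)
        assert [d.dup_type for d in out] == ["tandem"]

    def test_different_chromosomes(self):
        models = _models([("a", "chr1", 4), ("b", "chr2", 5)])
        assert detect_tandem([_pair("a", "b")], models) == []

    def test_rank_distance_rule(self):
        models = _models([("a", "chr1", 4), ("b", "chr1", 7)])
        assert detect_tandem([_pair("a", "b")], models, max_intervening=1) == []


class TestSegmental:
    def test_planted_collinear_run(self):
        spec = [(f"a{i}", "chrA", i + 1) for i in range(5)]
        spec += [(f"b{i}", "chrB", i + 1) for i in range(5)]
        models = _models(spec)
        pairs = [_pair(f"a{i}", f"b{i}") for i in range(5)]
        blocks = detect_segmental(pairs, models)
        assert len(blocks) == 1
        assert blocks[0].size == 5 and blocks[0].orientation == "same"

    def test_genome_order_shuffle_gives_no_block(self):
        # a genome-wide order shuffle scatters matched ranks beyond the
        # chaining gap, so no collinear block survives
        scattered = [36, 12, 60, 24, 48]
        spec = [(f"a{i}", "chrA", i + 1) for i in range(5)]
        spec += [(f"b{i}", "chrB", scattered[i]) for i in range(5)]
        models = _models(spec)
        pairs = [_pair(f"a{i}", f"b{i}") for i in range(5)]
        assert detect_segmental(pairs, models, min_block=3,
                                max_rank_gap=10) == []

    def test_inverted_run(self):
        spec = [(f"a{i}", "chrA", i + 1) for i in range(4)]
        spec += [(f"b{i}", "chrB", 10 - i) for i in range(4)]
        models = _models(spec)
        pairs = [_pair(f"a{i}", f"b{i}") for i in range(4)]
        blocks = detect_segmental(pairs, models)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_pairs_belong_to_one_block_only(self):
        spec = [(f"a{i}", "chrA", i + 1) for i in range(6)]
        spec += [(f"b{i}", "chrB", i + 1) for i in range(6)]
        models = _models(spec)
        pairs = [_pair(f"a{i}", f"b{i}") for i in range(6)]
        blocks = detect_segmental(pairs, models)
        seen = [p.pair for p in segmental_pairs(blocks)]
        assert len(seen) == len(set(seen))


class TestCodonAlign:
    def test_gap_propagation(self):
        rows = codon_align([("x", "MK-V")], {"x": "ATGAAAGTT"})
        assert rows[0][1] == "ATGAAA---GTT"

    def test_terminal_stop_stripped(self):
        rows = codon_align([("x", "MKV")], {"x": "ATGAAAGTTTAA"})
        assert rows[0][1] == "ATGAAAGTT"

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="x"):
            codon_align([("x", "MKV")], {"x": "ATGAAAGTTC"})

    def test_internal_stop(self):
        with pytest.raises(ValueError, match="stop"):
            codon_align([("x", "M*KV")], {"x": "ATGTAAAAAGTT"})


class TestNG86:
    def test_identical_sequences(self):
        cds = "ATGAAAGTTGCC"
        r = ng86_kaks(cds, cds)
        assert r.ka == 0 and r.ks == 0 and r.ratio is None

    def test_single_nonsynonymous_change_closed_form(self):
        # 12 lysine codons; one AAA -> AAC (K -> N) nonsynonymous change
        a = "AAA" * 12
        b = "AAC" + "AAA" * 11
        r = ng86_kaks(a, b)
        # AAA and AAC each have 1 synonymous change of 3 at position 3
        assert r.S == pytest.approx(4.0)
        assert r.N == pytest.approx(32.0)
        assert r.ks == 0
        pn = 1.0 / 32.0
        assert r.ka == pytest.approx(-0.75 * np.log(1 - 4 * pn / 3))

    def test_symmetry(self, rng):
        a = random_cds(50, rng)
        b = random_cds(50, rng)
        r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
        assert r1.sd == pytest.approx(r2.sd)
        assert r1.nd == pytest.approx(r2.nd)
        assert r1.S == pytest.approx(r2.S)

    def test_site_count_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            a, b = random_cds(n, rng), random_cds(n, rng)
            r = ng86_kaks(a, b)
            assert r.S + r.N == pytest.approx(3 * r.n_codons, abs=1e-9)

    def test_agrees_with_pathway_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 4))
            a, b = random_cds(n, rng), random_cds(n, rng)
            r = ng86_kaks(a, b)
            S, N, sd, nd, ks, ka = ng86_oracle(list(zip(
                [a[i:i + 3] for i in range(0, 3 * n, 3)],
                [b[i:i + 3] for i in range(0, 3 * n, 3)],
            )))
            assert r.S == pytest.approx(S) and r.N == pytest.approx(N)
            assert r.sd == pytest.approx(sd) and r.nd == pytest.approx(nd)

    def test_gap_codons_dropped(self):
        r = ng86_kaks("ATGAAA---", "ATG---GTT")
        assert r.n_codons == 1

    def test_no_comparable_codons(self):
        with pytest.raises(ValueError):
            ng86_kaks("---", "---")

    def test_saturation_flagged(self):
        # Trp vs Gln codons: few synonymous sites, many synonymous-path
        # differences -> the synonymous proportion saturates
        a = "TGG" * 30
        b = "CAA" * 30
        r = ng86_kaks(a, b)
        assert r.ks_saturated and r.ks is None and r.ratio is None


class TestDating:
    def test_zero(self):
        assert divergence_time(0.0) == 0.0

    def test_published_worked_example(self):
        assert divergence_time(0.13, 6.5e-9) == pytest.approx(1.0e7)

    def test_scale(self):
        assert divergence_time(0.0611) == pytest.approx(4.7e6, rel=0.01)

    def test_linearity_and_lambda_override(self):
        assert divergence_time(0.2) == pytest.approx(2 * divergence_time(0.1))
        assert divergence_time(0.13, 1.3e-8) == pytest.approx(5.0e6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)


class TestRBH:
    def test_identity_mapping_on_copy(self, rng):
        recs = [
            SeqRecord(f"p{i}",
                      "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                         size=80)))
            for i in range(5)
        ]
        copies = [SeqRecord(f"q{i}", r.sequence) for i, r in enumerate(recs)]
        rbh = reciprocal_best_hits(recs, copies)
        assert rbh == [(f"p{i}", f"q{i}") for i in range(5)]

    def test_planted_ortholog_with_decoys(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        ortho = list(seq)
        for i in rng.choice(100, size=5, replace=False):
            ortho[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
        decoys = [
            SeqRecord(f"d{k}",
                      "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                         size=100)))
            for k in range(3)
        ]
        rbh = reciprocal_best_hits(
            [SeqRecord("a", seq)],
            [SeqRecord("b", "".join(ortho))] + decoys,
            min_identity=0.90,
        )
        assert rbh == [("a", "b")]

    def test_tie_gives_no_call(self):
        a = [SeqRecord("a", "MKVLLDAGHE" * 8)]
        b = [SeqRecord("b1", "MKVLLDAGHE" * 8),
             SeqRecord("b2", "MKVLLDAGHE" * 8)]
        assert reciprocal_best_hits(a, b) == []

    def test_symmetric_under_swap(self, rng):
        recs = [
            SeqRecord(f"p{i}",
                      "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                         size=60)))
            for i in range(4)
        ]
        others = [SeqRecord(f"q{i}", r.sequence) for i, r in enumerate(recs)]
        ab = set(reciprocal_best_hits(recs, others))
        ba = {(x, y) for y, x in reciprocal_best_hits(others, recs)}
        assert ab == ba


class TestGenomeRoundTrip:
    def test_planted_duplications_recovered(self):
        g = generate_genome(n_chromosomes=2, genes_per_chr=30,
                            n_tandem_pairs=1,
                            segmental_blocks=((0, 1, 5, False),), seed=11)
        models = g.models_by_id()
        pairs = g.truth_pairs()
        truth_tandem = {
            tuple(sorted((p["id_a"], p["id_b"])))
            for p in g.truth["pairs"] if p["dup_type"] == "tandem"
        }
        tandem = detect_tandem(pairs, models)
        assert {(d.pair.id_a, d.pair.id_b) for d in tandem} == truth_tandem
        blocks = detect_segmental(
            [p for p in pairs if (p.id_a, p.id_b) not in truth_tandem], models
        )
        assert len(blocks) == 1 and blocks[0].size == 5

    def test_no_plants_no_detections(self):
        g = generate_genome(n_chromosomes=2, genes_per_chr=10,
                            n_tandem_pairs=0, segmental_blocks=(), seed=5)
        assert g.truth_pairs() == []
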