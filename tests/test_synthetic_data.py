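import numpy as np
import pytest
from Bio.Seq import Seq

from wrky.domain_grammar import assemble_domains
from wrky.family_classifier import assign_group
from wrky.regulation_expression import CREPattern, scan_cre
from wrky.synthetic_data import (
    generate_ct_table,
    generate_counts,
    generate_genome,
    generate_promoters,
    generate_proteome,
    generate_wrky_protein,
    mutate_cds,
    paper_shaped,
    random_cds,
)


class TestDeterminism:
    def test_protein_generation(self):
        a = generate_wrky_protein("IIc", seed=42)
        b = generate_wrky_protein("IIc", seed=42)
        assert a == b

    def test_genome_generation(self):
        g1 = generate_genome(seed=3)
        g2 = generate_genome(seed=3)
        assert g1.chromosomes == g2.chromosomes
        assert g1.cds == g2.cds
        assert g1.truth == g2.truth

    def test_ct_table(self):
        t1, _ = generate_ct_table(["g"], ["c"], {}, seed=1)
        t2, _ = generate_ct_table(["g"], ["c"], {}, seed=1)
        assert t1.equals(t2)


class TestProteinGenerator:
    @pytest.mark.parametrize("group,expected", [
        ("I", "I"), ("IIa", "II"), ("IIe", "II"), ("III", "III"), ("IV", "IV"),
    ])
    def test_round_trip(self, group, expected, rng):
        seq, truth = generate_wrky_protein(group, rng=rng)
        assert assign_group(assemble_domains(seq)) == expected
        assert truth["group"] == group

    def test_group_iii_has_single_c2hc(self, rng):
        seq, _ = generate_wrky_protein("III", rng=rng)
        doms = [d for d in assemble_domains(seq) if d.complete]
        assert len(doms) == 1
        assert doms[0].zinc_finger.finger_type == "C2HC"

    def test_group_i_has_two_complete_domains(self, rng):
        seq, _ = generate_wrky_protein("I", rng=rng)
        assert sum(d.complete for d in assemble_domains(seq)) == 2

    def test_length_floor_enforced(self):
        with pytest.raises(ValueError):
            generate_wrky_protein("I", length=60, seed=0)

    def test_proteome_truth_serialised(self, rng):
        records, truth = generate_proteome({"IIa": 2, "III": 1}, n_decoys=2,
                                           rng=rng)
        assert len(records) == 5
        from collections import Counter

        assert Counter(truth["group"]) == {"IIa": 2, "III": 1, "none": 2}


class TestMutateCds:
    def test_zero_targets_identity(self, rng):
        cds = random_cds(100, rng)
        assert mutate_cds(cds, 0.0, 0.0, rng=rng) == cds

    def test_ka_zero_preserves_translation(self, rng):
        cds = random_cds(150, rng)
        out = mutate_cds(cds, 0.3, 0.0, rng=rng)
        assert out != cds
        assert str(Seq(out).translate()) == str(Seq(cds).translate())

    def test_no_stops_created(self, rng):
        for _ in range(5):
            cds = random_cds(80, rng)
            out = mutate_cds(cds, 0.4, 0.2, rng=rng)
            assert "*" not in str(Seq(out).translate())

    def test_protected_codons_untouched_in_protein(self, rng):
        cds = random_cds(100, rng)
        protected = frozenset(range(10, 20))
        out = mutate_cds(cds, 0.2, 0.3, rng=rng, protected_codons=protected)
        before = str(Seq(cds).translate())
        after = str(Seq(out).translate())
        assert before[10:20] == after[10:20]

    def test_target_recovery_mean(self):
        from wrky.evolution_dynamics import ng86_kaks

        est = []
        for s in range(15):
            rng = np.random.default_rng(500 + s)
            a = random_cds(300, rng)
            b = mutate_cds(a, 0.3, 0.1, rng=rng)
            est.append(ng86_kaks(a, b).ks)
        assert np.mean(est) == pytest.approx(0.3, abs=0.01)


class TestPromoters:
    def test_exact_round_trip_with_wbox_catalog(self):
        catalog = [CREPattern("WBOXNT", "YTGACY", "W-box")]
        spec = {0: [("WBOXNT", 137, "-")], 1: [("WBOXNT", 20, "+")]}
        records, truth = generate_promoters(3, catalog, spec, seed=9)
        for rec in records:
            hits = scan_cre(rec.sequence, catalog, rec.id)
            planted = [t for t in truth if t.promoter_id == rec.id]
            assert {(h.pattern, h.start, h.strand) for h in hits} == {
                (t.pattern, t.start, t.strand) for t in planted
            }

    def test_unplanted_promoters_clean(self):
        catalog = [CREPattern("WBOXNT", "YTGACY", "W-box")]
        records, _ = generate_promoters(2, catalog, {}, seed=2)
        for rec in records:
            assert scan_cre(rec.sequence, catalog) == []


class TestExpressionGenerators:
    def test_counts_fold_recovery(self):
        genes = [f"g{i}" for i in range(30)]
        folds = {("g0", "treated"): 4.0}
        counts, lengths, _ = generate_counts(
            genes, ["control", "treated"], folds, seed=8
        )
        from wrky.regulation_expression import rpkm

        expr = rpkm(counts, lengths,
                    {"control": 2e6, "treated": 2e6})
        ratio = expr.loc["g0", "treated"] / expr.loc["g0", "control"]
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_ct_exact_recovery_at_zero_noise(self):
        folds = {("g1", "cond", "1h"): 4.0}
        ct, _ = generate_ct_table(["g1"], ["cond"], folds, sd=0.0, seed=0)
        from wrky.regulation_expression import qpcr_fold_changes

        table = qpcr_fold_changes(ct, "Act2")
        got = table.set_index(["gene", "condition", "timepoint"]).loc[
            ("g1", "cond", "1h"), "fold_change"]
        assert got == pytest.approx(4.0, abs=1e-9)


class TestPaperShapedPreset:
    def test_structure(self):
        ds = paper_shaped(seed=3)
        assert len(ds.proteins) == 105
        from collections import Counter

        comp = Counter(ds.truth["groups"].values())
        assert dict(comp) == ds.truth["composition"]
        assert ds.truth["n_tandem_pairs"] == 10
        assert ds.truth["n_segmental_pairs"] == 8
        assert len(ds.truth["wrky_per_chromosome"]) == 9
        assert sum(ds.truth["wrky_per_chromosome"].values()) == 105
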