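import numpy as np
import pandas as pd
import pytest

from wrky.io_formats import reverse_complement
from wrky.regulation_expression import (
    CREPattern,
    default_catalog,
    fold_change_ddct,
    hypergeometric_enrichment,
    qpcr_fold_changes,
    rpkm,
    scan_cre,
)
from wrky.synthetic_data import generate_ct_table

from oracles import hypergeom_tail_oracle

WBOX = CREPattern("WBOXNT", "YTGACY", "W-box")


class TestScanCre:
    def test_plus_strand_wbox(self):
        hits = scan_cre("AATTGACT", [WBOX])
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].start == 2 and plus[0].matched == "TTGACT"

    def test_minus_strand_hit_in_plus_coordinates(self):
        promoter = "AAAGTCAAAA"  # revcomp contains TTGACT at offset 1
        hits = scan_cre(promoter, [WBOX])
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        start = minus[0].start
        assert reverse_complement(
            promoter[start : start + 6]) == minus[0].matched

    def test_no_hits_in_homopolymer(self):
        assert scan_cre("A" * 50, [WBOX]) == []

    def test_n_never_matches(self):
        assert scan_cre("TTGNCT", [WBOX]) == []

    def test_default_catalog_loads(self):
        catalog = default_catalog()
        names = {p.name for p in catalog}
        assert {"WBOXNT", "WRKY71OS", "CAATBOX1", "ARR1AT", "HSE"} <= names

    def test_reverse_complement_invariance(self, rng):
        promoter = "".join(rng.choice(list("ACGT"), size=300))
        catalog = default_catalog()
        fwd = scan_cre(promoter, catalog)
        rev = scan_cre(reverse_complement(promoter), catalog)
        L = len(promoter)

        def key(hits, flip):
            out = set()
            for h in hits:
                if flip:
                    start = L - h.start - len(h.matched)
                    strand = "+" if h.strand == "-" else "-"
                else:
                    start, strand = h.start, h.strand
                out.add((h.pattern, start, strand, h.matched))
            return out

        assert key(fwd, False) == key(rev, True)


class TestRpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g"])
        out = rpkm(counts, {"g": 1000}, {"s1": 1_000_000})
        assert out.loc["g", "s1"] == pytest.approx(10.0)

    def test_zero_counts(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        assert rpkm(counts, {"g": 500}, {"s1": 10}).loc["g", "s1"] == 0

    def test_doubling_library_halves_values(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(5, 2)),
                              index=list("abcde"), columns=["x", "y"])
        lengths = {g: 1000 for g in "abcde"}
        r1 = rpkm(counts, lengths, {"x": 1e6, "y": 1e6})
        r2 = rpkm(counts, lengths, {"x": 2e6, "y": 2e6})
        assert np.allclose(r1.values, 2 * r2.values)

    def test_linear_in_counts(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(4, 2)),
                              index=list("abcd"), columns=["x", "y"])
        lengths = {g: 800 for g in "abcd"}
        libs = {"x": 1e6, "y": 1e6}
        assert np.allclose(
            rpkm(3 * counts, lengths, libs).values,
            3 * rpkm(counts, lengths, libs).values,
        )


class TestDdct:
    def test_worked_example(self):
        assert fold_change_ddct(20, 18, 22, 18) == pytest.approx(4.0)

    def test_equal_deltas_fold_one(self):
        assert fold_change_ddct(25, 20, 30, 25) == pytest.approx(1.0)

    def test_replicates_averaged(self):
        fold = fold_change_ddct([20, 20, 20], [18, 18, 18], [22] * 3, [18] * 3)
        assert fold == pytest.approx(4.0)

    def test_simulated_fold_recovery(self):
        folds = {("g1", "salt", "24h"): 8.0}
        ct, _ = generate_ct_table(["g1"], ["salt"], folds, sd=0.1, seed=4)
        table = qpcr_fold_changes(ct, "Act2")
        got = table.set_index(["gene", "condition", "timepoint"]).loc[
            ("g1", "salt", "24h"), "fold_change"]
        assert got == pytest.approx(8.0, rel=0.10)

    def test_control_timepoint_is_one_by_construction(self):
        ct, _ = generate_ct_table(["g1"], ["salt"], {}, sd=0.0, seed=0)
        table = qpcr_fold_changes(ct, "Act2")
        ctrl = table.set_index(["gene", "condition", "timepoint"]).loc[
            ("g1", "salt", "0h"), "fold_change"]
        assert ctrl == pytest.approx(1.0)


class TestEnrichment:
    def test_worked_example(self):
        population = {f"g{i}" for i in range(10)}
        study = {"g0", "g1", "g2", "g3"}
        annotation = {"T": {"g0", "g1", "g2", "g3", "g4"}}
        out = hypergeometric_enrichment(study, population, annotation)
        assert out[0].p == pytest.approx(5 / 210)
        assert out[0].q == pytest.approx(out[0].p)  # single term: q == p

    def test_study_equals_population(self):
        population = {f"g{i}" for i in range(6)}
        annotation = {"T1": {"g0", "g1"}, "T2": {"g3"}}
        out = hypergeometric_enrichment(population, population, annotation)
        assert all(r.p == pytest.approx(1.0) for r in out)

    def test_unannotated_terms_skipped(self):
        population = {"a", "b"}
        out = hypergeometric_enrichment({"a"}, population, {"T": set()})
        assert out == []

    def test_study_must_be_subset(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"x"}, {"a"}, {})

    def test_matches_enumeration_for_small_populations(self, rng):
        for _ in range(30):
            M = int(rng.integers(2, 13))
            population = {f"g{i}" for i in range(M)}
            n = int(rng.integers(1, M + 1))
            K = int(rng.integers(1, M + 1))
            study = set(rng.choice(sorted(population), size=n, replace=False))
            annotated = set(rng.choice(sorted(population), size=K,
                                       replace=False))
            out = hypergeometric_enrichment(study, population,
                                            {"T": annotated})
            k = len(study & annotated)
            assert out[0].p == pytest.approx(
                hypergeom_tail_oracle(M, K, n, k), abs=1e-12
            )

    def test_bh_qvalues_monotone_in_p_rank(self, rng):
        M = 40
        population = {f"g{i}" for i in range(M)}
        study = set(rng.choice(sorted(population), size=10, replace=False))
        annotation = {
            f"T{t}": set(rng.choice(sorted(population),
                                    size=int(rng.integers(1, 20)),
                                    replace=False))
            for t in range(12)
        }
        out = hypergeometric_enrichment(study, population, annotation)
        ranked = sorted(out, key=lambda r: r.p)
        qs = [r.q for r in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.p <= r.q + 1e-12 for r in out)
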