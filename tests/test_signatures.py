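"""SBS-96 catalogs, NNLS refitting, dominance, clustering, enrichment."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hdgckit.io_formats import VariantKey
from hdgckit.signatures import (
    CATEGORY_LABELS,
    MutationCatalog,
    category_index,
    cluster_exposures,
    context_category,
    dominance_table,
    enrichment_2x2,
    fit_exposures,
)
from hdgckit.synthetic import simulate_catalog, toy_signatures

from conftest import write_fasta


class TestCategories:
    def test_label_layout(self):
        assert len(CATEGORY_LABELS) == 96
        assert CATEGORY_LABELS[0] == "A[C>A]A"
        assert CATEGORY_LABELS[17] == "A[C>G]C"
        assert CATEGORY_LABELS[95] == "T[T>G]T"

    def test_pyrimidine_context(self, tmp_path):
        ref = write_fasta(tmp_path / "c.fa", {"c": "GACAG"})
        # A[C>A]A at position 3
        cat = context_category(VariantKey("c", 3, "C", "A"), ref)
        assert CATEGORY_LABELS[cat] == "A[C>A]A"

    def test_purine_reverse_complemented(self, tmp_path):
        # G>T with flanks T,A maps to T[C>A]A on the opposite strand
        ref = write_fasta(tmp_path / "d.fa", {"c": "ATGAG"})
        cat = context_category(VariantKey("c", 3, "G", "T"), ref)
        assert CATEGORY_LABELS[cat] == "T[C>A]A"

    def test_strand_involution(self):
        rng = np.random.default_rng(9)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(200):
            ref = str(rng.choice(list("ACGT")))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            five, three = (str(rng.choice(list("ACGT"))) for _ in range(2))
            a = category_index(ref, alt, five, three)
            b = category_index(comp[ref], comp[alt], comp[three], comp[five])
            assert a == b

    def test_non_snv_rejected(self, tmp_path):
        ref = write_fasta(tmp_path / "e.fa", {"c": "GACAG"})
        with pytest.raises(ValueError):
            context_category(VariantKey("c", 3, "CA", "C"), ref)

    def test_catalog_conservation(self, tmp_path):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ref = write_fasta(tmp_path / "f.fa", {"c": seq})
        keys = []
        for pos0 in range(10, 400, 13):
            base = seq[pos0]
            alt = "A" if base != "A" else "G"
            keys.append(VariantKey("c", pos0 + 1, base, alt))
        cat = MutationCatalog.from_variants({"S1": keys}, ref)
        assert cat.counts.sum() == len(keys)


class TestFitExposures:
    def test_exact_span_member(self):
        sigs = toy_signatures()
        catalog = MutationCatalog(["S1"], np.round(sigs.matrix[:, 2] * 100000).reshape(1, -1))
        expos, skipped = fit_exposures(catalog, sigs)
        assert not skipped
        e = expos[0]
        assert e.weights[2] == pytest.approx(1.0, abs=1e-4)
        assert e.reconstruction_cosine == pytest.approx(1.0, abs=1e-6)
        assert e.dominant == "TS3"

    def test_mixture_recovery(self):
        sigs = toy_signatures()
        rng = np.random.default_rng(12)
        row = simulate_catalog(sigs, np.array([0.6, 0.0, 0.4]), 2000, rng)
        expos, _ = fit_exposures(MutationCatalog(["S1"], row.reshape(1, -1)), sigs)
        w = expos[0].weights
        assert w[0] == pytest.approx(0.6, abs=0.05)
        assert w[2] == pytest.approx(0.4, abs=0.05)

    def test_identical_samples_identical_exposures(self):
        sigs = toy_signatures()
        rng = np.random.default_rng(13)
        row = simulate_catalog(sigs, np.array([0.3, 0.3, 0.4]), 1000, rng)
        cat = MutationCatalog(["A", "B"], np.vstack([row, row]))
        expos, _ = fit_exposures(cat, sigs)
        assert np.allclose(expos[0].weights, expos[1].weights)

    def test_empty_catalog_row_flagged(self):
        sigs = toy_signatures()
        cat = MutationCatalog(["A"], np.zeros((1, 96)))
        expos, skipped = fit_exposures(cat, sigs)
        assert expos == [] and skipped == ["A"]


class TestDominance:
    def _expo(self, weights, sample="S1"):
        from hdgckit.signatures import ExposureVector

        return ExposureVector(sample, ["TS1", "TS2", "TS3"], np.array(weights), 1.0)

    def test_argmax(self):
        assert self._expo([0.3, 0.2, 0.5]).dominant == "TS3"

    def test_tie_breaks_lexicographically(self):
        assert self._expo([0.4, 0.4, 0.2]).dominant == "TS1"

    def test_dominance_table_percent(self):
        expos = [self._expo([1, 0, 0], f"S{i}") for i in range(11)]
        expos += [self._expo([0, 1, 0], f"T{i}") for i in range(175)]
        tbl = dominance_table(expos).set_index("signature")
        # 11 of 186 dominant -> 5.9%
        assert tbl.loc["TS1", "percent"] == 5.9


class TestClustering:
    def _expos(self):
        from hdgckit.signatures import ExposureVector

        rng = np.random.default_rng(14)
        expos, labels = [], []
        for i in range(12):
            w = rng.dirichlet([20, 1, 1])
            expos.append(ExposureVector(f"A{i}", ["TS1", "TS2", "TS3"], w, 1.0))
            labels.append(0)
        for i in range(12):
            w = rng.dirichlet([1, 1, 20])
            expos.append(ExposureVector(f"B{i}", ["TS1", "TS2", "TS3"], w, 1.0))
            labels.append(1)
        return expos, labels

    def test_planted_groups_recovered(self):
        expos, truth = self._expos()
        cl = cluster_exposures(expos, k=2, seed=0)
        assert adjusted_rand_score(truth, cl["cluster"]) == 1.0

    def test_same_seed_same_labels(self):
        expos, _ = self._expos()
        a = cluster_exposures(expos, 3, seed=7)
        b = cluster_exposures(expos, 3, seed=7)
        assert (a["cluster"] == b["cluster"]).all()

    def test_k_exceeding_samples_rejected(self):
        expos, _ = self._expos()
        with pytest.raises(ValueError):
            cluster_exposures(expos, k=len(expos) + 1, seed=0)


class TestEnrichment:
    def test_reported_ebv_table(self):
        # 2 of 3 EBV-positive vs 8 of 69 EBV-negative patients dominant
        flag_dom = {f"S{i}": i < 2 or (3 <= i < 11) for i in range(72)}
        flag_ebv = {f"S{i}": i < 3 for i in range(72)}
        table, p, excluded = enrichment_2x2(flag_ebv, flag_dom)
        assert (table.a, table.b, table.c, table.d) == (2, 1, 8, 61)
        assert excluded == 0
        assert 0.04 < p < 0.06

    def test_identical_proportions_p_one(self):
        flag_a = {f"S{i}": i < 10 for i in range(20)}
        flag_b = {f"S{i}": i % 2 == 0 for i in range(20)}
        _table, p, _ = enrichment_2x2(flag_a, flag_b)
        assert p == 1.0

    def test_unknowns_excluded_and_counted(self):
        flag_a = {"S1": True, "S2": None, "S3": False}
        flag_b = {"S1": True, "S2": True, "S3": False}
        table, _p, excluded = enrichment_2x2(flag_a, flag_b)
        assert excluded == 1 and table.total == 2

    def test_all_unknown_rejected(self):
        with pytest.raises(ValueError):
            enrichment_2x2({"S1": None}, {"S1": True})
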