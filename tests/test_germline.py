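"""Consequence classification, PTV calling, and the six-criterion classifier."""

import numpy as np
import pytest
from Bio.Seq import Seq

from hdgckit.germline import (
    DEFAULT_WHITELIST,
    PTV_CLASSES,
    GeneModel,
    classify_consequence,
    classify_private,
    gene_frequency,
    is_ptv,
)
from hdgckit.io_formats import GenotypeCall, VariantKey, VariantRecord
from hdgckit.synthetic import make_private_criteria_panel

from conftest import write_fasta, write_gene_bed


@pytest.fixture(scope="module")
def two_gene_model(tmp_path_factory):
    """A + strand and a - strand two-exon gene on a 2 kb random contig."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    d = tmp_path_factory.mktemp("gm")
    ref = write_fasta(d / "g.fa", {"c": seq})
    rows = [
        ("c", 100, 250, "FWD", "+", 0),
        ("c", 310, 400, "FWD", "+", 0),   # 150 bp then 90 bp -> frame 150 % 3 = 0
        ("c", 600, 750, "REV", "-", 0),
        ("c", 810, 900, "REV", "-", 0),   # transcript order: (810,900) first
    ]
    rows[1] = ("c", 310, 400, "FWD", "+", 150 % 3)
    rows[2] = ("c", 600, 750, "REV", "-", 90 % 3)
    model = write_gene_bed(d / "g.bed", rows)
    return model, ref, seq


def _spliced_cds(model: GeneModel, gene: str, seq: str) -> str:
    g = model.genes[gene]
    parts = []
    exons = g.exons if g.strand == "+" else reversed(g.exons)
    for s, e, _f in exons:
        sub = seq[s:e]
        if g.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        parts.append(sub)
    return "".join(parts)


def _oracle_snv_consequence(model, gene, seq, pos0, alt):
    """Translate the whole CDS before/after the SNV and compare proteins."""
    g = model.genes[gene]
    mutated = seq[:pos0] + alt + seq[pos0 + 1:]
    before = str(Seq(_spliced_cds(model, gene, seq)).translate())
    after = str(Seq(_spliced_cds(model, gene, mutated)).translate())
    if before == after:
        return "synonymous"
    off = model.cds_offset(g, pos0)
    ci = off // 3
    if after[ci] == "*" and before[ci] != "*":
        return "nonsense"
    if before[ci] == "*":
        return "other"
    return "missense"


class TestClassifyConsequence:
    def test_random_cds_snvs_match_translation_oracle(self, two_gene_model):
        model, ref, seq = two_gene_model
        rng = np.random.default_rng(6)
        checked = {"nonsense": 0, "missense": 0, "synonymous": 0}
        for gene in ("FWD", "REV"):
            g = model.genes[gene]
            cds_positions = [
                p for s, e, _f in g.exons for p in range(s, e)
            ]
            for pos0 in rng.choice(cds_positions, size=60, replace=False):
                pos0 = int(pos0)
                base = seq[pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != base]))
                got_gene, got = classify_consequence(VariantKey("c", pos0 + 1, base, alt), model, ref)
                exp = _oracle_snv_consequence(model, gene, seq, pos0, alt)
                assert got_gene == gene
                assert got == exp
                if exp in checked:
                    checked[exp] += 1
        assert checked["missense"] > 0 and checked["synonymous"] > 0

    def test_coding_indel_lengths(self, two_gene_model):
        model, ref, seq = two_gene_model
        pos0 = 120  # mid-exon of FWD
        one_bp = VariantKey("c", pos0 + 1, seq[pos0:pos0 + 2], seq[pos0])
        three_bp = VariantKey("c", pos0 + 1, seq[pos0:pos0 + 4], seq[pos0])
        assert classify_consequence(one_bp, model, ref)[1] == "frameshift_indel"
        assert classify_consequence(three_bp, model, ref)[1] == "inframe_indel"

    def test_splice_site_window(self, two_gene_model):
        model, ref, seq = two_gene_model
        # FWD exon1 ends at 250 (0-based exclusive): intron bases 250, 251
        for pos0 in (250, 251, 308, 309):
            base = seq[pos0]
            alt = "A" if base != "A" else "G"
            assert classify_consequence(VariantKey("c", pos0 + 1, base, alt), model, ref)[1] == "splice_site"
        # third intron base is not a splice site
        base = seq[252]
        alt = "A" if base != "A" else "G"
        assert classify_consequence(VariantKey("c", 253, base, alt), model, ref)[1] == "other"

    def test_intergenic_is_other(self, two_gene_model):
        model, ref, seq = two_gene_model
        base = seq[10]
        alt = "A" if base != "A" else "G"
        assert classify_consequence(VariantKey("c", 11, base, alt), model, ref) == ("", "other")

    def test_missing_frame_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("c\t10\t40\tG1\t+\t.\n")
        with pytest.raises(ValueError, match="frame"):
            GeneModel.from_bed(p)

    def test_inconsistent_frame_rejected(self, tmp_path):
        p = tmp_path / "bad2.bed"
        p.write_text("c\t10\t40\tG1\t+\t0\nc\t50\t80\tG1\t+\t2\n")  # 30 % 3 == 0
        with pytest.raises(ValueError, match="frame"):
            GeneModel.from_bed(p)


class TestIsPtv:
    @pytest.mark.parametrize(
        "cons,expected",
        [("nonsense", True), ("splice_site", True), ("frameshift_indel", True),
         ("missense", False), ("inframe_indel", False), ("synonymous", False),
         ("other", False)],
    )
    def test_classes(self, cons, expected):
        assert is_ptv(cons) is expected

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            is_ptv("stop_gained")


def _record(consequence="missense", maf=(0.0, 0.0), mapp=0.9, unique=True):
    return VariantRecord(
        VariantKey("chr1", 100, "A", "G"), gene="G1", consequence=consequence,
        maf_db1=maf[0], maf_db2=maf[1], mappability=mapp, unique_locus=unique,
    )


def _gt(zyg="het"):
    return GenotypeCall("S1", zyg, depth=60, alt_depth=30 if zyg == "het" else 60)


class TestClassifyPrivate:
    def test_full_pass(self):
        call = classify_private(_record(maf=(0.004, 0.0)), _gt(), 1)
        assert call.is_private and all(call.flags)

    @pytest.mark.parametrize(
        "kwargs,genotype,occ,failing",
        [
            (dict(consequence="synonymous"), "het", 1, 0),
            (dict(), "hom_alt", 1, 1),
            (dict(maf=(0.006, 0.0)), "het", 1, 2),
            (dict(maf=(0.005, 0.0)), "het", 1, 2),   # strict: 0.005 is not < 0.005
            (dict(), "het", 2, 3),
            (dict(mapp=0.5), "het", 1, 4),            # strict: 0.5 is not > 0.5
            (dict(unique=False), "het", 1, 5),
        ],
    )
    def test_single_criterion_failures(self, kwargs, genotype, occ, failing):
        call = classify_private(_record(**kwargs), _gt(genotype), occ)
        assert not call.is_private
        assert [i for i, f in enumerate(call.flags) if not f] == [failing]

    def test_maf_or_mode(self):
        rec = _record(maf=(0.2, 0.001))
        assert not classify_private(rec, _gt(), 1).c3_rare
        assert classify_private(rec, _gt(), 1, maf_mode="or").c3_rare

    def test_strict_ptv_whitelist(self):
        call = classify_private(_record(consequence="missense"), _gt(), 1,
                                consequence_whitelist=PTV_CLASSES)
        assert not call.c1_consequence
        call = classify_private(_record(consequence="nonsense"), _gt(), 1,
                                consequence_whitelist=PTV_CLASSES)
        assert call.c1_consequence

    def test_flag_decomposition_random_annotations(self):
        rng = np.random.default_rng(8)
        consequences = ["missense", "synonymous", "nonsense", "other"]
        zygs = ["het", "hom_alt", "hom_ref"]
        for _ in range(2000):
            rec = _record(
                consequence=consequences[rng.integers(4)],
                maf=(float(rng.uniform(0, 0.02)), float(rng.uniform(0, 0.02))),
                mapp=float(rng.uniform(0, 1)),
                unique=bool(rng.random() < 0.5),
            )
            occ = int(rng.integers(1, 4))
            call = classify_private(rec, _gt(zygs[rng.integers(3)]), occ)
            # independent re-derivation of the conjunction
            expected = (
                (rec.consequence in DEFAULT_WHITELIST)
                and call.genotype.zygosity == "het"
                and rec.maf_db1 < 0.005 and rec.maf_db2 < 0.005
                and occ == 1
                and rec.mappability > 0.5
                and rec.unique_locus
            )
            assert call.is_private == expected
            assert call.is_private == all(call.flags)

    def test_toggling_one_annotation_flips_one_flag(self):
        base = classify_private(_record(maf=(0.004, 0.004)), _gt(), 1)
        variants = [
            classify_private(_record(consequence="synonymous", maf=(0.004, 0.004)), _gt(), 1),
            classify_private(_record(maf=(0.004, 0.004)), _gt("hom_alt"), 1),
            classify_private(_record(maf=(0.006, 0.004)), _gt(), 1),
            classify_private(_record(maf=(0.004, 0.004)), _gt(), 2),
            classify_private(_record(maf=(0.004, 0.004), mapp=0.3), _gt(), 1),
            classify_private(_record(maf=(0.004, 0.004), unique=False), _gt(), 1),
        ]
        for i, call in enumerate(variants):
            diffs = [j for j in range(6) if call.flags[j] != base.flags[j]]
            assert diffs == [i]

    def test_bad_occurrence_rejected(self):
        with pytest.raises(ValueError):
            classify_private(_record(), _gt(), 0)


class TestPanel:
    def test_exactly_four_private_calls(self):
        records, genotypes, occs, expected = make_private_criteria_panel()
        calls = [classify_private(r, g, o) for r, g, o in zip(records, genotypes, occs)]
        assert [c.is_private for c in calls] == expected
        assert sum(c.is_private for c in calls) == 4
        # every decoy fails exactly one criterion
        for call, exp in zip(calls, expected):
            if not exp:
                assert sum(not f for f in call.flags) == 1


class TestGeneFrequency:
    def _call(self, gene, private=True):
        rec = _record()
        rec.gene = gene
        call = classify_private(rec, _gt("het" if private else "hom_alt"), 1)
        return call

    def test_reported_carrier_percentages(self):
        calls = [(f"P{i}", self._call("CDH1")) for i in range(8)]
        calls += [(f"Q{i}", self._call("MUC4")) for i in range(53)]
        df = gene_frequency(calls, 284).set_index("gene")
        assert df.loc["CDH1", "percent"] == 2.8
        assert df.loc["MUC4", "percent"] == 18.7

    def test_patient_counts_once_per_gene(self):
        calls = [("P1", self._call("MUC4")) for _ in range(3)]
        df = gene_frequency(calls, 10).set_index("gene")
        assert df.loc["MUC4", "carrier_count"] == 1

    def test_non_private_calls_excluded(self):
        calls = [("P1", self._call("CDH1", private=False))]
        assert gene_frequency(calls, 10).empty

    def test_zero_cohort_rejected(self):
        with pytest.raises(ValueError):
            gene_frequency([], 0)
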