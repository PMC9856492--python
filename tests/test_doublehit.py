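"""LOH segment calling, double-hit events, and G-score summaries."""

import logging

import pytest

from hdgckit.doublehit import (
    DoubleHitEvent,
    LohSegment,
    ScnaSegment,
    call_double_hits,
    call_loh_segments,
    gene_gscore,
    summarize_double_hits,
)
from hdgckit.io_formats import GenotypeCall, VariantKey

from conftest import write_gene_bed


def _sites(vafs, start=1000, step=100, depth=80):
    return [(start + i * step, v, depth) for i, v in enumerate(vafs)]


class TestCallLoh:
    def test_uniform_high_vaf_run(self):
        segs = call_loh_segments(_sites([0.95] * 10), chrom="chr1")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_het_sites == 10
        assert seg.median_tumor_vaf_deviation == pytest.approx(0.45)
        assert (seg.start, seg.end) == (1000, 1901)

    def test_balanced_vafs_no_segment(self):
        assert call_loh_segments(_sites([0.48, 0.52] * 5), chrom="chr1") == []

    def test_run_below_min_sites_dropped(self):
        assert call_loh_segments(_sites([0.9] * 4), chrom="chr1") == []

    def test_low_depth_sites_skipped_without_breaking_run(self):
        sites = _sites([0.9] * 3) + _sites([0.5], start=1300, depth=5) + _sites([0.9] * 3, start=1400)
        segs = call_loh_segments(sorted(sites), chrom="chr1")
        assert len(segs) == 1 and segs[0].n_het_sites == 6

    def test_balanced_site_splits_runs(self):
        sites = _sites([0.9] * 4) + _sites([0.5], start=1400) + _sites([0.9] * 4, start=1500)
        assert call_loh_segments(sorted(sites), chrom="chr1") == []

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            call_loh_segments([(200, 0.9, 80), (100, 0.9, 80)])

    def test_raising_min_sites_never_adds_segments(self):
        sites = _sites([0.9] * 7 + [0.5] + [0.95] * 5)
        prev = None
        for ms in (3, 5, 7, 9):
            segs = call_loh_segments(sorted(sites), chrom="c", min_sites=ms)
            if prev is not None:
                assert len(segs) <= prev
            prev = len(segs)


def _het_call(pid, pos, tumor_zyg="het", tumor_vaf=0.5, depth=80, gene="G1"):
    key = VariantKey("chr1", pos, "A", "G")
    germ = GenotypeCall(pid, "het", depth=80, alt_depth=40)
    tum = GenotypeCall(f"{pid}_T", tumor_zyg, depth=depth, alt_depth=int(round(tumor_vaf * depth)))
    return (pid, gene, key, germ, tum)


class TestCallDoubleHits:
    def test_homozygous_tumor_genotype(self):
        events = call_double_hits([_het_call("P1", 500, "hom_alt", 1.0)], {})
        assert len(events) == 1
        assert "genotype_homozygous" in events[0].evidence

    def test_balanced_tumor_no_event(self):
        assert call_double_hits([_het_call("P1", 500, "het", 0.50, depth=100)], {}) == []

    def test_vaf_threshold_requires_depth(self):
        assert call_double_hits([_het_call("P1", 500, "het", 0.95, depth=8)], {}) == []
        events = call_double_hits([_het_call("P1", 500, "het", 0.95, depth=30)], {})
        assert len(events) == 1 and "vaf_threshold" in events[0].evidence

    def test_loh_overlap_requires_alt_retention(self):
        seg = LohSegment("chr1", 0, 1000, n_het_sites=6, median_tumor_vaf_deviation=0.4)
        ev = call_double_hits([_het_call("P1", 500, "het", 0.7)], {"P1": [seg]})
        assert len(ev) == 1 and ev[0].evidence == {"loh_overlap"}
        # alt allele lost: VAF below 0.5 inside LOH is not a double hit
        assert call_double_hits([_het_call("P1", 500, "het", 0.05)], {"P1": [seg]}) == []

    def test_lowering_hom_vaf_never_removes_events(self):
        calls = [_het_call("P1", p, "het", v) for p, v in
                 [(100, 0.85), (200, 0.92), (300, 0.5), (400, 0.97)]]
        prev: set = set()
        for hv in (0.95, 0.9, 0.85, 0.8):
            got = {e.key.pos for e in call_double_hits(calls, {}, hom_vaf=hv)}
            assert prev <= got
            prev = got

    def test_non_het_germline_rejected(self):
        pid, gene, key, _g, tum = _het_call("P1", 500)
        bad = GenotypeCall("P1", "hom_alt", depth=80, alt_depth=80)
        with pytest.raises(ValueError):
            call_double_hits([(pid, gene, key, bad, tum)], {})

    def test_missing_tumor_skipped_with_warning(self, caplog):
        pid, gene, key, germ, _t = _het_call("P1", 500)
        with caplog.at_level(logging.WARNING):
            events = call_double_hits([(pid, gene, key, germ, None)], {})
        assert events == [] and "skipping" in caplog.text


class TestSummarize:
    def _event(self, pid, gene, pos):
        return DoubleHitEvent(
            patient_id=pid, gene=gene, key=VariantKey("chr1", pos, "A", "G"),
            germline_zygosity="het", tumor_vaf=0.95, tumor_depth=80,
            evidence=frozenset({"vaf_threshold"}),
        )

    def test_share_with_one_or_two_events(self):
        # 35 of 66 event-bearing patients carry 1-2 events -> 53.0%
        events = []
        pid = 0
        for _ in range(35):
            events.append(self._event(f"P{pid}", "G1", 100 + pid)); pid += 1
        for _ in range(31):
            for j in range(3):
                events.append(self._event(f"P{pid}", "G1", 1000 + 10 * pid + j))
            pid += 1
        summary = summarize_double_hits(events, [f"P{i}" for i in range(80)])
        assert summary["n_event_bearing"] == 66
        assert summary["pct_1_or_2_of_bearing"] == 53.0

    def test_no_events_empty(self):
        summary = summarize_double_hits([], ["P1", "P2"])
        assert summary["per_gene"].empty
        assert (summary["per_patient"]["n_events"] == 0).all()

    def test_heavy_patient_counted_once(self):
        events = [self._event("P1", f"G{j}", 100 + j) for j in range(46)]
        summary = summarize_double_hits(events, ["P1"])
        pp = summary["per_patient"]
        assert len(pp) == 1 and pp["n_events"].iloc[0] == 46


class TestGeneGscore:
    @pytest.fixture()
    def model(self, tmp_path):
        return write_gene_bed(tmp_path / "g.bed", [("chr1", 1000, 1300, "G1", "+", 0)])

    def test_direct_product(self, model):
        segs = [ScnaSegment(f"P{i}", "chr1", 900, 1400, 0.8) for i in range(5)]
        df = gene_gscore(segs, model, n_patients=10).set_index("gene")
        assert df.loc["G1", "amp_freq"] == 0.5
        assert df.loc["G1", "g_amp"] == pytest.approx(0.5 * 0.8)
        assert df.loc["G1", "g_del"] == 0.0

    def test_no_segments_zero(self, model):
        df = gene_gscore([], model, n_patients=10).set_index("gene")
        assert (df.loc["G1"] == 0).all()

    def test_deletion_only(self, model):
        segs = [ScnaSegment("P1", "chr1", 900, 1400, -0.6)]
        df = gene_gscore(segs, model, n_patients=4).set_index("gene")
        assert df.loc["G1", "g_amp"] == 0.0
        assert df.loc["G1", "g_del"] == pytest.approx(0.25 * 0.6)

    def test_subthreshold_segments_ignored(self, model):
        segs = [ScnaSegment("P1", "chr1", 900, 1400, 0.2)]
        df = gene_gscore(segs, model, n_patients=4).set_index("gene")
        assert df.loc["G1", "amp_freq"] == 0.0
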