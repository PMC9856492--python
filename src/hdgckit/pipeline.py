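"""End-to-end cohort analysis: stage orchestration over flat TSV outputs.

``run_all`` executes the stages in dependency order — germline private
classification, LOH/double-hit detection, signature refitting and
clustering, cohort composition and survival statistics — and writes one
TSV per result plus a provenance JSON that records every input path and
threshold, so a run can be reproduced exactly. Reruns with unchanged
inputs and seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import classify_hdgc, cohort_composition, read_clinical_tsv
from .doublehit import call_double_hits, call_loh_segments, summarize_double_hits
from .germline import (
    DEFAULT_WHITELIST,
    PTV_CLASSES,
    GeneModel,
    classify_consequence,
    classify_private,
    gene_frequency,
    is_ptv,
)
from .io_formats import (
    ReferenceGenome,
    RegionTrack,
    VariantRecord,
    read_frequency_table,
    read_paired_vcfs,
)
from .signatures import (
    MutationCatalog,
    SignatureMatrix,
    cluster_exposures,
    dominance_table,
    assign_dominant,
    enrichment_2x2,
    fit_exposures,
)
from .stats import bh_fdr, km_estimate, logrank_test

logger = logging.getLogger(__name__)

STAGES = ("germline", "doublehit", "signatures", "stats", "report")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a cohort run.

    Thresholds default to the analysis settings: MAF < 0.5% in both
    databases, mappability > 0.5, tumor-homozygosity VAF >= 0.9 at depth
    >= 10, LOH runs of >= 5 sites deviating >= 0.25 from VAF 0.5, SCNA
    calls at |log2 ratio| >= 0.3, and exposure clustering at k in 3..5.
    """

    reference: str
    genes_bed: str
    frequencies: str
    vcf_dir: str
    clinical: str
    family_history: str | None = None
    mappability_bed: str | None = None
    uniqueness_bed: str | None = None
    signatures_tsv: str | None = None
    outdir: str = "hdgc_out"
    maf_cutoff: float = 0.005
    maf_mode: str = "and"
    whitelist: str = "default"          # "default" (PTV + missense) or "ptv"
    mappability_cutoff: float = 0.5
    hom_vaf: float = 0.9
    min_depth: int = 10
    min_sites: int = 5
    deviation_threshold: float = 0.25
    amp_threshold: float = 0.3
    del_threshold: float = -0.3
    k_list: tuple[int, ...] = (3, 4, 5)
    survival_horizon_months: float = 60.0
    condition1_mode: str = "combined"
    seed: int = 0

    @classmethod
    def from_bundle(cls, bundle: str | Path, outdir: str | Path, **overrides) -> "PipelineConfig":
        """Point every input at a synthetic bundle directory."""
        b = Path(bundle)
        defaults = dict(
            reference=str(b / "reference.fa"),
            genes_bed=str(b / "genes.bed"),
            frequencies=str(b / "frequencies.tsv"),
            vcf_dir=str(b / "vcf"),
            clinical=str(b / "clinical.tsv"),
            family_history=str(b / "family_history.tsv"),
            mappability_bed=str(b / "mappability.bed"),
            uniqueness_bed=str(b / "uniqueness.bed"),
            signatures_tsv=str(b / "signatures.tsv"),
            outdir=str(outdir),
        )
        defaults.update(overrides)
        return cls(**defaults)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the pipeline; returns the output directory.

    On stage failure a FAILED marker naming the stage is left next to any
    partial outputs and the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_all_inner(config, stages, outdir)
    except Exception as exc:  # noqa: BLE001 - marker + re-raise
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run_all_inner(config: PipelineConfig, stages, outdir: Path) -> Path:
    for f in dataclasses.fields(config):
        logger.info("config %s = %r", f.name, getattr(config, f.name))
    reference = ReferenceGenome(config.reference)
    gene_model = GeneModel.from_bed(config.genes_bed)
    freqs = read_frequency_table(config.frequencies, reference)
    mappability = (
        RegionTrack.from_bed(config.mappability_bed, default=1.0)
        if config.mappability_bed and Path(config.mappability_bed).exists()
        else RegionTrack([], default=1.0)
    )
    uniqueness = (
        RegionTrack.from_bed(config.uniqueness_bed, default=1.0)
        if config.uniqueness_bed and Path(config.uniqueness_bed).exists()
        else RegionTrack([], default=1.0)
    )
    patients = read_clinical_tsv(config.clinical, config.family_history)
    patient_ids = [p.patient_id for p in patients]
    whitelist = PTV_CLASSES if config.whitelist == "ptv" else DEFAULT_WHITELIST

    vcf_dir = Path(config.vcf_dir)
    paired = {}
    for pid in patient_ids:
        paired[pid] = read_paired_vcfs(
            vcf_dir / f"{pid}.germline.vcf", vcf_dir / f"{pid}.tumor.vcf", reference
        )

    # cohort occurrence counts over germline carriers
    occurrence: dict = {}
    for pid, calls in paired.items():
        for c in calls:
            if c.germline is not None and c.germline.zygosity in ("het", "hom_alt"):
                occurrence[c.key] = occurrence.get(c.key, 0) + 1

    # ----- germline stage ---------------------------------------------------
    private_calls = []          # (patient_id, PrivateVariantCall, PairedCall)
    for pid, calls in paired.items():
        for c in calls:
            if c.germline is None or c.germline.zygosity not in ("het", "hom_alt"):
                continue
            gene, consequence = classify_consequence(c.key, gene_model, reference)
            span = (c.key.pos - 1, c.key.pos - 1 + len(c.key.ref))
            maf1, maf2 = freqs.lookup(c.key)
            record = VariantRecord(
                key=c.key,
                gene=gene,
                consequence=consequence,
                maf_db1=maf1,
                maf_db2=maf2,
                mappability=mappability.min_over(c.key.chrom, *span),
                unique_locus=uniqueness.min_over(c.key.chrom, *span) > 0.5,
            )
            pv = classify_private(
                record,
                c.germline,
                occurrence[c.key],
                consequence_whitelist=whitelist,
                maf_cutoff=config.maf_cutoff,
                maf_mode=config.maf_mode,
                mappability_cutoff=config.mappability_cutoff,
            )
            private_calls.append((pid, pv, c))

    if "germline" in stages:
        rows = [
            dict(
                patient_id=pid,
                chrom=pv.record.key.chrom, pos=pv.record.key.pos,
                ref=pv.record.key.ref, alt=pv.record.key.alt,
                gene=pv.record.gene, consequence=pv.record.consequence,
                is_ptv=is_ptv(pv.record.consequence),
                c1_consequence=pv.c1_consequence, c2_het=pv.c2_het,
                c3_rare=pv.c3_rare, c4_singleton=pv.c4_singleton,
                c5_mappable=pv.c5_mappable, c6_unique=pv.c6_unique,
                is_private=pv.is_private,
            )
            for pid, pv, _c in private_calls
        ]
        _write_tsv(pd.DataFrame(rows), outdir / "private_calls.tsv")
        gf = gene_frequency([(pid, pv) for pid, pv, _ in private_calls], len(patient_ids))
        _write_tsv(gf, outdir / "gene_frequency.tsv")

    # ----- double-hit stage -------------------------------------------------
    loh_by_patient = {}
    if "doublehit" in stages or "stats" in stages or "report" in stages:
        loh_rows = []
        for pid, calls in paired.items():
            by_chrom: dict[str, list] = {}
            for c in calls:
                if (
                    c.germline is not None
                    and c.germline.zygosity == "het"
                    and c.tumor is not None
                    and c.tumor.vaf is not None
                ):
                    by_chrom.setdefault(c.key.chrom, []).append(
                        (c.key.pos - 1, c.tumor.vaf, c.tumor.depth)
                    )
            segs = []
            for chrom, sites in sorted(by_chrom.items()):
                segs.extend(
                    call_loh_segments(
                        sorted(sites),
                        chrom=chrom,
                        min_sites=config.min_sites,
                        deviation_threshold=config.deviation_threshold,
                        min_depth=config.min_depth,
                    )
                )
            loh_by_patient[pid] = segs
            loh_rows.extend(
                dict(patient_id=pid, chrom=s.chrom, start=s.start, end=s.end,
                     n_het_sites=s.n_het_sites,
                     median_vaf_deviation=s.median_tumor_vaf_deviation)
                for s in segs
            )
        _write_tsv(pd.DataFrame(loh_rows), outdir / "loh_segments.tsv")

        het_private = [
            (pid, pv.record.gene, pv.record.key, c.germline, c.tumor)
            for pid, pv, c in private_calls
            if pv.is_private and c.germline.zygosity == "het"
        ]
        events = call_double_hits(
            het_private, loh_by_patient,
            hom_vaf=config.hom_vaf, min_depth=config.min_depth,
        )
        _write_tsv(
            pd.DataFrame(
                [
                    dict(patient_id=e.patient_id, gene=e.gene,
                         chrom=e.key.chrom, pos=e.key.pos, ref=e.key.ref, alt=e.key.alt,
                         tumor_vaf=e.tumor_vaf, tumor_depth=e.tumor_depth,
                         evidence=",".join(sorted(e.evidence)))
                    for e in events
                ]
            ),
            outdir / "double_hits.tsv",
        )
        dh_summary = summarize_double_hits(events, patient_ids)
        _write_tsv(dh_summary["per_patient"], outdir / "double_hits_per_patient.tsv")
        _write_tsv(dh_summary["per_gene"], outdir / "double_hits_per_gene.tsv")
    else:
        events, dh_summary = [], None

    # ----- signatures stage -------------------------------------------------
    exposures = []
    sig_path = config.signatures_tsv
    if "signatures" in stages or "stats" in stages or "report" in stages:
        if not sig_path or not Path(sig_path).exists():
            logger.warning("signature matrix %r not found; signatures stage skipped", sig_path)
        else:
            sigs = SignatureMatrix.from_tsv(sig_path)
            somatic = {
                pid: [c.key for c in calls if c.germline is None and c.key.is_snv]
                for pid, calls in paired.items()
            }
            catalog = MutationCatalog.from_variants(somatic, reference)
            catalog.to_tsv(outdir / "catalog.tsv")
            exposures, skipped = fit_exposures(catalog, sigs)
            if skipped:
                logger.warning("samples with empty catalogs skipped: %s", skipped)
            _write_tsv(
                pd.DataFrame(
                    [
                        dict(sample_id=e.sample_id, dominant=e.dominant,
                             reconstruction_cosine=e.reconstruction_cosine)
                        | {sid: w for sid, w in zip(e.signature_ids, e.weights)}
                        for e in exposures
                    ]
                ),
                outdir / "exposures.tsv",
            )
            _write_tsv(dominance_table(exposures), outdir / "dominance.tsv")
            cluster_frames = []
            for k in config.k_list:
                if k <= len(exposures):
                    cl = cluster_exposures(exposures, k, seed=config.seed)
                    cl.insert(0, "k", k)
                    cluster_frames.append(cl)
            if cluster_frames:
                _write_tsv(pd.concat(cluster_frames, ignore_index=True), outdir / "clusters.tsv")

    # ----- statistics stage -------------------------------------------------
    if "stats" in stages or "report" in stages:
        elig_rows = [
            dict(
                patient_id=p.patient_id,
                conditions_met=",".join(
                    map(str, sorted(classify_hdgc(p, config.condition1_mode).conditions_met))
                ),
                eligible=classify_hdgc(p, config.condition1_mode).eligible,
            )
            for p in patients
        ]
        _write_tsv(pd.DataFrame(elig_rows), outdir / "eligibility.tsv")
        _write_tsv(
            cohort_composition(patients, config.condition1_mode), outdir / "composition.tsv"
        )

        summary_rows = []
        times = np.array([p.survival_time for p in patients])
        ev = np.array([p.survival_event for p in patients])
        if ev.any():
            km = km_estimate(times, ev)
            s, lo, hi = km.survival_at_with_ci(config.survival_horizon_months)
            summary_rows += [
                ("survival_at_horizon", s),
                ("survival_ci_low", lo),
                ("survival_ci_high", hi),
            ]
        if dh_summary is not None:
            bearing = set(
                dh_summary["per_patient"]
                .query("n_events > 0")["patient_id"]
            )
            mask = np.array([p.patient_id in bearing for p in patients])
            if mask.any() and (~mask).any() and ev.any():
                stat, p_lr = logrank_test(times[mask], ev[mask], times[~mask], ev[~mask])
                summary_rows += [("logrank_doublehit_stat", stat), ("logrank_doublehit_p", p_lr)]
            summary_rows += [
                ("n_double_hit_events", float(len(events))),
                ("n_event_bearing_patients", float(dh_summary["n_event_bearing"])),
                ("pct_1_or_2_of_bearing", dh_summary["pct_1_or_2_of_bearing"]),
                ("pct_1_or_2_of_all", dh_summary["pct_1_or_2_of_all"]),
            ]

        if exposures:
            ebv = {
                p.patient_id: (
                    None if p.ebv_status == "unknown" else p.ebv_status == "positive"
                )
                for p in patients
            }
            dom = assign_dominant(exposures).set_index("sample_id")["dominant"]
            enr_rows = []
            for sig in sorted(dom.unique()):
                flag_dom = {sid: dom[sid] == sig for sid in dom.index}
                try:
                    table, p_fisher, excluded = enrichment_2x2(flag_dom, ebv)
                except ValueError:
                    continue
                enr_rows.append(
                    dict(signature=sig, a=table.a, b=table.b, c=table.c, d=table.d,
                         fisher_p=p_fisher, n_excluded=excluded)
                )
            if enr_rows:
                enr = pd.DataFrame(enr_rows)
                enr["q_bh"] = bh_fdr(enr["fisher_p"].to_numpy())
                _write_tsv(enr, outdir / "signature_ebv_enrichment.tsv")
        _write_tsv(
            pd.DataFrame(summary_rows, columns=["statistic", "value"]),
            outdir / "stats_summary.tsv",
        )

    # ----- report / provenance ----------------------------------------------
    if "report" in stages:
        n_private = sum(1 for _pid, pv, _c in private_calls if pv.is_private)
        n_ptv = sum(
            1 for _pid, pv, _c in private_calls
            if pv.is_private and is_ptv(pv.record.consequence)
        )
        report = pd.DataFrame(
            [
                ("n_patients", len(patient_ids)),
                ("n_private_variants", n_private),
                ("n_private_ptv", n_ptv),
                ("n_double_hit_events", len(events)),
                ("n_loh_segments", sum(len(v) for v in loh_by_patient.values())),
                ("n_fitted_exposures", len(exposures)),
            ],
            columns=["quantity", "value"],
        )
        _write_tsv(report, outdir / "report.tsv")
    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": list(stages),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    return outdir
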