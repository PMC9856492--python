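"""LOH detection, germline-to-somatic double-hit calling, and G-score summaries.

A *double-hit* event is a germline heterozygous alteration observed as
homozygous in the paired tumor — the classical second hit, usually via
loss of heterozygosity (LOH). LOH is detected here directly from tumor
variant-allele fractions (VAFs) at germline heterozygous sites: in a
diploid heterozygote the tumor VAF sits near 0.5, and a run of sites
deviating strongly from 0.5 marks a region where one allele was lost.

The thresholds assume high tumor purity; ``hom_vaf`` is the knob to relax
when purity is lower. Copy-number segments are consumed, not called; the
gene-level G score reported here is a simplified frequency-times-amplitude
surrogate, not the GISTIC statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

import numpy as np
import pandas as pd

from .io_formats import GenotypeCall, VariantKey
from .germline import GeneModel
from .stats import percent

__all__ = [
    "LohSegment",
    "DoubleHitEvent",
    "ScnaSegment",
    "call_loh_segments",
    "call_double_hits",
    "summarize_double_hits",
    "gene_gscore",
    "read_segment_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LohSegment:
    """A run of germline-heterozygous sites with allelic imbalance in the tumor.

    Coordinates are 0-based half-open; the segment spans the first through
    the last supporting site.
    """

    chrom: str
    start: int
    end: int
    n_het_sites: int
    median_tumor_vaf_deviation: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.median_tumor_vaf_deviation <= 0.5):
            raise ValueError("median VAF deviation must lie in [0, 0.5]")
        if self.end <= self.start:
            raise ValueError("empty LOH segment")

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class DoubleHitEvent:
    patient_id: str
    gene: str
    key: VariantKey
    germline_zygosity: str
    tumor_vaf: float | None
    tumor_depth: int
    evidence: frozenset[str]  # subset of {genotype_homozygous, vaf_threshold, loh_overlap}

    def __post_init__(self) -> None:
        if self.germline_zygosity != "het":
            raise ValueError("double-hit events require a heterozygous germline call")
        if not self.evidence:
            raise ValueError("double-hit events require at least one evidence tag")


@dataclass(frozen=True)
class ScnaSegment:
    """A somatic copy-number segment with its log2 tumor/normal ratio."""

    patient_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty SCNA segment")


def call_loh_segments(
    het_sites: list[tuple[int, float, int]],
    chrom: str = "",
    min_sites: int = 5,
    deviation_threshold: float = 0.25,
    min_depth: int = 10,
) -> list[LohSegment]:
    """Call LOH segments from one chromosome's germline-het tumor VAFs.

    ``het_sites`` are (0-based position, tumor VAF, tumor depth) tuples
    sorted by position. Sites below ``min_depth`` are uninformative and are
    skipped without breaking a run. A segment is a maximal run of at least
    ``min_sites`` consecutive informative sites whose |VAF - 0.5| is at
    least ``deviation_threshold``; it spans the first through last site.
    """
    positions = [p for p, _, _ in het_sites]
    if positions != sorted(positions):
        raise ValueError("het sites must be sorted by position")
    informative = [(p, v) for p, v, d in het_sites if d >= min_depth]
    segments: list[LohSegment] = []
    run: list[tuple[int, float]] = []

    def flush() -> None:
        if len(run) >= min_sites:
            devs = [abs(v - 0.5) for _, v in run]
            segments.append(
                LohSegment(
                    chrom=chrom,
                    start=run[0][0],
                    end=run[-1][0] + 1,
                    n_het_sites=len(run),
                    median_tumor_vaf_deviation=float(median(devs)),
                )
            )

    for pos, vaf in informative:
        if abs(vaf - 0.5) >= deviation_threshold:
            run.append((pos, vaf))
        else:
            flush()
            run = []
    flush()
    return segments


def call_double_hits(
    germline_het_calls: list[tuple[str, str, VariantKey, GenotypeCall, GenotypeCall | None]],
    loh_segments: dict[str, list[LohSegment]],
    hom_vaf: float = 0.9,
    min_depth: int = 10,
) -> list[DoubleHitEvent]:
    """Call double-hit events from heterozygous germline calls and tumor evidence.

    Each input tuple is (patient_id, gene, variant key, germline call,
    tumor call or None); germline calls must be heterozygous. An event is
    emitted when any clause fires:

    * the tumor genotype is homozygous-alt (``genotype_homozygous``);
    * the tumor VAF is at least ``hom_vaf`` at depth >= ``min_depth``
      (``vaf_threshold``);
    * the variant lies inside an LOH segment of that patient with tumor
      VAF above 0.5 (``loh_overlap``) — the alternate allele was the one
      retained.

    At most one event per (patient, variant). Variants lacking both a
    tumor genotype and a usable VAF are skipped with a warning.
    """
    events: list[DoubleHitEvent] = []
    seen: set[tuple[str, VariantKey]] = set()
    for patient_id, gene, key, germ, tumor in germline_het_calls:
        if germ.zygosity != "het":
            raise ValueError(f"{patient_id} {key}: germline call is {germ.zygosity}, not het")
        if (patient_id, key) in seen:
            continue
        if tumor is None:
            logger.warning("%s %s: no tumor call, skipping double-hit evaluation", patient_id, key)
            continue
        vaf = tumor.vaf
        if tumor.zygosity == "missing" and vaf is None:
            logger.warning("%s %s: tumor genotype missing and no VAF, skipped", patient_id, key)
            continue
        evidence = set()
        if tumor.zygosity == "hom_alt":
            evidence.add("genotype_homozygous")
        if vaf is not None and vaf >= hom_vaf and tumor.depth >= min_depth:
            evidence.add("vaf_threshold")
        if vaf is not None and vaf > 0.5:
            for seg in loh_segments.get(patient_id, []):
                if seg.contains(key.chrom, key.pos - 1):
                    evidence.add("loh_overlap")
                    break
        if evidence:
            seen.add((patient_id, key))
            events.append(
                DoubleHitEvent(
                    patient_id=patient_id,
                    gene=gene,
                    key=key,
                    germline_zygosity="het",
                    tumor_vaf=vaf,
                    tumor_depth=tumor.depth,
                    evidence=frozenset(evidence),
                )
            )
    return events


def summarize_double_hits(
    events: list[DoubleHitEvent], patient_ids: list[str]
) -> dict[str, pd.DataFrame | float]:
    """Tally double-hit events per patient and per gene.

    Returns per-patient counts (all patients, zeros included), per-gene
    counts, and the share of *event-bearing* patients with exactly 1 or 2
    events; the share over all patients is reported alongside since the
    natural denominator is ambiguous.
    """
    per_patient = {p: 0 for p in patient_ids}
    per_gene: dict[str, int] = {}
    for ev in events:
        per_patient[ev.patient_id] = per_patient.get(ev.patient_id, 0) + 1
        per_gene[ev.gene] = per_gene.get(ev.gene, 0) + 1
    patient_df = pd.DataFrame(
        sorted(per_patient.items()), columns=["patient_id", "n_events"]
    )
    gene_df = pd.DataFrame(sorted(per_gene.items()), columns=["gene", "n_events"])
    bearing = patient_df[patient_df["n_events"] > 0]
    n_bearing = len(bearing)
    n_1or2 = int(((bearing["n_events"] >= 1) & (bearing["n_events"] <= 2)).sum())
    return {
        "per_patient": patient_df,
        "per_gene": gene_df,
        "n_event_bearing": n_bearing,
        "n_with_1_or_2": n_1or2,
        "pct_1_or_2_of_bearing": percent(n_1or2, n_bearing) if n_bearing else 0.0,
        "pct_1_or_2_of_all": percent(n_1or2, len(patient_ids)) if patient_ids else 0.0,
    }


def read_segment_tsv(path: str) -> list[ScnaSegment]:
    """Load externally produced segments: patient_id, chrom, start, end, log2_ratio."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
    return [
        ScnaSegment(r.patient_id, r.chrom, int(r.start), int(r.end), float(r.log2_ratio))
        for r in df.itertuples()
    ]


def gene_gscore(
    segments: list[ScnaSegment],
    gene_model: GeneModel,
    n_patients: int,
    amp_threshold: float = 0.3,
    del_threshold: float = -0.3,
) -> pd.DataFrame:
    """Frequency-times-amplitude copy-number summary per gene.

    For each gene, amp_freq (del_freq) is the fraction of patients with at
    least one overlapping segment at log2 ratio >= ``amp_threshold``
    (<= ``del_threshold``), and g_amp (g_del) is that frequency times the
    mean |log2 ratio| over all qualifying overlapping segments. A
    simplified surrogate for a G score — not the GISTIC statistic.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    rows = []
    for name, g in sorted(gene_model.genes.items()):
        amp_pat: set[str] = set()
        del_pat: set[str] = set()
        amp_ratios: list[float] = []
        del_ratios: list[float] = []
        for seg in segments:
            if seg.chrom != g.chrom or seg.end <= g.start or seg.start >= g.end:
                continue
            if seg.log2_ratio >= amp_threshold:
                amp_pat.add(seg.patient_id)
                amp_ratios.append(abs(seg.log2_ratio))
            elif seg.log2_ratio <= del_threshold:
                del_pat.add(seg.patient_id)
                del_ratios.append(abs(seg.log2_ratio))
        amp_freq = len(amp_pat) / n_patients
        del_freq = len(del_pat) / n_patients
        rows.append(
            (
                name,
                amp_freq,
                del_freq,
                amp_freq * (float(np.mean(amp_ratios)) if amp_ratios else 0.0),
                del_freq * (float(np.mean(del_ratios)) if del_ratios else 0.0),
            )
        )
    return pd.DataFrame(rows, columns=["gene", "amp_freq", "del_freq", "g_amp", "g_del"])
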