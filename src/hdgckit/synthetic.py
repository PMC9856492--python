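"""Self-contained synthetic paired tumor-normal cohort generator.

Emulates the inputs of an HDGC cohort analysis with planted ground truth:
a random reference genome, a CDS gene model, population allele
frequencies, mappability/uniqueness tracks, per-patient germline and tumor
VCFs, a clinical manifest with family histories and survival, a toy
signature matrix, and truth tables for every planted feature. Everything
is deterministic given the seed.

What is planted, per patient:

* private germline variants at per-gene carrier rates (one variant per
  carrier per gene), split between truncating classes and missense;
* decoy variants that each violate exactly one of the six private-variant
  criteria while passing the other five;
* shared common variants drawn from the frequency table under
  Hardy-Weinberg genotypes;
* LOH segments in the tumor — some wrapping a private heterozygote whose
  alternate allele is retained (a planted double hit), some background —
  each supported by a run of patient-specific heterozygous sites with
  deviant tumor allele fractions;
* somatic SNVs whose trinucleotide contexts are drawn from a per-sample
  Dirichlet mixture of three toy signatures;
* clinical covariates matching the cohort's published composition
  (condition mix, sex ratio, stage distribution, EBV rates) and
  exponential survival with uniform censoring.

Features of real data deliberately not emulated: linkage structure,
sequencing error, subclonality and tumor purity below ~1, multi-nucleotide
variants, and structural variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from .io_formats import (
    GenotypeCall,
    ReferenceGenome,
    VariantKey,
    normalize_variant,
    write_vcf,
)
from .germline import GeneModel, classify_consequence, is_ptv
from .signatures import CATEGORY_LABELS, SUBSTITUTION_CLASSES, SignatureMatrix

__all__ = [
    "SimulationConfig",
    "generate",
    "verify_truth",
    "toy_signatures",
    "simulate_catalog",
    "make_private_criteria_panel",
]

_BASES = np.array(["A", "C", "G", "T"])
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions.

    ``cdh1_like_carrier_fraction`` (2.8%) and ``muc4_like_carrier_fraction``
    (18.7%) reproduce the reported extremes of per-gene private-variant
    carrier frequency; ``condition_mix`` follows the published eligibility
    breakdown; ``five_year_survival`` sets the exponential hazard so the
    cohort's 5-year overall survival matches the reported 61.4%.
    """

    seed: int = 0
    n_patients: int = 50
    n_contigs: int = 2
    contig_length: int = 60_000
    n_genes: int = 12
    exon_length: int = 300
    intron_length: int = 120
    n_exons_per_gene: int = 2
    private_variant_rate: float = 0.06          # per-gene carrier probability
    fraction_ptv: float = 0.6                   # PTV share among planted privates
    cdh1_like_carrier_fraction: float = 0.028
    muc4_like_carrier_fraction: float = 0.187
    n_common_variants: int = 40
    n_decoys_per_criterion: int = 4
    double_hit_count: int = 12
    background_loh_per_tumor: int = 1
    loh_support_sites: int = 6                  # extra het sites per LOH segment
    loh_halfwidth: int = 1_200                  # bp around the anchor site
    signature_alpha: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_somatic_per_tumor: int = 300
    mean_depth: int = 80
    read_noise: bool = True                     # binomial read sampling
    retained_allele_fraction: float = 0.98      # tumor VAF of the kept allele in LOH
    condition_mix: tuple[float, ...] = (0.081, 0.025, 0.894, 0.0)
    female_fraction: float = 0.567
    ebv_mix: tuple[float, ...] = (0.028, 0.736, 0.236)  # positive/negative/unknown
    stage_iii_iv_fraction: float = 0.669
    five_year_survival: float = 0.614
    follow_up_max_months: float = 120.0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_genes < 3:
            raise ValueError("need at least 1 patient and 3 genes")
        for name in (
            "private_variant_rate",
            "fraction_ptv",
            "cdh1_like_carrier_fraction",
            "muc4_like_carrier_fraction",
            "five_year_survival",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.five_year_survival < 1.0:
            raise ValueError("five_year_survival must lie strictly in (0, 1)")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be at least 1")
        if abs(sum(self.condition_mix) - 1.0) > 1e-9:
            raise ValueError("condition_mix must sum to 1")
        footprint = self.n_exons_per_gene * self.exon_length + (
            self.n_exons_per_gene - 1
        ) * self.intron_length
        per_contig = -(-self.n_genes // self.n_contigs)
        if per_contig * (footprint + 2 * self.loh_halfwidth + 600) > self.contig_length:
            raise ValueError("contig_length too short for the requested gene layout")


def toy_signatures() -> SignatureMatrix:
    """Three deterministic toy signatures with low pairwise similarity.

    Each concentrates 90% of its mass on one substitution class (C>T, C>A,
    T>C) with a linear ramp over the 16 contexts, and spreads the rest
    uniformly; pairwise cosine similarity is about 0.05.
    """
    blocks = {"TS1": "C>T", "TS2": "C>A", "TS3": "T>C"}
    mat = np.zeros((96, 3))
    for j, (name, sub) in enumerate(blocks.items()):
        k = SUBSTITUTION_CLASSES.index(sub)
        ramp = np.arange(1, 17, dtype=float)
        ramp = 0.9 * ramp / ramp.sum()
        col = np.full(96, 0.1 / 80.0)
        col[k * 16:(k + 1) * 16] = ramp
        mat[:, j] = col
    return SignatureMatrix(list(blocks), mat)


def simulate_catalog(
    signatures: SignatureMatrix,
    weights: np.ndarray,
    n_mutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one 96-category catalog row from a signature mixture."""
    w = np.asarray(weights, dtype=float)
    p = signatures.matrix @ (w / w.sum())
    return rng.multinomial(n_mutations, p / p.sum())


# --------------------------------------------------------------------------
# reference / gene-model construction
# --------------------------------------------------------------------------

def _make_reference(cfg: SimulationConfig, rng: np.random.Generator, outdir: Path) -> ReferenceGenome:
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for i in range(cfg.n_contigs):
            seq = "".join(rng.choice(_BASES, size=cfg.contig_length))
            fh.write(f">chr{i + 1}\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")
    Faidx(str(fasta))  # builds the .fai index
    return ReferenceGenome(fasta)


def _make_gene_model(cfg: SimulationConfig, rng: np.random.Generator, outdir: Path) -> GeneModel:
    names = ["CDH1", "MUC4"] + [f"G{i:03d}" for i in range(3, cfg.n_genes + 1)]
    per_contig = -(-cfg.n_genes // cfg.n_contigs)
    spacing = cfg.contig_length // (per_contig + 1)
    rows = []
    for idx, name in enumerate(names):
        chrom = f"chr{idx // per_contig + 1}"
        start = (idx % per_contig) * spacing + spacing // 2
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for _ in range(cfg.n_exons_per_gene):
            exons.append((pos, pos + cfg.exon_length))
            pos += cfg.exon_length + cfg.intron_length
        order = exons if strand == "+" else list(reversed(exons))
        offset = 0
        frames = {}
        for s, e in order:
            frames[s] = offset % 3
            offset += e - s
        for s, e in exons:
            rows.append((chrom, s, e, name, strand, frames[s]))
    bed = outdir / "genes.bed"
    with open(bed, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return GeneModel.from_bed(bed)


# --------------------------------------------------------------------------
# variant planting helpers
# --------------------------------------------------------------------------

def _codon_positions(model: GeneModel, gene, codon_idx: int) -> list[int]:
    return [model.genomic_position(gene, codon_idx * 3 + i) for i in range(3)]


def _plant_coding_snv(
    model: GeneModel,
    gene_name: str,
    reference: ReferenceGenome,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    want: str,
    max_tries: int = 400,
) -> VariantKey | None:
    """Find an SNV in the gene's CDS with the requested consequence class."""
    g = model.genes[gene_name]
    n_codons = model.cds_length(gene_name) // 3
    for _ in range(max_tries):
        ci = int(rng.integers(2, n_codons - 2))
        within = int(rng.integers(0, 3))
        pos0 = _codon_positions(model, g, ci)[within]
        if any((g.chrom, p) in used for p in range(pos0 - 1, pos0 + 2)):
            continue
        ref = reference.fetch(g.chrom, pos0, pos0 + 1)
        for alt in rng.permutation([b for b in "ACGT" if b != ref]):
            key = VariantKey(g.chrom, pos0 + 1, ref, str(alt))
            gname, cons = classify_consequence(key, model, reference)
            if gname == gene_name and cons == want:
                used.add((g.chrom, pos0))
                return key
    return None


def _plant_frameshift(
    model: GeneModel,
    gene_name: str,
    reference: ReferenceGenome,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    max_tries: int = 200,
) -> VariantKey | None:
    """A 1-bp coding deletion, normalized, re-checked to stay in the CDS."""
    g = model.genes[gene_name]
    for _ in range(max_tries):
        s, e, _f = g.exons[int(rng.integers(0, len(g.exons)))]
        pos0 = int(rng.integers(s + 10, e - 10))
        ref = reference.fetch(g.chrom, pos0, pos0 + 2)
        key = normalize_variant(VariantKey(g.chrom, pos0 + 1, ref, ref[0]), reference)
        span = range(key.pos - 2, key.pos + len(key.ref) + 1)
        if any((g.chrom, p) in used for p in span):
            continue
        gname, cons = classify_consequence(key, model, reference)
        if gname == gene_name and cons == "frameshift_indel":
            used.update((g.chrom, p) for p in span)
            return key
    return None


def _plant_splice(
    model: GeneModel,
    gene_name: str,
    reference: ReferenceGenome,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
) -> VariantKey | None:
    g = model.genes[gene_name]
    candidates = sorted(model.splice_positions(g))
    rng.shuffle(candidates)
    for pos0 in candidates:
        if (g.chrom, pos0) in used:
            continue
        ref = reference.fetch(g.chrom, pos0, pos0 + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = VariantKey(g.chrom, pos0 + 1, ref, alt)
        gname, cons = classify_consequence(key, model, reference)
        if gname == gene_name and cons == "splice_site":
            used.add((g.chrom, pos0))
            return key
    return None


def _plant_private(
    model: GeneModel,
    gene_name: str,
    reference: ReferenceGenome,
    rng: np.random.Generator,
    used: set[tuple[str, int]],
    fraction_ptv: float,
) -> tuple[VariantKey, str] | None:
    if rng.random() < fraction_ptv:
        kind = str(rng.choice(["nonsense", "frameshift_indel", "splice_site"]))
    else:
        kind = "missense"
    if kind == "missense" or kind == "nonsense":
        key = _plant_coding_snv(model, gene_name, reference, rng, used, kind)
    elif kind == "frameshift_indel":
        key = _plant_frameshift(model, gene_name, reference, rng, used)
    else:
        key = _plant_splice(model, gene_name, reference, rng, used)
    if key is None:
        return None
    return key, kind


# --------------------------------------------------------------------------
# genotype emission
# --------------------------------------------------------------------------

def _emit_call(
    sample: str,
    allele_fraction: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    germline_truth: str | None = None,
) -> GenotypeCall:
    """Build a genotype call at a site with true alt-allele fraction ``p``.

    With read noise, depth is Poisson(mean_depth) (floored at 1) and alt
    reads are binomial; the written genotype is then re-derived from the
    observed VAF like a naive caller would (>=0.9 hom_alt, <=0.1 hom_ref,
    else het) unless a trusted germline genotype is supplied.
    """
    if cfg.read_noise:
        depth = max(int(rng.poisson(cfg.mean_depth)), 1)
        alt = int(rng.binomial(depth, allele_fraction))
    else:
        depth = cfg.mean_depth
        alt = int(round(allele_fraction * depth))
    if germline_truth is not None:
        zyg = germline_truth
    else:
        vaf = alt / depth
        zyg = "hom_alt" if vaf >= 0.9 else ("hom_ref" if vaf <= 0.1 else "het")
    return GenotypeCall(sample, zyg, depth=depth, alt_depth=alt)


# --------------------------------------------------------------------------
# main generator
# --------------------------------------------------------------------------

def generate(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write a complete synthetic bundle under ``outdir`` and return its path."""
    cfg.validate()
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    reference = _make_reference(cfg, rng, outdir)
    model = _make_gene_model(cfg, rng, outdir)
    contig_lengths = {c: reference.contig_length(c) for c in reference.contigs()}
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]
    used: set[tuple[str, int]] = set()

    # --- per-gene carrier rates -------------------------------------------
    rates = {}
    for name in model.genes:
        if name == "CDH1":
            rates[name] = cfg.cdh1_like_carrier_fraction
        elif name == "MUC4":
            rates[name] = cfg.muc4_like_carrier_fraction
        else:
            rates[name] = cfg.private_variant_rate

    # germline variant book-keeping: patient -> {key: (zygosity, kind)}
    germline: dict[str, dict[VariantKey, tuple[str, str]]] = {p: {} for p in patients}
    truth_private_rows: list[dict] = []

    def record_private(pid, key, gene, cons, role, flags):
        truth_private_rows.append(
            dict(
                patient_id=pid,
                chrom=key.chrom,
                pos=key.pos,
                ref=key.ref,
                alt=key.alt,
                gene=gene,
                consequence=cons,
                is_ptv=is_ptv(cons),
                role=role,
                c1=flags[0], c2=flags[1], c3=flags[2],
                c4=flags[3], c5=flags[4], c6=flags[5],
                is_private=all(flags),
            )
        )

    # --- passing private variants -----------------------------------------
    for gene_name, rate in rates.items():
        for pid in patients:
            if rng.random() >= rate:
                continue
            planted = _plant_private(model, gene_name, reference, rng, used, cfg.fraction_ptv)
            if planted is None:
                continue
            key, cons = planted
            germline[pid][key] = ("het", "private")
            record_private(pid, key, gene_name, cons, "pass", (True,) * 6)

    # --- decoys: each violates exactly one criterion -----------------------
    freq_rows: list[tuple[VariantKey, float, float]] = []
    lowmap_windows: list[tuple[str, int, int]] = []
    nonunique_windows: list[tuple[str, int, int]] = []
    gene_names = list(model.genes)
    decoy_specs = [
        ("c1", "synonymous"), ("c2", "missense"), ("c3", "missense"),
        ("c4", "missense"), ("c5", "missense"), ("c6", "missense"),
    ]
    for crit, want in decoy_specs:
        placed = 0
        while placed < cfg.n_decoys_per_criterion:
            gene_name = str(rng.choice(gene_names))
            pid = str(rng.choice(patients))
            key = _plant_coding_snv(model, gene_name, reference, rng, used, want)
            if key is None:
                continue
            flags = [want != "synonymous", True, True, True, True, True]
            zyg = "het"
            if crit == "c2":
                zyg = "hom_alt"
                flags[1] = False
            elif crit == "c3":
                freq_rows.append((key, 0.02, 0.01))
                flags[2] = False
            elif crit == "c4":
                other = str(rng.choice([p for p in patients if p != pid]))
                germline[other][key] = ("het", f"decoy_{crit}")
                record_private(other, key, gene_name, want, f"decoy_{crit}",
                               tuple([flags[0], True, True, False, True, True]))
                flags[3] = False
            elif crit == "c5":
                lowmap_windows.append((key.chrom, key.pos - 3, key.pos + 2))
                flags[4] = False
            elif crit == "c6":
                nonunique_windows.append((key.chrom, key.pos - 3, key.pos + 2))
                flags[5] = False
            germline[pid][key] = (zyg, f"decoy_{crit}")
            record_private(pid, key, gene_name, want, f"decoy_{crit}", tuple(flags))
            placed += 1

    # --- double hits and LOH regions ---------------------------------------
    passing = [
        (r["patient_id"], VariantKey(r["chrom"], r["pos"], r["ref"], r["alt"]), r["gene"])
        for r in truth_private_rows
        if r["role"] == "pass"
    ]
    rng.shuffle(passing)
    if cfg.double_hit_count > len(passing):
        raise ValueError(
            f"double_hit_count={cfg.double_hit_count} exceeds the "
            f"{len(passing)} planted private variants; raise the carrier rates"
        )
    taken_gene_patient: set[tuple[str, str]] = set()
    double_hits: list[tuple[str, VariantKey, str]] = []
    for pid, key, gene in passing:
        if len(double_hits) == cfg.double_hit_count:
            break
        if (pid, gene) in taken_gene_patient:
            continue
        # the LOH run needs every het site of this patient in the window to
        # be allele-imbalanced: skip anchors with another variant nearby
        crowded = any(
            k2 != key and k2.chrom == key.chrom and abs(k2.pos - key.pos) <= cfg.loh_halfwidth
            for k2 in germline[pid]
        )
        if crowded:
            continue
        double_hits.append((pid, key, gene))
        taken_gene_patient.add((pid, gene))
    if len(double_hits) < cfg.double_hit_count:
        raise ValueError(
            f"only {len(double_hits)} usable double-hit anchors for "
            f"double_hit_count={cfg.double_hit_count}; raise the carrier rates"
        )

    # LOH regions: (patient, chrom, lo, hi, kind, anchor key or None)
    loh_regions: list[tuple[str, str, int, int, str, VariantKey | None]] = []
    for pid, key, _gene in double_hits:
        lo = max(1, key.pos - 1 - cfg.loh_halfwidth)
        hi = min(contig_lengths[key.chrom] - 2, key.pos - 1 + cfg.loh_halfwidth)
        loh_regions.append((pid, key.chrom, lo, hi, "double_hit", key))
    gene_spans = [
        (g.chrom, g.start - 2, g.end + 2) for g in model.genes.values()
    ]

    def in_gene(chrom: str, pos0: int) -> bool:
        return any(c == chrom and s <= pos0 < e for c, s, e in gene_spans)

    for pid in patients:
        for _ in range(cfg.background_loh_per_tumor):
            chrom = str(rng.choice(list(contig_lengths)))
            for _try in range(50):
                center = int(rng.integers(cfg.loh_halfwidth + 10,
                                          contig_lengths[chrom] - cfg.loh_halfwidth - 10))
                lo, hi = center - cfg.loh_halfwidth, center + cfg.loh_halfwidth
                clash = any(
                    c == chrom and not (hi < l or lo > h)
                    for (_p, c, l, h, _k, _a) in loh_regions
                ) or any(
                    c == chrom and not (hi < s or lo >= e) for c, s, e in gene_spans
                )
                if not clash:
                    loh_regions.append((pid, chrom, lo, hi, "background", None))
                    break

    # support het sites inside each LOH region (patient-specific, intergenic
    # consequence-wise they are non-coding or synonymous-free, i.e. fail c1)
    loh_support: dict[tuple[str, VariantKey], None] = {}
    for pid, chrom, lo, hi, _kind, anchor in loh_regions:
        placed = 0
        tries = 0
        while placed < cfg.loh_support_sites:
            tries += 1
            if tries > 2000:
                raise RuntimeError(f"cannot place LOH support sites in {chrom}:{lo}-{hi}")
            pos0 = int(rng.integers(lo, hi))
            # support sites stay outside genes so they can never be scored
            # as coding variants of an unplanted consequence class
            if in_gene(chrom, pos0):
                continue
            if any((chrom, p) in used for p in range(pos0 - 1, pos0 + 2)):
                continue
            ref = reference.fetch(chrom, pos0, pos0 + 1)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            key = VariantKey(chrom, pos0 + 1, ref, alt)
            used.add((chrom, pos0))
            germline[pid][key] = ("het", "loh_support")
            loh_support[(pid, key)] = None
            placed += 1

    # --- common population variants ----------------------------------------
    loh_mask = [(c, l, h) for (_p, c, l, h, _k, _a) in loh_regions]

    def in_any_loh(chrom: str, pos0: int) -> bool:
        return any(c == chrom and l <= pos0 <= h for c, l, h in loh_mask)

    placed = 0
    while placed < cfg.n_common_variants:
        chrom = str(rng.choice(list(contig_lengths)))
        pos0 = int(rng.integers(5, contig_lengths[chrom] - 5))
        if (chrom, pos0) in used or in_any_loh(chrom, pos0):
            continue
        ref = reference.fetch(chrom, pos0, pos0 + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = VariantKey(chrom, pos0 + 1, ref, alt)
        used.add((chrom, pos0))
        f1 = float(rng.uniform(0.05, 0.4))
        f2 = float(np.clip(f1 * rng.uniform(0.5, 1.5), 0.0, 0.5))
        freq_rows.append((key, f1, f2))
        for pid in patients:
            u = rng.random()
            if u < f1 * f1:
                germline[pid][key] = ("hom_alt", "common")
            elif u < f1 * f1 + 2 * f1 * (1 - f1):
                germline[pid][key] = ("het", "common")
        placed += 1

    # --- tracks and frequency table ----------------------------------------
    with open(outdir / "mappability.bed", "w") as fh:
        for chrom, s, e in sorted(lowmap_windows):
            fh.write(f"{chrom}\t{s}\t{e}\t0.3\n")
    with open(outdir / "uniqueness.bed", "w") as fh:
        for chrom, s, e in sorted(nonunique_windows):
            fh.write(f"{chrom}\t{s}\t{e}\t0\n")
    with open(outdir / "frequencies.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tfreq1\tfreq2\n")
        for key, f1, f2 in sorted(freq_rows, key=lambda r: (r[0].chrom, r[0].pos)):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{f1:.6f}\t{f2:.6f}\n")

    # --- signatures and somatic SNVs ---------------------------------------
    sigs = toy_signatures()
    sigs.to_tsv(outdir / "signatures.tsv")
    context_index = _build_context_index(reference)
    sig_weights = rng.dirichlet(cfg.signature_alpha, size=cfg.n_patients)
    somatic: dict[str, dict[VariantKey, float]] = {p: {} for p in patients}
    dh_lookup = {(pid, key) for pid, key, _g in double_hits}
    loh_by_patient: dict[str, list[tuple[str, int, int]]] = {}
    for pid, chrom, lo, hi, _k, _a in loh_regions:
        loh_by_patient.setdefault(pid, []).append((chrom, lo, hi))

    for i, pid in enumerate(patients):
        cats = rng.multinomial(cfg.n_somatic_per_tumor, sigs.matrix @ sig_weights[i])
        taken = {(k.chrom, k.pos - 1) for k in germline[pid]}
        for cat, count in enumerate(cats):
            sites, alts = context_index[cat]
            for _ in range(count):
                for _try in range(30):
                    j = int(rng.integers(0, len(sites)))
                    chrom, pos0 = sites[j]
                    if (chrom, pos0) not in taken:
                        break
                taken.add((chrom, pos0))
                ref = reference.fetch(chrom, pos0, pos0 + 1)
                somatic[pid][VariantKey(chrom, pos0 + 1, ref, alts[j])] = 0.4

    # --- write VCFs ---------------------------------------------------------
    zyg_p = {"het": 0.5, "hom_alt": 1.0}
    for pid in patients:
        g_calls = []
        t_calls = []
        for key, (zyg, kind) in germline[pid].items():
            g_calls.append((key, _emit_call(pid, zyg_p[zyg], cfg, rng, germline_truth=zyg)))
            # tumor allele fraction: LOH regions distort het sites
            p_alt = zyg_p[zyg]
            if zyg == "het":
                in_loh = any(
                    c == key.chrom and l <= key.pos - 1 <= h
                    for c, l, h in loh_by_patient.get(pid, [])
                )
                if in_loh:
                    if (pid, key) in dh_lookup:
                        p_alt = cfg.retained_allele_fraction
                    else:
                        p_alt = (
                            cfg.retained_allele_fraction
                            if rng.random() < 0.5
                            else 1 - cfg.retained_allele_fraction
                        )
            t_calls.append((key, _emit_call(f"{pid}_T", p_alt, cfg, rng)))
        for key, p_alt in somatic[pid].items():
            t_calls.append((key, _emit_call(f"{pid}_T", p_alt, cfg, rng)))
        write_vcf(outdir / "vcf" / f"{pid}.germline.vcf", pid, g_calls, contig_lengths)
        write_vcf(outdir / "vcf" / f"{pid}.tumor.vcf", f"{pid}_T", t_calls, contig_lengths)

    # --- clinical data ------------------------------------------------------
    clinical, family = _make_clinical(cfg, rng, patients)
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    family.to_csv(outdir / "family_history.tsv", sep="\t", index=False)

    # --- truth tables -------------------------------------------------------
    pd.DataFrame(truth_private_rows).to_csv(outdir / "truth" / "private.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dict(patient_id=pid, gene=g, chrom=k.chrom, pos=k.pos, ref=k.ref, alt=k.alt)
         for pid, k, g in double_hits],
        columns=["patient_id", "gene", "chrom", "pos", "ref", "alt"],
    ).to_csv(outdir / "truth" / "double_hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dict(patient_id=pid, chrom=c, start=l, end=h + 1, kind=kind)
         for pid, c, l, h, kind, _a in loh_regions]
    ).to_csv(outdir / "truth" / "loh.tsv", sep="\t", index=False)
    pd.DataFrame(
        dict(sample_id=patients)
        | {f"w_{sid}": sig_weights[:, j] for j, sid in enumerate(sigs.signature_ids)}
    ).to_csv(outdir / "truth" / "exposures.tsv", sep="\t", index=False, float_format="%.6f")
    carriers: dict[str, set[str]] = {}
    for r in truth_private_rows:
        if r["role"] == "pass":
            carriers.setdefault(r["gene"], set()).add(r["patient_id"])
    pd.DataFrame(
        sorted((g, len(p)) for g, p in carriers.items()),
        columns=["gene", "carrier_count"],
    ).to_csv(outdir / "truth" / "carriers.tsv", sep="\t", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
    return outdir


def _build_context_index(reference: ReferenceGenome):
    """Map each SBS-96 category to its genomic sites and the alt to apply."""
    from .signatures import category_index

    index: list[tuple[list, list]] = [([], []) for _ in range(96)]
    for chrom in reference.contigs():
        seq = reference.fetch(chrom, 0, reference.contig_length(chrom))
        for pos0 in range(1, len(seq) - 1):
            ref = seq[pos0]
            five, three = seq[pos0 - 1], seq[pos0 + 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                cat = category_index(ref, alt, five, three)
                index[cat][0].append((chrom, pos0))
                index[cat][1].append(alt)
    for cat, (sites, _alts) in enumerate(index):
        if not sites:
            raise ValueError(f"no genomic site for category {CATEGORY_LABELS[cat]}; contigs too short")
    return index


def _make_clinical(cfg: SimulationConfig, rng: np.random.Generator, patients: list[str]):
    conditions = rng.choice([1, 2, 3, 4], size=len(patients), p=list(cfg.condition_mix))
    hazard = -np.log(cfg.five_year_survival) / 60.0
    man_rows, fam_rows = [], []
    for pid, cond in zip(patients, conditions):
        cond = int(cond)
        if cond == 3:
            age = float(rng.integers(20, 40))
            if rng.random() < 0.3:
                fam_rows.append(dict(patient_id=pid, degree=1, diagnosis="GC",
                                     age_at_dx=float(rng.integers(55, 75)), confirmed=False))
        elif cond == 1:
            age = float(rng.integers(40, 60))
            fam_rows.append(dict(patient_id=pid, degree=1, diagnosis="diffuse_GC",
                                 age_at_dx=float(rng.integers(35, 50)), confirmed=True))
            fam_rows.append(dict(patient_id=pid, degree=2, diagnosis="GC",
                                 age_at_dx=float(rng.integers(50, 70)), confirmed=False))
        elif cond == 2:
            age = float(rng.integers(40, 60))
            for _ in range(3):
                fam_rows.append(dict(patient_id=pid, degree=int(rng.integers(1, 3)),
                                     diagnosis="diffuse_GC",
                                     age_at_dx=float(rng.integers(50, 70)), confirmed=True))
        else:  # condition 4
            age = float(rng.integers(40, 50))
            fam_rows.append(dict(patient_id=pid, degree=1, diagnosis="lobular_breast",
                                 age_at_dx=float(rng.integers(35, 50)), confirmed=True))
        t_event = float(rng.exponential(1.0 / hazard))
        t_cens = float(rng.uniform(6.0, cfg.follow_up_max_months))
        stage = "III_IV" if rng.random() < cfg.stage_iii_iv_fraction else "I_II"
        man_rows.append(
            dict(
                patient_id=pid,
                age_at_dx=age,
                sex="female" if rng.random() < cfg.female_fraction else "male",
                histology="diffuse",
                personal_lobular_breast=False,
                stage_t="T3_4" if stage == "III_IV" else "T1_2",
                stage_n="N2_3" if stage == "III_IV" else "N0_1",
                stage_m="M0",
                ajcc_stage=stage,
                ebv_status=str(rng.choice(["positive", "negative", "unknown"], p=list(cfg.ebv_mix))),
                survival_time=round(min(t_event, t_cens), 2),
                survival_event=t_event <= t_cens,
                condition_planted=cond,
            )
        )
    return pd.DataFrame(man_rows), pd.DataFrame(fam_rows)


# --------------------------------------------------------------------------
# verification and fixed test panels
# --------------------------------------------------------------------------

def verify_truth(bundle: str | Path) -> list[str]:
    """Re-read a bundle and check that truth tables match the emitted files.

    Returns a list of human-readable failure messages (empty = all good).
    """
    from .io_formats import read_paired_vcfs

    bundle = Path(bundle)
    failures: list[str] = []
    for name in ("reference.fa", "genes.bed", "frequencies.tsv", "clinical.tsv",
                 "signatures.tsv", "truth/private.tsv", "truth/double_hits.tsv"):
        if not (bundle / name).exists():
            raise FileNotFoundError(bundle / name)
    reference = ReferenceGenome(bundle / "reference.fa")
    priv = pd.read_csv(bundle / "truth" / "private.tsv", sep="\t")
    dh = pd.read_csv(bundle / "truth" / "double_hits.tsv", sep="\t")
    expo = pd.read_csv(bundle / "truth" / "exposures.tsv", sep="\t")

    paired_cache: dict[str, dict] = {}

    def paired(pid: str):
        if pid not in paired_cache:
            calls = read_paired_vcfs(
                bundle / "vcf" / f"{pid}.germline.vcf",
                bundle / "vcf" / f"{pid}.tumor.vcf",
                reference,
            )
            paired_cache[pid] = {c.key: c for c in calls}
        return paired_cache[pid]

    for r in priv.itertuples():
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        call = paired(r.patient_id).get(key)
        if call is None or call.germline is None:
            failures.append(f"truth private {r.patient_id} {key} absent from germline VCF")
            continue
        expected_zyg = "hom_alt" if (not r.c2) else "het"
        if call.germline.zygosity != expected_zyg:
            failures.append(
                f"truth private {r.patient_id} {key}: germline zygosity "
                f"{call.germline.zygosity}, expected {expected_zyg}"
            )
    for r in dh.itertuples():
        key = VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        call = paired(r.patient_id).get(key)
        if call is None or call.tumor is None:
            failures.append(f"truth double hit {r.patient_id} {key} absent from tumor VCF")
            continue
        vaf = call.tumor.vaf
        if call.tumor.zygosity != "hom_alt" and (vaf is None or vaf < 0.8):
            failures.append(f"truth double hit {r.patient_id} {key}: tumor not near-homozygous")
    # cross-table consistency: carrier counts must be re-derivable from the
    # private-variant truth, so a dropped row in either table is caught
    carriers = pd.read_csv(bundle / "truth" / "carriers.tsv", sep="\t")
    derived = (
        priv[priv["role"] == "pass"]
        .groupby("gene")["patient_id"]
        .nunique()
        .to_dict()
    )
    for r in carriers.itertuples():
        if derived.get(r.gene, 0) != r.carrier_count:
            failures.append(
                f"carrier count for {r.gene}: table says {r.carrier_count}, "
                f"private truth yields {derived.get(r.gene, 0)}"
            )
    for gene, n in derived.items():
        if gene not in set(carriers["gene"]):
            failures.append(f"gene {gene} has {n} carriers but no carriers.tsv row")
    w_cols = [c for c in expo.columns if c.startswith("w_")]
    sums = expo[w_cols].sum(axis=1)
    for sid, s in zip(expo["sample_id"], sums):
        if abs(s - 1.0) > 1e-4:
            failures.append(f"truth exposures for {sid} sum to {s:.4f}, not 1")
    return failures


def make_private_criteria_panel():
    """A fixed in-memory panel exercising each private-variant criterion.

    Returns (records, genotypes, occurrence_counts, expected_private):
    4 variants passing all six criteria and 24 decoys (4 per criterion),
    each decoy violating exactly its one criterion.
    """
    from .io_formats import VariantRecord

    records, genotypes, occurrences, expected = [], [], [], []

    def add(i, consequence="missense", zyg="het", maf=(0.0, 0.0), occ=1,
            mapp=0.95, unique=True, private=False):
        key = VariantKey("chr1", 1000 + i * 10, "A", "G")
        records.append(
            VariantRecord(key, gene=f"GENE{i % 7}", consequence=consequence,
                          maf_db1=maf[0], maf_db2=maf[1],
                          mappability=mapp, unique_locus=unique)
        )
        genotypes.append(GenotypeCall(f"S{i}", zyg, depth=60, alt_depth=30 if zyg == "het" else 60))
        occurrences.append(occ)
        expected.append(private)

    i = 0
    for _ in range(4):
        add(i, private=True); i += 1
    for _ in range(4):
        add(i, consequence="synonymous"); i += 1          # fails c1
    for _ in range(4):
        add(i, zyg="hom_alt"); i += 1                     # fails c2
    for maf in [(0.006, 0.0), (0.0, 0.2), (0.01, 0.01), (0.005, 0.0)]:
        add(i, maf=maf); i += 1                           # fails c3 (0.005 is not < 0.005)
    for _ in range(4):
        add(i, occ=2); i += 1                             # fails c4
    for mapp in [0.5, 0.4, 0.1, 0.0]:
        add(i, mapp=mapp); i += 1                         # fails c5 (0.5 is not > 0.5)
    for _ in range(4):
        add(i, unique=False); i += 1                      # fails c6
    return records, genotypes, occurrences, expected
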