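"""Private germline variant classification and PTV calling.

Because high-penetrance predisposition alleles in a rare-disease cohort are
expected to be individually rare, the analysis centres on *private*
variants: coding variants passing six criteria simultaneously —

1. consequence class in a configurable whitelist (truncating classes, plus
   missense by default);
2. heterozygous in the germline;
3. alternate-allele frequency below 0.5% in both population databases;
4. present in exactly one patient of the cohort (singleton);
5. mappability strictly greater than 0.5;
6. a unique genomic locus (single BLAT-style placement).

Premature truncating variants (PTVs) are the frameshift-indel, nonsense,
and splice-site subset of consequences.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GenotypeCall, ReferenceGenome, VariantKey, VariantRecord
from .stats import percent

__all__ = [
    "CONSEQUENCE_CLASSES",
    "PTV_CLASSES",
    "DEFAULT_WHITELIST",
    "GeneModel",
    "PrivateVariantCall",
    "classify_consequence",
    "is_ptv",
    "classify_private",
    "gene_frequency",
]

CONSEQUENCE_CLASSES = (
    "nonsense",
    "splice_site",
    "frameshift_indel",
    "inframe_indel",
    "missense",
    "synonymous",
    "other",
)
PTV_CLASSES = frozenset({"nonsense", "splice_site", "frameshift_indel"})
# Whitelist for criterion 1. Truncating classes plus missense by default:
# the cohort's reported private variants include missense alterations, so
# the default is permissive; a strict truncating-only whitelist is
# available by passing PTV_CLASSES.
DEFAULT_WHITELIST = frozenset(PTV_CLASSES | {"missense"})

MAF_CUTOFF = 0.005
MAPPABILITY_CUTOFF = 0.5

SPLICE_WINDOW = 2  # bases of intron adjacent to an exon boundary


@dataclass
class _Gene:
    name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int, int]]  # (start0, end0, frame), genomic order

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


class GeneModel:
    """CDS exon intervals with strand and frame, per gene.

    Loaded from a BED-like TSV with columns chrom, start, end, gene,
    strand, frame — 0-based half-open intervals, frame being the CDS phase
    of the exon's first transcribed base (0, 1, or 2). Exons of a gene must
    not overlap; genes may not overlap each other on a contig.
    """

    def __init__(self, genes: list[_Gene]):
        self.genes = {g.name: g for g in genes}
        self._by_chrom: dict[str, tuple[list[int], list[_Gene]]] = {}
        grouped: dict[str, list[_Gene]] = {}
        for g in genes:
            grouped.setdefault(g.chrom, []).append(g)
        for chrom, gs in grouped.items():
            gs.sort(key=lambda g: g.start)
            self._by_chrom[chrom] = ([g.start for g in gs], gs)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModel":
        rows: dict[str, list[tuple[str, int, int, str, str]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: expected 6 columns (chrom start end gene strand frame)")
                chrom, start, end, gene, strand, frame = parts[:6]
                rows.setdefault(gene, []).append((chrom, int(start), int(end), strand, frame))
        genes = []
        for name, exon_rows in rows.items():
            chroms = {r[0] for r in exon_rows}
            strands = {r[3] for r in exon_rows}
            if len(chroms) != 1 or len(strands) != 1:
                raise ValueError(f"gene {name}: exons span multiple contigs or strands")
            strand = strands.pop()
            if strand not in ("+", "-"):
                raise ValueError(f"gene {name}: missing or invalid strand {strand!r}")
            exons = sorted((r[1], r[2], r[4]) for r in exon_rows)
            parsed = []
            for s, e, f in exons:
                if f in (".", ""):
                    raise ValueError(f"gene {name}: CDS exon at {s} lacks a frame")
                parsed.append((s, e, int(f)))
            genes.append(_Gene(name, chroms.pop(), strand, parsed))
        model = cls(genes)
        model._validate_frames()
        return model

    def _validate_frames(self) -> None:
        for g in self.genes.values():
            offset = 0
            for s, e, f in g.exons if g.strand == "+" else reversed(g.exons):
                if f != offset % 3:
                    raise ValueError(
                        f"gene {g.name}: exon at {s} declares frame {f}, expected {offset % 3}"
                    )
                offset += e - s

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> list[_Gene]:
        if chrom not in self._by_chrom:
            return []
        starts, gs = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, end0)
        hits = []
        for g in gs[max(0, i - len(gs)):i]:
            if g.end > start0 and g.start < end0:
                hits.append(g)
        return hits

    # --- transcript-coordinate machinery -------------------------------

    def _transcript_exons(self, g: _Gene) -> list[tuple[int, int, int]]:
        return g.exons if g.strand == "+" else list(reversed(g.exons))

    def cds_length(self, gene: str) -> int:
        g = self.genes[gene]
        return sum(e - s for s, e, _ in g.exons)

    def cds_offset(self, g: _Gene, pos0: int) -> int | None:
        """0-based offset of genomic position pos0 in the spliced CDS."""
        offset = 0
        for s, e, _ in self._transcript_exons(g):
            if s <= pos0 < e:
                return offset + (pos0 - s if g.strand == "+" else e - 1 - pos0)
            offset += e - s
        return None

    def genomic_position(self, g: _Gene, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        offset = cds_offset
        for s, e, _ in self._transcript_exons(g):
            if offset < e - s:
                return s + offset if g.strand == "+" else e - 1 - offset
            offset -= e - s
        raise IndexError(f"CDS offset {cds_offset} beyond gene {g.name}")

    def codon_at(self, g: _Gene, cds_offset: int, reference: ReferenceGenome) -> str:
        """The transcript-orientation codon containing ``cds_offset``."""
        codon_start = (cds_offset // 3) * 3
        bases = []
        for i in range(3):
            p = self.genomic_position(g, codon_start + i)
            b = reference.fetch(g.chrom, p, p + 1)
            bases.append(b if g.strand == "+" else _COMPLEMENT[b])
        return "".join(bases)

    def splice_positions(self, g: _Gene) -> set[int]:
        """Intronic positions within SPLICE_WINDOW of an exon boundary."""
        pos: set[int] = set()
        for (s1, e1, _), (s2, e2, _) in zip(g.exons, g.exons[1:]):
            for k in range(1, SPLICE_WINDOW + 1):
                pos.add(e1 + k - 1)   # donor side of the intron
                pos.add(s2 - k)       # acceptor side
        return pos


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_consequence(
    key: VariantKey, gene_model: GeneModel, reference: ReferenceGenome
) -> tuple[str, str]:
    """Assign (gene, consequence class) to a normalized variant.

    Rules: an indel whose affected span overlaps CDS is frameshift or
    in-frame by length change mod 3; an SNV in CDS is classified by codon
    translation (nonsense when the alternate codon is a stop and the
    reference codon is not); a variant in the first or last two intronic
    bases flanking an internal exon boundary is splice_site; everything
    else is other. Variants outside every gene return ("", "other").
    """
    start0 = key.pos - 1
    end0 = start0 + len(key.ref)
    genes = gene_model.genes_overlapping(key.chrom, start0 - SPLICE_WINDOW, end0 + SPLICE_WINDOW)
    if not genes:
        return "", "other"
    g = genes[0]
    in_cds = any(
        gene_model.cds_offset(g, p) is not None for p in range(start0, end0)
    )
    splice = gene_model.splice_positions(g)
    touches_splice = any(p in splice for p in range(start0, end0))

    if key.length_change != 0:  # indel
        if in_cds:
            return g.name, "frameshift_indel" if key.length_change % 3 else "inframe_indel"
        if touches_splice:
            return g.name, "splice_site"
        return g.name, "other"

    if key.is_snv:
        off = gene_model.cds_offset(g, start0)
        if off is not None:
            ref_codon = gene_model.codon_at(g, off, reference)
            within = off % 3
            alt_base = key.alt if g.strand == "+" else _COMPLEMENT[key.alt]
            alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
            if alt_codon in _STOPS and ref_codon not in _STOPS:
                return g.name, "nonsense"
            if _translate(alt_codon) == _translate(ref_codon):
                return g.name, "synonymous"  # includes stop-retained changes
            if ref_codon in _STOPS:
                return g.name, "other"  # stop-loss, outside the PTV classes
            return g.name, "missense"
        if touches_splice:
            return g.name, "splice_site"
        return g.name, "other"

    # equal-length multi-base substitution: not classified further
    return g.name, "other"


def is_ptv(consequence: str) -> bool:
    """True for the premature-truncating classes: frameshift, nonsense, splice."""
    if consequence not in CONSEQUENCE_CLASSES:
        raise ValueError(f"unknown consequence class {consequence!r}")
    return consequence in PTV_CLASSES


@dataclass
class PrivateVariantCall:
    """Per-variant verdict with one flag per criterion.

    ``is_private`` is, by construction, the conjunction of the six flags.
    """

    record: VariantRecord
    genotype: GenotypeCall
    c1_consequence: bool
    c2_het: bool
    c3_rare: bool
    c4_singleton: bool
    c5_mappable: bool
    c6_unique: bool

    @property
    def flags(self) -> tuple[bool, ...]:
        return (
            self.c1_consequence,
            self.c2_het,
            self.c3_rare,
            self.c4_singleton,
            self.c5_mappable,
            self.c6_unique,
        )

    @property
    def is_private(self) -> bool:
        return all(self.flags)


def classify_private(
    record: VariantRecord,
    genotype: GenotypeCall,
    cohort_occurrence_count: int,
    consequence_whitelist: frozenset[str] | set[str] = DEFAULT_WHITELIST,
    maf_cutoff: float = MAF_CUTOFF,
    maf_mode: str = "and",
    mappability_cutoff: float = MAPPABILITY_CUTOFF,
) -> PrivateVariantCall:
    """Evaluate the six private-variant criteria for one germline call.

    ``maf_mode="and"`` (default) requires rarity in both population
    databases; ``"or"`` requires rarity in at least one. The mappability
    cutoff is strict (a score exactly at the cutoff fails).
    """
    if cohort_occurrence_count < 1:
        raise ValueError("cohort_occurrence_count must be >= 1")
    if maf_mode not in ("and", "or"):
        raise ValueError("maf_mode must be 'and' or 'or'")
    for field_name in ("maf_db1", "maf_db2", "mappability", "unique_locus", "consequence"):
        if getattr(record, field_name, None) is None:
            raise ValueError(f"record {record.key} missing annotation {field_name}")
    rare1 = record.maf_db1 < maf_cutoff
    rare2 = record.maf_db2 < maf_cutoff
    return PrivateVariantCall(
        record=record,
        genotype=genotype,
        c1_consequence=record.consequence in consequence_whitelist,
        c2_het=genotype.zygosity == "het",
        c3_rare=(rare1 and rare2) if maf_mode == "and" else (rare1 or rare2),
        c4_singleton=cohort_occurrence_count == 1,
        c5_mappable=record.mappability > mappability_cutoff,
        c6_unique=bool(record.unique_locus),
    )


def gene_frequency(
    private_calls: list[tuple[str, PrivateVariantCall]], cohort_size: int
) -> pd.DataFrame:
    """Per-gene carrier counts over the cohort.

    ``private_calls`` pairs each call with its patient id; only calls with
    ``is_private`` contribute, and a patient counts at most once per gene
    regardless of how many qualifying variants they carry.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    carriers: dict[str, set[str]] = {}
    for patient_id, call in private_calls:
        if call.is_private and call.record.gene:
            carriers.setdefault(call.record.gene, set()).add(patient_id)
    rows = [
        (gene, len(pats), cohort_size, percent(len(pats), cohort_size))
        for gene, pats in sorted(carriers.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "carrier_count", "cohort_size", "percent"])
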