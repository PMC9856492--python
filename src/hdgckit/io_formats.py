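"""Standard-format I/O and variant-representation normalization.

All downstream modules key variants by :class:`VariantKey`, so every entry
point that reads variants (VCFs, population-frequency tables) normalizes the
representation on load: left-aligned and parsimonious, with the single
anchor base retained for indels. Coordinate conventions: VCF records are
1-based inclusive, BED-like tracks are 0-based half-open; conversions happen
only here, at the I/O boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF
from pyfaidx import Fasta

__all__ = [
    "VariantKey",
    "VariantRecord",
    "GenotypeCall",
    "PairedCall",
    "RegionTrack",
    "ReferenceGenome",
    "FrequencyTable",
    "NormalizationError",
    "VcfFormatError",
    "normalize_variant",
    "read_paired_vcfs",
    "read_frequency_table",
    "write_vcf",
]

ZYGOSITIES = ("hom_ref", "het", "hom_alt", "missing")


class NormalizationError(ValueError):
    """Raised when a variant cannot be normalized against the reference."""


class VcfFormatError(ValueError):
    """Raised on malformed or unsupported VCF content."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized bi-allelic variant identity.

    ``pos`` is the 1-based position of the first reference base. The
    representation invariant (left-aligned, parsimonious) is established by
    :func:`normalize_variant`; the constructor only checks basic sanity.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele in {self.chrom}:{self.pos} {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos} ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantRecord:
    """A variant plus the annotations the private-variant criteria consume.

    ``maf_db1``/``maf_db2`` play the roles of the two population frequency
    databases (1000 Genomes-like and Chinese Millionome-like); absent
    entries default to 0.0 (a novel variant is rare). ``unique_locus`` is
    the BLAT-style single-placement flag.
    """

    key: VariantKey
    gene: str = ""
    consequence: str = "other"
    maf_db1: float = 0.0
    maf_db2: float = 0.0
    mappability: float = 1.0
    unique_locus: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_db1", "maf_db2", "mappability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] for {self.key}")


@dataclass
class GenotypeCall:
    """Per-sample genotype with read support."""

    sample_id: str
    zygosity: str
    depth: int = 0
    alt_depth: int = 0

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.depth < 0 or self.alt_depth < 0 or self.alt_depth > self.depth:
            raise ValueError(
                f"bad depths for {self.sample_id}: alt {self.alt_depth} / total {self.depth}"
            )

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction, or None when depth is zero."""
        if self.depth == 0:
            return None
        return self.alt_depth / self.depth


@dataclass
class PairedCall:
    """One variant with its germline call and (possibly absent) tumor call."""

    key: VariantKey
    germline: GenotypeCall | None
    tumor: GenotypeCall | None

    @property
    def somatic_only(self) -> bool:
        return self.germline is None


class ReferenceGenome:
    """Thin contig-sequence accessor over an indexed FASTA.

    ``fetch(chrom, start0, end0)`` returns the uppercase sequence of the
    0-based half-open interval.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def contigs(self) -> list[str]:
        return list(self._fasta.keys())

    def contig_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"unknown contig {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        if chrom not in self._fasta:
            raise KeyError(f"unknown contig {chrom!r}")
        if start0 < 0 or end0 > len(self._fasta[chrom]) or start0 > end0:
            raise ValueError(f"interval {chrom}:{start0}-{end0} out of bounds")
        return str(self._fasta[chrom][start0:end0])


def normalize_variant(key: VariantKey, reference: ReferenceGenome) -> VariantKey:
    """Return the left-aligned, parsimonious representation of ``key``.

    Implements the usual trim-and-extend normalization: shared trailing
    bases are trimmed (extending left from the reference whenever an allele
    would empty), then shared leading bases beyond the single anchor base
    are dropped. Idempotent, and position-minimal among all representations
    describing the same allelic change.
    """
    chrom, pos, ref, alt = key.chrom, key.pos, key.ref, key.alt
    n = reference.contig_length(chrom)
    if pos + len(ref) - 1 > n:
        raise NormalizationError(f"{chrom}:{pos} ref allele runs off contig end")
    observed = reference.fetch(chrom, pos - 1, pos - 1 + len(ref))
    if observed != ref.upper():
        raise NormalizationError(
            f"reference mismatch at {chrom}:{pos}: VCF says {ref!r}, FASTA has {observed!r}"
        )
    ref = ref.upper()
    alt = alt.upper()

    while True:
        if ref[-1] == alt[-1] and len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1]:
            if pos == 1:
                raise NormalizationError(
                    f"cannot left-extend past start of contig at {chrom}:{pos}"
                )
            prev = reference.fetch(chrom, pos - 2, pos - 1)
            ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return VariantKey(chrom, pos, ref, alt)


class RegionTrack:
    """Non-overlapping valued intervals per contig (mappability, uniqueness).

    Intervals are 0-based half-open. Lookup of a position not covered by any
    interval returns ``default``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]], default: float = 0.0):
        self.default = default
        self._by_chrom: dict[str, tuple[list[int], list[int], list[float]]] = {}
        grouped: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            grouped.setdefault(chrom, []).append((start, end, value))
        for chrom, ivs in grouped.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping intervals on {chrom} near {s2}")
            starts, ends, values = zip(*ivs)
            self._by_chrom[chrom] = (list(starts), list(ends), list(values))

    @classmethod
    def from_bed(cls, path: str | Path, default: float = 0.0) -> "RegionTrack":
        """Load a BED4+ file: chrom, start, end, value."""
        ivs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected at least 4 columns")
                ivs.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        return cls(ivs, default=default)

    def value_at(self, chrom: str, pos0: int) -> float:
        if chrom not in self._by_chrom:
            return self.default
        starts, ends, values = self._by_chrom[chrom]
        i = bisect.bisect_right(starts, pos0) - 1
        if i >= 0 and pos0 < ends[i]:
            return values[i]
        return self.default

    def min_over(self, chrom: str, start0: int, end0: int) -> float:
        """Minimum track value over every base of [start0, end0)."""
        return min(self.value_at(chrom, p) for p in range(start0, end0))


class FrequencyTable:
    """Population allele frequencies keyed by normalized variant.

    Lookups of variants absent from the table return ``(0.0, 0.0)``: a
    variant never catalogued is treated as rare, which is what lets novel
    private variants through the rarity criterion.
    """

    def __init__(self, entries: dict[VariantKey, tuple[float, float]]):
        self._entries = entries

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, key: VariantKey) -> tuple[float, float]:
        return self._entries.get(key, (0.0, 0.0))


def read_frequency_table(path: str | Path, reference: ReferenceGenome | None = None) -> FrequencyTable:
    """Read a TSV of chrom, pos, ref, alt, freq1, freq2 (header optional).

    Keys are normalized on load when a reference is supplied, so an
    un-normalized row and its normalized twin resolve to the same entry.
    """
    entries: dict[VariantKey, tuple[float, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chrom":
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns")
            f1, f2 = float(parts[4]), float(parts[5])
            if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
                raise ValueError(f"{path}:{ln}: frequency outside [0, 1]")
            key = VariantKey(parts[0], int(parts[1]), parts[2], parts[3])
            if reference is not None:
                key = normalize_variant(key, reference)
            entries[key] = (f1, f2)
    return FrequencyTable(entries)


def _zygosity_for_alt(gt: Sequence[int], alt_index: int) -> str:
    """Map a diploid GT allele-index pair to a zygosity for one alt allele."""
    alleles = [a for a in gt if a is not None and a >= 0]
    if len(alleles) < 2:
        return "missing"
    copies = sum(1 for a in alleles if a == alt_index)
    if copies == 0:
        return "hom_ref"
    if copies >= 2:
        return "hom_alt"
    return "het"


def _read_single_sample_vcf(
    path: str | Path, reference: ReferenceGenome | None
) -> tuple[str, dict[VariantKey, GenotypeCall]]:
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise VcfFormatError(f"{path}: expected exactly 1 sample, found {len(vcf.samples)}")
    sample = vcf.samples[0]
    calls: dict[VariantKey, GenotypeCall] = {}
    for rec in vcf:
        gts = rec.genotypes
        if gts is None or not gts:
            raise VcfFormatError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GT")
        gt = gts[0][:-1]  # last element is phasing flag
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        # split multi-allelic records into bi-allelic keys
        for alt_i, alt in enumerate(rec.ALT, start=1):
            if alt in ("*", "<NON_REF>") or alt.startswith("<"):
                continue
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, alt)
            if reference is not None:
                key = normalize_variant(key, reference)
            zyg = _zygosity_for_alt(gt, alt_i)
            alt_depth = 0
            depth = 0
            if ad is not None:
                row = ad[0]
                alt_depth = max(int(row[alt_i]), 0) if alt_i < len(row) else 0
                depth = int(sum(max(int(x), 0) for x in row))
            if dp is not None:
                depth = max(depth, int(dp[0][0]))
            calls[key] = GenotypeCall(sample, zyg, depth=depth, alt_depth=min(alt_depth, depth))
    return sample, calls


def read_paired_vcfs(
    germline_path: str | Path,
    tumor_path: str | Path,
    reference: ReferenceGenome | None = None,
) -> list[PairedCall]:
    """Read a germline/tumor VCF pair into per-variant paired calls.

    The result is the union of both files' variants, keyed by normalized
    representation: variants absent from the tumor carry ``tumor=None``,
    tumor-only variants carry ``germline=None`` and are flagged somatic.
    Each file must contain exactly one sample with a GT field and AD
    (and/or DP) depths.
    """
    _, germ = _read_single_sample_vcf(germline_path, reference)
    _, tum = _read_single_sample_vcf(tumor_path, reference)
    keys = sorted(set(germ) | set(tum))
    return [PairedCall(k, germ.get(k), tum.get(k)) for k in keys]


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
"""

_GT_FOR_ZYG = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf(
    path: str | Path,
    sample_id: str,
    calls: Iterable[tuple[VariantKey, GenotypeCall]],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write bi-allelic VCF 4.2 records with GT:AD:DP for one sample.

    Records are sorted by (chrom, pos). Intended for the synthetic-data
    generator and for round-tripping subsets; reading always goes through
    :func:`read_paired_vcfs`.
    """
    rows = sorted(calls, key=lambda kc: (kc[0].chrom, kc[0].pos, kc[0].ref, kc[0].alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for key, call in rows:
            gt = _GT_FOR_ZYG[call.zygosity]
            ref_depth = call.depth - call.alt_depth
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ref_depth},{call.alt_depth}:{call.depth}\n"
            )
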