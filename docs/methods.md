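# Methods

Precise definitions and conventions used by `hdgckit`. All coordinates
follow the source formats: VCF positions are 1-based, BED intervals are
0-based half-open. Internally, `VariantKey.pos` is the 1-based VCF position.

## Variant representation and normalization

A variant is the tuple (chrom, pos, ref, alt) with `ref != alt` and
`pos >= 1`. `normalize_variant` converts any representation to its
left-aligned, parsimonious form:

1. While ref and alt end in the same base, trim the trailing base; if either
   allele would become empty, prepend the reference base to the left and
   decrement the position.
2. While ref and alt begin with the same base and both retain at least two
   bases, trim the leading base and increment the position.

The fixed point is unique; on indels it equals the minimum-position
parsimonious representation (tested against a brute-force enumeration
oracle). Frequency-table keys are normalized on load, so differently spelled
equivalent indels match.

## Paired VCF reading

`read_paired_vcfs` reads one single-sample germline VCF and one
single-sample tumor VCF (cyvcf2), splits multi-allelic records, normalizes
each allele, and joins germline and tumor calls by variant key. Genotypes
map to zygosity via the GT allele indices; depth and alternate depth come
from FORMAT `DP`/`AD` when present. VAF = alt_depth / depth, undefined at
zero depth.

## HDGC eligibility

`classify_hdgc` evaluates four conditions from the family-history table
(relatives' diagnoses, ages, and histological confirmation) and the
patient's own diagnosis:

1. ≥ 2 gastric-cancer cases in the family **and** ≥ 1 confirmed diffuse
   gastric cancer diagnosed before 50 (`condition1_mode="combined"`,
   default). `"either"` treats the two clauses as alternatives.
2. Bilateral or familial lobular breast cancer before 50.
3. Diffuse gastric cancer diagnosed before 40.
4. Personal or family history of both diffuse gastric cancer and lobular
   breast cancer.

A patient is eligible when any condition is met; `cohort_composition`
tabulates age, sex, family history, conditions, stage, and EBV status with
one-decimal percentages.

## Consequence classes and PTVs

Gene models are exon BED files (chrom, start, end, gene, strand, frame); the
frame column is validated against cumulative coding sequence (CDS) length.
For an SNV inside the CDS, the affected codon is translated
(Biopython) before and after substitution:

- new stop codon → `nonsense`;
- unchanged amino acid (including a retained stop) → `synonymous`;
- lost stop → `other`;
- changed amino acid → `missense`.

Coding indels are `frameshift_indel` when the length change is not a
multiple of 3, else `inframe_indel`. Positions within ±2 bp of an intron
boundary are `splice_site`; everything else is `other`. PTV =
{`frameshift_indel`, `nonsense`, `splice_site`}.

## Private-variant criteria

`classify_private` evaluates six flags and conjoins them:

1. consequence in the whitelist (default: PTV classes plus `missense`; a
   strict PTV-only whitelist is available);
2. heterozygous germline genotype;
3. MAF < 0.005 in **both** population databases (strict inequality; an
   `"or"` mode requires only one database);
4. cohort singleton: the variant is carried by exactly one patient;
5. mappability > 0.5 (strict) over the variant span;
6. unique locus (uniqueness track > 0.5 over the span).

The flags are reported individually so every rejection is attributable to
its criterion. `gene_frequency` collapses calls to one carrier per patient
per gene and reports one-decimal carrier percentages.

## LOH and double hits

LOH segments per tumor are maximal runs of consecutive informative
germline-het sites (tumor depth ≥ 10) with |VAF − 0.5| ≥ 0.25; runs with
≥ 5 such sites become segments. Sites below the depth cutoff are skipped
without terminating a run; an informative balanced site terminates it.

A double hit is a private heterozygous germline variant whose tumor call
satisfies any of:

- `genotype_homozygous`: tumor genotype hom-alt;
- `vaf_threshold`: tumor VAF ≥ 0.9 at depth ≥ 10;
- `loh_overlap`: position inside an LOH segment of the same tumor with
  VAF > 0.5 (alternate allele retained).

Each event records its evidence set; a (patient, variant) pair yields at
most one event. Summaries report the number of event-bearing patients and
the share carrying one or two events. The copy-number `gene_gscore` is the
surrogate frequency × mean |log2 ratio| of segments exceeding ±0.3,
computed per gene; it is deliberately not a reimplementation of GISTIC.

## SBS-96 catalogs and refitting

Single-base substitutions are keyed by the pyrimidine of the Watson–Crick
pair and its 5'/3' context; purine-reference SNVs are reverse-complemented.
Category index = 16·substitution + 4·five-prime + three-prime over the
orderings C>A, C>G, C>T, T>A, T>C, T>G and A, C, G, T. Exposures are fit per
sample by non-negative least squares (`scipy.optimize.nnls`) on the
count-normalized catalog and renormalized to sum to 1; the reconstruction
cosine compares the refit spectrum to the raw counts. The dominant signature
is the highest-weight signature (lexicographic tie-break). Exposure vectors
are clustered with k-means (`n_init=10`, seeded) for k ∈ {3, 4, 5}.

## Statistics

- `percent(count, total)`: 100·count/total rounded half away from zero to
  one decimal.
- Fisher's exact test: exact two-sided small-p-values method
  (`scipy.stats.fisher_exact`), verified against exhaustive hypergeometric
  enumeration for all tables with total ≤ 40.
- Test choice: Fisher when any expected cell count is < 5, else χ² without
  continuity correction.
- FDR: Benjamini–Hochberg step-up (`statsmodels multipletests`).
- Survival: Kaplan–Meier product-limit estimator with exponential-Greenwood
  confidence intervals and the log-rank test (lifelines).

## Synthetic cohorts

`hdgckit.synthetic.generate` writes a complete bundle from a single seed
(`numpy.random.default_rng`): a random reference, two-exon gene models on
both strands, per-gene carrier rates (a rare CDH1-like gene at 0.028, a
common MUC4-like gene at 0.187, background genes at 0.06), planted private
variants (60% PTV), decoys violating exactly one criterion each (including
boundary values MAF = 0.005 and mappability = 0.5), double-hit anchors with
surrounding LOH regions and intergenic het support sites, common
Hardy–Weinberg population variants, somatic SNVs drawn from three
low-overlap toy signatures, and clinical tables reproducing the modeled
cohort's condition mix, sex ratio, EBV mix, stage distribution, and
exponential survival with 5-year survival 0.614. Read depths are Poisson
(mean 80) with binomial allele sampling; `read_noise=False` emits exact
counts. Truth tables record every planted private variant (with expected
criterion flags), double hit, LOH region, exposure vector, and per-gene
carrier count; `verify_truth` re-reads the emitted files and cross-checks
them against the truth tables.
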